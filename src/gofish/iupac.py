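"""IUPAC nucleotide alphabet helpers shared across the package.

All sequences are handled 5'->3' as uppercase strings over the IUPAC DNA
alphabet; ``-`` is the only gap character and only appears in alignments.
"""

from __future__ import annotations

from itertools import product

#: IUPAC code -> set of concrete bases it covers.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: set of concrete bases (frozenset) -> IUPAC code, inverse of IUPAC_SETS.
SET_TO_CODE: dict[frozenset[str], str] = {v: k for k, v in IUPAC_SETS.items()}

DNA_ALPHABET = frozenset(IUPAC_SETS)
GAP = "-"

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def complement(seq: str) -> str:
    """Position-wise complement (no reversal)."""
    return seq.translate(_COMPLEMENT)


def revcomp(seq: str) -> str:
    """Reverse complement of an IUPAC DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def is_concrete(seq: str) -> bool:
    """True if *seq* contains only A/C/G/T."""
    return all(b in "ACGT" for b in seq)


def degeneracy(seq: str) -> int:
    """Number of concrete sequences a degenerate string expands to."""
    n = 1
    for b in seq:
        n *= len(IUPAC_SETS[b])
    return n


def expand_degenerate(seq: str, limit: int | None = None) -> list[str]:
    """All concrete expansions of *seq*, in lexicographic order.

    Parameters
    ----------
    seq:
        IUPAC DNA string (no gaps).
    limit:
        If given, raise ``ValueError`` when the expansion count exceeds it.
    """
    for i, b in enumerate(seq):
        if b not in IUPAC_SETS:
            raise ValueError(f"illegal IUPAC character {b!r} at position {i}")
    count = degeneracy(seq)
    if limit is not None and count > limit:
        raise ValueError(
            f"degenerate expansion of {seq!r} yields {count} sequences, "
            f"exceeding limit {limit}"
        )
    pools = [sorted(IUPAC_SETS[b]) for b in seq]
    return ["".join(p) for p in product(*pools)]


def code_for(bases: set[str] | frozenset[str]) -> str:
    """IUPAC code covering exactly *bases* (e.g. {A,G} -> R)."""
    return SET_TO_CODE[frozenset(bases)]
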