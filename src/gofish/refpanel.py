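"""Reference 12S sequence panels and alignments.

A :class:`ReferencePanel` is the universe against which assay specificity is
judged: taxon-labelled mitochondrial 12S segments for the species that could
plausibly contribute eDNA to a sample. FASTA headers follow the convention
``id|taxon|common_name|group`` with trailing fields optional; records lacking
a taxon fall back to ``taxon = id`` so a panel is always taxon-indexable.

Coordinates are 0-based half-open everywhere in this package; 1-based
inclusive coordinates appear only in human-readable reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .iupac import DNA_ALPHABET, GAP

GROUPS = ("bony_fish", "cartilaginous_fish", "mammal", "other")


@dataclass
class ReferenceSequence:
    """One taxon-labelled reference sequence (uppercase IUPAC DNA, no gaps)."""

    id: str
    taxon: str
    sequence: str
    common_name: str = ""
    group: str = "other"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        for pos, base in enumerate(self.sequence):
            if base not in DNA_ALPHABET:
                raise ValueError(
                    f"record {self.id!r}: illegal character {base!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


class ReferencePanel:
    """Ordered collection of :class:`ReferenceSequence` with a taxon index."""

    def __init__(self, records: list[ReferenceSequence]):
        ids = [r.id for r in records]
        dups = {i for i in ids if ids.count(i) > 1}
        if dups:
            raise ValueError(f"duplicate record id(s): {sorted(dups)}")
        self.records: list[ReferenceSequence] = list(records)
        self.by_id: dict[str, ReferenceSequence] = {r.id: r for r in records}
        self.by_taxon: dict[str, list[ReferenceSequence]] = {}
        for r in records:
            self.by_taxon.setdefault(r.taxon, []).append(r)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def taxa(self) -> list[str]:
        """Taxa in first-appearance order."""
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.taxon)
        return list(seen)

    def summary_frame(self) -> pd.DataFrame:
        """Panel summary table (id, taxon, common name, group, length)."""
        return pd.DataFrame(
            [
                {
                    "id": r.id,
                    "taxon": r.taxon,
                    "common_name": r.common_name,
                    "group": r.group,
                    "length": len(r),
                }
                for r in self.records
            ]
        )


def _normalise(seq: str) -> str:
    return seq.upper().replace("U", "T")


def _parse_header(header: str) -> tuple[str, str, str, str]:
    parts = header.split("|")
    rec_id = parts[0].strip()
    taxon = parts[1].strip() if len(parts) > 1 and parts[1].strip() else rec_id
    common = parts[2].strip() if len(parts) > 2 else ""
    group = parts[3].strip() if len(parts) > 3 and parts[3].strip() else "other"
    return rec_id, taxon, common, group


def read_fasta(path: str | Path) -> ReferencePanel:
    """Read a reference panel from FASTA (headers ``id|taxon|common|group``).

    Sequences are uppercased and U is normalised to T; order is preserved.
    Raises ``ValueError`` on an empty file, duplicate ids, or characters
    outside the IUPAC DNA alphabet.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        rec_id, taxon, common, group = _parse_header(rec.description)
        records.append(
            ReferenceSequence(
                id=rec_id,
                taxon=taxon,
                common_name=common,
                group=group,
                sequence=_normalise(str(rec.seq)),
            )
        )
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return ReferencePanel(records)


def write_fasta(panel: ReferencePanel, path: str | Path) -> None:
    """Write a panel back to FASTA with the ``id|taxon|common|group`` header."""
    with open(path, "w") as fh:
        for r in panel:
            fh.write(f">{r.id}|{r.taxon}|{r.common_name}|{r.group}\n")
            for i in range(0, len(r.sequence), 70):
                fh.write(r.sequence[i : i + 70] + "\n")


@dataclass
class Alignment:
    """Gapped equal-length rows keyed by id; gap character is ``-``."""

    rows: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {rid: len(s) for rid, s in self.rows.items()}
        if len(set(lengths.values())) > 1:
            raise ValueError(f"rows have unequal lengths: {lengths}")

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    @property
    def ids(self) -> list[str]:
        return list(self.rows)

    def __len__(self) -> int:
        return len(self.rows)

    def column(self, j: int) -> list[str]:
        return [s[j] for s in self.rows.values()]

    def ungapped(self, rid: str) -> str:
        return self.rows[rid].replace(GAP, "")


def read_alignment(path: str | Path) -> Alignment:
    """Read an aligned FASTA file; rows must all have the same length.

    The full header line (id plus any ``|``-separated annotation) keys the
    row by its first ``|`` field, matching :func:`read_fasta`.
    """
    rows: dict[str, str] = {}
    lengths: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        rec_id = _parse_header(rec.description)[0]
        if rec_id in rows:
            raise ValueError(f"duplicate row id {rec_id!r}")
        seq = _normalise(str(rec.seq))
        rows[rec_id] = seq
        lengths[rec_id] = len(seq)
    if not rows:
        raise ValueError(f"no FASTA records found in {path}")
    if len(set(lengths.values())) > 1:
        modal = max(set(lengths.values()), key=list(lengths.values()).count)
        bad = sorted(rid for rid, n in lengths.items() if n != modal)
        raise ValueError(f"unequal row lengths; offending ids: {bad}")
    return Alignment(rows)


def write_alignment(a: Alignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq in a.rows.items():
            fh.write(f">{rid}\n{seq}\n")


def extract_region(a: Alignment, start: int, end: int) -> Alignment:
    """Sub-alignment over columns [start, end), 0-based half-open."""
    if not (0 <= start < end <= a.length):
        raise ValueError(
            f"region [{start}, {end}) out of range for alignment of length {a.length}"
        )
    return Alignment({rid: seq[start:end] for rid, seq in a.rows.items()})
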