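"""Degenerate-aware primer-site search and virtual (nested) PCR.

Binding sites are reported in sense-strand coordinates (0-based half-open).
An amplicon spans from the forward primer's 5' start to the sense-strand
position complementary to the reverse primer's 5' start, inclusive of both
primer footprints — the "length including primers" convention of published
assay tables. Sequencing tails never anneal and never count toward length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .iupac import revcomp
from .refpanel import ReferencePanel
from .thermo import Oligo, audit_site, paired_template

__all__ = ["BindingSite", "Amplicon", "find_binding_sites", "virtual_pcr", "nested_virtual_pcr"]


@dataclass(frozen=True)
class BindingSite:
    """A primer annealing site on a reference, in sense-strand coordinates."""

    ref_id: str
    strand: str  # '+' (primer matches sense strand) or '-' (matches antisense)
    start: int
    end: int
    total_mismatches: int
    penalized_3p: int

    @property
    def five_prime(self) -> int:
        """Sense-strand coordinate of the primer's 5' end (half-open on '-')."""
        return self.start if self.strand == "+" else self.end


@dataclass(frozen=True)
class Amplicon:
    """A virtual PCR product; sequence is template-derived, not primer-corrected."""

    ref_id: str
    start: int
    end: int
    sequence: str
    fwd_site: BindingSite
    rev_site: BindingSite
    outer: "Amplicon | None" = field(default=None, compare=False)

    @property
    def length_incl_primers(self) -> int:
        return self.end - self.start

    def __post_init__(self) -> None:
        if len(self.sequence) != self.end - self.start:
            raise ValueError("amplicon sequence length does not match coordinates")


def _core_of(primer: Oligo | str) -> str:
    return primer.core if isinstance(primer, Oligo) else primer


def find_binding_sites(
    primer: Oligo | str,
    panel: ReferencePanel,
    max_total: int | None = None,
    max_3p_penalized: int | None = None,
    window: int = 5,
) -> list[BindingSite]:
    """All binding sites of *primer* (core only) on both strands of *panel*.

    A degenerate primer position matches any of its expansions at zero cost;
    mismatches are classified with permissive-wobble semantics and wobbles
    never count as penalized. ``max_total``/``max_3p_penalized`` of ``None``
    disable the respective threshold (report everything at every offset that
    meets the other threshold).
    """
    core = _core_of(primer)
    k = len(core)
    if window > k:
        raise ValueError(f"window {window} exceeds primer length {k}")
    sites: list[BindingSite] = []
    for rec in panel:
        seq = rec.sequence
        for start in range(0, len(seq) - k + 1):
            segment = seq[start : start + k]
            for strand in ("+", "-"):
                total, pen3, _ = audit_site(core, paired_template(segment, strand), window)
                if max_total is not None and total > max_total:
                    continue
                if max_3p_penalized is not None and pen3 > max_3p_penalized:
                    continue
                sites.append(
                    BindingSite(rec.id, strand, start, start + k, total, pen3)
                )
    sites.sort(key=lambda s: (s.ref_id, s.start, s.strand))
    return sites


def virtual_pcr(
    panel: ReferencePanel,
    fwd: Oligo | str,
    rev: Oligo | str,
    min_len: int = 50,
    max_len: int = 2000,
    max_total: int | None = 3,
    max_3p_penalized: int | None = 0,
    window: int = 3,
) -> list[Amplicon]:
    """Virtual PCR of a primer pair over a reference panel.

    Both primers are given 5'->3' as synthesized; a product forms for every
    properly oriented pair of binding sites whose span (inclusive of both
    primer footprints) is within [min_len, max_len]. Products priming off the
    antisense strand (forward site on '-') are reported in sense coordinates
    with their site strands flipped.
    """
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    fwd_sites = find_binding_sites(fwd, panel, max_total, max_3p_penalized, window)
    rev_sites = find_binding_sites(rev, panel, max_total, max_3p_penalized, window)
    amplicons: list[Amplicon] = []
    for f in fwd_sites:
        for r in rev_sites:
            if f.ref_id != r.ref_id:
                continue
            if f.strand == "+" and r.strand == "-" and f.start < r.start:
                start, end = f.start, r.end
            elif f.strand == "-" and r.strand == "+" and r.start < f.start:
                start, end = r.start, f.end
            else:
                continue
            if not (min_len <= end - start <= max_len):
                continue
            seq = panel.by_id[f.ref_id].sequence[start:end]
            amplicons.append(Amplicon(f.ref_id, start, end, seq, f, r))
    amplicons.sort(key=lambda a: (a.ref_id, a.start, a.end))
    return amplicons


def nested_virtual_pcr(
    panel: ReferencePanel,
    outer: tuple[Oligo | str, Oligo | str],
    inner: tuple[Oligo | str, Oligo | str],
    outer_kwargs: dict | None = None,
    inner_kwargs: dict | None = None,
) -> list[Amplicon]:
    """Two-round virtual PCR: inner products only inside an outer product.

    Each reported inner :class:`Amplicon` carries its containing outer
    product in ``.outer``. Inner site pairs falling outside every outer
    amplicon of the same reference yield nothing, mirroring nested PCR on a
    diluted first-round template.
    """
    outer_amps = virtual_pcr(panel, *outer, **(outer_kwargs or {}))
    inner_amps = virtual_pcr(panel, *inner, **(inner_kwargs or {}))
    nested: list[Amplicon] = []
    for ia in inner_amps:
        parent = next(
            (
                oa
                for oa in outer_amps
                if oa.ref_id == ia.ref_id and oa.start <= ia.start and ia.end <= oa.end
            ),
            None,
        )
        if parent is not None:
            nested.append(
                Amplicon(ia.ref_id, ia.start, ia.end, ia.sequence, ia.fwd_site, ia.rev_site, outer=parent)
            )
    return nested


def amplicons_frame(amplicons: list[Amplicon]):
    """Tabular summary (ref, start, end, length, mismatch counts) for reports."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "ref_id": a.ref_id,
                "start": a.start,
                "end": a.end,
                "length_incl_primers": a.length_incl_primers,
                "fwd_mismatches": a.fwd_site.total_mismatches,
                "rev_mismatches": a.rev_site.total_mismatches,
                "nested_in": f"{a.outer.start}-{a.outer.end}" if a.outer else "",
            }
            for a in amplicons
        ]
    )
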