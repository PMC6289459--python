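"""Species-specific nested primer design inside a broad-range amplicon.

The designer automates what an experienced assay developer does by eye on a
difference matrix: slide candidate primer windows over the target species'
first-round amplicon interior, keep those whose melting temperature falls in
the design window, demand that every non-target species in the panel shows at
least ``min_penalized_3p`` penalized (non-wobble) mismatches within the
3'-terminal ``window_3p`` bases of the primer, and require diagnostic
differences inside the amplified segment so a Sanger read of the product
confirms the species. Emitted designs carry universal sequencing tails
(forward TGTAAAACGACGGCCAGT, reverse CAGGAAACAGCTATGAC) and re-pass every
criterion when re-audited.

Non-targets that are sequence-identical to the target over the whole segment
can never be excluded by primers or by read; they abort the design with
:class:`NoDesignPossible` naming the indistinguishable set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .iupac import revcomp
from .refpanel import Alignment
from .thermo import (
    ThermoConditions,
    audit_site,
    melting_temperature,
    paired_template,
)

__all__ = [
    "M13_FORWARD_TAIL",
    "M13_REVERSE_TAIL",
    "DesignCriteria",
    "CandidatePrimer",
    "AssayDesign",
    "NoDesignPossible",
    "enumerate_candidates",
    "specificity_check",
    "diagnostic_positions",
    "design_assay",
    "add_m13_tails",
]

M13_FORWARD_TAIL = "TGTAAAACGACGGCCAGT"  # 18 nt
M13_REVERSE_TAIL = "CAGGAAACAGCTATGAC"  # 17 nt

#: Tm windows: the stated design window, and the wider band the published
#: assays actually span (printed primer Tms run 47.7-57.5 C).
PRESETS = {
    "paper": (50.0, 52.0),
    "observed": (47.7, 57.5),
}


@dataclass(frozen=True)
class DesignCriteria:
    """Tunable design criteria; defaults are the stated design rules."""

    tm_min: float = 50.0
    tm_max: float = 52.0
    min_penalized_3p: int = 2
    window_3p: int = 5
    primer_len_min: int = 17
    primer_len_max: int = 27
    amplicon_min: int = 120
    amplicon_max: int = 200
    #: published assay sizes count the sequencing tails (35 nt); the bounds
    #: above are applied on that tail-inclusive scale by default
    sizes_include_tails: bool = True
    require_internal_diagnostic: bool = True
    conditions: ThermoConditions = field(default_factory=ThermoConditions)

    def __post_init__(self) -> None:
        if self.tm_min > self.tm_max:
            raise ValueError("tm_min > tm_max")
        if self.primer_len_min > self.primer_len_max:
            raise ValueError("primer_len_min > primer_len_max")
        if self.amplicon_min > self.amplicon_max:
            raise ValueError("amplicon_min > amplicon_max")
        if self.min_penalized_3p < 0 or self.window_3p < 0:
            raise ValueError("counts must be >= 0")

    @classmethod
    def preset(cls, name: str, **overrides) -> "DesignCriteria":
        tm_min, tm_max = PRESETS[name]
        return cls(tm_min=tm_min, tm_max=tm_max, **overrides)


@dataclass(frozen=True)
class CandidatePrimer:
    """A candidate primer window with its thermodynamics and non-target audit.

    ``start``/``end`` are 0-based half-open coordinates of the footprint on
    the target amplicon (sense strand); ``core`` is the sequence 5'->3' as
    synthesized (reverse candidates are the reverse complement of the sense
    window). ``audit`` maps each non-target taxon to
    ``(total_mismatches, penalized_in_3p_window)``; ``no_site`` lists taxa
    lacking a homologous site (gap at the locus), which auto-pass.
    """

    core: str
    orientation: str  # 'forward' | 'reverse'
    start: int
    end: int
    tm: float
    audit: dict[str, tuple[int, int]] = field(default_factory=dict, compare=False)
    no_site: frozenset[str] = frozenset()

    @property
    def strand(self) -> str:
        return "+" if self.orientation == "forward" else "-"


@dataclass(frozen=True)
class AssayDesign:
    """A ranked nested primer pair for one target taxon."""

    target_taxon: str
    fwd: CandidatePrimer
    rev: CandidatePrimer
    fwd_tailed: str
    rev_tailed: str
    amplicon_length: int  # inclusive of both primer footprints, excl. tails
    diagnostics: dict[str, list[int]]  # non-target -> amplicon positions
    shared_detection: frozenset[str]  # taxa indistinguishable on the read
    rank_score: tuple

    @property
    def amplicon_size_incl_tails(self) -> int:
        """Product size on the published-table convention (tails included)."""
        return self.amplicon_length + len(M13_FORWARD_TAIL) + len(M13_REVERSE_TAIL)

    @property
    def cross_reactive(self) -> frozenset[str]:
        """Taxa failing primer specificity — empty by construction on emitted designs."""
        return frozenset(
            t
            for t, (_, pen) in {**self.fwd.audit, **self.rev.audit}.items()
            if t not in self.fwd.no_site and pen < 1
        )


class NoDesignPossible(Exception):
    """No primer pair satisfies the criteria for this target.

    Carries the limiting reason per criterion and the set of taxa whose
    segment is identical to the target's (indistinguishable by any assay on
    this amplicon).
    """

    def __init__(self, target: str, reasons: dict[str, int], indistinguishable: frozenset[str]):
        self.target = target
        self.reasons = dict(reasons)
        self.indistinguishable = frozenset(indistinguishable)
        detail = "; ".join(f"{k}: {v}" for k, v in self.reasons.items()) or "no candidates"
        twins = (
            f" (indistinguishable taxa: {sorted(self.indistinguishable)})"
            if self.indistinguishable
            else ""
        )
        super().__init__(f"no valid design for {target!r} — {detail}{twins}")


def enumerate_candidates(
    target_amplicon: str,
    criteria: DesignCriteria | None = None,
    orientation: str = "forward",
) -> list[CandidatePrimer]:
    """All primer windows on *target_amplicon* passing length and Tm bounds.

    *target_amplicon* is the first-round amplicon interior of the target
    species, excluding the broad-range primer footprints. Reverse candidates
    are returned 5'->3' as synthesized (reverse complement of the sense
    window). An amplicon shorter than the minimum primer length yields an
    empty list with a warning.
    """
    import warnings

    criteria = criteria or DesignCriteria()
    if orientation not in ("forward", "reverse"):
        raise ValueError("orientation must be 'forward' or 'reverse'")
    n = len(target_amplicon)
    if n < criteria.primer_len_min:
        warnings.warn("amplicon shorter than the minimum primer length; no candidates")
        return []
    out = []
    for length in range(criteria.primer_len_min, criteria.primer_len_max + 1):
        for start in range(0, n - length + 1):
            window = target_amplicon[start : start + length]
            if "-" in window:
                continue
            core = window if orientation == "forward" else revcomp(window)
            try:
                tm = melting_temperature(core, criteria.conditions)
            except ValueError:
                continue
            if criteria.tm_min <= tm <= criteria.tm_max:
                out.append(
                    CandidatePrimer(core, orientation, start, start + length, tm)
                )
    return out


def _audit_against(
    c: CandidatePrimer,
    nontarget_sites: dict[str, str],
    criteria: DesignCriteria,
) -> CandidatePrimer:
    """Fill in the per-non-target mismatch audit for a candidate.

    ``nontarget_sites`` maps taxon -> aligned sense-strand sequence at the
    candidate's locus (same width as the footprint; may contain gaps).
    """
    audit: dict[str, tuple[int, int]] = {}
    no_site = set()
    for taxon, site in nontarget_sites.items():
        if len(site) != c.end - c.start:
            raise ValueError(f"site width mismatch for taxon {taxon!r}")
        if "-" in site:
            no_site.add(taxon)
            continue
        total, pen3, _ = audit_site(
            c.core, paired_template(site, c.strand), criteria.window_3p
        )
        audit[taxon] = (total, pen3)
    return replace(c, audit=audit, no_site=frozenset(no_site))


def specificity_check(
    c: CandidatePrimer,
    nontarget_sites: dict[str, str],
    criteria: DesignCriteria | None = None,
) -> tuple[bool, CandidatePrimer]:
    """Pass iff every non-target shows >= ``min_penalized_3p`` penalized
    mismatches within the 3' window.

    Wobbles (G.T/T.G) are counted in the totals but never satisfy the
    criterion. Non-targets with no homologous site (gap at the locus)
    auto-pass and are flagged in ``no_site``. Returns the audited candidate
    alongside the verdict.
    """
    criteria = criteria or DesignCriteria()
    audited = _audit_against(c, nontarget_sites, criteria)
    ok = all(pen >= criteria.min_penalized_3p for _, pen in audited.audit.values())
    return ok, audited


def diagnostic_positions(
    target_amplicon: str,
    nontarget_amplicons: dict[str, str],
    span: tuple[int, int],
) -> dict[str, list[int]]:
    """Positions within *span* where the target differs from each non-target.

    *span* is the region strictly between (and excluding) the nested primer
    footprints, 0-based half-open in amplicon coordinates. An empty list for
    a taxon flags it as sequence-indistinguishable on the read.
    """
    start, end = span
    if end <= start:
        raise ValueError("empty diagnostic span")
    out: dict[str, list[int]] = {}
    for taxon, seq in nontarget_amplicons.items():
        out[taxon] = [
            j
            for j in range(start, end)
            if target_amplicon[j] != seq[j]
        ]
    return out


def add_m13_tails(fwd_core: str, rev_core: str, enabled: bool = True) -> tuple[str, str]:
    """Attach the universal sequencing tails (18 nt forward, 17 nt reverse)."""
    if not enabled:
        return fwd_core, rev_core
    return M13_FORWARD_TAIL + fwd_core, M13_REVERSE_TAIL + rev_core


def design_assay(
    alignment: Alignment,
    target_taxon: str,
    criteria: DesignCriteria | None = None,
    taxon_of: dict[str, str] | None = None,
    max_designs: int | None = None,
) -> list[AssayDesign]:
    """Enumerate, audit and rank nested primer pairs for *target_taxon*.

    *alignment* holds the first-round amplicon interiors (broad-range primer
    footprints already excluded), one row per taxon; ``taxon_of`` maps row id
    to taxon when row ids are not taxa themselves. Designs are ranked by the
    worst-case penalized 3' mismatch count over both primers and all
    non-targets (descending), then by distance of the primer Tms from the
    window midpoint, then by amplicon length nearest mid-range.

    Raises :class:`NoDesignPossible` when no pair passes, carrying per-
    criterion failure counts and the set of taxa identical to the target
    over the segment.
    """
    criteria = criteria or DesignCriteria()
    taxon_of = taxon_of or {rid: rid for rid in a_ids(alignment)}
    rows_by_taxon: dict[str, str] = {}
    for rid, row in alignment.rows.items():
        rows_by_taxon.setdefault(taxon_of.get(rid, rid), row)
    if target_taxon not in rows_by_taxon:
        raise ValueError(f"target taxon {target_taxon!r} not in alignment")
    nontargets = {t: r for t, r in rows_by_taxon.items() if t != target_taxon}
    if not nontargets:
        raise ValueError("need at least one non-target taxon")

    target_row = rows_by_taxon[target_taxon]
    indistinguishable = frozenset(
        t for t, r in nontargets.items() if r.replace("-", "") == target_row.replace("-", "")
    )
    if indistinguishable:
        raise NoDesignPossible(
            target_taxon,
            {"identical_segment": len(indistinguishable)},
            indistinguishable,
        )

    # map target ungapped positions -> alignment columns
    col_of = [j for j, ch in enumerate(target_row) if ch != "-"]
    target_seq = target_row.replace("-", "")

    reasons = {
        "tm_window": 0,
        "specificity": 0,
        "amplicon_length": 0,
        "diagnostic": 0,
    }

    def audited_candidates(orientation: str) -> list[CandidatePrimer]:
        cands = enumerate_candidates(target_seq, criteria, orientation)
        kept = []
        for c in cands:
            cols = col_of[c.start : c.end]
            sites = {
                t: "".join(row[j] for j in cols) for t, row in nontargets.items()
            }
            ok, audited = specificity_check(c, sites, criteria)
            if ok:
                kept.append(audited)
            else:
                reasons["specificity"] += 1
        return kept

    fwd_cands = audited_candidates("forward")
    rev_cands = audited_candidates("reverse")
    if not fwd_cands and not rev_cands:
        reasons["tm_window"] = 1  # nothing even reached the audit
    tail_extra = (
        len(M13_FORWARD_TAIL) + len(M13_REVERSE_TAIL)
        if criteria.sizes_include_tails
        else 0
    )
    designs: list[AssayDesign] = []
    for f in fwd_cands:
        for r in rev_cands:
            if r.start < f.end:  # reverse footprint must lie beyond the forward one
                continue
            length = r.end - f.start
            if not (criteria.amplicon_min <= length + tail_extra <= criteria.amplicon_max):
                reasons["amplicon_length"] += 1
                continue
            span = (f.end, r.start)
            diag = {}
            shared = set()
            if span[1] > span[0]:
                diag_cols = (col_of[span[0]], col_of[span[1] - 1] + 1)
                diag = {
                    t: [
                        j
                        for j in range(*diag_cols)
                        if target_row[j] != row[j]
                    ]
                    for t, row in nontargets.items()
                }
                shared = {t for t, pos in diag.items() if not pos}
            elif criteria.require_internal_diagnostic:
                reasons["diagnostic"] += 1
                continue
            # Taxa with no diagnostic difference on the read are reported as
            # a shared-detection set; both primers already passed the
            # specificity audit against them, so the pair stands.
            tailed_f, tailed_r = add_m13_tails(f.core, r.core)
            worst_pen = min(
                [pen for _, pen in f.audit.values()] + [pen for _, pen in r.audit.values()],
                default=0,
            )
            mid_tm = (criteria.tm_min + criteria.tm_max) / 2
            mid_len = (criteria.amplicon_min + criteria.amplicon_max) / 2
            score = (
                -worst_pen,
                abs(f.tm - mid_tm) + abs(r.tm - mid_tm),
                abs(length + tail_extra - mid_len),
                f.start,
                r.start,
            )
            designs.append(
                AssayDesign(
                    target_taxon,
                    f,
                    r,
                    tailed_f,
                    tailed_r,
                    length,
                    diag,
                    frozenset(shared),
                    score,
                )
            )
    if not designs:
        raise NoDesignPossible(target_taxon, reasons, frozenset())
    designs.sort(key=lambda d: d.rank_score)
    return designs[:max_designs] if max_designs else designs


def a_ids(a: Alignment) -> list[str]:
    return a.ids


def audit_design(
    design: AssayDesign,
    alignment: Alignment,
    criteria: DesignCriteria | None = None,
    taxon_of: dict[str, str] | None = None,
) -> bool:
    """Re-audit an emitted design from scratch; True iff it still passes.

    Used for the self-consistency guarantee: every emitted design re-passes
    Tm bounds, specificity against every distinguishable non-target, and the
    amplicon-length bounds.
    """
    criteria = criteria or DesignCriteria()
    taxon_of = taxon_of or {rid: rid for rid in alignment.ids}
    rows_by_taxon: dict[str, str] = {}
    for rid, row in alignment.rows.items():
        rows_by_taxon.setdefault(taxon_of.get(rid, rid), row)
    target_row = rows_by_taxon[design.target_taxon]
    col_of = [j for j, ch in enumerate(target_row) if ch != "-"]
    nontargets = {
        t: r for t, r in rows_by_taxon.items() if t != design.target_taxon
    }
    for cand in (design.fwd, design.rev):
        tm = melting_temperature(cand.core, criteria.conditions)
        if not (criteria.tm_min <= tm <= criteria.tm_max):
            return False
        cols = col_of[cand.start : cand.end]
        sites = {t: "".join(row[j] for j in cols) for t, row in nontargets.items()}
        ok, _ = specificity_check(cand, sites, criteria)
        if not ok:
            return False
    size = (
        design.amplicon_size_incl_tails
        if criteria.sizes_include_tails
        else design.amplicon_length
    )
    if not (criteria.amplicon_min <= size <= criteria.amplicon_max):
        return False
    return True
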