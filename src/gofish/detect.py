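"""Detection analysis: species assignment, presence/absence matrices, OTU
filtering, seasonal contrasts, and two-method concordance.

The assignment rule is deliberately strict: a Sanger consensus read counts as
a detection only when it matches a reference 100% over its full length (the
query, or its reverse complement, must be an exact substring of a panel
reference). Gel-positive reactions whose sequence matches a different taxon
are flagged ``nontarget_sequence`` and scored as non-detections.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .iupac import revcomp
from .refpanel import ReferencePanel

__all__ = [
    "QueryRecord",
    "DetectionMatrix",
    "OtuTable",
    "SeasonComparison",
    "ConcordanceReport",
    "assign_species",
    "build_detection_matrix",
    "filter_otu_detections",
    "fisher_exact_2x2",
    "compare_seasons",
    "concordance",
    "meteorological_season",
]


@dataclass(frozen=True)
class QueryRecord:
    """One assay result: a sample queried for one taxon.

    ``sequence`` is the Sanger consensus of a gel-positive product (None for
    gel-negative reactions).
    """

    sample_id: str
    date: dt.date
    site: str
    assay_taxon: str
    gel_positive: bool
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.gel_positive and not self.sequence:
            object.__setattr__(self, "sequence", None)


def assign_species(query: str, panel: ReferencePanel) -> frozenset[str]:
    """Taxa whose reference contains the query as an exact full-length substring.

    The reverse complement of the query is also tried. An empty set means
    unassigned (any mismatch disqualifies); more than one taxon means a
    shared-sequence ambiguity and the whole set is returned.
    """
    if not query:
        raise ValueError("empty query sequence")
    q = query.upper().replace("U", "T")
    rc = revcomp(q)
    hits = set()
    for rec in panel:
        if q in rec.sequence or rc in rec.sequence:
            hits.add(rec.taxon)
    return frozenset(hits)


# cell provenance labels
CONFIRMED = "gel+sanger_confirmed"
GEL_ONLY = "gel_only"
NONTARGET = "nontarget_sequence"
NEGATIVE = "negative"


class DetectionMatrix:
    """Samples x taxa presence/absence with per-cell provenance.

    ``values`` is a boolean DataFrame (index sample_id, columns taxa);
    ``provenance`` is a same-shaped DataFrame of provenance strings;
    ``samples`` carries (sample_id, date, site), sorted by site then date.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        provenance: pd.DataFrame,
        samples: pd.DataFrame,
    ):
        self.values = values.astype(bool)
        self.provenance = provenance
        self.samples = (
            samples.sort_values(["site", "date"])
            .drop_duplicates("sample_id")
            .reset_index(drop=True)
        )

    @property
    def taxa(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_detections(self) -> int:
        return int(self.values.to_numpy().sum())

    def counts_by_sample(self) -> pd.Series:
        """Number of taxa detected per sample (column sums of the grid)."""
        return self.values.sum(axis=1)

    def counts_by_taxon(self) -> pd.Series:
        return self.values.sum(axis=0)


def build_detection_matrix(
    records: list[QueryRecord], panel: ReferencePanel
) -> DetectionMatrix:
    """Assemble the presence/absence grid from per-assay records.

    A cell is detected iff the reaction was gel-positive AND the Sanger
    sequence assigns (possibly ambiguously) to the assay taxon. Duplicate
    (sample, taxon) records with conflicting results are an error.
    """
    seen: dict[tuple[str, str], tuple[bool, str | None]] = {}
    cells: dict[tuple[str, str], tuple[bool, str]] = {}
    meta: dict[str, tuple[dt.date, str]] = {}
    for rec in records:
        key = (rec.sample_id, rec.assay_taxon)
        payload = (rec.gel_positive, rec.sequence)
        if key in seen and seen[key] != payload:
            raise ValueError(
                f"conflicting duplicate record for sample {rec.sample_id!r}, "
                f"taxon {rec.assay_taxon!r}"
            )
        seen[key] = payload
        meta[rec.sample_id] = (rec.date, rec.site)
        if not rec.gel_positive:
            cells[key] = (False, NEGATIVE)
        elif not rec.sequence:
            cells[key] = (False, GEL_ONLY)
        else:
            assigned = assign_species(rec.sequence, panel)
            if rec.assay_taxon in assigned:
                cells[key] = (True, CONFIRMED)
            else:
                cells[key] = (False, NONTARGET)
    sample_ids = sorted(meta, key=lambda s: (meta[s][1], meta[s][0], s))
    taxa = sorted({t for _, t in cells})
    values = pd.DataFrame(False, index=sample_ids, columns=taxa)
    prov = pd.DataFrame("not_tested", index=sample_ids, columns=taxa)
    for (sid, taxon), (det, p) in cells.items():
        values.loc[sid, taxon] = det
        prov.loc[sid, taxon] = p
    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "date": [meta[s][0] for s in sample_ids],
            "site": [meta[s][1] for s in sample_ids],
        }
    )
    return DetectionMatrix(values, prov, samples)


@dataclass
class OtuTable:
    """Denoised unique sequences with per-sample read counts.

    ``counts``: DataFrame indexed by otu_id, one column per sample.
    ``sequences``: otu_id -> sequence.
    """

    counts: pd.DataFrame
    sequences: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative read counts")

    @property
    def otu_totals(self) -> pd.Series:
        """Total reads per OTU sequence across samples."""
        return self.counts.sum(axis=1)

    @property
    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)


def filter_otu_detections(table: OtuTable, threshold: float = 0.001) -> OtuTable:
    """Zero per-sample counts below ``threshold`` of that OTU's total reads.

    The comparison is strict (count/total < threshold is removed; equality is
    retained), with totals computed on the input table. The operation is
    idempotent.
    """
    counts = table.counts.copy()
    totals = table.otu_totals
    for otu in counts.index:
        total = totals.loc[otu]
        if total <= 0:
            continue
        row = counts.loc[otu]
        counts.loc[otu] = row.where(row / total >= threshold, 0)
    return OtuTable(counts, dict(table.sequences))


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    Two-sided by the probability-mass rule: the sum of hypergeometric
    probabilities of all tables with the observed margins whose probability
    does not exceed the observed table's. All-zero tables return 1 by
    convention.
    """
    for x in (a, b, c, d):
        if x < 0:
            raise ValueError("counts must be >= 0")
    if a + b + c + d == 0:
        return 1.0
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def meteorological_season(date: dt.date) -> str:
    """Meteorological season: Mar-May spring, Jun-Aug summer, Sep-Nov fall,
    Dec-Feb winter."""
    m = date.month
    if m in (3, 4, 5):
        return "spring"
    if m in (6, 7, 8):
        return "summer"
    if m in (9, 10, 11):
        return "fall"
    return "winter"


@dataclass
class SeasonComparison:
    seasons: tuple[str, str]
    table: tuple[int, int, int, int]  # (pos_s1, neg_s1, pos_s2, neg_s2)
    p_value: float
    positive_share: dict[str, float]  # share of positives per season (over the pair)
    excluded_taxa: tuple[str, ...]


def compare_seasons(
    m: DetectionMatrix,
    pair: tuple[str, str],
    season_of=meteorological_season,
    exclude: tuple[str, ...] = (),
) -> SeasonComparison:
    """Fisher contrast of detection rates between two seasons.

    The detection unit is one (sample, taxon) cell. ``exclude`` removes taxa
    (e.g. a cold-water species with an inverted seasonal pattern) from the
    counts. Raises ``ValueError`` when either season has no samples.
    """
    s1, s2 = pair
    taxa = [t for t in m.taxa if t not in exclude]
    if not taxa:
        raise ValueError("no taxa left after exclusion")
    season_by_sample = {
        row.sample_id: season_of(row.date) for row in m.samples.itertuples()
    }
    counts = {s1: [0, 0], s2: [0, 0]}
    n_samples = {s1: 0, s2: 0}
    for sid, season in season_by_sample.items():
        if season not in counts:
            continue
        n_samples[season] += 1
        row = m.values.loc[sid, taxa]
        pos = int(row.sum())
        counts[season][0] += pos
        counts[season][1] += len(taxa) - pos
    for season, n in n_samples.items():
        if n == 0:
            raise ValueError(f"season {season!r} has no samples")
    a, b = counts[s1]
    c, d = counts[s2]
    p = fisher_exact_2x2(a, b, c, d)
    total_pos = a + c
    share = {
        s1: a / total_pos if total_pos else 0.0,
        s2: c / total_pos if total_pos else 0.0,
    }
    return SeasonComparison((s1, s2), (a, b, c, d), p, share, tuple(exclude))


#: default read-count bins (lower edges, labels) for stratifying positives
DEFAULT_READ_BINS = ((100, "0.1K"), (1000, "1K"), (10000, "10K"))


@dataclass
class ConcordanceReport:
    """Agreement between two presence/absence methods on the same grid."""

    n_a: int
    n_b: int
    shared: int
    a_only: int
    b_only: int

    @property
    def union(self) -> int:
        return self.shared + self.a_only + self.b_only

    @property
    def sensitivity_a(self) -> float:
        """Apparent sensitivity of method A: its detections / union of detections."""
        return self.n_a / self.union if self.union else 1.0

    @property
    def sensitivity_b(self) -> float:
        return self.n_b / self.union if self.union else 1.0

    read_bins: dict[str, dict[str, int]] | None = None


def concordance(
    m_a: DetectionMatrix,
    m_b: DetectionMatrix,
    reads: pd.DataFrame | None = None,
    bins=DEFAULT_READ_BINS,
) -> ConcordanceReport:
    """Compare two detection matrices cell by cell.

    Both matrices must cover the same sample x taxon grid. When ``reads``
    (per-cell read counts for method B) is given, B-positives are stratified
    into read bins and split by their method-A status.
    """
    if set(m_a.values.index) != set(m_b.values.index) or set(m_a.taxa) != set(m_b.taxa):
        missing = (
            sorted(set(m_a.values.index) ^ set(m_b.values.index)),
            sorted(set(m_a.taxa) ^ set(m_b.taxa)),
        )
        raise ValueError(f"grids differ; symmetric difference (samples, taxa) = {missing}")
    b = m_b.values.loc[m_a.values.index, m_a.taxa]
    a = m_a.values
    shared = int((a & b).to_numpy().sum())
    a_only = int((a & ~b).to_numpy().sum())
    b_only = int((~a & b).to_numpy().sum())
    report = ConcordanceReport(
        n_a=shared + a_only, n_b=shared + b_only, shared=shared, a_only=a_only, b_only=b_only
    )
    if reads is not None:
        reads = reads.loc[a.index, a.columns]
        strat: dict[str, dict[str, int]] = {}
        edges = sorted(bins, key=lambda e: e[0])
        for i, (lo, label) in enumerate(edges):
            hi = edges[i + 1][0] if i + 1 < len(edges) else np.inf
            in_bin = (reads >= lo) & (reads < hi) & b
            strat[label] = {
                "a_positive": int((in_bin & a).to_numpy().sum()),
                "a_negative": int((in_bin & ~a).to_numpy().sum()),
            }
        report.read_bins = strat
    return report
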