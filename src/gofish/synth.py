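"""Synthetic 12S-like panels and detection time series.

The generator emulates the architecture this toolkit assumes: a broad-range
amplicon with exactly conserved primer-binding flanks and a hypervariable
interior, a panel of species derived from a common ancestor by independent
substitutions, optional twin pairs (sequence-identical species such as
congeneric herrings or menhadens), and seasonal presence/absence series
with per-detection read counts. All randomness flows from the single spec
seed, so outputs are byte-identical across runs.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .refpanel import Alignment, ReferencePanel, ReferenceSequence
from .detect import DetectionMatrix, OtuTable, QueryRecord
from .iupac import revcomp

__all__ = [
    "MIFISH_U_F",
    "MIFISH_U_R",
    "SynthPanelSpec",
    "SynthSeriesSpec",
    "PanelTruth",
    "generate_panel",
    "generate_time_series",
]

# Broad-range vertebrate 12S primer pair used for the first round; the
# forward site is the primer itself, the reverse site (sense strand) its
# reverse complement. Embedding the literal sites means synthetic panels
# exercise the real first-round primers.
MIFISH_U_F = "GTCGGTAAAACTCGTGCCAGC"
MIFISH_U_R = "CATAGTGGGGTATCTAATCCCAGTTTG"

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SynthPanelSpec:
    """Recipe for a synthetic reference panel.

    ``substitution_rate`` is the per-site probability that a species differs
    from the common ancestor in the hypervariable interior; flanks are kept
    exact so every species amplifies in the first round. Twin pairs are
    appended as verbatim copies under a different taxon name.
    """

    n_species: int = 12
    flank5: str = MIFISH_U_F
    flank3: str = revcomp(MIFISH_U_R)
    inner_length: int = 172  # total segment = 220 with the default flanks
    # default interior divergence emulates a taxonomically broad regional
    # panel (effectively independent hypervariable interiors, ~2/3 pairwise
    # differences); lower it to emulate panels of close relatives
    substitution_rate: float = 0.5
    n_twin_pairs: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.substitution_rate <= 1:
            raise ValueError("substitution_rate must be in [0, 1]")
        if self.inner_length < 2 * 27 + 20:
            raise ValueError("inner_length too short to hold nested primer pairs")
        if self.n_twin_pairs > self.n_species:
            raise ValueError("more twin pairs than species")
        if self.n_species < 2:
            raise ValueError("need at least 2 species")


@dataclass
class PanelTruth:
    """Ground truth of a generated panel, for tests and audits."""

    ancestor_inner: str
    mutated_positions: dict[str, list[int]]
    twins: list[tuple[str, str]]


def _taxon_name(i: int) -> str:
    return f"Simulatus species{i:02d}"


def generate_panel(spec: SynthPanelSpec) -> tuple[ReferencePanel, Alignment, PanelTruth]:
    """Draw a panel of related species around a uniform-random ancestor.

    Substitutions only (no indels), so the returned alignment is simply the
    gapless stack of segments. Twin species are exact copies of the last
    ``n_twin_pairs`` originals.
    """
    rng = np.random.default_rng(spec.seed)
    ancestor = "".join(rng.choice(BASES, size=spec.inner_length))
    records: list[ReferenceSequence] = []
    mutated: dict[str, list[int]] = {}
    for i in range(spec.n_species):
        taxon = _taxon_name(i)
        sites = np.flatnonzero(rng.random(spec.inner_length) < spec.substitution_rate)
        inner = list(ancestor)
        for j in sites:
            choices = [b for b in "ACGT" if b != inner[j]]
            inner[j] = choices[rng.integers(3)]
        seq = spec.flank5 + "".join(inner) + spec.flank3
        records.append(
            ReferenceSequence(
                id=f"SYN{i:03d}", taxon=taxon, common_name=f"synthetic fish {i}", group="bony_fish", sequence=seq
            )
        )
        mutated[taxon] = [int(j) for j in sites]
    twins: list[tuple[str, str]] = []
    for k in range(spec.n_twin_pairs):
        src = records[spec.n_species - 1 - k]
        twin_taxon = src.taxon.replace("species", "geminus")
        records.append(
            ReferenceSequence(
                id=f"SYN{spec.n_species + k:03d}",
                taxon=twin_taxon,
                common_name=f"twin of {src.common_name}",
                group=src.group,
                sequence=src.sequence,
            )
        )
        mutated[twin_taxon] = list(mutated[src.taxon])
        twins.append((src.taxon, twin_taxon))
    panel = ReferencePanel(records)
    alignment = Alignment({r.id: r.sequence for r in records})
    return panel, alignment, PanelTruth(ancestor, mutated, twins)


@dataclass(frozen=True)
class SynthSeriesSpec:
    """Recipe for a seasonal presence/absence time series.

    ``detection_prob`` maps taxon -> season -> occupancy probability; taxa
    not listed use ``default_prob``. Read counts per true detection are
    log-normal (parameters on the log scale), emulating the heavy-tailed
    per-species read abundances of a metabarcoding run.
    """

    detection_prob: dict[str, dict[str, float]] = field(default_factory=dict)
    default_prob: float = 0.5
    sites: tuple[str, ...] = ("east_river", "outer_harbor")
    n_samples_per_site: int = 17
    start_date: dt.date = dt.date(2017, 3, 31)
    interval_days: int = 7
    false_negative: float = 0.0
    read_lognorm_mean: float = 7.0
    read_lognorm_sigma: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.false_negative <= 1:
            raise ValueError("false_negative must be in [0, 1]")
        for taxon, by_season in self.detection_prob.items():
            for p in by_season.values():
                if not 0 <= p <= 1:
                    raise ValueError(f"probability out of range for {taxon!r}")


def generate_time_series(
    panel: ReferencePanel,
    spec: SynthSeriesSpec,
    taxa: list[str] | None = None,
    season_of=None,
    flank_lengths: tuple[int, int] = (len(MIFISH_U_F), len(MIFISH_U_R)),
) -> tuple[list[QueryRecord], OtuTable, DetectionMatrix]:
    """Simulate assay records, a read-count table, and the true matrix.

    For each (sample, taxon), occupancy is Bernoulli with the taxon's
    seasonal probability. A true detection emits a gel-positive record whose
    sequence is the taxon's amplicon interior (error-free) plus a log-normal
    read count; with probability ``false_negative`` the record is emitted
    gel-negative while the truth matrix still scores the cell detected.
    """
    from .detect import meteorological_season

    season_of = season_of or meteorological_season
    taxa = taxa or panel.taxa
    unknown = [t for t in taxa if t not in panel.by_taxon]
    if unknown:
        raise ValueError(f"unknown taxa: {unknown}")
    rng = np.random.default_rng(spec.seed)

    f5, f3 = flank_lengths

    def inner_of(taxon: str) -> str:
        seq = panel.by_taxon[taxon][0].sequence
        # strip the conserved flanks so the query sits inside the segment
        return seq[f5 : len(seq) - f3] if len(seq) > f5 + f3 else seq

    records: list[QueryRecord] = []
    truth_cells: dict[tuple[str, str], bool] = {}
    meta: dict[str, tuple[dt.date, str]] = {}
    counts: dict[str, dict[str, int]] = {t: {} for t in taxa}
    for site in spec.sites:
        for k in range(spec.n_samples_per_site):
            date = spec.start_date + dt.timedelta(days=k * spec.interval_days)
            sid = f"{site}_{date.isoformat()}"
            meta[sid] = (date, site)
            season = season_of(date)
            for taxon in taxa:
                p = spec.detection_prob.get(taxon, {}).get(season, spec.default_prob)
                occupied = rng.random() < p
                truth_cells[(sid, taxon)] = occupied
                observed = occupied and rng.random() >= spec.false_negative
                if occupied:
                    reads = int(
                        np.ceil(
                            rng.lognormal(spec.read_lognorm_mean, spec.read_lognorm_sigma)
                        )
                    )
                    counts[taxon][sid] = reads
                records.append(
                    QueryRecord(
                        sample_id=sid,
                        date=date,
                        site=site,
                        assay_taxon=taxon,
                        gel_positive=observed,
                        sequence=inner_of(taxon) if observed else None,
                    )
                )
    sample_ids = sorted(meta, key=lambda s: (meta[s][1], meta[s][0]))
    values = pd.DataFrame(
        [[truth_cells[(sid, t)] for t in taxa] for sid in sample_ids],
        index=sample_ids,
        columns=taxa,
    )
    prov = values.map(lambda v: "truth" if v else "negative")
    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "date": [meta[s][0] for s in sample_ids],
            "site": [meta[s][1] for s in sample_ids],
        }
    )
    truth = DetectionMatrix(values, prov, samples)
    otu_counts = pd.DataFrame(
        [[counts[t].get(sid, 0) for sid in sample_ids] for t in taxa],
        index=[f"OTU_{t.replace(' ', '_')}" for t in taxa],
        columns=sample_ids,
    )
    sequences = {f"OTU_{t.replace(' ', '_')}": inner_of(t) for t in taxa}
    return records, OtuTable(otu_counts, sequences), truth
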