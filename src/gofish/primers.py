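"""Packaged primer tables: the published broad-range and species-specific sets.

Two plain-TSV fixtures ship with the package: the broad-range vertebrate 12S
primers (reference-segment, first-round, and metabarcoding pairs) and the 21
species-specific nested assays with their printed melting temperatures,
amplicon sizes and cycling metadata. Annealing temperature and cycle number
are metadata passed through from the published protocol, not computed.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .thermo import Oligo
from .design import M13_FORWARD_TAIL, M13_REVERSE_TAIL

__all__ = ["load_species_primers", "load_broad_primers", "PublishedAssay", "published_assays"]


def _read(name: str) -> pd.DataFrame:
    with resources.files("gofish.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", dtype=str).assign(
            tm_printed=lambda d: d["tm_printed"].astype(float)
        )


def load_species_primers() -> pd.DataFrame:
    """The species-specific assay table, one row per primer (42 rows)."""
    df = _read("species_primers.tsv")
    df["amplicon_size"] = df["amplicon_size"].astype(int)
    df["cycles"] = df["cycles"].astype(int)
    df["annealing_c"] = df["annealing_c"].astype(int)
    return df


def load_broad_primers() -> pd.DataFrame:
    """Broad-range 12S primers (reference, first-round and metabarcoding sets)."""
    df = _read("broad_primers.tsv")
    df["tail"] = df["tail"].fillna("")
    return df


@dataclass(frozen=True)
class PublishedAssay:
    """One species-specific nested assay as published."""

    code: str
    common_name: str
    target_taxon: str
    group: str
    fwd: Oligo
    rev: Oligo
    fwd_name: str
    rev_name: str
    fwd_tm_printed: float
    rev_tm_printed: float
    amplicon_size: int
    annealing_c: int
    cycles: int
    nontarget_amplification: bool


def published_assays() -> list[PublishedAssay]:
    """The species-specific primer table grouped into assay pairs."""
    df = load_species_primers()
    assays = []
    for code, grp in df.groupby("assay", sort=False):
        fwd = grp[grp.orientation == "forward"].iloc[0]
        rev = grp[grp.orientation == "reverse"].iloc[0]
        assays.append(
            PublishedAssay(
                code=code,
                common_name=fwd.common_name,
                target_taxon=fwd.target_taxon,
                group=fwd.group,
                fwd=Oligo(fwd.core, M13_FORWARD_TAIL),
                rev=Oligo(rev.core, M13_REVERSE_TAIL),
                fwd_name=fwd.primer_name,
                rev_name=rev.primer_name,
                fwd_tm_printed=float(fwd.tm_printed),
                rev_tm_printed=float(rev.tm_printed),
                amplicon_size=int(fwd.amplicon_size),
                annealing_c=int(fwd.annealing_c),
                cycles=int(fwd.cycles),
                nontarget_amplification=fwd.nontarget_amplification == "Y",
            )
        )
    return assays
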