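"""Oligo thermodynamics and primer-template mismatch semantics.

Melting temperatures are computed with the unified nearest-neighbor model
(SantaLucia, PNAS 1998) and the Owczarzy 2004 sodium correction, the
combination used by common oligo-vendor calculators. The default conditions
reconstruct such a calculator's defaults: 0.25 uM oligo, 50 mM Na+, no
divalents or dNTPs, with oligo and complement assumed equimolar (effective
duplex concentration = oligo_conc / 2). Tm is always computed on the
species-specific (or broad-range) core only — sequencing tails are excluded.

Mismatch semantics follow permissive-wobble classification: a G.T or T.G
primer-template pair destabilises a duplex only mildly, so it is classed
``permissive_wobble`` and never counts toward the penalized-mismatch tally
that confers assay specificity. All classification happens in duplex
orientation: the template base given is the base the primer base physically
pairs against (callers convert from sense-strand coordinates; see
:func:`paired_template`).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace

from .iupac import IUPAC_SETS, complement, expand_degenerate, is_concrete

__all__ = [
    "ThermoConditions",
    "Oligo",
    "MismatchClass",
    "melting_temperature",
    "expand_degenerate",
    "classify_mismatch",
    "count_3prime_penalized",
    "audit_site",
    "paired_template",
]

R_GAS = 1.98717  # cal / (mol K)

# Unified NN parameters, 5'->3' stacks: (dH kcal/mol, dS cal/mol/K)
NN_UNIFIED: dict[str, tuple[float, float]] = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
# Duplex initiation per terminal base pair
INIT_GC = (0.1, -2.8)
INIT_AT = (2.3, 4.1)
SYMMETRY_DS = -1.4  # self-complementary duplexes only

MIN_CORE_LEN = 8
DEGENERACY_LIMIT = 512


@dataclass(frozen=True)
class ThermoConditions:
    """Solution conditions for Tm prediction.

    ``duplex`` selects the concentration term of the two-state model:
    ``"equimolar"`` assumes oligo and complement at equal concentration
    (effective CT = oligo_conc/2, the vendor-calculator reconstruction used
    as default); ``"excess"`` assumes the oligo far exceeds its template
    (effective CT = oligo_conc).
    """

    oligo_conc: float = 0.25  # uM
    na_mM: float = 50.0
    mg_mM: float = 0.0
    dntp_mM: float = 0.0
    duplex: str = "equimolar"

    def __post_init__(self) -> None:
        for name in ("oligo_conc", "na_mM", "mg_mM", "dntp_mM"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.duplex not in ("equimolar", "excess"):
            raise ValueError("duplex must be 'equimolar' or 'excess'")

    @property
    def effective_ct(self) -> float:
        """Effective duplex concentration (molar) entering the R*ln(CT) term."""
        ct = self.oligo_conc * 1e-6
        return ct / 2.0 if self.duplex == "equimolar" else ct

    @property
    def monovalent_molar(self) -> float:
        """Effective monovalent cation concentration (M).

        Divalents, when present, fold in as Na-equivalents via the common
        120*sqrt([Mg]-[dNTP]) approximation.
        """
        mg_free = max(self.mg_mM - self.dntp_mM, 0.0)
        return (self.na_mM + 120.0 * math.sqrt(mg_free)) * 1e-3


DEFAULT_CONDITIONS = ThermoConditions()


@dataclass(frozen=True)
class Oligo:
    """A synthesized primer: species-specific/broad-range core plus optional tail."""

    core: str
    tail: str = ""

    def __post_init__(self) -> None:
        if len(self.core) < 15:
            raise ValueError(f"primer core must be >= 15 nt, got {len(self.core)}")

    @property
    def full(self) -> str:
        """The sequence as synthesized, 5' tail + core."""
        return self.tail + self.core

    def tm(self, conditions: ThermoConditions | None = None) -> float:
        return melting_temperature(self.core, conditions)


def _tm_concrete(core: str, conditions: ThermoConditions) -> float:
    dh, ds = 0.0, 0.0
    for i in range(len(core) - 1):
        h, s = NN_UNIFIED[core[i : i + 2]]
        dh += h
        ds += s
    for terminal in (core[0], core[-1]):
        h, s = INIT_GC if terminal in "GC" else INIT_AT
        dh += h
        ds += s
    ct = conditions.effective_ct
    if core == complement(core)[::-1]:  # self-complementary
        ds += SYMMETRY_DS
        ct *= 4  # x = 1 instead of 4 relative to the equimolar case
    tm_1m = (dh * 1000.0) / (ds + R_GAS * math.log(ct))  # Kelvin, 1 M Na+
    # Owczarzy 2004 reciprocal-Tm sodium correction
    mono = conditions.monovalent_molar
    fgc = sum(b in "GC" for b in core) / len(core)
    ln_na = math.log(mono)
    inv_tm = 1.0 / tm_1m + (4.29 * fgc - 3.95) * 1e-5 * ln_na + 9.40e-6 * ln_na**2
    return 1.0 / inv_tm - 273.15


def melting_temperature(
    core: str,
    conditions: ThermoConditions | None = None,
    degenerate: str = "min",
) -> float:
    """Nearest-neighbor Tm (deg C) of a primer core under *conditions*.

    Degenerate cores are expanded and summarised with ``degenerate``:
    ``"min"`` (default; the most conservative annealing estimate) or
    ``"mean"``.
    """
    conditions = conditions or DEFAULT_CONDITIONS
    core = core.upper().replace("U", "T")
    if not core:
        raise ValueError("empty sequence")
    if "-" in core:
        raise ValueError("gapped sequence")
    if len(core) < MIN_CORE_LEN:
        raise ValueError(f"core too short for NN model: {len(core)} < {MIN_CORE_LEN}")
    if degenerate not in ("min", "mean"):
        raise ValueError("degenerate must be 'min' or 'mean'")
    tms = [
        _tm_concrete(s, conditions)
        for s in expand_degenerate(core, DEGENERACY_LIMIT)
    ]
    return min(tms) if degenerate == "min" else sum(tms) / len(tms)


class MismatchClass(enum.Enum):
    MATCH = "match"
    PERMISSIVE_WOBBLE = "permissive_wobble"
    PENALIZED = "penalized"


_WOBBLE_PAIRS = {("G", "T"), ("T", "G")}


def classify_mismatch(primer_base: str, template_base: str) -> MismatchClass:
    """Classify a primer-template base pair given in duplex orientation.

    ``template_base`` is the base the primer base physically pairs against.
    Watson-Crick pairs are matches; G.T/T.G are permissive wobbles; every
    other combination is a penalized mismatch. Degenerate codes are
    rejected — expand first.
    """
    p, t = primer_base.upper(), template_base.upper()
    if p not in "ACGT" or t not in "ACGT" or len(p) != 1 or len(t) != 1:
        raise ValueError(
            f"classify_mismatch requires concrete A/C/G/T bases, got ({primer_base!r}, {template_base!r})"
        )
    if t == complement(p):
        return MismatchClass.MATCH
    if (p, t) in _WOBBLE_PAIRS:
        return MismatchClass.PERMISSIVE_WOBBLE
    return MismatchClass.PENALIZED


def _classify_sets(primer_set: frozenset[str], template_set: frozenset[str]) -> MismatchClass:
    """Best-case classification with IUPAC degeneracy on either side.

    A degenerate position matches if any expansion matches (zero cost);
    failing that, it is a wobble if any expansion pair wobbles.
    """
    if any(complement(p) in template_set for p in primer_set):
        return MismatchClass.MATCH
    if any((p, t) in _WOBBLE_PAIRS for p in primer_set for t in template_set):
        return MismatchClass.PERMISSIVE_WOBBLE
    return MismatchClass.PENALIZED


def paired_template(site_sense: str, strand: str) -> str:
    """Convert a sense-strand binding site into primer-coordinate duplex bases.

    Returns a string of the same length where position i is the template base
    physically pairing with primer position i. A ``+``-strand (forward)
    primer anneals to the antisense strand, so each sense base maps to its
    complement; a ``-``-strand (reverse) primer anneals to the sense strand
    read 3'->5', so the site is simply reversed.
    """
    if strand == "+":
        return complement(site_sense)
    if strand == "-":
        return site_sense[::-1]
    raise ValueError(f"strand must be '+' or '-', got {strand!r}")


def audit_site(primer_core: str, site: str, window: int = 5) -> tuple[int, int, int]:
    """Audit a primer against a duplex-orientation template site.

    Returns ``(total_mismatches, penalized_in_window, wobbles_in_window)``
    where mismatch totals count every non-match position (wobbles included)
    and the window covers the ``window`` bases nearest the primer 3' end.
    IUPAC degeneracy on either side is matched at zero cost.
    """
    if len(site) != len(primer_core):
        raise ValueError(
            f"site length {len(site)} != primer length {len(primer_core)}"
        )
    if window > len(primer_core):
        raise ValueError("window longer than primer")
    total = 0
    penalized_3p = 0
    wobble_3p = 0
    n = len(primer_core)
    for i, (p, t) in enumerate(zip(primer_core, site)):
        cls = _classify_sets(IUPAC_SETS[p], IUPAC_SETS[t])
        if cls is not MismatchClass.MATCH:
            total += 1
        if i >= n - window:
            if cls is MismatchClass.PENALIZED:
                penalized_3p += 1
            elif cls is MismatchClass.PERMISSIVE_WOBBLE:
                wobble_3p += 1
    return total, penalized_3p, wobble_3p


def count_3prime_penalized(primer_core: str, site: str, window: int = 5) -> int:
    """Penalized (non-match, non-wobble) positions among the 3'-terminal
    ``window`` bases, with *site* given in duplex orientation."""
    return audit_site(primer_core, site, window)[1]
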