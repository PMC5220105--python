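"""N2O isotopologue accounting.

The IRMS measures the molecular ion ratios 45R = [45N2O]/[44N2O] and
46R = [46N2O]/[44N2O].  Converting these to molecular fractions and then to
absolute isotopologue amounts is the entry point for all tracer-production
rate calculations:

    45F = 45R / (1 + 45R + 46R)      46F = 46R / (1 + 45R + 46R)
    45N2O = 45F * [total N2O]        46N2O = 46F * [total N2O]

(The fraction formulas are the algebraic simplification of the nested form
45F = 1/(1 + 46R/45R + 1/45R).)  The module also carries delta notation,
site preference, the two-point standard calibration, kill-control (t0)
blank subtraction, and the optional mass-dependent 17O correction of the
mass-45 signal.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

from . import constants as C

__all__ = [
    "ReferenceScale",
    "MolecularRatios",
    "MolecularFractions",
    "N2OIsotopologueState",
    "DeltaValue",
    "N2OIsotopeSignature",
    "ratios_to_fractions",
    "fractions_to_ratios",
    "fractions_to_amounts",
    "amounts_to_ratios",
    "delta_from_ratio",
    "ratio_from_delta",
    "site_preference",
    "two_point_calibration",
    "subtract_t0_blank",
    "r17_mass_dependent",
    "mass45_15n_component",
    "natural_abundance_ratios",
]


class ReferenceScale(enum.Enum):
    AIR_N2 = "AIR_N2"
    VSMOW = "VSMOW"


@dataclass(frozen=True)
class MolecularRatios:
    """Calibrated molecular ion ratios of N2O."""

    r45: float
    r46: float

    def __post_init__(self) -> None:
        if self.r45 < 0 or self.r46 < 0:
            raise ValueError(f"molecular ratios must be >= 0, got {self}")


@dataclass(frozen=True)
class MolecularFractions:
    """Molecular fractions of the heavy isotopologues (of total N2O)."""

    f45: float
    f46: float

    def __post_init__(self) -> None:
        if self.f45 < 0 or self.f46 < 0:
            raise ValueError(f"molecular fractions must be >= 0, got {self}")
        if self.f45 + self.f46 > 1.0 + C.TOL_FRACTION:
            raise ValueError(f"f45 + f46 must be <= 1, got {self}")

    @property
    def f44(self) -> float:
        return 1.0 - self.f45 - self.f46


@dataclass(frozen=True)
class N2OIsotopologueState:
    """Absolute isotopologue amounts (nmol) of N2O in one bottle."""

    n44: float
    n45: float
    n46: float

    def __post_init__(self) -> None:
        for name in ("n44", "n45", "n46"):
            if getattr(self, name) < -C.TOL_AMOUNT:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")

    @property
    def total(self) -> float:
        return self.n44 + self.n45 + self.n46


@dataclass(frozen=True)
class DeltaValue:
    """A delta value (permil) on a named reference scale."""

    value: float
    reference: ReferenceScale = ReferenceScale.AIR_N2

    def __post_init__(self) -> None:
        if self.value <= -1000.0:
            raise ValueError("delta values below -1000 permil are unphysical")


@dataclass(frozen=True)
class N2OIsotopeSignature:
    """Bulk and site-specific isotopic composition of an N2O pool.

    ``sp`` (site preference) is the delta15N of the central (alpha) nitrogen
    minus that of the terminal (beta) nitrogen; the bulk delta15N is their
    mean.  Both identities are enforced at construction.
    """

    d15n_bulk: float
    d18o: float
    d15n_alpha: float
    d15n_beta: float

    def __post_init__(self) -> None:
        if abs(self.d15n_bulk - 0.5 * (self.d15n_alpha + self.d15n_beta)) > 1e-6:
            raise ValueError("d15n_bulk must equal (alpha + beta)/2")

    @property
    def sp(self) -> float:
        return self.d15n_alpha - self.d15n_beta

    @classmethod
    def from_bulk_and_sp(cls, d15n_bulk: float, d18o: float, sp: float) -> "N2OIsotopeSignature":
        return cls(
            d15n_bulk=d15n_bulk,
            d18o=d18o,
            d15n_alpha=d15n_bulk + sp / 2.0,
            d15n_beta=d15n_bulk - sp / 2.0,
        )


def ratios_to_fractions(r: MolecularRatios) -> MolecularFractions:
    """Convert 45/44 and 46/44 ratios to molecular fractions.

    ``r45 = r46 = 0`` (no heavy isotopologues) maps to zero fractions.
    """
    denom = 1.0 + r.r45 + r.r46
    return MolecularFractions(f45=r.r45 / denom, f46=r.r46 / denom)


def fractions_to_ratios(f: MolecularFractions) -> MolecularRatios:
    """Inverse of :func:`ratios_to_fractions`."""
    f44 = f.f44
    if f44 <= 0:
        raise ValueError("cannot form ratios when f44 = 0 (no 44N2O)")
    return MolecularRatios(r45=f.f45 / f44, r46=f.f46 / f44)


def fractions_to_amounts(f: MolecularFractions, total_n2o: float) -> N2OIsotopologueState:
    """Split a total N2O amount (nmol) into isotopologue amounts."""
    if total_n2o < 0:
        raise ValueError(f"total_n2o must be >= 0, got {total_n2o}")
    n45 = f.f45 * total_n2o
    n46 = f.f46 * total_n2o
    return N2OIsotopologueState(n44=total_n2o - n45 - n46, n45=n45, n46=n46)


def amounts_to_ratios(state: N2OIsotopologueState) -> MolecularRatios:
    if state.n44 <= 0:
        raise ValueError("cannot form ratios when n44 = 0")
    return MolecularRatios(r45=state.n45 / state.n44, r46=state.n46 / state.n44)


def delta_from_ratio(
    r_sample: float,
    r_reference: float,
    reference: ReferenceScale = ReferenceScale.AIR_N2,
) -> DeltaValue:
    """delta = (r_sample / r_reference - 1) * 1000 permil."""
    if r_reference <= 0:
        raise ValueError("reference ratio must be > 0")
    return DeltaValue(value=(r_sample / r_reference - 1.0) * 1000.0, reference=reference)


def ratio_from_delta(delta: DeltaValue | float, r_reference: float) -> float:
    """Exact inverse of :func:`delta_from_ratio`."""
    if r_reference <= 0:
        raise ValueError("reference ratio must be > 0")
    value = delta.value if isinstance(delta, DeltaValue) else float(delta)
    return r_reference * (1.0 + value / 1000.0)


def site_preference(d15n_alpha: float, d15n_beta: float) -> float:
    """SP = delta15N(alpha, central N) - delta15N(beta, terminal N)."""
    return d15n_alpha - d15n_beta


def two_point_calibration(
    measured: DeltaValue,
    std1_measured: DeltaValue,
    std1_true: DeltaValue,
    std2_measured: DeltaValue,
    std2_true: DeltaValue,
) -> DeltaValue:
    """Linear calibration through two isotopic standards.

    Maps the measured scale onto the true scale with the straight line
    through (std1_measured, std1_true) and (std2_measured, std2_true).
    """
    x1, x2 = std1_measured.value, std2_measured.value
    if x1 == x2:
        raise ValueError("degenerate calibration: identical standard measurements")
    slope = (std2_true.value - std1_true.value) / (x2 - x1)
    return DeltaValue(
        value=std1_true.value + slope * (measured.value - x1),
        reference=measured.reference,
    )


def subtract_t0_blank(
    state: N2OIsotopologueState,
    t0_state: N2OIsotopologueState,
    state_sd: tuple[float, float, float] | None = None,
    t0_sd: tuple[float, float, float] | None = None,
) -> tuple[tuple[float, float, float], tuple[float, float, float] | None]:
    """Excess isotopologue amounts relative to the kill-control (t0) bottle.

    Returns per-isotopologue differences (44, 45, 46) in nmol; these may be
    negative — downstream significance testing, not clipping, decides what
    is real production.  If per-term standard deviations are supplied the
    quadrature-propagated sds are returned as well.
    """
    diff = (
        state.n44 - t0_state.n44,
        state.n45 - t0_state.n45,
        state.n46 - t0_state.n46,
    )
    if state_sd is None and t0_sd is None:
        return diff, None
    s = state_sd or (0.0, 0.0, 0.0)
    t = t0_sd or (0.0, 0.0, 0.0)
    sd = tuple(math.hypot(a, b) for a, b in zip(s, t))
    return diff, sd  # type: ignore[return-value]


def r17_mass_dependent(r18: float, table: dict | None = None) -> float:
    """17O/16O implied by an 18O/16O ratio under mass-dependent fractionation.

    17R = 17R_ref * (18R / 18R_ref) ** 0.516.
    """
    c = table or C.default_constants()
    return c["r17_vsmow"] * (r18 / c["r18_vsmow"]) ** c["o17_exponent"]


def mass45_15n_component(
    r45: float,
    d18o: float | None = None,
    correct_o17: bool = False,
    table: dict | None = None,
) -> float:
    """Portion of the mass-45 molecular ratio attributable to 15N.

    The mass-45 isotopologue pool includes 14N14N17O.  In natural-abundance
    work (``correct_o17=True``) the 17O contribution is removed using the
    mass-dependent relation anchored at the sample's delta18O (a sample at
    delta18O = 0 gets exactly the VSMOW 17O abundance).  In tracer work the
    15N enrichment dwarfs the 17O term and no correction is applied.
    """
    if not correct_o17:
        return r45
    c = table or C.default_constants()
    d18 = 0.0 if d18o is None else d18o
    r18 = c["r18_vsmow"] * (1.0 + d18 / 1000.0)
    return r45 - r17_mass_dependent(r18, c)


def natural_abundance_ratios(
    d15n_bulk: float = 0.0,
    d18o: float = 0.0,
    table: dict | None = None,
) -> MolecularRatios:
    """Molecular ratios of an N2O pool with a given bulk isotopic composition.

    Assumes a statistical (uncorrelated) distribution of the rare isotopes:
    45R = 2*15R + 17R and 46R = 18R + 15R^2 + 2*15R*17R, with 17R tied to
    18R by the mass-dependent relation.
    """
    c = table or C.default_constants()
    r15 = c["r15_air_n2"] * (1.0 + d15n_bulk / 1000.0)
    r18 = c["r18_vsmow"] * (1.0 + d18o / 1000.0)
    r17 = r17_mass_dependent(r18, c)
    return MolecularRatios(
        r45=2.0 * r15 + r17,
        r46=r18 + r15 * r15 + 2.0 * r15 * r17,
    )
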