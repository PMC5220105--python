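"""Acid-base speciation, abiotic NOx kinetics, and N2O air-water equilibrium.

The speciation functions are plain Henderson-Hasselbalch relations: the
protonated species HNO2 (pKa 2.8) and NH3 (pKa of NH4+ 9.25) are the
reactive forms in the abiotic chemistry and in enzymatic ammonia oxidation
respectively, so their concentrations at incubation pH decide whether the
uncatalyzed reactions can matter.

The four-reaction abiotic N2O-forming network is evaluated as
instantaneous mass-action rates:

    2 HNO2        <-> NO2(g) + NO + H2O    r = k [HNO2]^2     k = 1.6 M-1 d-1
    NO + NO2      <-> N2O3                 r = k [NO][NO2]    k = 9.5e7 M-1 d-1
    N2O3 + NH2OH   -> N2O + HNO2 + H2O     r = k [N2O3][NH2OH] k = 1.7e13 M-1 d-1
    2 NO + O2      -> 2 NO2                r = k [NO]^2 [O2]  k = 1.8e11 M-2 d-1

The first reaction is rate-limiting at circumneutral pH: at ~2e-11 M HNO2
its rate is >10 orders of magnitude below observed tracer N2O production,
which is the quantitative basis for excluding uncatalyzed nitrous-acid
disproportionation as an N2O source.  An optional mass-action integrator
is included for illustration.

Air-water equilibrium uses the cited seawater solubility polynomial
(moist-air form, mol L-1 atm-1); the saturation anomaly is
dN2O = measured - equilibrium.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from . import constants as C

__all__ = [
    "SpeciationParams",
    "KineticNetworkParams",
    "SaturationResult",
    "hno2_concentration",
    "nh3_fraction",
    "abiotic_pathway_rates",
    "integrate_network",
    "n2o_equilibrium",
    "delta_n2o",
]


@dataclass(frozen=True)
class SpeciationParams:
    pka_nh4: float = C.PKA_NH4
    pka_hno2: float = C.PKA_HNO2
    temperature: float = 25.0  # degC; pKa values used as printed (25 degC)

    def __post_init__(self) -> None:
        for pka in (self.pka_nh4, self.pka_hno2):
            if not 0.0 < pka < 14.0:
                raise ValueError(f"pKa must lie in (0, 14), got {pka}")


@dataclass(frozen=True)
class KineticNetworkParams:
    k_hno2_disprop: float = C.K_HNO2_DISPROPORTIONATION
    k_no_no2: float = C.K_NO_NO2
    k_n2o3_nh2oh: float = C.K_N2O3_NH2OH
    k_no_o2: float = C.K_NO_O2

    def __post_init__(self) -> None:
        for k in (self.k_hno2_disprop, self.k_no_no2, self.k_n2o3_nh2oh, self.k_no_o2):
            if k <= 0:
                raise ValueError("rate constants must be > 0")


@dataclass(frozen=True)
class SaturationResult:
    measured: float     # nM
    equilibrium: float  # nM

    @property
    def delta_n2o(self) -> float:
        """Saturation anomaly, nM; positive = oversaturated."""
        return self.measured - self.equilibrium


def hno2_concentration(
    ph: float, total_nitrite: float, params: SpeciationParams | None = None
) -> float:
    """[HNO2] (M) in a nitrite pool of total concentration ``total_nitrite`` (M)."""
    if total_nitrite < 0:
        raise ValueError("total nitrite must be >= 0")
    p = params or SpeciationParams()
    return total_nitrite / (1.0 + 10.0 ** (ph - p.pka_hno2))


def nh3_fraction(ph: float, params: SpeciationParams | None = None) -> float:
    """Fraction of the total ammonium pool present as free NH3."""
    p = params or SpeciationParams()
    return 1.0 / (1.0 + 10.0 ** (p.pka_nh4 - ph))


def abiotic_pathway_rates(
    concentrations: dict[str, float],
    params: KineticNetworkParams | None = None,
) -> dict[str, float]:
    """Instantaneous mass-action rates (M/day) of the four abiotic reactions.

    ``concentrations`` supplies molar values for any of HNO2, NO, NO2g,
    N2O3, NH2OH, O2; missing species default to zero.
    """
    for name, value in concentrations.items():
        if value < 0:
            raise ValueError(f"[{name}] must be >= 0")
    p = params or KineticNetworkParams()
    c = {k: concentrations.get(k, 0.0) for k in ("HNO2", "NO", "NO2g", "N2O3", "NH2OH", "O2")}
    return {
        "hno2_disproportionation": p.k_hno2_disprop * c["HNO2"] ** 2,
        "no_no2_combination": p.k_no_no2 * c["NO"] * c["NO2g"],
        "n2o3_nh2oh_n2o": p.k_n2o3_nh2oh * c["N2O3"] * c["NH2OH"],
        "no_o2_oxidation": p.k_no_o2 * c["NO"] ** 2 * c["O2"],
    }


def integrate_network(
    initial: dict[str, float],
    t_days: float,
    params: KineticNetworkParams | None = None,
    n_eval: int = 100,
):
    """Integrate the mass-action network forward in time (illustrative).

    Returns (times, trajectories) where trajectories maps species names,
    plus cumulative 'N2O', to concentration arrays (M).  The stiff network
    is handled with an implicit solver.
    """
    from scipy.integrate import solve_ivp

    species = ["HNO2", "NO", "NO2g", "N2O3", "NH2OH", "O2", "N2O"]
    y0 = [initial.get(s, 0.0) for s in species]

    def rhs(_t, y):
        c = dict(zip(species, np.maximum(y, 0.0)))
        r = abiotic_pathway_rates(c, params)
        r10, r11 = r["hno2_disproportionation"], r["no_no2_combination"]
        r12, r13 = r["n2o3_nh2oh_n2o"], r["no_o2_oxidation"]
        return [
            -2.0 * r10 + r12,          # HNO2
            r10 - r11 - 2.0 * r13,     # NO
            r10 - r11 + 2.0 * r13,     # NO2(g/aq radical)
            r11 - r12,                 # N2O3
            -r12,                      # NH2OH
            -r13,                      # O2
            r12,                       # N2O (cumulative product)
        ]

    sol = solve_ivp(
        rhs, (0.0, t_days), y0, method="LSODA",
        t_eval=np.linspace(0.0, t_days, n_eval), rtol=1e-8, atol=1e-30,
    )
    return sol.t, dict(zip(species, sol.y))


def n2o_equilibrium(
    temperature: float,
    salinity: float,
    x_n2o_atm: float = C.X_N2O_ATM,
    pressure_atm: float = 1.0,
) -> float:
    """Dissolved N2O (nM) at air-water equilibrium.

    Evaluates the moist-air solubility function F' (mol L-1 atm-1) from
    the constants table and multiplies by the atmospheric N2O mole
    fraction and total pressure.
    """
    if not -2.0 <= temperature <= 40.0 or not 0.0 <= salinity <= 40.0:
        warnings.warn(
            f"T = {temperature} degC, S = {salinity} outside the fitted range",
            stacklevel=2,
        )
    a1, a2, a3, a4 = C.WEISS_PRICE_N2O_A
    b1, b2, b3 = C.WEISS_PRICE_N2O_B
    t100 = (temperature + 273.15) / 100.0
    ln_f = (
        a1 + a2 / t100 + a3 * math.log(t100) + a4 * t100 * t100
        + salinity * (b1 + b2 * t100 + b3 * t100 * t100)
    )
    return math.exp(ln_f) * x_n2o_atm * pressure_atm * 1e9  # mol/L -> nM


def delta_n2o(measured: float, equilibrium: float) -> SaturationResult:
    """Saturation disequilibrium of dissolved N2O (both in nM)."""
    return SaturationResult(measured=measured, equilibrium=equilibrium)
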