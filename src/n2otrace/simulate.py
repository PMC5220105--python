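"""Synthetic incubation experiments with known ground truth.

The generator emulates a triplicate bottle-sacrifice tracer experiment:
bottles of lake or sea water spiked with 1 uM of 98.5% 15NH4+ (paired with
natural-abundance NO2-) or 1 uM of 99.2% 15NO2- (paired with natural
NH4+), sacrificed at 0, ~5, ~17 and ~30 h.  Dissolved pools evolve by
zero-order ammonia and nitrite oxidation; N2O isotopologues accumulate at
a rate set by the ground-truth yield with N atoms drawn per the chosen
formation mechanism; measurements are perturbed by multiplicative noise on
concentrations/amounts and additive noise on atom fractions.

Pool forward model.  The per-timepoint zero-order balances treat the NO2-
atom fraction F as constant over [0, t] while F actually drifts as the
labeled pool turns over.  Two discretizations are provided:

* ``pool_model="trapezoid"`` (default): each bottle's pools satisfy the
  balances written with the trapezoidal mean F = (F(0) + F(t))/2 — the
  same convention the rate estimator uses, so noise-free inversion is
  exact.  This is the second-order-accurate discretization of the true
  dynamics.
* ``pool_model="ode"``: the exact closed-form solution of the continuous
  zero-order system, for quantifying the (small) discretization bias.

Both conserve total fixed N and 15N exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import constants as C
from .attribution import MechanismKind, MechanismSpec, mechanism_isotopologue_distribution
from .chemistry import n2o_equilibrium
from .isotopocules import (
    N2OIsotopeSignature,
    fractions_to_amounts,
    natural_abundance_ratios,
    ratios_to_fractions,
)
from .kinetics import TreatmentLabel, initial_atom_fraction

__all__ = [
    "NoiseModel",
    "ExperimentDesign",
    "GroundTruth",
    "simulate_experiment",
    "simulate_profile",
    "BOTTLE_COLUMNS",
]

#: Canonical bottle-measurement table columns (units fixed by the format).
BOTTLE_COLUMNS = [
    "experiment_id",
    "treatment",
    "ph_status",
    "ph",
    "o2_status",
    "o2_um",
    "tracer",
    "bottle_id",
    "time_h",
    "conc_nh4_um",
    "conc_no2_um",
    "conc_no3_um",
    "f15_no2",
    "f15_no3",
    "n2o_total_nmol",
    "r45",
    "r46",
]

PROFILE_COLUMNS = [
    "depth_m",
    "temperature_c",
    "salinity",
    "ph",
    "o2_um",
    "nh4_um",
    "no2_um",
    "no3_um",
    "n2o_nm",
    "d15n_n2o",
    "d18o_n2o",
    "d15n_alpha",
    "d15n_beta",
    "d15n_no3",
    "d18o_no3",
]


@dataclass(frozen=True)
class NoiseModel:
    """Relative/absolute measurement noise, matched to replicate scatter
    of the order reported for field incubations (~2% on concentrations)."""

    conc_rel: float = 0.02        # multiplicative, on uM concentrations
    n2o_rel: float = 0.01         # multiplicative, on total N2O nmol
    ratio_rel: float = 0.01       # multiplicative, on 45/44 and 46/44 ratios
    f15_abs: float = 0.002        # additive, on atom fractions

    def __post_init__(self) -> None:
        for v in (self.conc_rel, self.n2o_rel, self.ratio_rel, self.f15_abs):
            if v < 0:
                raise ValueError("noise levels must be >= 0")

    @classmethod
    def none(cls) -> "NoiseModel":
        return cls(0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class ExperimentDesign:
    """Bottle-sacrifice design of one incubation experiment."""

    treatments: tuple[TreatmentLabel, ...] = (TreatmentLabel(),)
    timepoints: tuple[float, ...] = (0.0, 5.0, 17.0, 30.0)  # hours
    replicates: int = 3
    t0_replicates: int = 1
    tracer_conc: float = 1.0          # uM added
    purity_nh4: float = 0.985         # 15NH4Cl tracer purity
    purity_no2: float = 0.992         # Na15NO2 tracer purity
    ambient_nh4: float = 0.47         # uM before tracer addition
    ambient_no2: float = 0.20
    ambient_no3: float = 60.0
    volume_l: float = 0.12

    def __post_init__(self) -> None:
        if self.replicates < 1 or self.t0_replicates < 1:
            raise ValueError("replicates must be >= 1")
        if sorted(self.timepoints) != list(self.timepoints):
            raise ValueError("timepoints must be ascending")
        if 0.0 not in self.timepoints:
            raise ValueError("design must include a t = 0 kill control")

    def f0_nh4(self, tracer: str) -> float:
        """Initial 15F of the NH4+ pool under the given tracer regime."""
        if tracer == "NH4_labeled":
            return initial_atom_fraction(self.tracer_conc, self.purity_nh4, self.ambient_nh4)
        return initial_atom_fraction(0.0, 0.0, self.ambient_nh4)

    def f0_no2(self, tracer: str) -> float:
        if tracer == "NO2_labeled":
            return initial_atom_fraction(self.tracer_conc, self.purity_no2, self.ambient_no2)
        return initial_atom_fraction(0.0, 0.0, self.ambient_no2)


@dataclass(frozen=True)
class GroundTruth:
    """True process parameters behind a simulated experiment."""

    r_amm_ox: float = 0.50            # uM/day
    r_nit_ox: float = 0.64            # uM/day
    mechanism_kind: MechanismKind = MechanismKind.HYBRID
    n2o_yield: float = 1e-4           # mol 15N-N2O per mol 15N-NOx (NH4 frame)
    background_n2o_nmol: float = 1.2  # ~10 nM in a 0.12 L bottle
    background_d15n: float = 4.9
    background_d18o: float = 44.5
    background_sp: float = 15.3
    nh4_regeneration: float = 0.0     # uM/day, optional bias injector
    periplasmic_exchange: float = 1.0 # fraction of exogenous NO2- seen by the mechanism
    amm_influx_f15: float | None = None  # None: influx carries the NH4 pool's f15
    noise: NoiseModel = field(default_factory=NoiseModel)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.r_amm_ox < 0 or self.r_nit_ox < 0:
            raise ValueError("rates must be >= 0")
        if self.n2o_yield < 0:
            raise ValueError("yield must be >= 0")
        if not 0.0 <= self.periplasmic_exchange <= 1.0:
            raise ValueError("periplasmic_exchange must lie in [0, 1]")

    @property
    def background_signature(self) -> N2OIsotopeSignature:
        return N2OIsotopeSignature.from_bulk_and_sp(
            self.background_d15n, self.background_d18o, self.background_sp
        )


def _pools_trapezoid(
    t_days: float,
    n14_no2_0: float,
    n15_no2_0: float,
    n14_no3_0: float,
    n15_no3_0: float,
    r_amm: float,
    r_nit: float,
    f_influx: float,
) -> tuple[float, float, float, float]:
    """Zero-order pool update using the trapezoidal atom-fraction mean.

    Solves b(t) = b0 + f_influx*R_amm*t - Fbar*R_nit*t with
    Fbar = (b0/N0 + b(t)/N(t))/2, which is linear in b(t).
    """
    n0 = n14_no2_0 + n15_no2_0
    n_t = n0 + (r_amm - r_nit) * t_days
    if n_t <= 0:
        raise ValueError(
            f"NO2- pool driven negative at t = {t_days:.3f} d by R_nit_ox = {r_nit}"
        )
    f_0 = n15_no2_0 / n0 if n0 > 0 else 0.0
    half = 0.5 * r_nit * t_days
    b_t = (n15_no2_0 + f_influx * r_amm * t_days - f_0 * half) / (1.0 + half / n_t)
    if b_t < -1e-12:
        raise ValueError(
            f"15NO2- pool driven negative at t = {t_days:.3f} d by R_nit_ox = {r_nit}"
        )
    b_t = max(b_t, 0.0)
    fbar = 0.5 * (f_0 + b_t / n_t)
    n15_no3 = n15_no3_0 + fbar * r_nit * t_days
    n14_no3 = n14_no3_0 + (1.0 - fbar) * r_nit * t_days
    return n_t - b_t, b_t, n14_no3, n15_no3


def _pools_ode(
    t_days: float,
    n14_no2_0: float,
    n15_no2_0: float,
    n14_no3_0: float,
    n15_no3_0: float,
    r_amm: float,
    r_nit: float,
    f_influx: float,
) -> tuple[float, float, float, float]:
    """Exact closed-form solution of the continuous zero-order system.

    db/dt = f_influx*R_amm - (b/N)*R_nit with N(t) = N0 + (R_amm - R_nit)*t.
    For f_influx = 0 this integrates to b = b0 * (N/N0)^(R_nit/(R_nit-R_amm));
    otherwise a fine fixed-step RK4 is used.
    """
    n0 = n14_no2_0 + n15_no2_0
    dn = r_amm - r_nit
    n_t = n0 + dn * t_days
    if n_t <= 0:
        raise ValueError(
            f"NO2- pool driven negative at t = {t_days:.3f} d by R_nit_ox = {r_nit}"
        )
    if f_influx == 0.0:
        if r_nit == 0.0:
            b_t = n15_no2_0
        elif dn == 0.0:
            b_t = n15_no2_0 * np.exp(-r_nit * t_days / n0)
        else:
            b_t = n15_no2_0 * (n_t / n0) ** (-r_nit / dn)
    else:
        steps = 2000
        h = t_days / steps
        b = n15_no2_0

        def db(tt: float, bb: float) -> float:
            n = n0 + dn * tt
            return f_influx * r_amm - (bb / n) * r_nit

        for i in range(steps):
            tt = i * h
            k1 = db(tt, b)
            k2 = db(tt + h / 2, b + h * k1 / 2)
            k3 = db(tt + h / 2, b + h * k2 / 2)
            k4 = db(tt + h, b + h * k3)
            b += h * (k1 + 2 * k2 + 2 * k3 + k4) / 6.0
        b_t = b
    b_t = max(b_t, 0.0)
    # 15N transferred to NO3- = influx of 15N minus change in 15NO2-
    transfer15 = n15_no2_0 + f_influx * r_amm * t_days - b_t
    n15_no3 = n15_no3_0 + transfer15
    n14_no3 = n14_no3_0 + r_nit * t_days - transfer15
    return n_t - b_t, b_t, n14_no3, n15_no3


def _mechanism_fractions(
    truth: GroundTruth, f_nh4: float, f_no2_exogenous: float
) -> dict[str, float]:
    """Pool atom fractions seen by the N2O-forming mechanism.

    ``periplasmic_exchange`` < 1 mixes the exogenous NO2- label with an
    unlabeled endogenous (periplasmic) NO2- pool fed by ammonia oxidation.
    """
    f_endogenous = f_nh4  # NO2- made in the periplasm carries the NH4 label
    w = truth.periplasmic_exchange
    f_no2_eff = w * f_no2_exogenous + (1.0 - w) * f_endogenous
    return {"NH4": f_nh4, "NO2": f_no2_eff}


def _production_scale(design: ExperimentDesign, truth: GroundTruth) -> float:
    """Total N2O molecule production rate (nM/day), same in both regimes.

    Anchored in the 15NH4+-labeled frame so that the yield estimator
    (15N incorporation over 15NOx production) recovers ``n2o_yield``.
    """
    f_nh4_ref = design.f0_nh4("NH4_labeled")
    f_no2_ref = design.f0_no2("NH4_labeled")
    fr = _mechanism_fractions(truth, f_nh4_ref, f_no2_ref)
    _, p45, p46 = mechanism_isotopologue_distribution(
        MechanismSpec(kind=truth.mechanism_kind, source_f15=fr)
    )
    m15 = p45 + 2.0 * p46  # expected 15N atoms per produced molecule
    if m15 <= 0:
        return 0.0
    return truth.n2o_yield * truth.r_amm_ox * f_nh4_ref * 1000.0 / m15


def simulate_experiment(
    design: ExperimentDesign,
    truth: GroundTruth,
    pool_model: str = "trapezoid",
    experiment_id: str = "synthetic",
) -> pd.DataFrame:
    """Generate a bottle-measurement table for the full design.

    Deterministic given ``truth.rng_seed``; bottle order is fixed by the
    (treatment, timepoint, replicate) loop.
    """
    if pool_model not in ("trapezoid", "ode"):
        raise ValueError("pool_model must be 'trapezoid' or 'ode'")
    step = _pools_trapezoid if pool_model == "trapezoid" else _pools_ode
    rng = np.random.default_rng(truth.rng_seed)
    f_nat = C.natural_abundance_15f()

    bg_ratios = natural_abundance_ratios(truth.background_d15n, truth.background_d18o)
    bg_state = fractions_to_amounts(ratios_to_fractions(bg_ratios), truth.background_n2o_nmol)

    rows = []
    for treatment in design.treatments:
        tracer = treatment.tracer
        f_nh4_0 = design.f0_nh4(tracer)
        f_no2_0 = design.f0_no2(tracer)
        # both regimes add 1 uM to each pool (tracer to one, carrier to the other)
        nh4_0 = design.ambient_nh4 + design.tracer_conc
        no2_0 = design.ambient_no2 + design.tracer_conc
        n15_no2_0 = no2_0 * f_no2_0
        n14_no2_0 = no2_0 - n15_no2_0
        n15_no3_0 = design.ambient_no3 * f_nat
        n14_no3_0 = design.ambient_no3 - n15_no3_0

        p_total_nm_day = _production_scale(design, truth)
        fr = _mechanism_fractions(truth, f_nh4_0, f_no2_0)
        _, p45, p46 = mechanism_isotopologue_distribution(
            MechanismSpec(kind=truth.mechanism_kind, source_f15=fr)
        )

        bottle_no = 0
        for tp in design.timepoints:
            n_rep = design.t0_replicates if tp == 0.0 else design.replicates
            t_days = tp / 24.0
            influx_f = truth.amm_influx_f15
            if influx_f is None:
                influx_f = f_nh4_0 if tracer == "NH4_labeled" else 0.0
            if truth.nh4_regeneration > 0 and influx_f > 0 and t_days > 0:
                # regeneration dilutes 15F_NH4 exponentially toward natural
                # abundance; the influx over [0, t] carries the time average
                f_nat_amb = C.natural_abundance_15f()
                tau = truth.nh4_regeneration * t_days / nh4_0
                influx_f = f_nat_amb + (influx_f - f_nat_amb) * (1.0 - np.exp(-tau)) / tau
            n14_2, n15_2, n14_3, n15_3 = step(
                t_days, n14_no2_0, n15_no2_0, n14_no3_0, n15_no3_0,
                truth.r_amm_ox, truth.r_nit_ox, influx_f,
            )
            produced_nmol = p_total_nm_day * t_days * design.volume_l
            # N2O-N is debited from the NH4+ budget (it leaves via the
            # NH2OH intermediate, never entering the measured NOx pools),
            # keeping total fixed N exactly conserved.
            n2o_n_um = 2.0 * p_total_nm_day * t_days / 1000.0
            nh4_t = (
                nh4_0 - truth.r_amm_ox * t_days - n2o_n_um
                + truth.nh4_regeneration * t_days
            )
            if nh4_t < 0:
                raise ValueError(
                    f"NH4+ pool driven negative at t = {tp} h by R_amm_ox = {truth.r_amm_ox}"
                )
            n44 = bg_state.n44 + produced_nmol * (1.0 - p45 - p46)
            n45 = bg_state.n45 + produced_nmol * p45
            n46 = bg_state.n46 + produced_nmol * p46

            conc_no2 = n14_2 + n15_2
            conc_no3 = n14_3 + n15_3
            f15_no2 = n15_2 / conc_no2
            f15_no3 = n15_3 / conc_no3
            total_n2o = n44 + n45 + n46
            r45, r46 = n45 / n44, n46 / n44

            for _rep in range(n_rep):
                bottle_no += 1
                nz = truth.noise
                m_nh4 = nh4_t * (1.0 + nz.conc_rel * rng.standard_normal())
                m_no2 = conc_no2 * (1.0 + nz.conc_rel * rng.standard_normal())
                m_no3 = conc_no3 * (1.0 + nz.conc_rel * rng.standard_normal())
                m_f2 = np.clip(f15_no2 + nz.f15_abs * rng.standard_normal(), 0.0, 1.0)
                m_f3 = np.clip(f15_no3 + nz.f15_abs * rng.standard_normal(), 0.0, 1.0)
                m_n2o = total_n2o * (1.0 + nz.n2o_rel * rng.standard_normal())
                m_r45 = r45 * (1.0 + nz.ratio_rel * rng.standard_normal())
                m_r46 = r46 * (1.0 + nz.ratio_rel * rng.standard_normal())
                rows.append({
                    "experiment_id": experiment_id,
                    "treatment": treatment.name,
                    "ph_status": treatment.ph_status,
                    "ph": treatment.ph,
                    "o2_status": treatment.o2_status,
                    "o2_um": treatment.o2,
                    "tracer": tracer,
                    "bottle_id": f"{treatment.name}_{tracer}_b{bottle_no:02d}",
                    "time_h": tp,
                    "conc_nh4_um": max(m_nh4, 0.0),
                    "conc_no2_um": max(m_no2, 0.0),
                    "conc_no3_um": max(m_no3, 0.0),
                    "f15_no2": float(m_f2),
                    "f15_no3": float(m_f3),
                    "n2o_total_nmol": max(m_n2o, 0.0),
                    "r45": max(m_r45, 0.0),
                    "r46": max(m_r46, 0.0),
                })
    return pd.DataFrame(rows, columns=BOTTLE_COLUMNS)


#: End-member site preferences (permil): hydroxylamine-pathway N2O vs
#: denitrification-pathway N2O.
SP_HIGH_END = 34.0
SP_LOW_END = -5.0


def simulate_profile(
    n_depths: int = 10,
    high_sp_weight: float | np.ndarray = 0.5,
    delta_n2o_nm: float | np.ndarray = 10.0,
    temperature: float = 11.7,
    salinity: float = 35.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Small synthetic depth profile for saturation and SP bookkeeping.

    Each depth's N2O site preference is the mole-weighted mix of the two
    end-members (34 permil and -5 permil); the measured N2O concentration
    is the air-water equilibrium value plus the requested saturation
    anomaly.
    """
    w = np.broadcast_to(np.asarray(high_sp_weight, dtype=float), (n_depths,)).copy()
    if np.any((w < 0) | (w > 1)):
        raise ValueError("mixing weights must lie in [0, 1]")
    dn2o = np.broadcast_to(np.asarray(delta_n2o_nm, dtype=float), (n_depths,)).copy()
    rng = np.random.default_rng(seed)
    depth = np.linspace(5.0, 5.0 + 45.0 * max(n_depths - 1, 1) / 9.0, n_depths)
    temp = temperature - 0.02 * depth
    eq = np.array([n2o_equilibrium(t, salinity) for t in temp])
    sp = w * SP_HIGH_END + (1.0 - w) * SP_LOW_END
    d15n = 5.0 + rng.normal(0.0, 0.2, n_depths)
    d18o = 44.0 + rng.normal(0.0, 0.3, n_depths)
    return pd.DataFrame({
        "depth_m": depth,
        "temperature_c": temp,
        "salinity": np.full(n_depths, salinity),
        "ph": np.full(n_depths, 7.5),
        "o2_um": np.linspace(250.0, 50.0, n_depths),
        "nh4_um": np.linspace(3.8, 0.9, n_depths),
        "no2_um": np.linspace(1.2, 0.2, n_depths),
        "no3_um": np.linspace(58.0, 92.0, n_depths),
        "n2o_nm": eq + dn2o,
        "d15n_n2o": d15n,
        "d18o_n2o": d18o,
        "d15n_alpha": d15n + sp / 2.0,
        "d15n_beta": d15n - sp / 2.0,
        "d15n_no3": np.full(n_depths, 5.3),
        "d18o_no3": np.full(n_depths, 3.0),
    }, columns=PROFILE_COLUMNS)
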