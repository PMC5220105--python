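"""Nitrification rate inference from 15N-labeled pool time series.

Two estimators of the ammonia oxidation rate are provided, mirroring the
two tracer designs of a bottle-sacrifice incubation experiment:

* ``ammonia_oxidation_rate_regression`` — ordinary least squares of the
  excess [15NOx-] produced during 15NH4+ incubations against time, scaled
  by the isotope dilution factor 1/15F0 of the initial NH4+ pool.

* ``zero_order_rates`` — the four-equation zero-order pool model applied to
  15NO2- incubations.  Writing F for the 15N atom fraction of the NO2-
  pool, the per-timepoint balances are

      [14NO2-](t) = [14NO2-]0 + R_amm_ox*t - (1-F)*R_nit_ox*t
      [15NO2-](t) = [15NO2-]0 - F*R_nit_ox*t
      [14NO3-](t) = [14NO3-]0 + (1-F)*R_nit_ox*t
      [15NO3-](t) = [15NO3-]0 + F*R_nit_ox*t

  R_nit_ox comes from the 15N balances (NO2- loss and NO3- gain give two
  estimates, combined by weighted least squares) and R_amm_ox from the
  14NO2- balance.  F drifts as the labeled pool turns over, so each
  per-timepoint solve uses the trapezoidal mean of F at 0 and t.

A first-order alternative (log-linear fit of [NH4+]) and simple treatment
comparisons round out the module.  Times are hours internally; rates are
reported per day.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .constants import natural_abundance_15f

__all__ = [
    "Pool",
    "RateMethod",
    "IsotopePoolSeries",
    "RatePair",
    "TreatmentLabel",
    "initial_atom_fraction",
    "ammonia_oxidation_rate_regression",
    "zero_order_rates",
    "net_nitrite_consumption",
    "first_order_fit",
    "percent_rate_change",
]

HOURS_PER_DAY = 24.0


class Pool(enum.Enum):
    NH4 = "NH4"
    NO2 = "NO2"
    NO3 = "NO3"
    NOX = "NOx"


class RateMethod(enum.Enum):
    REGRESSION_15NOX = "regression_15NOx"
    ZERO_ORDER_POOL_MODEL = "zero_order_pool_model"
    FIRST_ORDER = "first_order"


@dataclass(frozen=True)
class IsotopePoolSeries:
    """Time series of one dissolved N pool across sacrificed bottles.

    ``times`` are hours since tracer addition; repeated times are replicate
    bottles.  ``atom_fraction_15`` is optional (concentration-only series
    are valid inputs for the first-order fit and the regression estimator).
    """

    pool: Pool
    times: tuple[float, ...]
    conc_total: tuple[float, ...]
    atom_fraction_15: tuple[float, ...] | None = None
    replicate_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        n = len(self.times)
        if len(self.conc_total) != n:
            raise ValueError("times and conc_total must have equal length")
        if any(t < 0 for t in self.times):
            raise ValueError("times must be >= 0 hours")
        if sorted(self.times) != list(self.times):
            raise ValueError("times must be ascending (replicates share a time)")
        if any(c < 0 for c in self.conc_total):
            raise ValueError("concentrations must be >= 0")
        if self.atom_fraction_15 is not None:
            if len(self.atom_fraction_15) != n:
                raise ValueError("atom_fraction_15 length mismatch")
            if any(not 0.0 <= f <= 1.0 for f in self.atom_fraction_15):
                raise ValueError("atom fractions must lie in [0, 1]")


@dataclass(frozen=True)
class RatePair:
    """(R_amm_ox, R_nit_ox) in uM/day with 1-sigma uncertainties."""

    r_amm_ox: float | None
    r_nit_ox: float | None
    sd_amm_ox: float | None = None
    sd_nit_ox: float | None = None
    method: RateMethod = RateMethod.ZERO_ORDER_POOL_MODEL
    n: int = 0

    def __post_init__(self) -> None:
        for sd in (self.sd_amm_ox, self.sd_nit_ox):
            if sd is not None and sd < 0:
                raise ValueError("standard deviations must be >= 0")


@dataclass(frozen=True)
class TreatmentLabel:
    """Experimental treatment: pH / O2 manipulation and tracer identity."""

    ph_status: str = "untreated"      # untreated | reduced
    ph: float = 7.54
    o2_status: str = "untreated"
    o2: float = 290.0                 # uM
    tracer: str = "NH4_labeled"       # NH4_labeled | NO2_labeled

    def __post_init__(self) -> None:
        if not 0.0 < self.ph < 14.0:
            raise ValueError("pH must be in (0, 14)")
        if self.o2 < 0:
            raise ValueError("O2 must be >= 0")
        if self.ph_status not in ("untreated", "reduced"):
            raise ValueError(f"bad ph_status {self.ph_status!r}")
        if self.o2_status not in ("untreated", "reduced"):
            raise ValueError(f"bad o2_status {self.o2_status!r}")
        if self.tracer not in ("NH4_labeled", "NO2_labeled"):
            raise ValueError(f"bad tracer {self.tracer!r}")

    @property
    def name(self) -> str:
        return f"{self.o2_status}-O2_{self.ph_status}-pH"


def initial_atom_fraction(
    added_tracer: float,
    tracer_purity: float,
    ambient_conc: float,
    ambient_delta15: float = 0.0,
) -> float:
    """15F of a pool right after spiking it with labeled substrate.

    15F0 = (added*purity + ambient*f_amb) / (added + ambient), with f_amb
    the atom fraction implied by the ambient pool's delta15N (default 0
    permil, i.e. natural abundance).
    """
    if added_tracer < 0 or ambient_conc < 0:
        raise ValueError("concentrations must be >= 0")
    total = added_tracer + ambient_conc
    if total <= 0:
        raise ValueError("added + ambient pool must be > 0")
    if not 0.0 <= tracer_purity <= 1.0:
        raise ValueError("tracer purity must lie in [0, 1]")
    f_amb = natural_abundance_15f(ambient_delta15)
    return (added_tracer * tracer_purity + ambient_conc * f_amb) / total


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, slope standard error and two-sided slope p-value."""
    res = stats.linregress(x, y)
    stderr = float(res.stderr) if np.isfinite(res.stderr) else 0.0
    pvalue = float(res.pvalue) if np.isfinite(res.pvalue) else 1.0
    return float(res.slope), stderr, pvalue


def ammonia_oxidation_rate_regression(series: IsotopePoolSeries, f0: float) -> RatePair:
    """Ammonia oxidation rate from excess 15NOx- production (uM vs hours).

    OLS slope of [15NOx-] against time, times 24 h/day, times the isotope
    dilution factor 1/15F0 of the initial NH4+ pool.
    """
    if not 0.0 < f0 <= 1.0:
        raise ValueError("f0 must lie in (0, 1]")
    t = np.asarray(series.times, dtype=float)
    if len(np.unique(t)) < 3:
        raise ValueError("need >= 3 distinct timepoints for the regression estimator")
    y = np.asarray(series.conc_total, dtype=float)
    slope, stderr, _ = _ols(t, y)
    scale = HOURS_PER_DAY / f0
    return RatePair(
        r_amm_ox=slope * scale,
        r_nit_ox=None,
        sd_amm_ox=stderr * scale,
        sd_nit_ox=None,
        method=RateMethod.REGRESSION_15NOX,
        n=len(t),
    )


def _split_t0(series: IsotopePoolSeries) -> tuple[float, float, np.ndarray]:
    """Mean t0 (14N, 15N) sub-pools and indices of the post-t0 bottles."""
    t = np.asarray(series.times, dtype=float)
    conc = np.asarray(series.conc_total, dtype=float)
    if series.atom_fraction_15 is None:
        raise ValueError(f"{series.pool.value} series needs atom fractions")
    f = np.asarray(series.atom_fraction_15, dtype=float)
    at0 = t == 0.0
    if not at0.any():
        raise ValueError("series must include t = 0 (kill control) bottles")
    n15_0 = float(np.mean(conc[at0] * f[at0]))
    n14_0 = float(np.mean(conc[at0] * (1.0 - f[at0])))
    return n14_0, n15_0, np.flatnonzero(~at0)


def zero_order_rates(
    series_no2: IsotopePoolSeries,
    series_no3: IsotopePoolSeries,
    timepoints: tuple[float, ...] | None = None,
    min_hours: float = 12.0,
    sd_no2: float | None = None,
    sd_no3: float | None = None,
) -> RatePair:
    """(R_amm_ox, R_nit_ox) from the zero-order pool model, in uM/day.

    Each post-t0 bottle yields one (R_amm_ox, R_nit_ox) estimate; estimates
    from the selected timepoints (default: all t > ``min_hours``, mirroring
    the use of the mid and final timepoints of a ~30 h incubation) are
    averaged, with the sd across estimates as the uncertainty.  The two 15N
    balances (NO2- loss, NO3- gain) are combined by inverse-variance
    weights when per-pool measurement sds are given, equal weights
    otherwise.
    """
    if series_no2.times != series_no3.times:
        raise ValueError("NO2- and NO3- series must come from the same bottles")
    t = np.asarray(series_no2.times, dtype=float)
    conc2 = np.asarray(series_no2.conc_total, dtype=float)
    conc3 = np.asarray(series_no3.conc_total, dtype=float)
    f2 = np.asarray(series_no2.atom_fraction_15, dtype=float)
    f3 = np.asarray(series_no3.atom_fraction_15, dtype=float)

    n14_2_0, n15_2_0, post = _split_t0(series_no2)
    n14_3_0, n15_3_0, _ = _split_t0(series_no3)
    f2_0 = n15_2_0 / (n15_2_0 + n14_2_0)

    if timepoints is not None:
        selected = [i for i in post if any(abs(t[i] - tp) < 1e-9 for tp in timepoints)]
    else:
        selected = [i for i in post if t[i] > min_hours]
    if not selected:
        raise ValueError("no bottles at the requested timepoints")

    w2 = 1.0 / sd_no2**2 if sd_no2 else 1.0
    w3 = 1.0 / sd_no3**2 if sd_no3 else 1.0

    # Each 15N balance (NO2- loss, NO3- gain) yields its own rate estimate
    # per bottle.  The reported rate is their (weighted) mean; the reported
    # sd is taken across ALL per-balance estimates so the disagreement
    # between the two balances — which carries the kill-control measurement
    # error that replicate scatter alone cannot see — is reflected in the
    # uncertainty.
    est_amm, est_nit, weights = [], [], []
    for i in selected:
        ti = t[i] / HOURS_PER_DAY  # days
        if ti <= 0:
            raise ValueError("per-timepoint rates require t > 0")
        n15_2 = conc2[i] * f2[i]
        n14_2 = conc2[i] * (1.0 - f2[i])
        n15_3 = conc3[i] * f3[i]
        fbar = 0.5 * (f2_0 + f2[i])
        if fbar <= 0:
            if abs(n15_3 - n15_3_0) > 1e-12:
                import warnings

                warnings.warn(
                    "15F_NO2- is zero but 15NO3- grew: inconsistent data",
                    stacklevel=2,
                )
            est_nit.append(0.0)
            est_amm.append((n14_2 - n14_2_0) / ti)
            weights.append(1.0)
            continue
        for r_nit, w in (
            (-(n15_2 - n15_2_0) / (fbar * ti), w2),
            ((n15_3 - n15_3_0) / (fbar * ti), w3),
        ):
            est_nit.append(r_nit)
            est_amm.append((n14_2 - n14_2_0) / ti + (1.0 - fbar) * r_nit)
            weights.append(w)

    amm = np.asarray(est_amm)
    nit = np.asarray(est_nit)
    w = np.asarray(weights)
    return RatePair(
        r_amm_ox=float(np.average(amm, weights=w)),
        r_nit_ox=float(np.average(nit, weights=w)),
        sd_amm_ox=float(amm.std(ddof=1)) if len(amm) > 1 else 0.0,
        sd_nit_ox=float(nit.std(ddof=1)) if len(nit) > 1 else 0.0,
        method=RateMethod.ZERO_ORDER_POOL_MODEL,
        n=len(selected),
    )


def net_nitrite_consumption(rates: RatePair) -> float:
    """Net NO2- consumption = R_nit_ox - R_amm_ox (uM/day)."""
    if rates.r_amm_ox is None or rates.r_nit_ox is None:
        raise ValueError("both rates must be present")
    return rates.r_nit_ox - rates.r_amm_ox


def first_order_fit(series_nh4: IsotopePoolSeries) -> tuple[float, float]:
    """First-order decay constant of the NH4+ pool, per day.

    Least-squares fit of ln[NH4+] against time; returns (k, se_k).  With
    exactly two points this reduces to k = ln(c0/c1)/dt.
    """
    t = np.asarray(series_nh4.times, dtype=float) / HOURS_PER_DAY
    c = np.asarray(series_nh4.conc_total, dtype=float)
    if np.any(c <= 0):
        raise ValueError("first-order fit requires strictly positive concentrations")
    if len(np.unique(t)) < 2:
        raise ValueError("need >= 2 distinct timepoints")
    if len(t) == 2:
        k = float(np.log(c[0] / c[1]) / (t[1] - t[0]))
        return k, 0.0
    slope, stderr, _ = _ols(t, np.log(c))
    return -slope, stderr


def percent_rate_change(rate_a: float, rate_b: float) -> float:
    """Percent decrease from rate_a to rate_b: (1 - b/a) * 100."""
    if rate_a == 0:
        raise ValueError("reference rate must be nonzero")
    return (1.0 - rate_b / rate_a) * 100.0
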