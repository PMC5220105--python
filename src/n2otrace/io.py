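"""Delimited-text table formats, config handling, and pipeline helpers.

Two table formats move data through the pipeline, both plain UTF-8
delimited text (comma by default, tab accepted) with a header row and
units pinned by the column names:

* bottle-measurement tables (one row per sacrificed incubation bottle);
* depth-profile tables (one row per depth, surface down).

Validation is loud: every offending row is reported with its 1-based row
number; missing values are empty cells, never silent zeros.  Unknown
columns pass through untouched.
"""

from __future__ import annotations

import hashlib
import io as _stdio
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .attribution import (
    RegimeObservation,
    binomial_expected_ratio,
    classify_mechanism,
    isotope_dilution_factor,
    n2o_yield,
    production_rates,
    total_15n_incorporation,
)
from .isotopocules import (
    MolecularRatios,
    fractions_to_amounts,
    ratios_to_fractions,
)
from .kinetics import (
    IsotopePoolSeries,
    Pool,
    RateMethod,
    ammonia_oxidation_rate_regression,
    first_order_fit,
    zero_order_rates,
)
from .simulate import BOTTLE_COLUMNS, PROFILE_COLUMNS, ExperimentDesign, GroundTruth
from .chemistry import delta_n2o, n2o_equilibrium
from . import constants as C

__all__ = [
    "TableValidationError",
    "read_bottle_table",
    "write_bottle_table",
    "read_profile_table",
    "write_profile_table",
    "default_config",
    "load_config",
    "config_hash",
    "bottle_states",
    "excess_15nox_series",
    "rates_table",
    "attribution_table",
    "saturation_table",
]

REQUIRED_BOTTLE = [c for c in BOTTLE_COLUMNS if c not in ("experiment_id",)]
REQUIRED_PROFILE = ["depth_m", "temperature_c", "salinity", "n2o_nm"]


class TableValidationError(ValueError):
    """Raised when a table fails schema validation; message lists rows."""


def _read_delimited(path: str | Path, sep: str | None) -> pd.DataFrame:
    if sep is None:
        head = Path(path).read_text(encoding="utf-8").splitlines()[0]
        sep = "\t" if "\t" in head else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, na_values=[""])


def _exact_float(value) -> float:
    # full-precision parse; pandas' fast float parser is not round-trip safe
    try:
        return float(value)
    except (TypeError, ValueError):
        return float("nan")


def _numeric(df: pd.DataFrame, columns: list[str], errors: list[str]) -> pd.DataFrame:
    out = df.copy()
    for col in columns:
        parsed = out[col].map(_exact_float)
        bad = parsed.isna() & out[col].notna()
        for idx in out.index[bad]:
            errors.append(f"row {idx + 2}: column {col!r} is not a number ({out.at[idx, col]!r})")
        out[col] = parsed
    return out


def read_bottle_table(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read and validate a bottle-measurement table."""
    df = _read_delimited(path, sep)
    errors: list[str] = []
    missing = [c for c in REQUIRED_BOTTLE if c not in df.columns]
    if missing:
        raise TableValidationError(f"missing required columns: {missing}")
    numeric_cols = [
        "ph", "o2_um", "time_h", "conc_nh4_um", "conc_no2_um", "conc_no3_um",
        "f15_no2", "f15_no3", "n2o_total_nmol", "r45", "r46",
    ]
    df = _numeric(df, numeric_cols, errors)
    for col in ("f15_no2", "f15_no3"):
        bad = df.index[(df[col] < 0) | (df[col] > 1)]
        for idx in bad:
            errors.append(f"row {idx + 2}: {col} = {df.at[idx, col]} outside [0, 1]")
    for col in ("time_h", "conc_nh4_um", "conc_no2_um", "conc_no3_um",
                "n2o_total_nmol", "r45", "r46"):
        bad = df.index[df[col] < 0]
        for idx in bad:
            errors.append(f"row {idx + 2}: {col} = {df.at[idx, col]} is negative")
    if errors:
        raise TableValidationError("bottle table validation failed:\n" + "\n".join(errors))
    return df


def write_bottle_table(df: pd.DataFrame, path: str | Path, sep: str = ",") -> None:
    df.to_csv(path, sep=sep, index=False)


def read_profile_table(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read and validate a depth-profile table (surface-down ordering)."""
    df = _read_delimited(path, sep)
    errors: list[str] = []
    missing = [c for c in REQUIRED_PROFILE if c not in df.columns]
    if missing:
        raise TableValidationError(f"missing required columns: {missing}")
    numeric_cols = [c for c in PROFILE_COLUMNS if c in df.columns]
    df = _numeric(df, numeric_cols, errors)
    for idx in df.index[df["depth_m"] < 0]:
        errors.append(f"row {idx + 2}: depth_m is negative")
    depths = df["depth_m"].to_numpy()
    if np.any(np.diff(depths) <= 0):
        errors.append("depth_m must increase monotonically (surface down)")
    if errors:
        raise TableValidationError("profile table validation failed:\n" + "\n".join(errors))
    return df


def write_profile_table(df: pd.DataFrame, path: str | Path, sep: str = ",") -> None:
    df.to_csv(path, sep=sep, index=False)


# --- config -----------------------------------------------------------------

def default_config() -> dict:
    """Full default configuration (constants / design / truth sections)."""
    design = ExperimentDesign()
    truth = GroundTruth()
    return {
        "constants": C.default_constants(),
        "design": {
            "timepoints": list(design.timepoints),
            "replicates": design.replicates,
            "t0_replicates": design.t0_replicates,
            "tracer_conc": design.tracer_conc,
            "purity_nh4": design.purity_nh4,
            "purity_no2": design.purity_no2,
            "ambient_nh4": design.ambient_nh4,
            "ambient_no2": design.ambient_no2,
            "ambient_no3": design.ambient_no3,
            "volume_l": design.volume_l,
        },
        "truth": {
            "r_amm_ox": truth.r_amm_ox,
            "r_nit_ox": truth.r_nit_ox,
            "mechanism": truth.mechanism_kind.value,
            "n2o_yield": truth.n2o_yield,
            "background_n2o_nmol": truth.background_n2o_nmol,
            "background_d15n": truth.background_d15n,
            "background_d18o": truth.background_d18o,
            "background_sp": truth.background_sp,
            "nh4_regeneration": truth.nh4_regeneration,
            "periplasmic_exchange": truth.periplasmic_exchange,
            "noise": {
                "conc_rel": truth.noise.conc_rel,
                "n2o_rel": truth.noise.n2o_rel,
                "ratio_rel": truth.noise.ratio_rel,
                "f15_abs": truth.noise.f15_abs,
            },
        },
    }


def load_config(path: str | Path | None) -> dict:
    """Load a YAML config, merged over the defaults section-by-section."""
    cfg = default_config()
    if path is None:
        return cfg
    user = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    for section, values in user.items():
        if section not in cfg:
            raise KeyError(f"unknown config section {section!r}")
        if section == "truth" and "noise" in values:
            cfg["truth"]["noise"].update(values.pop("noise"))
        cfg[section].update(values)
    return cfg


def config_hash(cfg: dict) -> str:
    """Stable short hash of a config for provenance logging."""
    canonical = yaml.safe_dump(cfg, sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]


# --- pipeline helpers -------------------------------------------------------

def bottle_states(group: pd.DataFrame):
    """Isotopologue states (nmol) of each bottle in a treatment group.

    Returns (t0_states, [(time_h, state), ...] for the post-t0 bottles).
    """
    t0_states, post = [], []
    for _, row in group.iterrows():
        r = MolecularRatios(r45=row["r45"], r46=row["r46"])
        state = fractions_to_amounts(ratios_to_fractions(r), row["n2o_total_nmol"])
        if row["time_h"] == 0:
            t0_states.append(state)
        else:
            post.append((float(row["time_h"]), state))
    return t0_states, post


def excess_15nox_series(group: pd.DataFrame) -> IsotopePoolSeries:
    """Excess [15NOx-] (uM) vs time for a 15NH4+ treatment group."""
    g = group.sort_values("time_h", kind="stable")
    nox15 = (g["conc_no2_um"] * g["f15_no2"] + g["conc_no3_um"] * g["f15_no3"]).to_numpy()
    t = g["time_h"].to_numpy(dtype=float)
    baseline = nox15[t == 0].mean()
    if not np.isfinite(baseline):
        raise TableValidationError("15NOx excess requires t = 0 bottles")
    return IsotopePoolSeries(
        pool=Pool.NOX,
        times=tuple(t),
        conc_total=tuple(np.maximum(nox15 - baseline, 0.0)),
    )


def _pool_series(group: pd.DataFrame, pool: Pool) -> IsotopePoolSeries:
    g = group.sort_values("time_h", kind="stable")
    conc_col = "conc_no2_um" if pool is Pool.NO2 else "conc_no3_um"
    f_col = "f15_no2" if pool is Pool.NO2 else "f15_no3"
    return IsotopePoolSeries(
        pool=pool,
        times=tuple(g["time_h"].to_numpy(dtype=float)),
        conc_total=tuple(g[conc_col].to_numpy(dtype=float)),
        atom_fraction_15=tuple(g[f_col].to_numpy(dtype=float)),
        replicate_ids=tuple(g["bottle_id"]),
    )


def _f0_nh4_from_config(cfg: dict) -> float:
    from .kinetics import initial_atom_fraction

    d = cfg["design"]
    return initial_atom_fraction(d["tracer_conc"], d["purity_nh4"], d["ambient_nh4"])


def rates_table(
    bottles: pd.DataFrame,
    method: str = "zero-order",
    timepoints: tuple[float, ...] | None = None,
    cfg: dict | None = None,
) -> pd.DataFrame:
    """Tidy rate table (one row per treatment group) for a bottle table.

    ``method`` is one of 'regression' (15NH4+ groups), 'zero-order'
    (15NO2- groups) or 'first-order' (NH4+ decay).
    """
    cfg = cfg or default_config()
    rows = []
    for (treatment, tracer), group in bottles.groupby(["treatment", "tracer"], sort=False):
        if method == "regression":
            if tracer != "NH4_labeled":
                continue
            f0 = _f0_nh4_from_config(cfg)
            rp = ammonia_oxidation_rate_regression(excess_15nox_series(group), f0)
        elif method == "zero-order":
            if tracer != "NO2_labeled":
                continue
            rp = zero_order_rates(
                _pool_series(group, Pool.NO2),
                _pool_series(group, Pool.NO3),
                timepoints=timepoints,
            )
        elif method == "first-order":
            g = group.sort_values("time_h", kind="stable")
            series = IsotopePoolSeries(
                pool=Pool.NH4,
                times=tuple(g["time_h"].to_numpy(dtype=float)),
                conc_total=tuple(g["conc_nh4_um"].to_numpy(dtype=float)),
            )
            k, se = first_order_fit(series)
            rows.append({
                "treatment": treatment, "tracer": tracer, "method": "first_order",
                "r_amm_ox": np.nan, "sd_amm_ox": np.nan,
                "r_nit_ox": np.nan, "sd_nit_ox": np.nan,
                "k_per_day": k, "sd_k": se, "n": len(g),
            })
            continue
        else:
            raise ValueError(f"unknown method {method!r}")
        rows.append({
            "treatment": treatment, "tracer": tracer, "method": rp.method.value,
            "r_amm_ox": rp.r_amm_ox, "sd_amm_ox": rp.sd_amm_ox,
            "r_nit_ox": rp.r_nit_ox, "sd_nit_ox": rp.sd_nit_ox,
            "k_per_day": np.nan, "sd_k": np.nan, "n": rp.n,
        })
    return pd.DataFrame(rows)


def attribution_table(
    bottles: pd.DataFrame,
    alpha: float = 0.05,
    cfg: dict | None = None,
) -> pd.DataFrame:
    """Attribution report: production rates, 46:45 ratios, mechanism ranking.

    Treatments sharing pH/O2 status but differing in tracer are paired so
    the mechanism classifier sees both regimes.  The initial 15F of the
    NO2- pool is taken from the t0 bottles; that of the NH4+ pool from the
    design config (it is not measurable from the table).
    """
    cfg = cfg or default_config()
    vol = cfg["design"]["volume_l"]
    f0_nh4 = _f0_nh4_from_config(cfg)

    prods: dict[tuple[str, str], dict] = {}
    for (treatment, tracer), group in bottles.groupby(["treatment", "tracer"], sort=False):
        t0_states, post = bottle_states(group)
        p = production_rates(post, t0_states, volume_l=vol)
        f0_no2 = float(group.loc[group["time_h"] == 0, "f15_no2"].mean())
        key = (group["ph_status"].iloc[0], group["o2_status"].iloc[0])
        prods.setdefault(key, {})[tracer] = {
            "treatment": treatment, "p": p, "f0_no2": f0_no2,
        }

    rows = []
    for (ph_status, o2_status), regimes in prods.items():
        observations = []
        for tracer, entry in regimes.items():
            if tracer == "NH4_labeled":
                observations.append(
                    RegimeObservation(regime="NH4", rates=entry["p"], f0_labeled=f0_nh4)
                )
            else:
                observations.append(
                    RegimeObservation(
                        regime="NO2", rates=entry["p"], f0_labeled=entry["f0_no2"]
                    )
                )
        cls = classify_mechanism(observations, alpha=alpha)
        for tracer, entry in regimes.items():
            p = entry["p"]
            f0 = f0_nh4 if tracer == "NH4_labeled" else entry["f0_no2"]
            observed = p.rate46 / p.rate45 if p.rate45 > 0 else np.nan
            rows.append({
                "ph_status": ph_status,
                "o2_status": o2_status,
                "treatment": entry["treatment"],
                "tracer": tracer,
                "rate45_nmol_day": p.rate45,
                "rate46_nmol_day": p.rate46,
                "p45": p.p45,
                "p46": p.p46,
                "incorporation_nm_day": total_15n_incorporation(p),
                "dilution_factor": isotope_dilution_factor(f0),
                "observed_46_45": observed,
                "binomial_expected_46_45": binomial_expected_ratio(min(f0, 1 - 1e-12)),
                "mechanism_ranking": ";".join(cls["ranking"]),
                "flags": " | ".join(cls["flags"]),
            })
    return pd.DataFrame(rows)


def saturation_table(profile: pd.DataFrame, x_n2o_atm: float | None = None) -> pd.DataFrame:
    """Append equilibrium N2O and the saturation anomaly to a profile table."""
    x = x_n2o_atm if x_n2o_atm is not None else C.X_N2O_ATM
    out = profile.copy()
    eq = [
        n2o_equilibrium(t, s, x)
        for t, s in zip(out["temperature_c"], out["salinity"])
    ]
    out["n2o_equilibrium_nm"] = eq
    out["delta_n2o_nm"] = [
        delta_n2o(m, e).delta_n2o for m, e in zip(out["n2o_nm"], eq)
    ]
    return out
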