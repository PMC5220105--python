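"""Reference isotope ratios and physical constants.

All delta values in this package are referenced to atmospheric N2 for
nitrogen and to Vienna Standard Mean Ocean Water (VSMOW) for oxygen.  The
values below are the conventional reference ratios; every one of them can be
overridden through a YAML config block (see :func:`load_constants`) so that
alternative calibrations can be propagated through the whole pipeline.
"""

from __future__ import annotations

from typing import Any, Mapping

import yaml

#: 15N/14N of atmospheric N2.
R15_AIR_N2 = 0.0036765
#: 18O/16O of VSMOW.
R18_VSMOW = 0.0020052
#: 17O/16O of VSMOW.
R17_VSMOW = 0.0003799
#: Exponent of the mass-dependent 17O/18O fractionation relation.
O17_MASS_DEPENDENT_EXPONENT = 0.516

#: Default dry-air N2O mole fraction (mol/mol); ~327 ppb, configurable.
X_N2O_ATM = 327e-9

#: Acid dissociation constants (as printed for 25 degC; used T-independent).
PKA_NH4 = 9.25
PKA_HNO2 = 2.8

#: Rate constants of the abiotic N2O-forming network (per day).
K_HNO2_DISPROPORTIONATION = 1.6       # M-1 day-1, 2 HNO2 -> NO2 + NO + H2O
K_NO_NO2 = 9.5e7                      # M-1 day-1, NO + NO2 -> N2O3
K_N2O3_NH2OH = 1.7e13                 # M-1 day-1, N2O3 + NH2OH -> N2O + HNO2 + H2O
K_NO_O2 = 1.8e11                      # M-2 day-1, 2 NO + O2 -> 2 NO2

#: Coefficients of the moist-air N2O solubility function F' (mol L-1 atm-1)
#: of Weiss & Price: ln F' = a1 + a2*(100/T) + a3*ln(T/100) + a4*(T/100)^2
#: + S*(b1 + b2*(T/100) + b3*(T/100)^2), T in kelvin, S in PSU.
WEISS_PRICE_N2O_A = (-165.8806, 222.8743, 92.0792, -1.48425)
WEISS_PRICE_N2O_B = (-0.056235, 0.031619, -0.0048472)

#: Numerical tolerances used by invariant checks.
TOL_FRACTION = 1e-9     # absolute, on molecular/atom fractions
TOL_AMOUNT = 1e-6       # nmol, on isotopologue amounts

_DEFAULTS: dict[str, Any] = {
    "r15_air_n2": R15_AIR_N2,
    "r18_vsmow": R18_VSMOW,
    "r17_vsmow": R17_VSMOW,
    "o17_exponent": O17_MASS_DEPENDENT_EXPONENT,
    "x_n2o_atm": X_N2O_ATM,
    "pka_nh4": PKA_NH4,
    "pka_hno2": PKA_HNO2,
    "k_hno2_disprop": K_HNO2_DISPROPORTIONATION,
    "k_no_no2": K_NO_NO2,
    "k_n2o3_nh2oh": K_N2O3_NH2OH,
    "k_no_o2": K_NO_O2,
}


def default_constants() -> dict[str, Any]:
    """Return a fresh copy of the constants table."""
    return dict(_DEFAULTS)


def load_constants(source: str | Mapping[str, Any] | None = None) -> dict[str, Any]:
    """Merge user overrides into the default constants table.

    ``source`` may be a mapping, a YAML string, or ``None``.  Unknown keys
    raise ``KeyError`` so typos in config files fail loudly.
    """
    table = default_constants()
    if source is None:
        return table
    if isinstance(source, str):
        source = yaml.safe_load(source) or {}
    for key, value in source.items():
        if key not in table:
            raise KeyError(f"unknown constant {key!r}")
        table[key] = float(value)
    return table


def natural_abundance_15f(delta15: float = 0.0) -> float:
    """15N atom fraction implied by a delta value on the AIR-N2 scale."""
    r = R15_AIR_N2 * (1.0 + delta15 / 1000.0)
    return r / (1.0 + r)
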