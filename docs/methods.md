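# Methods

## Isotopologue accounting

N₂O occurs as mass-44 (¹⁴N¹⁴N¹⁶O), mass-45 (¹⁵N¹⁴N¹⁶O, ¹⁴N¹⁵N¹⁶O,
¹⁴N¹⁴N¹⁷O) and mass-46 (¹⁵N¹⁵N¹⁶O, ¹⁴N¹⁴N¹⁸O) molecular species. The IRMS
delivers the calibrated ratios ⁴⁵R and ⁴⁶R relative to mass 44; these are
converted to molecular fractions f_i = R_i/(1 + ⁴⁵R + ⁴⁶R) (the algebraic
simplification of the nested published form) and to absolute amounts by
multiplying with the independently measured total N₂O. All conversions are
exact and round-trip to 1e-12 relative precision; f₄₄ + f₄₅ + f₄₆ = 1 by
construction.

Reference ratios: ¹⁵R(air N₂) = 0.0036765, ¹⁸R(VSMOW) = 0.0020052,
¹⁷R(VSMOW) = 0.0003799, all overridable through the YAML constants block.
Mass 45 includes a ¹⁷O contribution; in natural-abundance work it is
removed with the mass-dependent relation ¹⁷R = ¹⁷R_ref·(¹⁸R/¹⁸R_ref)^0.516.
In tracer work (¹⁵F ≫ natural abundance) the ¹⁷O term is three orders of
magnitude below the tracer signal and is neglected; this is the default.

Kill-control (t₀) blanks are subtracted per isotopologue. Negative excess
amounts are retained, not clipped: clipping would bias the production-rate
regressions, and the slope significance test is the arbiter of what is
real production.

## Rate estimators

**Regression estimator (¹⁵NH₄⁺ incubations).** Ordinary least squares of
excess [¹⁵NOₓ⁻] (µM) on time, converted to per-day and multiplied by the
isotope dilution factor 1/¹⁵F⁰(NH₄⁺). ¹⁵F⁰ is computed from the added
tracer (amount × purity) and the ambient pool assumed at δ¹⁵N = 0‰. The
estimator assumes ¹⁵F(NH₄⁺) stays constant; NH₄⁺ regeneration violates
this and biases the rate low — the generator can inject that bias (see
below) but the estimator deliberately does not correct for it.

**Zero-order pool model (¹⁵NO₂⁻ incubations).** The four balances for
¹⁴/¹⁵NO₂⁻ and ¹⁴/¹⁵NO₃⁻ are solved per bottle: R_nit_ox from the two ¹⁵N
balances (¹⁵NO₂⁻ loss and ¹⁵NO₃⁻ gain), R_amm_ox from the ¹⁴NO₂⁻ balance.
The balances treat ¹⁵F(NO₂⁻) as constant over [0, t] while it actually
drifts as the labeled pool turns over; each per-bottle solve therefore
uses the trapezoidal mean of ¹⁵F at 0 and t, which is second-order
accurate in the drift. The ammonia-oxidation influx is assigned entirely
to ¹⁴NO₂⁻ (the NH₄⁺ pool is unlabeled in these incubations); a switch
allows a natural-abundance split. Per-bottle estimates from the selected
timepoints (default: all t > 12 h, i.e. the mid and final timepoints of a
30 h incubation) are combined as follows: the reported rate is the
(optionally inverse-variance weighted) mean over all per-balance
per-bottle estimates, and the reported sd is the standard deviation across
those estimates. Keeping the two ¹⁵N balances as separate estimates —
rather than collapsing them before taking the spread — matters: the
kill-control measurement error is shared by every bottle and is invisible
to replicate scatter, but it moves the two balances apart, so the
between-balance spread carries it into the reported uncertainty. With this
convention the ±2 sd interval is conservatively calibrated (empirical
coverage ≈ 100% at 2% measurement noise) where the collapsed version
covered only ~89%.

Time is hours internally; all rates are reported per day.

**First-order alternative.** Log-linear least squares of [NH₄⁺] against
time returns a decay constant per day (two points reduce to the closed
form k = ln(c₀/c₁)/Δt). It is provided for completeness when zero-order
kinetics is in doubt; units are per-day (a first-order constant cannot
carry M⁻¹).

**Comparisons.** Net nitrite consumption is R_nit_ox − R_amm_ox; treatment
effects are reported as percent change (1 − R_b/R_a)·100.

## N₂O production, yield, and attribution

Blank-corrected ⁴⁵N₂O and ⁴⁶N₂O amounts are regressed on time (OLS); each
slope carries a two-sided t-test against zero (α = 0.05 by default — the
conventional threshold). Total ¹⁵N incorporation is Rate₄₅ + 2·Rate₄₆,
volume-normalized to nM-N/day. The yield (mol ¹⁵N-N₂O per mol ¹⁵N-NOₓ⁻)
divides the incorporation by the ¹⁵NOₓ⁻ production rate, i.e. the
regression ammonia-oxidation rate × ¹⁵F⁰ × 1000 — the only arithmetic
consistent with reporting both quantities independently.

Candidate mechanisms are scored against the observed (rate₄₅, rate₄₆)
pattern across the available tracer regimes. Each mechanism's per-molecule
isotopologue probabilities follow from how the two N atoms are drawn:
both i.i.d. from the NH₄⁺-derived pool (binomial), one from each pool
(hybrid), or both from the NO₂⁻ pool (nitrite pairing / nitrifier
denitrification). Because the physical production rate cannot depend on
which pool carries the label, a single non-negative total rate is fit by
least squares across all regimes simultaneously, with residuals scaled by
the slope standard errors (or by the rate magnitudes in the noise-free
limit); the residual sum of squares ranks the mechanisms. Two decision
flags mirror the tracer logic: significant ⁴⁵ without commensurate ⁴⁶ in
the ¹⁵NO₂⁻ regime supports hybrid formation and rejects nitrite pairing
whenever the binomial-in-¹⁵F(NO₂⁻) prediction exceeds the observed
⁴⁶:⁴⁵ upper bound (rate₄₆ + 2 sd)/rate₄₅; and an NH₄⁺-regime ⁴⁶:⁴⁵ ratio
below f/(2(1−f)) flags a hybrid contribution. If nothing is significant
the result is "indeterminate". The two-pool (periplasmic vs exogenous
NO₂⁻) variant is deliberately implemented only in the generator, not in
the classifier — endpoint data cannot distinguish it from hybrid
formation.

The delta-trajectory predictor mixes mechanism-distributed product into a
background N₂O pool by exact mole balance and reports the apparent changes
in bulk δ¹⁵N (from the ¹⁵N atom content, mass 45 counting one atom and
mass 46 two) and in δ¹⁸O (driven by the ⁴⁶R change, exactly as an IRMS
attributing the mass-46 signal to ¹⁸O sees it). This encodes the
discrimination argument: at high labeling, binomial pairing floods mass 46
and inflates apparent δ¹⁸O by orders of magnitude more than hybrid
formation does, at comparable δ¹⁵N response per mole produced.

## Aquatic chemistry

Speciation is Henderson–Hasselbalch with pKa(HNO₂) = 2.8 and
pKa(NH₄⁺) = 9.25, used temperature-independent as printed (a hook accepts
user-supplied corrected values). The abiotic network is evaluated as
instantaneous mass-action rates by default — the exclusion argument is
about rate magnitudes (at ~2×10⁻¹¹ M HNO₂ the disproportionation rate is
more than ten orders of magnitude below observed ⁴⁵N₂O production), not
integrated dynamics — with an optional stiff-ODE integrator for
illustration. Air-water equilibrium uses the cited seawater solubility
polynomial (moist-air form, mol L⁻¹ atm⁻¹) at a default atmospheric mole
fraction of 327 ppb (configurable); ΔN₂O = measured − equilibrium.

## Synthetic-data generator

The generator emulates the triplicate bottle-sacrifice design: timepoints
0, 5, 17, 30 h with one kill control and three replicates per later
timepoint; 1 µM tracer additions at purities 0.985 (¹⁵NH₄Cl) and 0.992
(Na¹⁵NO₂); 0.12 L bottles. Ambient pools default to 0.47 µM NH₄⁺ (which
places ¹⁵F⁰(NH₄⁺) at 0.67), 0.2 µM NO₂⁻ and 60 µM NO₃⁻, matching the
hypolimnion water the design emulates. Ground truth defaults are
R_amm_ox = 0.50 and R_nit_ox = 0.64 µM/day, a hybrid mechanism, an N₂O
yield of 1×10⁻⁴, and a 1.2 nmol background N₂O pool (≈10 nM) at
δ¹⁵N = 4.9‰, δ¹⁸O = 44.5‰, SP = 15.3‰.

Pools evolve by the zero-order balances. The default forward model is the
trapezoidal-mean discretization — the same convention the estimator uses —
so noise-free inversion recovers the generating rates exactly; the exact
continuous-time solution is available (`pool_model="ode"`) and shows the
size of the shared discretization choice (≈1.5% on R_amm_ox over 30 h at
the default turnover). Both variants conserve total fixed N and ¹⁵N
exactly; the small amount of N routed into N₂O is debited from the NH₄⁺
budget (it leaves the measured pools via the NH₂OH intermediate), keeping
the budget closed without perturbing the NOₓ balances the estimator reads.

N₂O isotopologues accumulate linearly at a total rate anchored in the
¹⁵NH₄⁺-labeled frame: P = yield × R_amm_ox × ¹⁵F⁰ × 1000 / m₁₅, where m₁₅
is the expected ¹⁵N atoms per molecule under the chosen mechanism, so the
yield estimator applied to NH₄⁺-regime data recovers the truth parameter;
the same physical P applies in the ¹⁵NO₂⁻ regime with that regime's pool
atom fractions. A `periplasmic_exchange` fraction < 1 mixes the exogenous
NO₂⁻ label with unlabeled endogenous nitrite before the mechanism draws
from it. Optional NH₄⁺ regeneration dilutes ¹⁵F(NH₄⁺) exponentially and
feeds the time-averaged label into the NOₓ influx, reproducing the
downward bias of the regression estimator.

Measurement noise defaults — 2% relative on concentrations, 1% on total
N₂O and on molecular ratios, 0.002 absolute on atom fractions (truncated
to [0, 1]) — were chosen to reproduce the order of replicate scatter
reported for such incubations (rate sds of a few hundredths of µM/day).

What the generator does *not* emulate: Michaelis–Menten saturation or
community dynamics, O₂ drawdown, gas–liquid headspace partitioning, NO₂⁻
uptake by processes other than nitrite oxidation, and instrument drift
beyond the two-point linear calibration. Passing recovery tests therefore
demonstrates the internal consistency of estimator and forward model under
the stated design, not robustness to every bias present in field data —
the regeneration and two-pool options exist precisely to probe two such
biases.

Problem sizes used in the shipped tests: 500 replicate noisy experiments
for estimator calibration (bias < 2%, ±2 sd coverage ≥ 90%, within-3-sd
rate ≥ 95%) and 100 random noise-free parameter draws per mechanism for
classifier accuracy; both complete in seconds.

## Numerical conventions and degenerate inputs

Fractions are checked to 1e-9 absolute, amounts to 1e-6 nmol. Ratio and
delta conversions reject non-positive references; the pool model raises a
named error when a requested rate would drive a pool negative within the
simulated window; `ratios_to_fractions` handles the all-light case
(⁴⁵R = ⁴⁶R = 0) exactly; the binomial expectation is 0 at f = 0 and raises
at f = 1 (the ratio diverges). Table parsing uses exact Python float
conversion (the fast pandas parser is not round-trip safe) and reports
every offending row by number.

## Known limitations

* ¹⁵F(NH₄⁺) is not measurable from the bottle table, so the attribution
  report takes it from the design config; a wrong ambient NH₄⁺ estimate
  propagates into the binomial expectation and the dilution factor.
* The mechanism classifier assumes a single active mechanism; genuine
  mixtures rank between the pure endpoints but are not decomposed.
* The endpoint design cannot separate slow periplasmic NO₂⁻ exchange from
  hybrid formation; the generator can produce such data, and the
  classifier will (correctly, given the information available) call it
  hybrid-like.
* pKa values are treated as temperature-independent; speciation at
  temperatures far from 25 °C should supply corrected constants.
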