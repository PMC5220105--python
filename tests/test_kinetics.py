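"""Rate estimators: regression, zero-order pool model, first-order fit."""

import numpy as np
import pytest

from n2otrace import (
    ExperimentDesign,
    GroundTruth,
    NoiseModel,
    TreatmentLabel,
    simulate_experiment,
)
from n2otrace.io import _pool_series, excess_15nox_series
from n2otrace.kinetics import (
    IsotopePoolSeries,
    Pool,
    RatePair,
    ammonia_oxidation_rate_regression,
    first_order_fit,
    initial_atom_fraction,
    net_nitrite_consumption,
    percent_rate_change,
    zero_order_rates,
)


class TestInitialAtomFraction:
    def test_spiked_pool(self):
        # 1 uM of 98.5% tracer into 0.47 uM ambient at 0 permil
        assert initial_atom_fraction(1.0, 0.985, 0.47) == pytest.approx(0.6712, abs=1e-4)

    def test_unspiked_pool_is_natural_abundance(self):
        assert initial_atom_fraction(0.0, 0.0, 1.0) == pytest.approx(0.003663, abs=1e-6)

    def test_pure_tracer(self):
        assert initial_atom_fraction(1.0, 1.0, 0.0) == 1.0

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            initial_atom_fraction(0.0, 1.0, 0.0)


class TestRegressionEstimator:
    def test_linear_series_with_dilution_factor(self):
        # slope 0.24 uM/day = 0.01 uM/h at f0 = 0.67 -> 0.358 uM/day
        t = (0.0, 5.0, 17.0, 30.0)
        series = IsotopePoolSeries(Pool.NOX, t, tuple(0.01 * x for x in t))
        rp = ammonia_oxidation_rate_regression(series, f0=0.67)
        assert rp.r_amm_ox == pytest.approx(0.24 / 0.67, rel=1e-9)
        assert rp.sd_amm_ox == pytest.approx(0.0, abs=1e-9)

    def test_flat_series_gives_zero(self):
        series = IsotopePoolSeries(Pool.NOX, (0.0, 10.0, 20.0), (0.1, 0.1, 0.1))
        assert ammonia_oxidation_rate_regression(series, 0.67).r_amm_ox == pytest.approx(0.0)

    def test_recovers_simulator_truth(self, noise_free_table):
        group = noise_free_table[noise_free_table.tracer == "NH4_labeled"]
        f0 = initial_atom_fraction(1.0, 0.985, 0.47)
        rp = ammonia_oxidation_rate_regression(excess_15nox_series(group), f0)
        assert rp.r_amm_ox == pytest.approx(0.50, rel=1e-9)

    def test_too_few_timepoints_rejected(self):
        series = IsotopePoolSeries(Pool.NOX, (0.0, 10.0), (0.0, 0.1))
        with pytest.raises(ValueError):
            ammonia_oxidation_rate_regression(series, 0.67)


class TestZeroOrderEstimator:
    def test_noise_free_recovery_is_exact(self, no2_design, noise_free_truth):
        df = simulate_experiment(no2_design, noise_free_truth)
        rp = zero_order_rates(_pool_series(df, Pool.NO2), _pool_series(df, Pool.NO3))
        assert rp.r_amm_ox == pytest.approx(0.50, rel=1e-9)
        assert rp.r_nit_ox == pytest.approx(0.64, rel=1e-9)

    def test_constant_pools_give_zero_rates(self):
        t = (0.0, 17.0, 17.0, 30.0)
        no2 = IsotopePoolSeries(Pool.NO2, t, (1.2,) * 4, (0.8,) * 4)
        no3 = IsotopePoolSeries(Pool.NO3, t, (60.0,) * 4, (0.004,) * 4)
        rp = zero_order_rates(no2, no3)
        assert rp.r_amm_ox == pytest.approx(0.0, abs=1e-12)
        assert rp.r_nit_ox == pytest.approx(0.0, abs=1e-12)

    def test_no_nitrite_oxidation_keeps_no3_unlabeled(self, no2_design):
        truth = GroundTruth(r_nit_ox=0.0, noise=NoiseModel.none())
        df = simulate_experiment(no2_design, truth)
        assert np.allclose(df["f15_no3"], df["f15_no3"].iloc[0])
        rp = zero_order_rates(_pool_series(df, Pool.NO2), _pool_series(df, Pool.NO3))
        assert rp.r_nit_ox == pytest.approx(0.0, abs=1e-12)

    def test_agrees_with_regression_under_constant_labeling(
        self, two_regime_design, noise_free_truth
    ):
        df = simulate_experiment(two_regime_design, noise_free_truth)
        f0 = initial_atom_fraction(1.0, 0.985, 0.47)
        reg = ammonia_oxidation_rate_regression(
            excess_15nox_series(df[df.tracer == "NH4_labeled"]), f0
        )
        g = df[df.tracer == "NO2_labeled"]
        zo = zero_order_rates(_pool_series(g, Pool.NO2), _pool_series(g, Pool.NO3))
        assert abs(reg.r_amm_ox / zo.r_amm_ox - 1.0) < 0.01

    def test_noisy_recovery_within_three_sd(self, no2_design):
        hits = 0
        n_sim = 100
        for seed in range(n_sim):
            df = simulate_experiment(no2_design, GroundTruth(rng_seed=seed))
            rp = zero_order_rates(_pool_series(df, Pool.NO2), _pool_series(df, Pool.NO3))
            hits += (
                abs(rp.r_amm_ox - 0.50) <= 3 * rp.sd_amm_ox
                and abs(rp.r_nit_ox - 0.64) <= 3 * rp.sd_nit_ox
            )
        assert hits / n_sim >= 0.95


class TestConservationProperties:
    @pytest.mark.parametrize("r_amm, r_nit", [(0.5, 0.64), (0.2, 0.9), (0.7, 0.1)])
    def test_nox_mass_balance(self, r_amm, r_nit):
        """d(NO2 + NO3) = R_amm_ox * t for any rate pair."""
        design = ExperimentDesign(treatments=(TreatmentLabel(tracer="NO2_labeled"),))
        truth = GroundTruth(r_amm_ox=r_amm, r_nit_ox=r_nit, noise=NoiseModel.none())
        df = simulate_experiment(design, truth)
        nox = df["conc_no2_um"] + df["conc_no3_um"]
        t_days = df["time_h"] / 24.0
        expected = nox[df.time_h == 0].iloc[0] + r_amm * t_days
        assert np.allclose(nox, expected, atol=1e-9)

    def test_15n_conserved_without_labeled_influx(self, no2_design, noise_free_truth):
        """NH4+ unlabeled: 15N only shuttles from NO2- to NO3-."""
        df = simulate_experiment(no2_design, noise_free_truth)
        n15 = df["conc_no2_um"] * df["f15_no2"] + df["conc_no3_um"] * df["f15_no3"]
        assert np.allclose(n15, n15.iloc[0], atol=1e-9)


class TestFirstOrderFit:
    def test_recovers_exact_exponential(self):
        t = np.array([0.0, 6.0, 17.0, 30.0])
        c = 2.0 * np.exp(-0.46 * t / 24.0)
        series = IsotopePoolSeries(Pool.NH4, tuple(t), tuple(c))
        k, se = first_order_fit(series)
        assert k == pytest.approx(0.46, rel=1e-9)

    def test_constant_series_gives_zero(self):
        series = IsotopePoolSeries(Pool.NH4, (0.0, 10.0, 20.0), (1.5,) * 3)
        k, _ = first_order_fit(series)
        assert k == pytest.approx(0.0, abs=1e-12)

    def test_two_point_closed_form(self):
        series = IsotopePoolSeries(Pool.NH4, (0.0, 12.0), (1.92, 1.56))
        k, _ = first_order_fit(series)
        assert k == pytest.approx(np.log(1.92 / 1.56) / 0.5, rel=1e-12)

    def test_nonpositive_concentration_rejected(self):
        series = IsotopePoolSeries(Pool.NH4, (0.0, 10.0, 20.0), (1.0, 0.5, 0.0))
        with pytest.raises(ValueError):
            first_order_fit(series)


class TestComparisons:
    @pytest.mark.parametrize(
        "a, b, pct", [(0.356, 0.314, 11.8), (0.380, 0.325, 14.5), (0.5, 0.5, 0.0)]
    )
    def test_percent_rate_change(self, a, b, pct):
        assert percent_rate_change(a, b) == pytest.approx(pct, abs=0.05)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            percent_rate_change(0.0, 0.1)

    @pytest.mark.parametrize(
        "pair, net", [((0.50, 0.64), 0.14), ((0.54, 0.72), 0.18), ((0.3, 0.3), 0.0)]
    )
    def test_net_nitrite_consumption(self, pair, net):
        rp = RatePair(r_amm_ox=pair[0], r_nit_ox=pair[1])
        assert net_nitrite_consumption(rp) == pytest.approx(net)
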