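import pytest

from n2otrace import (
    ExperimentDesign,
    GroundTruth,
    NoiseModel,
    TreatmentLabel,
    simulate_experiment,
)


@pytest.fixture(scope="session")
def two_regime_design() -> ExperimentDesign:
    """Default design with one 15NH4+ and one 15NO2- treatment."""
    return ExperimentDesign(
        treatments=(
            TreatmentLabel(tracer="NH4_labeled"),
            TreatmentLabel(tracer="NO2_labeled"),
        )
    )


@pytest.fixture(scope="session")
def no2_design() -> ExperimentDesign:
    return ExperimentDesign(treatments=(TreatmentLabel(tracer="NO2_labeled"),))


@pytest.fixture(scope="session")
def noise_free_truth() -> GroundTruth:
    return GroundTruth(noise=NoiseModel.none())


@pytest.fixture(scope="session")
def noise_free_table(two_regime_design, noise_free_truth):
    """Noise-free bottle table covering both tracer regimes."""
    return simulate_experiment(two_regime_design, noise_free_truth)
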