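import numpy as np
import pytest

from acetokin.calibration import TimeSeriesDataset
from acetokin.kinetics import CultureState, ModelSpec
from acetokin.literature import reference_params
from acetokin.synthetic import ScenarioConfig, generate_dataset

#: standard synthetic batch conditions used across tests
INITIAL = CultureState(H=400.0, P=0.0, X=0.01)
GRID = np.linspace(0.0, 80.0, 8)


def make_scenario(structure, noise_cv=0.05, n_replicates=1, seed=0, params=None):
    """Synthetic batch scenario with the reference parameters for a structure."""
    params = params if params is not None else reference_params(structure)
    return ScenarioConfig(
        spec=ModelSpec(structure, params),
        initial=INITIAL,
        sampling_times=GRID.copy(),
        noise_cv=noise_cv,
        n_replicates=n_replicates,
        seed=seed,
    )


def noiseless_dataset(structure, sd_fraction=None):
    """Noise-free dataset from the reference parameters; optionally attach
    per-point standard deviations at a fixed fraction of each value."""
    sc = make_scenario(structure, noise_cv=0.0, n_replicates=1)
    data, truth = generate_dataset(sc)
    if sd_fraction is not None:
        sd = {
            v: np.maximum(sd_fraction * np.abs(data.observed[v]), 1e-6)
            for v in data.observed
        }
        data = TimeSeriesDataset(times=data.times, observed=data.observed, sd=sd)
    return data, truth, sc


@pytest.fixture(scope="session")
def quick_t1_fit():
    """A small but real T1 calibration shared by estimator-surface tests."""
    from acetokin.calibration import MCMCCalibrator

    sc = make_scenario("t1", noise_cv=0.05, n_replicates=3, seed=4)
    data, truth = generate_dataset(sc)
    cal = MCMCCalibrator(
        "t1",
        n_iterations=2000,
        n_chains=2,
        random_state=42,
        initial_state=sc.initial,
    ).fit(data)
    return cal, data, truth, sc
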