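import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from herbscreen import PipelineConfig, SimConfig, WarpSpec, build_plant_library, simulate_study
from herbscreen.cube import DataCube
from herbscreen.pretreat import PretreatConfig


@pytest.fixture(scope="session")
def small_library():
    return build_plant_library(2, 3, seed=7)


@pytest.fixture(scope="session")
def small_sim():
    # coarse grids keep unit tests fast; the generator's peaks live in
    # 1.8-6.3 min, so the time axis must still span the run
    return SimConfig(
        n_matrices=3,
        spike_ratios=(0.1, 0.5),
        wavelength_grid=np.arange(210.0, 391.0, 6.0),
        time_grid=np.linspace(0.0, 8.0, 641),
        rt_jitter_sd=0.004,
        seed=5,
    )


@pytest.fixture(scope="session")
def small_pipe_config():
    return PipelineConfig(
        warp=WarpSpec(20, 2),
        cv_folds=4,
        max_factors=3,
        pretreat=PretreatConfig(),
        seed=5,
    )


@pytest.fixture(scope="session")
def small_binary_study(small_library, small_sim):
    cube, labels = simulate_study(small_library, "plant-01", "binary", small_sim)
    return cube


@pytest.fixture()
def tiny_cube():
    rng = np.random.default_rng(0)
    return DataCube(
        values=rng.uniform(0, 1, (3, 2, 5)),
        sample_ids=["s0", "s1", "s2"],
        wavelengths=np.array([220.0, 254.0]),
        times=np.linspace(0.0, 1.0, 5),
        labels=np.array([1, 1, 2]),
    )
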