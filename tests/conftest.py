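import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from restifit.fitting import CellFeatureVector
from restifit.models import (
    ActinParams,
    ExfoliationParams,
    RepairParams,
    TimeGrid,
    simulate_actin,
    simulate_damaged_area,
    simulate_dead_cell,
)
from restifit.synthetic import CONTROL_MEANS

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def fine_grid():
    """0–20 min at 0.1 min — the reference fitting resolution."""
    return TimeGrid(0.0, 20.0, 0.1)


@pytest.fixture(scope="session")
def control_actin_params():
    keys = (
        "act_depoly1",
        "act_depoly2",
        "act_poly",
        "act_max",
        "act_min",
        "act_ss",
        "t_min",
        "t_max",
    )
    return ActinParams(**{k: CONTROL_MEANS[k] for k in keys})


@pytest.fixture(scope="session")
def control_repair_params():
    return RepairParams(k_repair=CONTROL_MEANS["k_repair"], da0=100.0)


@pytest.fixture(scope="session")
def control_exfol_params():
    return ExfoliationParams(
        k_stay=CONTROL_MEANS["k_stay"],
        k_run=CONTROL_MEANS["k_run"],
        dcd_max=CONTROL_MEANS["dcd_max"],
        t_detach=CONTROL_MEANS["t_detach"],
    )


@pytest.fixture(scope="session")
def mean_cell():
    """Ground-truth feature vector of the average control cell."""
    return CellFeatureVector(organoid_id="avg", treatment="control", **CONTROL_MEANS)


@pytest.fixture(scope="session")
def actin_traj(control_actin_params, fine_grid):
    return simulate_actin(control_actin_params, fine_grid)


@pytest.fixture(scope="session")
def da_traj(control_repair_params, fine_grid):
    return simulate_damaged_area(control_repair_params, fine_grid)


@pytest.fixture(scope="session")
def dcd_traj(control_exfol_params, fine_grid):
    return simulate_dead_cell(control_exfol_params, fine_grid)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
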