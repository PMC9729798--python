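import math

import numpy as np
import pytest

from dietmri import CohortDesign, make_basis_set, make_phantom, make_roi_masks


@pytest.fixture(scope="session")
def phantom():
    return make_phantom()


@pytest.fixture(scope="session")
def roi_masks():
    return make_roi_masks()


@pytest.fixture(scope="session")
def basis():
    return make_basis_set()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def at_structure_beta() -> dict[str, float]:
    """Fixed effects with area and time structure but no diet dependence."""
    return {
        "Intercept": math.log(35.0),
        "area[S.hypothalamus]": 0.10,
        "area[S.hippocampus]": -0.05,
        "area[S.NAc]": 0.06,
        "time[S.0.0]": -0.04,
        "time[S.7.0]": -0.02,
        "time[S.14.0]": 0.01,
        "time[S.28.0]": 0.02,
    }


def null_beta() -> dict[str, float]:
    return {"Intercept": math.log(35.0)}


def reduced_null_design(seed: int) -> CohortDesign:
    """Study-sized groups on a reduced grid (2 regions, 3 days) for
    calibration Monte-Carlos."""
    return CohortDesign(
        n_per_group=8,
        regions=("hypothalamus", "hippocampus"),
        days=(0.0, 7.0, 14.0),
        beta=null_beta(),
        sigma_time_slope=0.0,
        seed=seed,
    )
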