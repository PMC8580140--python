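import warnings

import numpy as np
import pytest

from harold import cohort, glm


@pytest.fixture(autouse=True)
def _quiet_convergence_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Estimated scale is 0.0")
        warnings.filterwarnings("ignore", message="Maximum Likelihood")
        warnings.filterwarnings(
            "ignore", category=RuntimeWarning, module="statsmodels"
        )
        yield


@pytest.fixture(scope="session")
def sensorimotor_schedule():
    return cohort.generate_event_schedule("sensorimotor", seed=1)


@pytest.fixture(scope="session")
def short_schedule():
    """Reduced sensorimotor run used by fast GLM/MVB tests."""
    return cohort.generate_event_schedule(
        "sensorimotor", seed=1, n_scans=140, n_trials=56
    )


@pytest.fixture(scope="session")
def short_design(short_schedule):
    return glm.build_design_matrix(short_schedule, basis="canonical")


@pytest.fixture(scope="session")
def tiny_spec():
    return cohort.CohortSpec.preset(
        "haroldnull", n_subjects=6, seed=7, n_voxels=8,
        n_scans=140, n_trials=56,
    )


def ar1_noise(rng: np.random.Generator, n: int, phi: float, size: int = 1):
    e = rng.standard_normal((n, size))
    out = np.empty((n, size))
    out[0] = e[0] / np.sqrt(1 - phi**2)
    for t in range(1, n):
        out[t] = phi * out[t - 1] + e[t]
    return out
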