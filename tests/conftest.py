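import numpy as np
import pandas as pd
import pytest

from hssurv import GroupedSurvivalData, draw_parameters, generate_dataset, generate_truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_grouped() -> GroupedSurvivalData:
    """Three groups, two covariates; covariate x2 absent from group c."""
    frame = pd.DataFrame(
        {
            "group": ["a"] * 8 + ["b"] * 8 + ["c"] * 8,
            "time": np.linspace(0.5, 4.0, 24),
            "event": ([1, 0] * 12),
            "x1": np.arange(24, dtype=float) / 7.0 - 1.5,
            "x2": list(np.linspace(-1, 1, 16)) + [np.nan] * 8,
        }
    )
    return GroupedSurvivalData.from_frame(frame)


@pytest.fixture
def small_simulated():
    """A condition-1 style simulated dataset with its truth (3 groups, 4 covariates)."""
    avail = np.ones((3, 4), dtype=bool)
    avail[2, 3] = False
    rng = np.random.default_rng(7)
    gamma = generate_truth(1, avail, rng)
    truth = draw_parameters(gamma, avail, rng)
    data = generate_dataset(truth, avail, 40, np.random.default_rng(8))
    return data, truth, avail
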