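import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from acrodat.model import _gate_mask
from acrodat.scenario import enumerate_scenarios
from acrodat.simulate import SimConfig


@pytest.fixture(scope="session")
def level_grid():
    """All 243 level vectors as an (243, 5) int array, id order."""
    return np.array([tuple(v) for _, v in enumerate_scenarios()], dtype=int)


@pytest.fixture(scope="session")
def non_gate_ids(level_grid):
    """The 108 scenario ids with IGF-I and tumor both below level 3."""
    mask = ~_gate_mask(level_grid)
    return tuple(int(i + 1) for i in np.flatnonzero(mask))


@pytest.fixture(scope="session")
def recovery_config(non_gate_ids):
    """Generative setup for end-to-end parameter recovery at n ~ 20,000.

    The sequential (continuation-ratio logistic) family makes the fitted
    two-stage model correctly specified, IGF-I and tumor act only through
    the gate (zero compensatory weight, as in the published algorithm), no
    rater heterogeneity, and all ratings are spent on the 108 compensatory
    scenarios (185 raters x 108 scenarios = 19,980 ratings).
    """
    return SimConfig(
        n_raters=185,
        per_rater=108,
        common_ids=non_gate_ids,
        weights=(0.0, 0.0, 0.45, 0.40, 0.35),
        cutpoints=(0.45, 1.55),
        rater_bias_sd=0.0,
        noise_sd=0.583,
        family="sequential",
        gate_in_truth=True,
        seed=0,
    )
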