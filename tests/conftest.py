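import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import tubecast as tc

settings.register_profile(
    "det", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("det")


@pytest.fixture
def small_params():
    """A fast small-world configuration for engine-level tests."""
    return tc.SimParams(group_size=50, alpha=0.1, x=2.0, width=40, height=30,
                        nest_area=13, stop_count=120, snapshot_interval=50,
                        seed=7)


@pytest.fixture
def midrun_state(small_params):
    """A state part-way through a run: structure, pheromone and origins set."""
    rng = np.random.default_rng(11)
    state = small_params.make_state()
    while state.built_count < 60:
        tc.step(state, small_params, rng)
    return state


@pytest.fixture
def tube_state():
    """Single-cell nest with a two-cell straight tube built eastward.

    Cells: origin o = (10, 11) (nest-adjacent, its own beginning point),
    tip t = (10, 12) inheriting o's origin.  Used for direction geometry.
    """
    arena = tc.init_arena(width=21, height=21, nest_area=1, group_size=50)
    state = tc.BuildState.from_arena(arena)
    cp = tc.ChoiceParams(x=2.0)
    tc.build(state, (10, 11), cp)
    tc.build(state, (10, 12), cp)
    return state, cp
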