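import numpy as np
import pytest

from flockwatch.synthetic_flock import (
    VideoScenario,
    litter_zonemap,
    render_video,
    simulate_crossing_schedule,
    stacked_zonemap,
)


@pytest.fixture(scope="session")
def aviary_zonemap():
    return stacked_zonemap(320, 320, 4)


@pytest.fixture(scope="session")
def litter_map():
    return litter_zonemap(320, 320)


# seed verified to satisfy the well-separated-agents precondition of the
# perfect-recovery invariant
@pytest.fixture(scope="session")
def rendered_scenario(aviary_zonemap):
    scenario = VideoScenario(
        zonemap=aviary_zonemap,
        n_agents=6,
        duration=60.0,
        seed=1,
        crossing_rates={(1, 2): 1.5, (2, 1): 1.5, (3, 4): 1.5, (4, 3): 1.5},
        background_noise_sd=0.0,
    )
    truth = simulate_crossing_schedule(scenario)
    render = render_video(scenario, truth)
    return scenario, truth, render


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
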