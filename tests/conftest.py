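import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from migrentic import geolocate, synth


@pytest.fixture(scope="session")
def small_params():
    return synth.PopulationParams(n_birds=4, seed=11)


@pytest.fixture(scope="session")
def small_pop(small_params):
    return synth.simulate_population(small_params)


@pytest.fixture(scope="session")
def bird(small_pop):
    return small_pop[0]


@pytest.fixture(scope="session")
def geo_cfg():
    return geolocate.GeolocationConfig()


@pytest.fixture(scope="session")
def bird_light(bird):
    return synth.render_light(bird)


@pytest.fixture(scope="session")
def bird_twilights(bird_light, geo_cfg):
    return geolocate.detect_twilights(bird_light, geo_cfg)


@pytest.fixture(scope="session")
def bird_track(bird, bird_twilights, geo_cfg):
    return geolocate.build_track(bird.bird_id, bird_twilights, geo_cfg)


@pytest.fixture(scope="session")
def bird_immersion(bird):
    return synth.render_immersion(bird, seed=21)
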