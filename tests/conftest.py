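import numpy as np
import pytest

from coagkit import build_normal_region, predict_cat, predict_params
from coagkit.synthetic import generate_panels, make_ground_truth_map


@pytest.fixture(scope="session")
def truth_map():
    return make_ground_truth_map()


@pytest.fixture(scope="session")
def healthy_panels(truth_map):
    return generate_panels(20, seed=3, sd=10.0)


@pytest.fixture(scope="session")
def healthy_curves(truth_map, healthy_panels):
    """Noise-free CATs synthesized from near-normal panels."""
    return [predict_cat(truth_map, p) for p in healthy_panels]


@pytest.fixture(scope="session")
def healthy_params(truth_map, healthy_panels):
    return [predict_params(truth_map, p) for p in healthy_panels]


@pytest.fixture(scope="session")
def normal_region(healthy_curves):
    return build_normal_region(healthy_curves)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
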