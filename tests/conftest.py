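import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def eight_point_dataset():
    """Fixed 8-point sample from the noisy-line generator."""
    from conformnet import generate_regression_data

    ds = generate_regression_data("F1", m=8, seed=1234, noise_sd=0.2)
    return ds.x.copy(), ds.y.copy()


@pytest.fixture(scope="session")
def tiny_corpus():
    """Small balanced two-class image corpus shared across tests."""
    from conformnet import generate_network_image_corpus

    return generate_network_image_corpus(n_images=20, image_size=32, seed=7)


@pytest.fixture(scope="session")
def tiny_source_corpus():
    from conformnet import make_source_task_corpus

    return make_source_task_corpus(n_images=24, n_classes=4, image_size=32, seed=3)
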