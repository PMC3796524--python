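import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from murimorph.geometry_io import LandmarkConfiguration, default_scheme
from murimorph.synthetic import default_template


@pytest.fixture(scope="session")
def scheme():
    return default_scheme()


@pytest.fixture(scope="session")
def template():
    return default_template()


def make_noisy_dataset(template, n, noise_sd, seed, transform=True):
    """Template + iid landmark noise, optionally re-posed, as configurations."""
    rng = np.random.default_rng(seed)
    configs = []
    for i in range(n):
        pts = template + rng.normal(0.0, noise_sd, size=template.shape)
        if transform:
            theta = rng.uniform(-np.pi / 4, np.pi / 4)
            c, s = np.cos(theta), np.sin(theta)
            rot = np.array([[c, -s], [s, c]])
            pts = pts @ rot.T * rng.uniform(0.5, 2.0) + rng.uniform(-1, 1, size=2)
        configs.append(LandmarkConfiguration(points=pts, specimen_id=f"S{i:03d}"))
    return configs


@pytest.fixture()
def small_noise_dataset(template):
    """8 specimens with noise at 0.1% of centroid size: the near-mean regime."""
    return make_noisy_dataset(template, 8, 0.001, seed=42)


@pytest.fixture()
def moderate_dataset(template):
    """50 specimens with 1.5% noise, arbitrary pose."""
    return make_noisy_dataset(template, 50, 0.015, seed=7)
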