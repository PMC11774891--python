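import numpy as np
import pytest

from rapespec import GeneratorConfig, generate_samples, label_samples
from rapespec.synthetic import SampleSet


@pytest.fixture(scope="session")
def lot300():
    """A 300-seed synthetic lot at the reference class structure."""
    return generate_samples(GeneratorConfig(n_samples=300, seed=11))


@pytest.fixture(scope="session")
def labeled300(lot300):
    labeled, _ = label_samples(lot300)
    return labeled


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def toy_samples(reflectance, rgb=None, wavelengths=None, label=None):
    """Wrap a reflectance matrix into a SampleSet with defaulted RGB/labels."""
    reflectance = np.asarray(reflectance, dtype=float)
    n, b = reflectance.shape
    if wavelengths is None:
        wavelengths = np.arange(400.0, 400.0 + b)
    if rgb is None:
        rgb = np.full((n, 3), 100.0)
    if label is None:
        label = np.full(n, np.nan)
    return SampleSet(wavelengths, reflectance, rgb, label)
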