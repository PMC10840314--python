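import numpy as np
import pytest

from saskit.sasdata import Profile
from saskit.synthetic import sphere_profile

RG_SPHERE_50 = np.sqrt(3.0 / 5.0) * 50.0   # 38.7298...
RG_SPHERE_40 = np.sqrt(3.0 / 5.0) * 40.0   # 30.9839...


@pytest.fixture
def qgrid():
    return np.linspace(0.005, 0.25, 300)


@pytest.fixture
def sphere50(qgrid):
    """Noiseless solid-sphere profile, R = 50 A, I(0) = 100."""
    return sphere_profile(50.0, 100.0, qgrid)


@pytest.fixture
def guinier_profile():
    """Factory for exact Guinier-law profiles with optional uniform sigma."""

    def make(rg=20.0, i0=100.0, qmax=0.25, n=200, sigma_frac=0.01):
        q = np.linspace(0.003, qmax, n)
        i = i0 * np.exp(-(q * rg) ** 2 / 3.0)
        sigma = sigma_frac * i if sigma_frac > 0 else np.zeros_like(i)
        return Profile(q, i, sigma)

    return make
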