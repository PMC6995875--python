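import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sfdlayers.media import LayerOpticalProperties, LayeredMedium
from sfdlayers.shef import SHEFConfig

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def shef9() -> SHEFConfig:
    return SHEFConfig(order=9)


@pytest.fixture(scope="session")
def reference_two_layer():
    """The sensitivity-analysis configuration: bottom mus' = 1 mm^-1,
    mua = 0.1 mm^-1; 300 um top layer with mua = 0.01 mm^-1; g = 0.8."""

    def make(ratio: float = 1.0, mua_top: float = 0.01) -> LayeredMedium:
        bottom = LayerOpticalProperties(mua=0.1, musp=1.0, g=0.8, n=1.4)
        top = LayerOpticalProperties(mua=mua_top, musp=ratio * 1.0, g=0.8, n=1.4)
        return LayeredMedium.two_layer(top, bottom, 0.3)

    return make


def sda_reflectance(mua: float, musp: float, n: float, fx) -> np.ndarray:
    """Standard diffusion approximation SFD reflectance (independent oracle).

    Effective attenuation sqrt(3 mua mutr + (2 pi fx)^2) with the
    partial-current (effective-reflection-coefficient) boundary condition.
    """
    fx = np.asarray(fx, dtype=float)
    mutr = mua + musp
    a_prime = musp / mutr
    r_eff = 0.0636 * n + 0.668 + 0.710 / n - 1.440 / n**2
    a_bc = (1 - r_eff) / (2 * (1 + r_eff))
    mu_eff = np.sqrt(3 * mua * mutr + (2 * np.pi * fx) ** 2)
    return 3 * a_bc * a_prime / ((mu_eff / mutr + 1) * (mu_eff / mutr + 3 * a_bc))
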