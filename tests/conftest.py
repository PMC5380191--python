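import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from torsionfold.peptide import build_ideal_peptide
from torsionfold.torsion2d import FourierCoefficients

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


def random_coefficients(max_order: int, rng: np.random.Generator,
                        scale: float = 1.0) -> FourierCoefficients:
    """Random coefficient set respecting the structural zeros."""
    m = max_order
    co = FourierCoefficients.zeros(m)
    co.c_cc[:] = rng.normal(scale=scale, size=(m + 1, m + 1))
    co.c_cs[:, 1:] = rng.normal(scale=scale, size=(m + 1, m))
    co.c_sc[1:, :] = rng.normal(scale=scale, size=(m, m + 1))
    co.c_ss[1:, 1:] = rng.normal(scale=scale, size=(m, m))
    return co


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def helix12():
    """Ideal alpha-helical 12-mer, (phi, psi) = (-57, -47)."""
    return build_ideal_peptide("A" * 12, [(-57.0, -47.0)] * 12)


@pytest.fixture(scope="session")
def extended12():
    """Fully extended 12-mer, (phi, psi) = (180, 180)."""
    return build_ideal_peptide("A" * 12, [(180.0, 180.0)] * 12)


HAIRPIN_ANGLES = ([(-135.0, 135.0)] * 5
                  + [(60.0, 30.0), (90.0, 0.0)]
                  + [(-135.0, 135.0)] * 5)


@pytest.fixture(scope="session")
def trpzip_like():
    """Hairpin-folded 12-mer with TRP at positions 2, 4, 9, 11."""
    return build_ideal_peptide("SWTWENGKWTWK", HAIRPIN_ANGLES)
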