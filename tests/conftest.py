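import numpy as np
import pytest

from cabletaper import PassiveParams, make_cylinder, make_quadratic_cable


@pytest.fixture
def fly_params() -> PassiveParams:
    """Blowfly tangential-cell passive set (r_a = 60 Ωcm, g_l = 5e-4 S/cm²)."""
    return PassiveParams(r_a=60.0, g_l=5.0e-4, tau=20.0)


@pytest.fixture
def granule_params() -> PassiveParams:
    """Dentate gyrus granule-cell passive set (r_a = 210 Ωcm, g_l = 4e-5 S/cm²)."""
    return PassiveParams(r_a=210.0, g_l=4.0e-5, tau=20.0)


@pytest.fixture
def unit_cylinder():
    """A 2 mm cylinder of radius 1 µm — the exactly solvable reference cable."""
    return make_cylinder(2000.0, 1.0, 2001)


@pytest.fixture
def shallow_quadratic():
    """Quadratic taper shallow enough (median ϵ < 0.01) for tight
    asymptotic-vs-oracle agreement: radius 1.02 → 1.0 µm over 1 mm."""
    alpha = (1.02 - 1.0) / 1000.0**2
    return make_quadratic_cable(1000.0, 1.0, alpha, 2001)


@pytest.fixture
def steep_quadratic():
    """Strongly tapering quadratic (1.5 → 0.25 µm over 500 µm)."""
    alpha = (1.5 - 0.25) / 500.0**2
    return make_quadratic_cable(500.0, 0.25, alpha, 1001)


def monotone_decreasing_from(v: np.ndarray, k: int, atol: float = 1e-12) -> bool:
    """True if v decreases (weakly) moving away from index k on both sides."""
    left = np.all(np.diff(v[: k + 1]) >= -atol)
    right = np.all(np.diff(v[k:]) <= atol)
    return bool(left and right)
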