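"""Synthetic cables and trees, and the taper-rate parameter ϵ.

Every fixture the test-suite and examples need is generated here from a
seed: smoothly oscillating "noisy" cables whose taper rate can be dialled
up or down, canonical profiles (cylinder, frustum, quadratic), and random
binary trees.  The module also estimates the small parameter ϵ that
controls the accuracy of the multiple-scales voltage approximation.

Convention for ϵ.  The asymptotics assume the radius varies on a slower
spatial scale than the voltage (r(x) = ρ(ϵx), ϵ ≪ 1).  As a concrete local
measure we define

    ϵ(x) = λ(x) · |r′(x)| / r(x)

i.e. the ratio of the voltage decay length λ(x) to the e-fold length of the
radius.  A cylinder gives ϵ ≡ 0; the approximation degrades as ϵ grows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .morphology import RadiusProfile, TreeMorphology, resample_profile
from .params import PassiveParams, electrotonic_length_um

__all__ = [
    "PassiveParams",
    "EpsilonReport",
    "make_periodic_cable",
    "make_quadratic_cable",
    "make_frustum",
    "make_cylinder",
    "make_random_tree",
    "estimate_epsilon",
]


@dataclass(frozen=True)
class EpsilonReport:
    """Pointwise taper-rate parameter ϵ(x) with summary quantiles."""

    x: np.ndarray
    epsilon: np.ndarray

    @property
    def median(self) -> float:
        return float(np.median(self.epsilon))

    @property
    def mean(self) -> float:
        return float(np.mean(self.epsilon))

    def quantile(self, q) -> float:
        return float(np.quantile(self.epsilon, q))


def make_periodic_cable(
    length: float,
    mean_radius: float,
    period: float,
    amplitude_range: float,
    n_points: int = 1001,
    seed: int = 0,
) -> RadiusProfile:
    """Cable with periodically oscillating radius, random amplitude per period.

    Within each period of length ``period`` the radius follows a raised-cosine
    bump of amplitude drawn uniformly from [0, amplitude_range], alternating
    above and below ``mean_radius`` so the profile is C¹ and oscillates about
    the mean.  Doubling the period while halving the amplitude range smooths
    the cable (smaller ϵ).

    The per-period amplitude *fractions* are drawn from a fixed-size pool so
    they depend only on the seed, not on the period: a smoothing ladder
    built at one seed is then genuinely the same random cable progressively
    smoothed, rather than a fresh draw per rung.
    """
    if period <= 0:
        raise ValueError("period must be positive")
    if amplitude_range < 0 or amplitude_range >= mean_radius:
        raise ValueError("amplitude_range must lie in [0, mean_radius)")
    rng = np.random.default_rng(seed)
    n_periods = int(np.ceil(length / period))
    if n_periods > 4096:
        raise ValueError("too many periods (max 4096)")
    amps = rng.uniform(0.0, 1.0, size=4096)[: max(n_periods, 1)] * amplitude_range
    x = np.linspace(0.0, length, int(n_points))
    j = np.minimum((x / period).astype(int), n_periods - 1)
    xi = x / period - j  # phase in [0, 1) within the period
    sign = np.where(j % 2 == 0, 1.0, -1.0)
    r = mean_radius + sign * amps[j] * 0.5 * (1.0 - np.cos(2.0 * np.pi * xi))
    if np.any(r <= 0):
        raise ValueError("generated radii are not strictly positive")
    return RadiusProfile(x=x, r=r)


def make_quadratic_cable(
    L: float, r_L: float, alpha: float, n_points: int = 1001
) -> RadiusProfile:
    """Quadratic taper r(x) = α (L − x)² + r_L, exact on the grid."""
    if L <= 0 or r_L <= 0 or alpha < 0:
        raise ValueError("L and r_L must be positive; alpha non-negative")
    x = np.linspace(0.0, L, int(n_points))
    return RadiusProfile(x=x, r=alpha * (L - x) ** 2 + r_L)


def make_frustum(
    L: float, r_proximal: float, r_distal: float, n_points: int = 1001
) -> RadiusProfile:
    """Linearly tapering cable from r_proximal at x=0 to r_distal at x=L."""
    if min(r_proximal, r_distal) <= 0 or L <= 0:
        raise ValueError("radii and length must be positive")
    x = np.linspace(0.0, L, int(n_points))
    return RadiusProfile(x=x, r=r_proximal + (r_distal - r_proximal) * x / L)


def make_cylinder(L: float, r: float, n_points: int = 1001) -> RadiusProfile:
    """Uniform cable of radius r."""
    return make_frustum(L, r, r, n_points)


def make_random_tree(
    n_tips: int,
    segment_length_range: tuple[float, float] = (40.0, 120.0),
    seed: int = 0,
    radius: float = 0.5,
    step: float = 10.0,
) -> TreeMorphology:
    """Random strictly binary rooted tree with ``n_tips`` terminals.

    Branch (inter-branch-point) lengths are drawn uniformly from
    ``segment_length_range`` and sampled every ~``step`` µm along a random
    3-D direction.  Radii are a constant placeholder (they are meant to be
    re-assigned, e.g. by the tree optimiser).  Deterministic per seed.
    """
    if n_tips < 1:
        raise ValueError("n_tips must be >= 1")
    rng = np.random.default_rng(seed)
    ids, types, xyz, radii, parents = [1], [1], [(0.0, 0.0, 0.0)], [radius], [-1]

    def new_direction():
        v = rng.normal(size=3)
        return v / np.linalg.norm(v)

    def grow(parent_swc_id: int, origin: np.ndarray, quota: int) -> None:
        # one branch segment, then split the tip quota between two daughters
        length = rng.uniform(*segment_length_range)
        direction = new_direction()
        n_steps = max(int(np.ceil(length / step)), 1)
        pid = parent_swc_id
        pos = origin
        for s in range(1, n_steps + 1):
            pos = origin + direction * (length * s / n_steps)
            nid = len(ids) + 1
            ids.append(nid)
            types.append(3)
            xyz.append(tuple(pos))
            radii.append(radius)
            parents.append(pid)
            pid = nid
        if quota > 1:
            q1 = int(rng.integers(1, quota))
            grow(pid, pos, q1)
            grow(pid, pos, quota - q1)

    grow(1, np.zeros(3), int(n_tips))
    return TreeMorphology(
        ids=np.array(ids),
        type_code=np.array(types),
        xyz=np.array(xyz),
        radius=np.array(radii),
        parent_id=np.array(parents),
    )


def estimate_epsilon(
    p: RadiusProfile,
    params: PassiveParams,
    n: int = 1001,
    smooth_window_um: float | None = None,
) -> EpsilonReport:
    """Pointwise ϵ(x) = λ(x)|r′(x)|/r(x) on a uniform grid.

    ``smooth_window_um`` applies a moving average of that width before
    differentiating; use roughly one oscillation period for noisy or
    periodic profiles, where the raw derivative is dominated by the
    fast wiggle rather than the trend the asymptotics care about.
    """
    q = resample_profile(p, n)
    r = q.r.copy()
    if smooth_window_um is not None and smooth_window_um > 0:
        dx = q.x[1] - q.x[0]
        w = max(int(round(smooth_window_um / dx)), 1)
        kernel = np.ones(w) / w
        rpad = np.pad(r, (w // 2, w - 1 - w // 2), mode="edge")
        r = np.convolve(rpad, kernel, mode="valid")
    lam = electrotonic_length_um(r, params)
    rprime = np.gradient(r, q.x)
    eps = lam * np.abs(rprime) / r
    return EpsilonReport(x=q.x, epsilon=eps)
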