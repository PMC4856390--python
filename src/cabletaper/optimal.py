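"""The variationally optimal dendritic taper.

Maximising the aggregate current transfer to the proximal end

    J = ∫₀ᴸ v(0, x′) dx′          (unit current injected at each x′)

over radius profiles, with the distal reflection neglected, leads through
the Euler–Lagrange equation to a *quadratic* optimal profile

    r(x) = α (L − x)² + r_L,

equivalently an electrotonic length λ(x) that decreases linearly toward
the distal tip with slope −2/7 in the unconstrained problem.  In practice
α is treated as free and fitted to match either the cable volume or the
proximal radius, following how the optimum is applied to measured
morphologies.

"Current transfer" is meant literally: J aggregates the *current* the
cable hands to a fixed proximal interface (the soma), not the voltage it
produces across a shape-dependent load.  At leading order the axial
current launched at x′ reaches the proximal end attenuated by
(λ(0)/λ(x′))^{7/2} e^{−Λ(x′)} — axial current goes as r² dv/dx ∝ λ^{7/2}
e^{−Λ} — which is exactly the λ^{−7/2} e^{−Λ} integrand of the variational
derivation once the constant λ(0) prefactor of the fixed interface is
pulled out.  The module therefore evaluates

    J = ∫₀ᴸ t(x′) dx′,   t = delivered current fraction ∈ (0, 1],

in µm, by two independent routes: the closed-form asymptotic integrand, and
the finite-difference oracle with the proximal end grounded (a perfect
somatic sink, identical for every shape).  Measuring voltage at a
matched-infinite collar instead penalises thick proximal ends through the
collar's own conductance and inverts shape comparisons; that reading is
deliberately not offered here.
"""

from __future__ import annotations

import numpy as np

from .asymptotic import electrotonic_profile
from .morphology import RadiusProfile
from .numeric import delivered_current_profile
from .params import PassiveParams

__all__ = [
    "fit_alpha_volume",
    "fit_alpha_proximal",
    "quadratic_volume",
    "transfer_functional_J",
    "euler_lagrange_residual",
    "perturb_volume_preserving",
]


def quadratic_volume(L: float, r_L: float, alpha: float) -> float:
    """Volume (µm³) of r(x) = α(L−x)² + r_L: π(α²L⁵/5 + 2αr_L L³/3 + r_L²L)."""
    return float(
        np.pi * (alpha**2 * L**5 / 5.0 + 2.0 * alpha * r_L * L**3 / 3.0
                 + r_L**2 * L)
    )


def fit_alpha_volume(L: float, r_L: float, V: float) -> float:
    """α such that the quadratic profile has volume V (closed form).

    The volume is a quadratic polynomial in α, so the positive root is
    available in closed form.  V must exceed the α = 0 floor π r_L² L.
    """
    if L <= 0 or r_L <= 0:
        raise ValueError("L and r_L must be positive")
    floor = np.pi * r_L**2 * L
    if V < floor:
        raise ValueError(
            f"volume {V:.6g} µm³ below the cylinder floor {floor:.6g} µm³"
        )
    if V == floor:
        return 0.0
    a = L**5 / 5.0
    b = 2.0 * r_L * L**3 / 3.0
    c = r_L**2 * L - V / np.pi
    alpha = (-b + np.sqrt(b * b - 4.0 * a * c)) / (2.0 * a)
    return float(alpha)


def fit_alpha_proximal(L: float, r_L: float, r_0: float) -> float:
    """α such that the quadratic profile has proximal radius r(0) = r_0."""
    if r_0 < r_L:
        raise ValueError("r_0 must be >= r_L")
    return float((r_0 - r_L) / L**2)


def transfer_functional_J(
    p: RadiusProfile,
    params: PassiveParams,
    include_reflection: bool = False,
    method: str = "asymptotic",
    n: int | None = None,
) -> float:
    """Aggregate current transfer J = ∫₀ᴸ t(x′) dx′, in µm.

    t(x′) is the fraction of a current injected at x′ that reaches the
    proximal end.  ``method='asymptotic'`` evaluates the closed-form
    leading-order attenuation (λ(0)/λ(x′))^{7/2} e^{−Λ(x′)} by quadrature,
    optionally with the sealed-end reflection factor [1 + k e^{−2(Λ(L)−Λ)}]
    (on a cylinder the reflected wave doubles the delivered current for
    injections at the sealed tip).  ``method='oracle'`` integrates the
    exact delivered-current profile from the finite-difference solver with
    a grounded proximal end (one adjoint solve; sealed distal end).

    On a cylinder both routes have closed forms — λ(1 − e^{−L/λ}) without
    reflection, λ(1 − e^{−2L/λ}) with it, λ·tanh(L/λ) exactly — agreeing
    up to O(e^{−2L/λ}).
    """
    if method == "oracle":
        x, t = delivered_current_profile(p, params, n=n)
        return float(np.trapezoid(t, x))
    if method != "asymptotic":
        raise ValueError("method must be 'asymptotic' or 'oracle'")
    ep = electrotonic_profile(p, params, n=n)
    integrand = (ep.lam[0] / ep.lam) ** 3.5 * np.exp(-ep.Lam)
    if include_reflection:
        from .asymptotic import _reflection_ratio

        k = _reflection_ratio(ep)
        integrand = integrand * (
            1.0 + k * np.exp(-2.0 * (ep.Lam[-1] - ep.Lam))
        )
    return float(np.trapezoid(integrand, ep.x))


def euler_lagrange_residual(
    p: RadiusProfile, params: PassiveParams, n: int | None = None
):
    """Pointwise residual λ′(x) + 2/7 of the reduced optimality condition.

    With the distal reflection neglected, the Euler–Lagrange equation for J
    reduces to d/dx[λ(x)] = −2/7 (x increasing distally): the electrotonic
    length of an optimal cable shrinks linearly at slope 2/7.  A cylinder
    (λ′ ≡ 0) therefore has constant residual +2/7; the optimal quadratic
    with α = 8 r_a g_l / 49 has residual ≈ 0 away from the distal tip
    (exactly 0 only in the r_L → 0 limit).

    Returns (x µm, residual) arrays.
    """
    ep = electrotonic_profile(p, params, n=n)
    return ep.x, ep.lam_prime + 2.0 / 7.0


def perturb_volume_preserving(
    p: RadiusProfile,
    amplitude: float,
    seed: int = 0,
    n_bumps: int = 6,
) -> RadiusProfile:
    """Smooth random perturbation with volume and both end radii held fixed.

    The admissible variations of the transfer-optimality problem pin the
    terminal radii (they are boundary constraints of the variational
    formulation) and the volume.  The radius is multiplied by
    1 + a·q(x) + β·w(x) where q is a windowed sum of random Gaussian bumps
    with max|q| = 1, w(x) = [4x(L−x)/L²]² is a smooth window vanishing at
    both ends, a = ``amplitude`` and β solves the exact volume-restoration
    condition (a quadratic with a root near −a·⟨q⟩).  Deterministic per
    seed; amplitude 0 returns the profile unchanged.
    """
    if amplitude == 0.0:
        return RadiusProfile(x=p.x.copy(), r=p.r.copy())
    rng = np.random.default_rng(seed)
    x, r, L = p.x, p.r, p.L
    sigma = L / (3.0 * n_bumps)
    centers = rng.uniform(2.0 * sigma, L - 2.0 * sigma, size=n_bumps)
    signs = rng.choice([-1.0, 1.0], size=n_bumps)
    w = (4.0 * x * (L - x) / L**2) ** 2
    q = np.zeros_like(x)
    for c, s in zip(centers, signs):
        q += s * np.exp(-((x - c) ** 2) / (2.0 * sigma**2))
    q *= w
    q /= np.max(np.abs(q))

    # volume of r·(1 + a q + β w): quadratic in β, pick the root near 0
    a = amplitude
    base = r * (1.0 + a * q)
    m2 = float(np.trapezoid((r * w) ** 2, x))
    m1 = float(np.trapezoid(base * r * w, x))
    m0 = float(np.trapezoid(base**2 - r**2, x))
    disc = m1 * m1 - m2 * m0
    if disc < 0:
        raise ValueError("amplitude too large: volume cannot be restored")
    beta = (-m1 + np.sqrt(disc)) / m2
    r_new = r * (1.0 + a * q + beta * w)
    if np.any(r_new <= 0):
        raise ValueError("amplitude too large: radii would become non-positive")
    return RadiusProfile(x=x.copy(), r=r_new)
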