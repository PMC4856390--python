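"""First-order multiple-scales (WKB-type) voltage solution for tapering cables.

The passive voltage on a cable whose radius r(x) varies slowly compared to
the voltage decay length admits the leading-order steady solution

    v(x) ≈ √λ(x) · [ A e^{+Λ(x)} + B e^{−Λ(x)} ],

where λ(x) = √(r(x) / 2 r_a g_l) is the local electrotonic length and
Λ(x) = ∫₀ˣ ds/λ(s) the cumulative electrotonic distance.  For a point
current injected at x′, requiring decay toward the soma on the proximal
side, a sealed end at x = L, continuity at x′ and the current-conservation
jump in the r²-weighted flux fixes the two-region coefficients in closed
form.  The amplitude on the proximal side with unit current is exactly the
input resistance at x′:

    R(x′) = (r_a λ(x′) / 2π r²(x′)) · [1 + k e^{−2(Λ(L)−Λ(x′))}],
    k     = (2 − λ′(L)) / (2 + λ′(L))      (distal reflection ratio).

On a cylinder (λ′ ≡ 0, λ constant) the expression collapses to the
classical closed form R∞/(1 + tanh((L−x′)/λ)), so the approximation is
*exact* for constant radius; errors grow with the local taper-rate
parameter ϵ = λ|r′|/r.

Normalisation convention: the √λ prefactor is divided by √λ(x′) so that
the coefficients carry units of voltage and B₁ evaluated with unit current
is literally the input resistance in MΩ.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .morphology import RadiusProfile, resample_profile
from .numeric import VoltageSolution
from .params import UM_PER_CM, PassiveParams, electrotonic_length_um


class TaperDegeneracyError(ValueError):
    """The taper at the sealed end is too steep for the first-order formula
    (the reflection-ratio denominator 2 + λ′(L) vanishes or flips sign)."""


@dataclass(frozen=True)
class ElectrotonicProfile:
    """λ(x), Λ(x) and λ′(x) on a uniform grid.

    ``lam`` is in µm, ``Lam`` is the dimensionless cumulative electrotonic
    distance ∫₀ˣ ds/λ(s) (non-decreasing, Λ(0) = 0), and ``lam_prime`` is
    the dimensionless slope dλ/dx.
    """

    x: np.ndarray
    lam: np.ndarray
    Lam: np.ndarray
    lam_prime: np.ndarray
    r: np.ndarray  # µm, the radii the profile was built from

    @property
    def L(self) -> float:
        return float(self.x[-1])

    def at(self, x: float):
        """(λ, Λ, r) interpolated at one position."""
        return (
            float(np.interp(x, self.x, self.lam)),
            float(np.interp(x, self.x, self.Lam)),
            float(np.interp(x, self.x, self.r)),
        )


@dataclass(frozen=True)
class GreensCoefficients:
    """Two-region amplitudes (mV) of the first-order point-source solution.

    For x ≤ x′:  v = √(λ(x)/λ(x′)) · B1 · e^{−(Λ(x′)−Λ(x))}
    For x > x′:  v = √(λ(x)/λ(x′)) · [A2 e^{Λ(x)−Λ(x′)} + B2 e^{−(Λ(x)−Λ(x′))}]

    Continuity at x′ holds because B1 = A2 + B2 by construction.  ``k`` is
    the distal reflection ratio (2−λ′(L))/(2+λ′(L)); it appears in A2
    through the sealed-end condition and tends to 0 influence as
    (L − x′)/λ grows.
    """

    A2: float
    B1: float
    B2: float
    k: float
    inj_x: float
    I_app: float


def electrotonic_profile(
    p: RadiusProfile, params: PassiveParams, n: int | None = None
) -> ElectrotonicProfile:
    """Compute λ, Λ and λ′ on a uniform grid (default 1001 points).

    Λ is accumulated with the trapezoid rule; λ′ uses central differences
    (second-order one-sided at the ends), consistent with the second-order
    accuracy of the numerical oracle.
    """
    if n is None:
        n = max(len(p.x), 1001)
    q = resample_profile(p, n)
    lam = electrotonic_length_um(q.r, params)
    Lam = cumulative_trapezoid(1.0 / lam, q.x, initial=0.0)
    lam_prime = np.gradient(lam, q.x, edge_order=2)
    return ElectrotonicProfile(x=q.x, lam=lam, Lam=Lam, lam_prime=lam_prime, r=q.r)


def _reflection_ratio(ep: ElectrotonicProfile) -> float:
    lamp_L = float(ep.lam_prime[-1])
    if lamp_L >= 2.0 or lamp_L <= -2.0:
        raise TaperDegeneracyError(
            f"|λ'(L)| = {abs(lamp_L):.3g} ≥ 2: taper too steep at the sealed "
            "end for the first-order solution"
        )
    return (2.0 - lamp_L) / (2.0 + lamp_L)


def greens_coefficients(
    ep: ElectrotonicProfile,
    params: PassiveParams,
    inj_x: float,
    I_app: float = 1.0,
) -> GreensCoefficients:
    """Closed-form coefficients for a point current at ``inj_x`` (µm, nA)."""
    if not (0.0 < inj_x <= ep.L):
        raise ValueError("inj_x must lie in (0, L]")
    k = _reflection_ratio(ep)
    lam_p, Lam_p, r_p = ep.at(inj_x)
    dLam_L = float(ep.Lam[-1]) - Lam_p
    # prefactor r_a λ / (2π r²) in Ω, then Ω → MΩ so that mV = MΩ·nA
    pref_MOhm = (
        params.r_a * (lam_p / UM_PER_CM)
        / (2.0 * np.pi * (r_p / UM_PER_CM) ** 2)
    ) / 1.0e6
    B2 = pref_MOhm * I_app
    A2 = B2 * k * np.exp(-2.0 * dLam_L)
    return GreensCoefficients(
        A2=float(A2), B1=float(A2 + B2), B2=float(B2),
        k=float(k), inj_x=float(inj_x), I_app=float(I_app),
    )


def voltage_approx(ep: ElectrotonicProfile, gc: GreensCoefficients) -> VoltageSolution:
    """Reconstruct the first-order voltage over the whole grid (mV)."""
    lam_p, Lam_p, _ = ep.at(gc.inj_x)
    amp = np.sqrt(ep.lam / lam_p)
    v = np.empty_like(ep.x)
    left = ep.x <= gc.inj_x
    v[left] = gc.B1 * np.exp(ep.Lam[left] - Lam_p)
    right = ~left
    d = ep.Lam[right] - Lam_p
    v[right] = gc.A2 * np.exp(d) + gc.B2 * np.exp(-d)
    v *= amp
    return VoltageSolution(
        x=ep.x, v=v, inj_x=gc.inj_x, I_app=gc.I_app,
        bc_proximal="matched_infinite", bc_distal="sealed",
    )


def input_resistance_approx(
    ep: ElectrotonicProfile, params: PassiveParams, inj_x: float
) -> float:
    """First-order input resistance B₁(x′) with unit current, in MΩ."""
    return greens_coefficients(ep, params, inj_x, I_app=1.0).B1


def current_transfer(ep: ElectrotonicProfile, inj_x: float) -> float:
    """Leading-order transfer ratio v(0, x′)/v(x′, x′) ∈ (0, 1].

    Equals √(λ(0)/λ(x′)) · e^{−Λ(x′)}; the input-resistance factor cancels
    in the ratio, so the distal reflection plays no role.
    """
    if not (0.0 <= inj_x <= ep.L):
        raise ValueError("inj_x must lie in [0, L]")
    if inj_x == 0.0:
        return 1.0
    lam_p, Lam_p, _ = ep.at(inj_x)
    return float(np.sqrt(ep.lam[0] / lam_p) * np.exp(-Lam_p))
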