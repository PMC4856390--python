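"""Finite-difference oracle for the generalised cable equation.

Steady state, transients and Green's matrices for a single tapering cable,
plus a compartmental steady-state solver for whole trees.  The spatial
discretisation is conservative (flux form): the axial flux r²(x) dv/dx is
differenced at cell faces, which makes the system matrix symmetric positive
definite, guarantees discrete current conservation, and gives second-order
accuracy.  Unlike the asymptotic solution, the oracle keeps the full
lateral-area factor √(1 + r′(x)²) in the membrane term; the asymptotics
drop its O(ϵ²) contribution, and that difference is part of what the
analytic-vs-numeric comparisons measure.

Steady problem (v in volts, lengths in cm internally):

    d/dx[ r² dv/dx ] − 2 r_a g_l r √(1+r′²) v = −(r_a/π) I δ(x − x′)

Boundary conditions:

* ``sealed``           — zero axial flux (natural in flux form),
* ``killed``           — v = 0 (node eliminated from the system),
* ``matched_infinite`` — Robin load v(0)/R∞ with R∞ the input resistance of
  a semi-infinite uniform cable continuing at the boundary radius; this
  emulates v → 0 as x → −∞ on a finite grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .morphology import RadiusProfile, TreeMorphology, resample_profile
from .params import UM_PER_CM, PassiveParams, electrotonic_length_um

BC_LABELS = ("sealed", "killed", "matched_infinite")


@dataclass
class VoltageSolution:
    """Steady voltage above rest along a cable."""

    x: np.ndarray  # µm
    v: np.ndarray  # mV
    inj_x: float  # µm (snapped to the grid)
    I_app: float  # nA
    bc_proximal: str
    bc_distal: str


@dataclass
class GreensMatrix:
    """G[i, j] = steady voltage at x_i per unit current at x_j, in MΩ."""

    x: np.ndarray  # µm
    G: np.ndarray  # MΩ

    def input_resistance(self) -> np.ndarray:
        return np.diag(self.G)


class NumericalSolveError(RuntimeError):
    pass


def default_grid_size(p: RadiusProfile, params: PassiveParams,
                      points_per_lambda: int = 200,
                      n_min: int = 101, n_max: int = 20001) -> int:
    """Grid size giving dx ≤ min λ / points_per_lambda, clipped to bounds."""
    lam_min = float(np.min(electrotonic_length_um(p.r, params)))
    n = int(np.ceil(p.L / (lam_min / points_per_lambda))) + 1
    return int(np.clip(n, n_min, n_max))


def _assemble(p: RadiusProfile, params: PassiveParams, n: int | None,
              bc_proximal: str, bc_distal: str, include_slant: bool = True):
    """Build the symmetric tridiagonal system in cm/volt/amp units.

    Returns (grid µm, dx_cm, lower/diag bands, source scale r_a/π,
    killed-node mask).  Row i of the system reads
        −a_{i-1/2}(v_{i-1}-v_i)/dx − a_{i+1/2}(v_{i+1}-v_i)/dx + b_i w_i v_i
          (+ Robin terms) = (r_a/π) I_i
    with a = r², b = 2 r_a g_l r √(1+r′²) and w_i the control-volume width
    (dx, halved at the ends).
    """
    if bc_proximal not in BC_LABELS or bc_distal not in BC_LABELS:
        raise ValueError(f"boundary labels must be one of {BC_LABELS}")
    if n is None:
        n = default_grid_size(p, params)
    q = resample_profile(p, n)
    x_um = q.x
    dx = (x_um[1] - x_um[0]) / UM_PER_CM
    r = q.r / UM_PER_CM
    if np.any(r <= 0) or not np.all(np.isfinite(r)):
        raise NumericalSolveError("degenerate radii on the solver grid")
    a = r * r
    a_face = 0.5 * (a[:-1] + a[1:])  # r² at cell faces
    rp = np.gradient(r, dx)
    slant = np.sqrt(1.0 + rp * rp) if include_slant else 1.0
    b = 2.0 * params.r_a * params.g_l * r * slant
    w = np.full(n, dx)
    w[0] = w[-1] = 0.5 * dx

    diag = b * w
    diag[:-1] += a_face / dx
    diag[1:] += a_face / dx
    lower = -a_face / dx  # sub/super diagonal (symmetric)

    killed = np.zeros(n, dtype=bool)
    for side, bc in ((0, bc_proximal), (-1, bc_distal)):
        if bc == "killed":
            killed[side] = True
        elif bc == "matched_infinite":
            lam_cm = electrotonic_length_um(q.r[side], params) / UM_PER_CM
            # semi-infinite collar: R∞ = r_a λ / (π r²); scaled by r_a/π the
            # Robin load contributes a[side]/λ to the diagonal.
            diag[side] += a[side] / lam_cm
        # sealed: natural, nothing to add
    return q, dx, lower, diag, params.r_a / np.pi, killed


def _solve_banded(lower, diag, rhs, killed):
    """Solve the symmetric tridiagonal system, eliminating killed nodes."""
    n = len(diag)
    keep = ~killed
    idx = np.flatnonzero(keep)
    d = diag[keep]
    # sub-diagonal between consecutive kept nodes (killed nodes only occur
    # at the ends, so kept nodes stay contiguous)
    sub = lower[idx[:-1]]
    ab = np.zeros((2, len(d)))
    ab[0, 1:] = sub
    ab[1, :] = d
    try:
        sol = sla.solveh_banded(ab, rhs[keep], lower=False)
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise NumericalSolveError(f"singular cable system: {exc}") from None
    out = np.zeros((n,) + rhs.shape[1:]) if rhs.ndim > 1 else np.zeros(n)
    out[keep] = sol
    return out


def solve_steady(
    p: RadiusProfile,
    params: PassiveParams,
    inj_x: float,
    I_app: float = 1.0,
    bc_proximal: str = "matched_infinite",
    bc_distal: str = "sealed",
    n: int | None = None,
    include_slant: bool = True,
) -> VoltageSolution:
    """Steady voltage for a point current injection at ``inj_x`` (µm, nA).

    The injection site is snapped to the nearest grid node; the snapped
    coordinate is reported in the returned solution.
    """
    if not (0.0 <= inj_x <= p.L):
        raise ValueError("inj_x must lie within [0, L]")
    q, dx, lower, diag, scale, killed = _assemble(
        p, params, n, bc_proximal, bc_distal, include_slant
    )
    k = int(np.argmin(np.abs(q.x - inj_x)))
    rhs = np.zeros(len(q.x))
    rhs[k] = scale * I_app * 1.0e-9  # nA → A; equation already integrated over dx
    v = _solve_banded(lower, diag, rhs, killed)
    return VoltageSolution(
        x=q.x, v=v * 1.0e3, inj_x=float(q.x[k]), I_app=I_app,
        bc_proximal=bc_proximal, bc_distal=bc_distal,
    )


def greens_matrix(
    p: RadiusProfile,
    params: PassiveParams,
    bc_proximal: str = "matched_infinite",
    bc_distal: str = "sealed",
    n: int | None = None,
    include_slant: bool = True,
) -> GreensMatrix:
    """Full steady Green's matrix (MΩ) from one banded factorisation."""
    if n is None:
        # the dense RHS is m×m; keep the default matrix a manageable size
        n = min(default_grid_size(p, params), 2001)
    q, dx, lower, diag, scale, killed = _assemble(
        p, params, n, bc_proximal, bc_distal, include_slant
    )
    m = len(q.x)
    rhs = np.eye(m) * scale  # unit amp at each node
    G = _solve_banded(lower, diag, rhs, killed)
    return GreensMatrix(x=q.x, G=G / 1.0e6)  # Ω → MΩ


def membrane_current_total(sol: VoltageSolution, p: RadiusProfile,
                           params: PassiveParams) -> float:
    """Total steady membrane leak current in nA (diagnostic).

    At steady state with sealed/killed ends this equals the injected
    current; with a matched_infinite end part of the current leaves through
    the collar instead.
    """
    x_cm = sol.x / UM_PER_CM
    r = np.interp(sol.x, p.x, p.r) / UM_PER_CM
    rp = np.gradient(r, x_cm)
    per_len = 2.0 * np.pi * r * np.sqrt(1.0 + rp * rp) * params.g_l * (sol.v / 1.0e3)
    dx = x_cm[1] - x_cm[0]
    w = np.full(len(x_cm), dx)
    w[0] = w[-1] = 0.5 * dx
    return float(np.sum(per_len * w) * 1.0e9)  # A → nA


def solve_transient(
    p: RadiusProfile,
    params: PassiveParams,
    inj_x: float,
    I_shape,
    T: float,
    dt: float,
    bc_proximal: str = "matched_infinite",
    bc_distal: str = "sealed",
    n: int | None = None,
    include_slant: bool = True,
):
    """Crank–Nicolson time stepping of the time-dependent cable equation.

    ``I_shape`` is either a constant current in nA or a callable t_ms → nA.
    Returns (times ms, x µm, V[t, x] mV).  The scheme is the trapezoidal
    rule (unconditionally stable, second order in dt) with a Rannacher
    start-up — the first two steps are taken as four backward-Euler
    half-steps — which damps the stiff modes a discontinuous current onset
    excites (plain trapezoidal stepping leaves them ringing for a long
    time).  The matched_infinite Robin load is treated quasi-statically.
    """
    if dt <= 0 or T < dt:
        raise ValueError("need dt > 0 and T >= dt")
    q, dx, lower, diag, scale, killed = _assemble(
        p, params, n, bc_proximal, bc_distal, include_slant
    )
    m = len(q.x)
    k = int(np.argmin(np.abs(q.x - inj_x)))
    current = I_shape if callable(I_shape) else (lambda t, c=float(I_shape): c)

    # capacitive lumping: τ · b_i w_i (same membrane coefficient as the leak)
    r = q.r / UM_PER_CM
    rp = np.gradient(r, dx)
    slant = np.sqrt(1.0 + rp * rp) if include_slant else 1.0
    w = np.full(m, dx)
    w[0] = w[-1] = 0.5 * dx
    cap = params.tau * 2.0 * params.r_a * params.g_l * r * slant * w

    keep = ~killed
    idx = np.flatnonzero(keep)
    sub = lower[idx[:-1]]
    d = diag[keep]
    c = cap[keep]
    nk = len(d)
    # A± = C/dt ± K/2 as banded (upper) forms
    abp = np.zeros((2, nk))
    abp[0, 1:] = sub / 2.0
    abp[1, :] = c / dt + d / 2.0
    cho = sla.cholesky_banded(abp, lower=False)

    def apply_minus(vk):
        out = (c / dt - d / 2.0) * vk
        out[:-1] -= (sub / 2.0) * vk[1:]
        out[1:] -= (sub / 2.0) * vk[:-1]
        return out

    # backward-Euler half-step operator for the Rannacher start-up
    hdt = dt / 2.0
    abbe = np.zeros((2, nk))
    abbe[0, 1:] = sub
    abbe[1, :] = c / hdt + d
    cho_be = sla.cholesky_banded(abbe, lower=False)

    n_steps = int(round(T / dt))
    times = np.arange(n_steps + 1) * dt
    V = np.zeros((n_steps + 1, m))
    vk = np.zeros(nk)
    kk = int(np.sum(keep[:k]))  # index of injection node in the kept system

    def force(t: float) -> np.ndarray:
        f = np.zeros(nk)
        if keep[k]:
            f[kk] = scale * current(t) * 1.0e-9
        return f

    n_startup = min(2, n_steps)
    for s in range(1, n_steps + 1):
        if s <= n_startup:
            for half in (0.5, 1.0):
                t_new = times[s - 1] + half * dt
                rhs = (c / hdt) * vk + force(t_new)
                vk = sla.cho_solve_banded((cho_be, False), rhs)
        else:
            rhs = apply_minus(vk) + 0.5 * (force(times[s - 1]) + force(times[s]))
            vk = sla.cho_solve_banded((cho, False), rhs)
        if not np.all(np.isfinite(vk)):  # pragma: no cover
            raise NumericalSolveError("transient scheme produced non-finite values")
        V[s, keep] = vk
    return times, q.x, V * 1.0e3


def delivered_current_profile(
    p: RadiusProfile,
    params: PassiveParams,
    n: int | None = None,
    bc_distal: str = "sealed",
    include_slant: bool = True,
):
    """Fraction of injected current delivered to a grounded proximal end.

    The proximal end is clamped to rest (killed boundary: a perfect somatic
    sink, identical for every cable shape) and t(x′) is the steady axial
    current flowing into it per unit current injected at x′.  By
    reciprocity of the flux-form system a single adjoint solve — unit
    source at the node next to the sink — yields t at every injection site
    at once.  Returns (x µm, t dimensionless in (0, 1]).
    """
    q, dx, lower, diag, scale, killed = _assemble(
        p, params, n, "killed", bc_distal, include_slant
    )
    rhs = np.zeros(len(q.x))
    rhs[1] = 1.0
    u = _solve_banded(lower, diag, rhs, killed)
    r = q.r / UM_PER_CM
    a_face0 = 0.5 * (r[0] ** 2 + r[1] ** 2)
    return q.x, (a_face0 / dx) * u


# -- trees -----------------------------------------------------------------

def tree_conductance_matrix(
    tree: TreeMorphology,
    params: PassiveParams,
    soma_bc: str = "sealed",
    soma_conductance_uS: float = 0.0,
) -> sp.csr_matrix:
    """Sparse symmetric node-conductance matrix in siemens.

    Each parent edge is a frustum: axial conductance π r₁ r₂ / (r_a l),
    membrane leak g_l times the lateral (slant) frustum area, split equally
    between the two end nodes.  ``soma_bc`` is ``sealed`` (default: the root
    is an ordinary terminal compartment) or ``lumped`` (an extra somatic
    leak of ``soma_conductance_uS`` µS at the root).
    """
    n = tree.n_nodes
    rows, cols, vals = [], [], []
    diag = np.zeros(n)
    for kk in range(n):
        pid = int(tree.parent_id[kk])
        if pid == -1:
            continue
        j = tree.index_of(pid)
        l_cm = float(np.linalg.norm(tree.xyz[kk] - tree.xyz[j])) / UM_PER_CM
        if l_cm <= 0:
            raise NumericalSolveError(
                f"zero-length edge at node {int(tree.ids[kk])}"
            )
        r1 = tree.radius[j] / UM_PER_CM
        r2 = tree.radius[kk] / UM_PER_CM
        g_ax = np.pi * r1 * r2 / (params.r_a * l_cm)
        area = np.pi * (r1 + r2) * np.hypot(l_cm, r2 - r1)
        g_m_half = 0.5 * params.g_l * area
        rows += [j, kk]
        cols += [kk, j]
        vals += [-g_ax, -g_ax]
        diag[j] += g_ax + g_m_half
        diag[kk] += g_ax + g_m_half
    if soma_bc == "lumped":
        diag[tree.index_of(tree.root_id)] += soma_conductance_uS * 1.0e-6
    elif soma_bc != "sealed":
        raise ValueError("soma_bc must be 'sealed' or 'lumped'")
    K = sp.coo_matrix(
        (np.concatenate([vals, diag]),
         (np.concatenate([rows, np.arange(n)]),
          np.concatenate([cols, np.arange(n)]))),
        shape=(n, n),
    ).tocsr()
    return K


def solve_tree_steady(
    tree: TreeMorphology,
    params: PassiveParams,
    inj_node: int,
    I_app: float = 1.0,
    soma_bc: str = "sealed",
    soma_conductance_uS: float = 0.0,
):
    """Steady node voltages (mV) for a point current (nA) at ``inj_node``.

    Returns (node ids, voltages) aligned with the tree's node order.
    """
    K = tree_conductance_matrix(tree, params, soma_bc, soma_conductance_uS)
    rhs = np.zeros(tree.n_nodes)
    rhs[tree.index_of(inj_node)] = I_app * 1.0e-9
    v = spla.spsolve(K.tocsc(), rhs)
    if not np.all(np.isfinite(v)):  # pragma: no cover
        raise NumericalSolveError("tree system solve failed")
    return tree.ids.copy(), v * 1.0e3


def tree_greens_matrix(
    tree: TreeMorphology,
    params: PassiveParams,
    soma_bc: str = "sealed",
    soma_conductance_uS: float = 0.0,
) -> np.ndarray:
    """Dense node Green's matrix in MΩ (fine for trees up to a few thousand
    nodes; the whole inverse is needed for transfer-ratio maps)."""
    K = tree_conductance_matrix(tree, params, soma_bc, soma_conductance_uS)
    G = np.linalg.inv(K.toarray())
    return G / 1.0e6
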