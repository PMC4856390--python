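"""Oracle integrity: the finite-difference solver against closed forms.

Classical cable theory gives exact solutions for cylinders; everything else
is pinned down by convergence order, symmetry (reciprocity), and discrete
conservation, which hold for the flux-form discretisation by construction.
"""

import numpy as np
import pytest

from cabletaper import (
    delivered_current_profile,
    electrotonic_length_um,
    greens_matrix,
    make_cylinder,
    make_periodic_cable,
    make_quadratic_cable,
    make_random_tree,
    path_to_profile,
    solve_steady,
    solve_transient,
    solve_tree_steady,
)
from cabletaper.morphology import TreeMorphology
from cabletaper.numeric import membrane_current_total
from cabletaper.params import UM_PER_CM

from conftest import monotone_decreasing_from


def input_resistance_inf(r_um, params):
    """Semi-infinite cylinder input resistance r_a λ / (π r²) in MΩ."""
    lam_cm = electrotonic_length_um(r_um, params) / UM_PER_CM
    return params.r_a * lam_cm / (np.pi * (r_um / UM_PER_CM) ** 2) / 1e6


class TestCylinderClosedForms:
    def test_interior_injection_matches_classical_closed_form(
        self, unit_cylinder, fly_params
    ):
        """Pure exponential decay toward the matched end; cosh reflection
        toward the sealed end."""
        lam = electrotonic_length_um(1.0, fly_params)
        sol = solve_steady(unit_cylinder, fly_params, inj_x=1000.0, n=4001)
        k = int(np.argmin(np.abs(sol.x - 1000.0)))
        expected = np.where(
            sol.x <= sol.x[k],
            sol.v[k] * np.exp(-(sol.x[k] - sol.x) / lam),
            sol.v[k] * np.cosh((2000.0 - sol.x) / lam) / np.cosh((2000.0 - sol.x[k]) / lam),
        )
        np.testing.assert_allclose(sol.v, expected, rtol=5e-3)

    def test_sealed_sealed_input_resistance(self, unit_cylinder, fly_params):
        lam = electrotonic_length_um(1.0, fly_params)
        sol = solve_steady(
            unit_cylinder, fly_params, inj_x=0.0,
            bc_proximal="sealed", bc_distal="sealed", n=4001,
        )
        R_expected = input_resistance_inf(1.0, fly_params) / np.tanh(2000.0 / lam)
        assert sol.v[0] == pytest.approx(R_expected, rel=5e-3)
        # voltage profile follows cosh((L-x)/λ)/sinh(L/λ)
        shape = np.cosh((2000.0 - sol.x) / lam)
        np.testing.assert_allclose(
            sol.v / sol.v[0], shape / shape[0], rtol=5e-3, atol=1e-9
        )

    def test_matched_infinite_equals_long_collar(self, fly_params):
        """The Robin collar load reproduces an explicitly added 10λ collar."""
        lam = electrotonic_length_um(1.0, fly_params)
        short = make_cylinder(1000.0, 1.0, 501)
        long = make_cylinder(1000.0 + 10 * lam, 1.0, 3001)
        s1 = solve_steady(short, fly_params, inj_x=800.0, n=2001)
        s2 = solve_steady(
            long, fly_params, inj_x=10 * lam + 800.0,
            bc_proximal="killed", bc_distal="sealed", n=8001,
        )
        v2 = np.interp(s1.x + 10 * lam, s2.x, s2.v)
        np.testing.assert_allclose(s1.v, v2, rtol=6e-3)

    def test_killed_end_delivered_current_closed_form(self, fly_params):
        """Current into a grounded end: t(x') = cosh((L−x')/λ)/cosh(L/λ)."""
        lam = electrotonic_length_um(1.0, fly_params)
        cyl = make_cylinder(1500.0, 1.0, 1501)
        x, t = delivered_current_profile(cyl, fly_params, n=6001)
        expected = np.cosh((1500.0 - x) / lam) / np.cosh(1500.0 / lam)
        np.testing.assert_allclose(t[5:], expected[5:], rtol=5e-3)


class TestOracleIntegrity:
    def test_second_order_convergence(self, steep_quadratic, fly_params):
        ref = solve_steady(steep_quadratic, fly_params, inj_x=250.0, n=32001)
        errs = []
        for n in (1001, 2001, 4001):
            s = solve_steady(steep_quadratic, fly_params, inj_x=250.0, n=n)
            v_ref = np.interp(s.x, ref.x, ref.v)
            errs.append(np.max(np.abs(s.v - v_ref)) / np.max(v_ref))
        r1, r2 = errs[0] / errs[1], errs[1] / errs[2]
        assert 3.5 < r1 < 4.5 and 3.5 < r2 < 4.5

    def test_greens_matrix_symmetric_and_positive(self, fly_params):
        cab = make_periodic_cable(800.0, 0.6, 100.0, 0.2, 801, seed=13)
        G = greens_matrix(cab, fly_params, n=601).G
        asym = np.max(np.abs(G - G.T)) / np.max(np.abs(G))
        assert asym < 1e-8
        assert np.all(np.diag(G) > 0)

    def test_cylinder_interior_diagonal_is_half_infinite_resistance(self, fly_params):
        """Mid-cable input conductance doubles: current escapes both ways."""
        cyl = make_cylinder(4000.0, 1.0, 2001)
        G = greens_matrix(
            cyl, fly_params, bc_proximal="sealed", bc_distal="sealed", n=2001
        )
        mid = len(G.x) // 2
        assert G.G[mid, mid] == pytest.approx(
            input_resistance_inf(1.0, fly_params) / 2.0, rel=5e-3
        )

    def test_steady_current_conservation(self, steep_quadratic, fly_params):
        sol = solve_steady(
            steep_quadratic, fly_params, inj_x=200.0, I_app=2.5,
            bc_proximal="sealed", bc_distal="sealed", n=2001,
        )
        total = membrane_current_total(sol, steep_quadratic, fly_params)
        assert abs(total - 2.5) / 2.5 < 1e-8

    def test_monotone_attenuation_from_injection(self, steep_quadratic, fly_params):
        sol = solve_steady(steep_quadratic, fly_params, inj_x=300.0, n=2001)
        k = int(np.argmin(np.abs(sol.x - sol.inj_x)))
        assert np.all(sol.v > 0)
        assert monotone_decreasing_from(sol.v, k)

    def test_degenerate_injection_position_rejected(self, unit_cylinder, fly_params):
        with pytest.raises(ValueError):
            solve_steady(unit_cylinder, fly_params, inj_x=-5.0)
        with pytest.raises(ValueError):
            solve_steady(unit_cylinder, fly_params, inj_x=1e9)


class TestTransient:
    def test_converges_to_steady_state(self, steep_quadratic, fly_params):
        ss = solve_steady(steep_quadratic, fly_params, inj_x=250.0, n=801)
        _, _, V = solve_transient(
            steep_quadratic, fly_params, inj_x=250.0, I_shape=1.0,
            T=20 * fly_params.tau, dt=fly_params.tau / 20, n=801,
        )
        assert np.max(np.abs(V[-1] - ss.v)) / np.max(ss.v) < 1e-3

    def test_zero_current_stays_at_rest(self, unit_cylinder, fly_params):
        _, _, V = solve_transient(
            unit_cylinder, fly_params, inj_x=500.0, I_shape=0.0,
            T=10.0, dt=0.5, n=301,
        )
        assert np.all(V == 0.0)

    def test_pulse_peak_latency_grows_with_injection_distance(
        self, steep_quadratic, fly_params
    ):
        """Brief pulse: the proximal-end response peaks later for more
        distal injection sites (diffusive delay along the cable)."""
        def pulse(t):
            return 1.0 if t <= 2.0 else 0.0

        latencies = []
        for site in (150.0, 350.0):
            times, x, V = solve_transient(
                steep_quadratic, fly_params, inj_x=site, I_shape=pulse,
                T=60.0, dt=0.25, n=401,
            )
            latencies.append(times[int(np.argmax(V[:, 0]))])
        assert latencies[1] > latencies[0]

    def test_rejects_bad_time_step(self, unit_cylinder, fly_params):
        with pytest.raises(ValueError):
            solve_transient(unit_cylinder, fly_params, 0.0, 1.0, T=1.0, dt=0.0)


def chain_tree_from_profile(L, n, radius_fn):
    """Straight chain of n nodes along x with radii radius_fn(x)."""
    x = np.linspace(0.0, L, n)
    return TreeMorphology(
        ids=np.arange(1, n + 1),
        type_code=np.full(n, 3),
        xyz=np.column_stack([x, np.zeros(n), np.zeros(n)]),
        radius=radius_fn(x),
        parent_id=np.concatenate([[-1], np.arange(1, n)]),
    )


class TestTreeSolver:
    def test_chain_matches_cable_solver(self, fly_params):
        L, n = 600.0, 601
        alpha = (1.2 - 0.4) / L**2
        tree = chain_tree_from_profile(L, n, lambda x: alpha * (L - x) ** 2 + 0.4)
        tip = n
        ids, v_tree = solve_tree_steady(tree, fly_params, inj_node=tip, I_app=1.0)
        prof = path_to_profile(tree, tip)
        sol = solve_steady(
            prof, fly_params, inj_x=L, bc_proximal="sealed",
            bc_distal="sealed", n=2 * n - 1, include_slant=False,
        )
        v_cable = np.interp(np.linspace(0, L, n), sol.x, sol.v)
        assert np.max(np.abs(v_tree - v_cable)) / np.max(v_cable) < 0.01

    def test_reciprocity_on_random_tree(self, fly_params):
        tree = make_random_tree(n_tips=6, seed=21)
        root = tree.root_id
        k = int(tree.ids[tree.n_nodes // 2])
        _, v_from_k = solve_tree_steady(tree, fly_params, inj_node=k)
        _, v_from_root = solve_tree_steady(tree, fly_params, inj_node=root)
        a = v_from_k[tree.index_of(root)]
        b = v_from_root[tree.index_of(k)]
        assert abs(a - b) / abs(a) < 1e-8

    def test_root_injection_peaks_at_root(self, fly_params):
        tree = make_random_tree(n_tips=5, seed=3)
        _, v = solve_tree_steady(tree, fly_params, inj_node=tree.root_id)
        assert np.argmax(v) == tree.index_of(tree.root_id)
        assert np.all(v > 0)
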