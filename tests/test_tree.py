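"""Mapping the optimal taper onto branched trees: apparent lengths, the
Rall 3/2 split, volume matching, and transfer/democracy maps."""

import numpy as np
import pytest

from cabletaper import (
    apparent_lengths,
    constant_radius_tree,
    distribute_radii,
    equalisation_index,
    make_random_tree,
    match_volume,
    transfer_map,
)
from cabletaper.morphology import TreeMorphology
from cabletaper.optimal import fit_alpha_proximal


def y_tree(l_stem=100.0, l1=50.0, l2=50.0, n_per=5, radius=0.5):
    """Stem along +x with a symmetric/asymmetric Y-split, n_per nodes per
    branch segment."""
    ids, types, xyz, radii, parents = [1], [1], [(0.0, 0.0, 0.0)], [radius], [-1]

    def add_chain(start_id, origin, direction, length, n):
        pid = int(start_id)
        pts = []
        for s in range(1, n + 1):
            pos = np.asarray(origin) + np.asarray(direction) * (length * s / n)
            nid = len(ids) + 1
            ids.append(nid)
            types.append(3)
            xyz.append(tuple(pos))
            radii.append(radius)
            parents.append(pid)
            pid = nid
            pts.append(pos)
        return pid, pts[-1]

    stem_end, stem_pos = add_chain(1, (0, 0, 0), (1, 0, 0), l_stem, n_per)
    add_chain(stem_end, stem_pos, (0.6, 0.8, 0.0), l1, n_per)
    add_chain(stem_end, stem_pos, (0.6, -0.8, 0.0), l2, n_per)
    return TreeMorphology(
        ids=np.array(ids), type_code=np.array(types), xyz=np.array(xyz),
        radius=np.array(radii), parent_id=np.array(parents),
    ), stem_end


class TestApparentLengths:
    def test_unbranched_chain_is_path_length(self):
        t = make_random_tree(n_tips=1, seed=4)
        al = apparent_lengths(t)
        total = sum(
            t.edge_length(int(i)) for i, p in zip(t.ids, t.parent_id) if p != -1
        )
        assert al[t.root_id] == pytest.approx(total, rel=1e-12)

    def test_symmetric_branch_printed_value(self):
        """Two 50 µm daughters combine to (2·50^{3/2})^{2/3} ≈ 79.37 µm."""
        tree, bp = y_tree(l1=50.0, l2=50.0)
        al = apparent_lengths(tree)
        assert al[bp] == pytest.approx((2 * 50.0**1.5) ** (2.0 / 3.0), rel=1e-9)
        assert al[bp] == pytest.approx(79.37, abs=0.01)

    def test_degenerate_daughter_keeps_other_length(self):
        tree, bp = y_tree(l1=50.0, l2=1e-9)
        al = apparent_lengths(tree)
        assert al[bp] == pytest.approx(50.0, rel=1e-6)

    def test_terminals_are_zero_and_growth_additive(self):
        t = make_random_tree(n_tips=6, seed=2)
        al = apparent_lengths(t)
        kids = t.children_map()
        for i in t.ids:
            if not kids[int(i)]:
                assert al[int(i)] == 0.0
            elif len(kids[int(i)]) == 1:
                c = kids[int(i)][0]
                assert al[int(i)] == pytest.approx(
                    al[c] + t.edge_length(c), rel=1e-12
                )
            else:
                assert al[int(i)] >= max(
                    al[c] + t.edge_length(c) for c in kids[int(i)]
                ) - 1e-12


class TestDistributeRadii:
    def test_unbranched_chain_reproduces_single_cable_quadratic(self):
        t = make_random_tree(n_tips=1, seed=4)
        al = apparent_lengths(t)
        r_L, r0 = 0.1, 1.2
        ot = distribute_radii(t, al, r_L, r0)
        alpha = fit_alpha_proximal(al[t.root_id], r_L, r0)
        # walk the chain accumulating arclength
        d = 0.0
        node = t.root_id
        kids = t.children_map()
        while True:
            k = ot.tree.index_of(node)
            expected = alpha * (al[t.root_id] - d) ** 2 + r_L
            assert ot.tree.radius[k] == pytest.approx(max(expected, r_L), rel=1e-9)
            if not kids[node]:
                break
            child = kids[node][0]
            d += t.edge_length(child)
            node = child

    @pytest.mark.parametrize("rule", ["literal", "linear"])
    def test_symmetric_split_factor(self, rule):
        """Equal daughters each get r₀ · 2^{−2/3} ≈ 0.63 r₀."""
        tree, bp = y_tree(l1=50.0, l2=50.0)
        al = apparent_lengths(tree)
        ot = distribute_radii(tree, al, 0.05, 1.0, ratio_rule=rule)
        (node, r0, daughters), = [rec for rec in ot.branch_records if rec[0] == bp]
        for rd in daughters:
            assert rd / r0 == pytest.approx(2.0 ** (-2.0 / 3.0), rel=1e-9)

    def test_asymmetric_literal_ratio(self):
        tree, bp = y_tree(l1=100.0, l2=50.0)
        al = apparent_lengths(tree)
        ot = distribute_radii(tree, al, 0.05, 1.0, ratio_rule="literal")
        (node, r0, (r1, r2)), = [rec for rec in ot.branch_records if rec[0] == bp]
        assert r1 / r2 == pytest.approx(2.0**1.5, rel=1e-9)
        assert r1**1.5 + r2**1.5 == pytest.approx(r0**1.5, rel=1e-12)

    @pytest.mark.parametrize("rule", ["literal", "linear"])
    def test_rall_residual_machine_precision(self, rule):
        t = make_random_tree(n_tips=12, seed=8)
        al = apparent_lengths(t)
        ot = distribute_radii(t, al, 0.05, 1.5, ratio_rule=rule)
        assert ot.branch_records
        assert ot.rall_residuals().max() < 1e-9

    def test_invalid_inputs_rejected(self):
        t = make_random_tree(n_tips=2, seed=0)
        al = apparent_lengths(t)
        with pytest.raises(ValueError):
            distribute_radii(t, al, 0.5, 0.4)
        with pytest.raises(ValueError):
            distribute_radii(t, al, 0.1, 1.0, ratio_rule="bogus")


class TestMatchVolume:
    def test_volume_matched_within_tolerance(self):
        t = make_random_tree(n_tips=8, seed=5)
        ot = match_volume(t, r_L=0.2, tol=1e-3)
        assert abs(ot.volume_ratio - 1.0) < 1e-3
        assert ot.iterations <= 60
        assert ot.rall_residuals().max() < 1e-9
        assert np.all(ot.tree.radius >= ot.r_L - 1e-12)

    def test_fixed_point_converges_immediately(self):
        t = make_random_tree(n_tips=6, seed=1)
        ot = match_volume(t, r_L=0.2, tol=1e-3)
        again = match_volume(
            ot.tree, r_L=ot.r_L, r_proximal_init=ot.r_proximal, tol=1e-3
        )
        assert again.iterations <= 2
        assert again.volume_ratio == pytest.approx(1.0, abs=1e-4)

    def test_tolerance_scaling(self):
        t = make_random_tree(n_tips=8, seed=6)
        loose = match_volume(t, r_L=0.2, tol=1e-2)
        tight = match_volume(t, r_L=0.2, tol=1e-4)
        err_loose = abs(loose.volume_ratio - 1.0)
        err_tight = abs(tight.volume_ratio - 1.0)
        assert err_loose <= 1e-2 and err_tight <= 1e-4
        # precision follows the requested tolerance (the bisection may land
        # essentially on the root early, so only weak monotonicity is exact)
        assert err_tight <= err_loose + 1e-12

    def test_infeasible_floor_rejected(self):
        t = make_random_tree(n_tips=4, seed=2, radius=0.05)
        with pytest.raises(ValueError, match="floor"):
            match_volume(t, r_L=2.0)

    def test_radii_non_increasing_root_to_tip(self):
        t = make_random_tree(n_tips=10, seed=12)
        ot = match_volume(t, r_L=0.15)
        for i, pid in zip(ot.tree.ids, ot.tree.parent_id):
            if pid != -1:
                r_child = ot.tree.radius[ot.tree.index_of(int(i))]
                r_parent = ot.tree.radius[ot.tree.index_of(int(pid))]
                assert r_child <= r_parent + 1e-12


class TestTransferMap:
    def test_root_ratio_is_one_and_all_bounded(self, fly_params):
        t = make_random_tree(n_tips=6, seed=3)
        tm = transfer_map(t, fly_params)
        root_pos = t.index_of(t.root_id)
        assert tm["ratio"][root_pos] == pytest.approx(1.0)
        assert np.all((tm["ratio"] > 0) & (tm["ratio"] <= 1.0 + 1e-12))
        assert np.all(tm["input_resistance_MOhm"] > 0)

    def test_optimal_beats_constant_on_extended_tree(self, fly_params):
        t = make_random_tree(n_tips=16, segment_length_range=(150.0, 300.0), seed=0)
        opt = match_volume(t, r_L=0.15)
        tm_o = transfer_map(opt.tree, fly_params)
        tm_c = transfer_map(constant_radius_tree(t), fly_params)
        assert tm_o["mean_transfer"] >= tm_c["mean_transfer"]

    def test_equalisation_impact_better_for_optimal(self, fly_params):
        t = make_random_tree(n_tips=16, segment_length_range=(150.0, 300.0), seed=1)
        opt = match_volume(t, r_L=0.15)
        cv_opt = equalisation_index(opt.tree, fly_params)
        cv_const = equalisation_index(constant_radius_tree(t), fly_params)
        assert cv_opt <= cv_const

    def test_equalisation_scale_invariance(self, fly_params):
        t = make_random_tree(n_tips=5, seed=7)
        cv1 = equalisation_index(t, fly_params)
        t2 = t.copy()
        t2.radius *= 2.0
        cv2 = equalisation_index(t2, fly_params)
        assert np.isfinite(cv1) and np.isfinite(cv2) and cv1 > 0 and cv2 > 0

    def test_constant_radius_tree_preserves_volume(self):
        t = make_random_tree(n_tips=9, seed=10)
        c = constant_radius_tree(t)
        assert c.total_volume() == pytest.approx(t.total_volume(), rel=1e-9)
        assert len(np.unique(c.radius)) == 1
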