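"""Mapping the optimal quadratic taper onto branched morphologies.

A branched tree is reduced to an equivalent unbranched cable through
*apparent lengths*: at each branch point the two daughter subtrees of
lengths l₁, l₂ look to the parent like a single continuation of length
l₀ = (l₁^{3/2} + l₂^{3/2})^{2/3} — the length-analogue of Rall's 3/2 power
rule r₀^{3/2} = r₁^{3/2} + r₂^{3/2}, which conserves conductance across the
branch so the whole tree collapses to one cable.

The optimal radii are then assigned in three steps:

i.   compute apparent lengths by a post-order sweep from the tips;
ii.  lay the quadratic taper r(x) = α(l₀ − x)² + r_L down every path,
     splitting the radius at each branch point among the daughters in the
     Rall-consistent ratio given by their apparent lengths;
iii. rescale the proximal radius (bisection) until the re-radiused tree
     matches the original tree's volume.

Two daughter-ratio rules are provided: ``literal`` (r₁:r₂ = l₁^{3/2}:l₂^{3/2})
and ``linear`` (r₁:r₂ = l₁:l₂, the unique rule that makes the daughter of
apparent length l receive exactly the radius the equivalent cable has at
that electrotonic position).  Both satisfy the Rall relation exactly.
Trifurcations extend the sums to all daughters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .morphology import TreeMorphology
from .numeric import tree_greens_matrix
from .params import PassiveParams

__all__ = [
    "apparent_lengths",
    "distribute_radii",
    "match_volume",
    "transfer_map",
    "equalisation_index",
    "constant_radius_tree",
    "OptimalTree",
]

RATIO_RULES = ("literal", "linear")


@dataclass
class OptimalTree:
    """A re-radiused tree plus provenance of the optimisation.

    ``branch_records`` holds, for every branch point, the parent radius at
    the branch and the daughter initial radii assigned there — the Rall
    relation r₀^{3/2} = Σ r_d^{3/2} holds on these records by construction.
    (Node radii in ``tree`` are sampled *after* taper along each edge, so
    the relation cannot be read off them directly.)
    """

    tree: TreeMorphology
    r_L: float
    r_proximal: float
    ratio_rule: str
    branch_records: list = field(default_factory=list)
    n_floored: int = 0
    volume_ratio: float = 1.0
    iterations: int = 0

    def rall_residuals(self) -> np.ndarray:
        """Relative Rall residual |r₀^{3/2} − Σ r_d^{3/2}| / r₀^{3/2} per branch."""
        out = []
        for _, r0, daughters in self.branch_records:
            lhs = r0**1.5
            out.append(abs(lhs - sum(rd**1.5 for rd in daughters)) / lhs)
        return np.asarray(out)


def apparent_lengths(tree: TreeMorphology) -> dict[int, float]:
    """Apparent (equivalent-cable) length of the subtree distal to each node.

    Terminals have apparent length 0; along an unbranched stretch the value
    grows by the edge arclength; at a branch the daughters' values combine
    as (Σ l_d^{3/2})^{2/3}.  One post-order traversal, in µm.
    """
    children = tree.children_map()
    al: dict[int, float] = {}
    stack = [(tree.root_id, False)]
    while stack:
        node, processed = stack.pop()
        if not processed:
            stack.append((node, True))
            for c in children[node]:
                stack.append((c, False))
        else:
            ls = [al[c] + tree.edge_length(c) for c in children[node]]
            if not ls:
                al[node] = 0.0
            elif len(ls) == 1:
                al[node] = ls[0]
            else:
                al[node] = float(sum(l**1.5 for l in ls) ** (2.0 / 3.0))
    return al


def _daughter_radii(r0: float, lengths: list[float], rule: str) -> list[float]:
    """Split a parent radius among daughters, conserving Σ r^{3/2} = r0^{3/2}."""
    expo = {"literal": 1.5, "linear": 1.0}[rule]
    wts = np.array([l**expo for l in lengths])
    if np.all(wts == 0):
        wts = np.ones_like(wts)
    c = r0 / float(np.sum(wts**1.5)) ** (2.0 / 3.0)
    return [float(c * w) for w in wts]


def distribute_radii(
    tree: TreeMorphology,
    al: dict[int, float],
    r_L: float,
    r_proximal: float,
    ratio_rule: str = "literal",
) -> OptimalTree:
    """Assign quadratic-taper radii over the whole tree (step ii).

    The path from the root carries r(x) = α(l₀ − x)² + r_L with l₀ the
    root's apparent length and α = (r_proximal − r_L)/l₀²; at each branch
    the radius is split per ``ratio_rule`` and each daughter restarts the
    quadratic with its own apparent length.  All radii are floored at r_L.
    """
    if ratio_rule not in RATIO_RULES:
        raise ValueError(f"ratio_rule must be one of {RATIO_RULES}")
    if not (r_proximal > r_L > 0):
        raise ValueError("need r_proximal > r_L > 0")
    children = tree.children_map()
    out = tree.copy()
    records: list = []
    n_floored = 0

    def taper(r_start: float, L_app: float, d: float) -> float:
        if L_app <= 0:
            return r_L
        alpha = (r_start - r_L) / L_app**2
        u = max(L_app - d, 0.0)
        return alpha * u * u + r_L

    root = tree.root_id
    out.radius[out.index_of(root)] = r_proximal
    # stack entries: (node, branch-start radius, branch apparent length,
    #                 arc distance of node from branch start)
    stack = [(root, r_proximal, al[root], 0.0)]
    while stack:
        node, r_start, L_app, d = stack.pop()
        kids = children[node]
        r_here = taper(r_start, L_app, d)
        if len(kids) == 1:
            c = kids[0]
            dc = d + tree.edge_length(c)
            rc = taper(r_start, L_app, dc)
            if rc < r_L:
                rc, n_floored = r_L, n_floored + 1
            out.radius[out.index_of(c)] = rc
            stack.append((c, r_start, L_app, dc))
        elif len(kids) >= 2:
            ls = [al[c] + tree.edge_length(c) for c in kids]
            rds = _daughter_radii(r_here, ls, ratio_rule)
            records.append((node, r_here, list(rds)))
            for c, l_c, r_c in zip(kids, ls, rds):
                if r_c < r_L:
                    r_c, n_floored = r_L, n_floored + 1
                dc = tree.edge_length(c)
                rc_node = taper(r_c, l_c, dc)
                if rc_node < r_L:
                    rc_node, n_floored = r_L, n_floored + 1
                out.radius[out.index_of(c)] = rc_node
                stack.append((c, r_c, l_c, dc))
    np.maximum(out.radius, r_L, out=out.radius)
    return OptimalTree(
        tree=out, r_L=r_L, r_proximal=r_proximal, ratio_rule=ratio_rule,
        branch_records=records, n_floored=n_floored,
    )


def match_volume(
    tree: TreeMorphology,
    r_L: float | None = None,
    ratio_rule: str = "literal",
    tol: float = 1.0e-3,
    max_iter: int = 100,
    r_proximal_init: float | None = None,
) -> OptimalTree:
    """Full optimal-taper mapping with volume matching (steps i–iii).

    ``r_L`` defaults to the minimal radius anywhere on the tree and the
    initial proximal radius to the measured maximum.  The proximal radius
    is then adjusted by root bracketing/bisection until the optimal tree's
    volume matches the original within ``tol`` (relative).  The volume is a
    monotone function of the proximal radius, so convergence is guaranteed
    once a bracket is found.
    """
    target = tree.total_volume()
    if r_L is None:
        r_L = float(np.min(tree.radius))
    if r_proximal_init is None:
        r_proximal_init = float(np.max(tree.radius))
    r_proximal_init = max(r_proximal_init, 2.0 * r_L)
    al = apparent_lengths(tree)

    evals = {"count": 0}

    def vol_err(r_prox: float) -> float:
        evals["count"] += 1
        ot = distribute_radii(tree, al, r_L, r_prox, ratio_rule)
        return ot.tree.total_volume() - target

    # fast path: the supplied proximal radius may already match (fixed point)
    if abs(vol_err(r_proximal_init)) <= 0.1 * tol * target:
        r_star = r_proximal_init
    else:
        lo = r_L * (1.0 + 1.0e-9)
        if vol_err(lo) > 0:
            raise ValueError(
                "target volume below the all-r_L floor: choose a smaller r_L"
            )
        hi = max(r_proximal_init, lo * 2.0)
        e_hi = vol_err(hi)
        it = 0
        while e_hi < 0:
            lo, hi = hi, hi * 2.0
            e_hi = vol_err(hi)
            it += 1
            if it > max_iter:
                raise RuntimeError("could not bracket the volume match")
        # bisection to a tenth of the requested volume tolerance
        r_star = 0.5 * (lo + hi)
        for _ in range(max_iter):
            e = vol_err(r_star)
            if abs(e) <= 0.1 * tol * target:
                break
            if e > 0:
                hi = r_star
            else:
                lo = r_star
            r_star = 0.5 * (lo + hi)
    ot = distribute_radii(tree, al, r_L, float(r_star), ratio_rule)
    v = ot.tree.total_volume()
    ot.volume_ratio = v / target
    ot.iterations = evals["count"]
    if abs(ot.volume_ratio - 1.0) > tol:
        raise RuntimeError(
            f"volume match failed: ratio {ot.volume_ratio:.6f} outside tol {tol}"
        )
    return ot


def transfer_map(
    tree: TreeMorphology,
    params: PassiveParams,
    soma_bc: str = "sealed",
    soma_conductance_uS: float = 0.0,
) -> dict:
    """Steady current-transfer ratio to the root from every node.

    For each node k the ratio is v_root/v_k under unit current injected at
    k, i.e. G[root, k] / G[k, k] from the tree Green's matrix.  Returns a
    dict with node ids, per-node ratios, path distances to the root, the
    (uniformly node-weighted) mean ratio and the input resistances.
    """
    G = tree_greens_matrix(tree, params, soma_bc, soma_conductance_uS)
    root_idx = tree.index_of(tree.root_id)
    diag = np.diag(G)
    ratios = G[root_idx, :] / diag
    # path distance to root per node
    dist = np.zeros(tree.n_nodes)
    for k in range(tree.n_nodes):
        pid = int(tree.parent_id[k])
        if pid != -1:
            dist[k] = dist[tree.index_of(pid)] + tree.edge_length(int(tree.ids[k]))
    return {
        "ids": tree.ids.copy(),
        "ratio": ratios,
        "distance_um": dist,
        "mean_transfer": float(np.mean(ratios)),
        "input_resistance_MOhm": diag,
    }


def equalisation_index(tree: TreeMorphology, params: PassiveParams,
                       soma_bc: str = "sealed",
                       quantity: str = "impact") -> float:
    """Coefficient of variation of per-node somatic impact — lower is more
    "democratic"; a single-node tree scores 0.

    ``quantity='impact'`` (default) uses the somatic impact G(root, k): the
    root voltage per unit current injected at node k.  Equalising this
    across synaptic sites is the classical dendritic-democracy notion, and
    it is the quantity the optimal taper actually equalises — the high
    local input resistance of thin distal branches offsets their stronger
    attenuation.  ``quantity='ratio'`` uses the transfer ratio
    G(root, k)/G(k, k) instead; by construction the ratio strips out that
    input-resistance compensation, so tapered trees do *not* generally
    reduce its spread.
    """
    tm = transfer_map(tree, params, soma_bc=soma_bc)
    if quantity == "impact":
        vals = tm["ratio"] * tm["input_resistance_MOhm"]
    elif quantity == "ratio":
        vals = tm["ratio"]
    else:
        raise ValueError("quantity must be 'impact' or 'ratio'")
    return float(np.std(vals) / np.mean(vals))


def constant_radius_tree(tree: TreeMorphology) -> TreeMorphology:
    """Same topology with one constant radius chosen to preserve volume.

    Solves Σ π r² l_e = V for r over all parent edges (cylindrical edges).
    """
    total_len = 0.0
    for k in range(tree.n_nodes):
        if int(tree.parent_id[k]) != -1:
            total_len += tree.edge_length(int(tree.ids[k]))
    if total_len <= 0:
        raise ValueError("tree has no edges")
    V = tree.total_volume()
    r_const = float(np.sqrt(V / (np.pi * total_len)))
    out = tree.copy()
    out.radius[:] = r_const
    return out
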