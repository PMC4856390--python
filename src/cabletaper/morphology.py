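"""Radius profiles and SWC tree morphologies.

Two containers cover everything the solvers need: :class:`RadiusProfile`
for a single unbranched cable sampled as (arclength, radius) pairs, and
:class:`TreeMorphology` for a rooted SWC-style tree.  Radii — not diameters —
are stored everywhere; SWC column 6 is already a radius, so no factor of two
is ever applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class SWCParseError(ValueError):
    """Malformed SWC content (bad line, wrong column count, bad numbers)."""


class SWCStructureError(ValueError):
    """Structurally invalid tree (multiple roots, cycles, dangling parents)."""


@dataclass(frozen=True)
class RadiusProfile:
    """Sampled taper r(x) of one unbranched cable, proximal → distal.

    ``x`` holds arclength positions in µm with ``x[0] == 0`` at the proximal
    end; ``r`` holds the corresponding radii in µm.
    """

    x: np.ndarray
    r: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        r = np.asarray(self.r, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "r", r)
        if x.ndim != 1 or r.ndim != 1 or len(x) != len(r):
            raise ValueError("x and r must be 1-D arrays of equal length")
        if len(x) < 2:
            raise ValueError("a profile needs at least two sample points")
        if x[0] != 0.0:
            raise ValueError("profiles start at x = 0 (proximal end)")
        if not np.all(np.diff(x) > 0):
            raise ValueError("x must be strictly increasing")
        if not np.all(np.isfinite(x)) or not np.all(np.isfinite(r)):
            raise ValueError("x and r must be finite")
        if not np.all(r > 0):
            raise ValueError("all radii must be strictly positive")

    @property
    def L(self) -> float:
        """Total cable length in µm."""
        return float(self.x[-1])

    def volume(self) -> float:
        """Cable volume π ∫ r²(x) dx in µm³ (trapezoidal)."""
        return float(np.pi * np.trapezoid(self.r**2, self.x))

    def radius_at(self, x: float | np.ndarray):
        """Linear interpolation of the radius at arbitrary positions."""
        return np.interp(x, self.x, self.r)


@dataclass
class TreeMorphology:
    """SWC-style rooted tree: parallel arrays over nodes, order preserved.

    ``parent_id`` is -1 for the (single) root.  Node ids are arbitrary
    positive integers; ``index_of`` maps an id to its array position.
    """

    ids: np.ndarray
    type_code: np.ndarray
    xyz: np.ndarray  # (n, 3) µm
    radius: np.ndarray  # µm
    parent_id: np.ndarray
    _index: dict[int, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=int)
        self.type_code = np.asarray(self.type_code, dtype=int)
        self.xyz = np.asarray(self.xyz, dtype=float)
        self.radius = np.asarray(self.radius, dtype=float)
        self.parent_id = np.asarray(self.parent_id, dtype=int)
        self._index = {int(i): k for k, i in enumerate(self.ids)}
        self.validate()

    # -- structure ---------------------------------------------------------
    def validate(self) -> None:
        n = len(self.ids)
        if len(self._index) != n:
            raise SWCStructureError("duplicate node ids")
        if not np.all(np.isfinite(self.xyz)):
            raise SWCStructureError("non-finite coordinates")
        if not np.all(self.radius > 0):
            raise SWCStructureError("all radii must be strictly positive")
        roots = np.flatnonzero(self.parent_id == -1)
        if len(roots) != 1:
            raise SWCStructureError(f"expected exactly one root, found {len(roots)}")
        for k in range(n):
            pid = int(self.parent_id[k])
            if pid != -1 and pid not in self._index:
                raise SWCStructureError(
                    f"node {int(self.ids[k])} has unknown parent {pid}"
                )
        # acyclicity + connectivity: walk each node to the root
        root = int(self.ids[roots[0]])
        seen_ok: set[int] = {root}
        for start in self.ids:
            trail = []
            i = int(start)
            while i not in seen_ok:
                trail.append(i)
                if i in trail[:-1] or len(trail) > n:
                    raise SWCStructureError(f"cycle detected at node {i}")
                pid = int(self.parent_id[self._index[i]])
                if pid == -1:
                    break
                i = pid
            seen_ok.update(trail)

    @property
    def n_nodes(self) -> int:
        return len(self.ids)

    @property
    def root_id(self) -> int:
        return int(self.ids[np.flatnonzero(self.parent_id == -1)[0]])

    def index_of(self, node_id: int) -> int:
        try:
            return self._index[int(node_id)]
        except KeyError:
            raise KeyError(f"no node with id {node_id}") from None

    def children_map(self) -> dict[int, list[int]]:
        """Mapping node id → list of child ids, in node order."""
        ch: dict[int, list[int]] = {int(i): [] for i in self.ids}
        for i, pid in zip(self.ids, self.parent_id):
            if pid != -1:
                ch[int(pid)].append(int(i))
        return ch

    def edge_length(self, child_id: int) -> float:
        """Euclidean distance in µm from a node to its parent."""
        k = self.index_of(child_id)
        pid = int(self.parent_id[k])
        if pid == -1:
            raise ValueError("the root has no parent edge")
        return float(np.linalg.norm(self.xyz[k] - self.xyz[self.index_of(pid)]))

    def total_volume(self) -> float:
        """Sum of frustum volumes over all parent edges, µm³."""
        v = 0.0
        for k in range(self.n_nodes):
            pid = int(self.parent_id[k])
            if pid == -1:
                continue
            j = self.index_of(pid)
            l = float(np.linalg.norm(self.xyz[k] - self.xyz[j]))
            r1, r2 = float(self.radius[j]), float(self.radius[k])
            v += np.pi * l * (r1 * r1 + r1 * r2 + r2 * r2) / 3.0
        return v

    def copy(self) -> "TreeMorphology":
        return TreeMorphology(
            ids=self.ids.copy(),
            type_code=self.type_code.copy(),
            xyz=self.xyz.copy(),
            radius=self.radius.copy(),
            parent_id=self.parent_id.copy(),
        )


# -- SWC input/output ------------------------------------------------------

def read_swc(path) -> TreeMorphology:
    """Read a 7-column SWC file ('#' comments allowed) into a tree.

    Raises :class:`SWCParseError` naming the offending line for malformed
    content and :class:`SWCStructureError` for invalid topology.
    """
    ids, types, xyz, radii, parents = [], [], [], [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise SWCParseError(
                    f"{path}:{lineno}: expected 7 columns, got {len(parts)}"
                )
            try:
                i = int(parts[0])
                t = int(parts[1])
                x, y, z, r = (float(p) for p in parts[2:6])
                pid = int(parts[6])
            except ValueError as exc:
                raise SWCParseError(f"{path}:{lineno}: {exc}") from None
            ids.append(i)
            types.append(t)
            xyz.append((x, y, z))
            radii.append(r)
            parents.append(pid)
    if not ids:
        raise SWCParseError(f"{path}: no data lines")
    return TreeMorphology(
        ids=np.array(ids),
        type_code=np.array(types),
        xyz=np.array(xyz),
        radius=np.array(radii),
        parent_id=np.array(parents),
    )


def write_swc(tree: TreeMorphology, path) -> None:
    """Write a tree as 7-column SWC; floats use shortest round-trip repr."""
    tree.validate()
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for k in range(tree.n_nodes):
            fh.write(
                f"{int(tree.ids[k])} {int(tree.type_code[k])} "
                f"{float(tree.xyz[k, 0])!r} {float(tree.xyz[k, 1])!r} "
                f"{float(tree.xyz[k, 2])!r} "
                f"{float(tree.radius[k])!r} {int(tree.parent_id[k])}\n"
            )


def path_to_profile(tree: TreeMorphology, tip_id: int) -> RadiusProfile:
    """Radius profile along the root → tip path, arclength from the root.

    Arclength uses 3-D Euclidean inter-node distances; x = 0 at the root
    (the proximal end of every profile).
    """
    k = tree.index_of(tip_id)
    chain = [k]
    while int(tree.parent_id[chain[-1]]) != -1:
        chain.append(tree.index_of(int(tree.parent_id[chain[-1]])))
    chain.reverse()
    pts = tree.xyz[chain]
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    x = np.concatenate([[0.0], np.cumsum(seg)])
    return RadiusProfile(x=x, r=tree.radius[chain])


def resample_profile(p: RadiusProfile, n: int) -> RadiusProfile:
    """Resample onto a uniform n-point grid on [0, L] (linear interpolation).

    Endpoints are preserved exactly; n must be at least 2.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    x = np.linspace(0.0, p.L, int(n))
    r = np.interp(x, p.x, p.r)
    r[0], r[-1] = p.r[0], p.r[-1]
    return RadiusProfile(x=x, r=r)


# -- CSV profiles ----------------------------------------------------------

def read_profile_csv(path) -> RadiusProfile:
    """Read a profile from CSV with columns x_um, r_um."""
    df = pd.read_csv(path)
    return RadiusProfile(x=df["x_um"].to_numpy(), r=df["r_um"].to_numpy())


def write_profile_csv(p: RadiusProfile, path) -> None:
    pd.DataFrame({"x_um": p.x, "r_um": p.r}).to_csv(path, index=False)
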