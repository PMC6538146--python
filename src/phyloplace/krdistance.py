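"""Phylogenetic Kantorovich-Rubinstein (earth mover) distance.

The KR distance between two unit-mass placement distributions on a
shared reference tree is the minimal total work (mass times moving
distance along tree paths) needed to turn one distribution into the
other.  On a tree, the optimal transport has a closed form: for every
infinitesimal segment, the mass that must cross it is the net signed
difference of the two distributions on one side, so

    KR(a, b) = integral over the tree of |net (a - b) mass below| dlen,

computed here in one children-before-parents pass, with exact handling
of individual mass-point positions within each edge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Sample
from .masses import BinnedMassVector, MassVector
from .tree import ReferenceTree

__all__ = ["MassPointsOnTree", "kr_distance", "pairwise_kr", "squash_points"]

MASS_TOLERANCE = 1e-6


@dataclass
class MassPointsOnTree:
    """Point masses on tree edges, sorted by position within each edge.

    ``positions[col]`` and ``masses[col]`` hold the mass points of the
    edge at canonical column ``col``; positions are distances from the
    proximal (root-side) end of the edge.
    """

    tree: ReferenceTree
    positions: list[np.ndarray]
    masses: list[np.ndarray]
    name: str = ""

    def total(self) -> float:
        return float(sum(m.sum() for m in self.masses))

    def edge_totals(self) -> np.ndarray:
        return np.array([m.sum() for m in self.masses])

    @classmethod
    def from_sample(cls, sample: Sample, normalized: bool = True) -> "MassPointsOnTree":
        """Materialize every placement as a point mass at its proximal position."""
        tree = sample.tree
        pos: list[list[float]] = [[] for _ in range(tree.num_edges)]
        mas: list[list[float]] = [[] for _ in range(tree.num_edges)]
        for q in sample.pqueries:
            for p in q.placements:
                col = tree.edge_column(p.edge_num)
                pos[col].append(p.proximal_length)
                mas[col].append(q.multiplicity * p.like_weight_ratio)
        return cls._build(tree, pos, mas, normalized, sample.name)

    @classmethod
    def from_binned(cls, binned: BinnedMassVector, normalized: bool = True) -> "MassPointsOnTree":
        """One mass point per non-empty bin, at the bin center."""
        tree = binned.tree
        pos = [list(binned.centers[c][binned.bins[c] > 0]) for c in range(tree.num_edges)]
        mas = [list(binned.bins[c][binned.bins[c] > 0]) for c in range(tree.num_edges)]
        return cls._build(tree, pos, mas, normalized, binned.name)

    @classmethod
    def from_mass_vector(cls, mv: MassVector, normalized: bool = True) -> "MassPointsOnTree":
        """One mass point per edge, at the edge midpoint (b = 1 view)."""
        tree = mv.tree
        mid = tree.branch_lengths / 2.0
        pos = [[mid[c]] if mv.values[c] > 0 else [] for c in range(tree.num_edges)]
        mas = [[mv.values[c]] if mv.values[c] > 0 else [] for c in range(tree.num_edges)]
        return cls._build(tree, pos, mas, normalized, mv.name)

    @classmethod
    def _build(cls, tree, pos, mas, normalized, name) -> "MassPointsOnTree":
        total = sum(sum(m) for m in mas)
        if normalized:
            if total <= 0:
                raise ValueError("cannot normalize an all-zero mass distribution")
            scale = 1.0 / total
        else:
            scale = 1.0
        positions, masses = [], []
        for p, m in zip(pos, mas):
            p = np.asarray(p, dtype=float)
            m = np.asarray(m, dtype=float) * scale
            order = np.argsort(p, kind="stable")
            positions.append(p[order])
            masses.append(m[order])
        return cls(tree=tree, positions=positions, masses=masses, name=name)


def squash_points(
    points: list[MassPointsOnTree], weights=None
) -> MassPointsOnTree:
    """Weighted average of point-mass distributions (union of scaled points)."""
    if not points:
        raise ValueError("need at least one distribution")
    tree = points[0].tree
    if weights is None:
        weights = np.ones(len(points))
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0) or w.sum() == 0:
        raise ValueError("weights must be non-negative and not all zero")
    w = w / w.sum()
    positions, masses = [], []
    for col in range(tree.num_edges):
        p = np.concatenate([pt.positions[col] for pt in points])
        m = np.concatenate([wi * pt.masses[col] for wi, pt in zip(w, points)])
        order = np.argsort(p, kind="stable")
        positions.append(p[order])
        masses.append(m[order])
    return MassPointsOnTree(tree=tree, positions=positions, masses=masses)


def _edge_work(positions, net_masses, length, incoming):
    """Work on one edge, sweeping from the distal end toward the proximal end.

    ``incoming`` is the signed net mass flowing in at the distal end;
    returns (work, net mass leaving at the proximal end).
    """
    work = 0.0
    cur = incoming
    prev = length
    for pos, m in zip(positions[::-1], net_masses[::-1]):
        work += abs(cur) * (prev - pos)
        cur += m
        prev = pos
    work += abs(cur) * prev
    return work, cur


def kr_distance(a: MassPointsOnTree, b: MassPointsOnTree) -> float:
    """Order-1 KR / earth-mover distance between two unit-mass distributions."""
    tree = a.tree
    if not tree.same_topology_as(b.tree):
        raise ValueError("KR distance requires a shared reference tree")
    ta, tb = a.total(), b.total()
    if abs(ta - tb) > MASS_TOLERANCE:
        raise ValueError(
            f"total masses differ ({ta} vs {tb}); KR distance needs equal masses"
        )
    lens = tree.branch_lengths
    node_net = np.zeros(tree.num_nodes)
    work = 0.0

    # A root edge hangs above the root: mass on it flows toward the root
    # through its distal end, nothing lies beyond its proximal end.
    root_edge_col = (
        tree.edge_column(tree.root_edge_num) if tree.root_edge_num >= 0 else -1
    )
    if root_edge_col >= 0:
        pos = np.concatenate([a.positions[root_edge_col], b.positions[root_edge_col]])
        net = np.concatenate([a.masses[root_edge_col], -b.masses[root_edge_col]])
        order = np.argsort(pos, kind="stable")
        pos, net = pos[order], net[order]
        cur, prev = 0.0, 0.0
        for p, m in zip(pos, net):
            work += abs(cur) * (p - prev)
            cur += m
            prev = p
        work += abs(cur) * (lens[root_edge_col] - prev)
        node_net[0] += cur

    for v in tree.postorder_nodes():
        if v == 0:
            continue
        col = tree.edge_column(int(tree.node_edge_num[v]))
        pos = np.concatenate([a.positions[col], b.positions[col]])
        net = np.concatenate([a.masses[col], -b.masses[col]])
        order = np.argsort(pos, kind="stable")
        w, out = _edge_work(pos[order], net[order], lens[col], node_net[v])
        work += w
        node_net[tree.parent[v]] += out
    return work


def pairwise_kr(
    samples_points: list[MassPointsOnTree],
    names: list[str] | None = None,
    threads: int = 1,
) -> pd.DataFrame:
    """Symmetric matrix of pairwise KR distances.

    The result is independent of ``threads``: pairs are partitioned
    deterministically and each distance is computed in isolation.
    """
    n = len(samples_points)
    if n < 2:
        raise ValueError("need at least two distributions")
    if names is None:
        names = [pt.name or f"S{i}" for i, pt in enumerate(samples_points)]
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    mat = np.zeros((n, n))
    if threads > 1:
        from joblib import Parallel, delayed

        vals = Parallel(n_jobs=threads)(
            delayed(kr_distance)(samples_points[i], samples_points[j]) for i, j in pairs
        )
    else:
        vals = [kr_distance(samples_points[i], samples_points[j]) for i, j in pairs]
    for (i, j), d in zip(pairs, vals):
        mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=names, columns=names)
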