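"""Synthetic placement fixtures with planted structure.

Every method in this package can be exercised without external data:
this module generates random bifurcating reference trees, samples of
placed queries whose mass is concentrated on chosen ("planted") clades,
and per-sample metadata whose features track the planted clade masses
through a linear link with gaussian noise.

Emulated features of real placement data: LWR uncertainty spread over a
small edge neighborhood, positions along branches, query multiplicities
and library-size variation.  Not emulated: phylogenetic signal in the
placements themselves (edges within a region are chosen uniformly, not
by sequence similarity) and reference-tree misspecification.

All randomness flows through one ``numpy.random.default_rng`` (PCG64)
stream seeded from the fixture spec, so a seed fully determines the
output on any platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import Placement, Pquery, Sample, write_jplace
from .tree import ReferenceTree

__all__ = [
    "FixtureSpec",
    "random_tree",
    "simulate_samples",
    "write_fixture",
    "disjoint_clades",
]


def disjoint_clades(tree: ReferenceTree, k: int = 2, min_edges: int = 3) -> list[int]:
    """Pick ``k`` inner edges whose subtrees are pairwise disjoint.

    Deterministic greedy choice by decreasing subtree size (capped at
    half the tree so the backbone keeps mass too), used to plant
    separated mass concentrations for clustering fixtures.
    """
    m = tree.num_edges
    cands = []
    for col in range(m):
        e = int(tree.edge_order[col])
        sub = tree.subtree_edge_columns(e)
        if min_edges <= sub.size <= m // 2:
            cands.append((sub.size, e, set(int(c) for c in sub) | {col}))
    cands.sort(key=lambda t: (-t[0], t[1]))
    chosen: list[int] = []
    used: set[int] = set()
    for size, e, region in cands:
        if not (region & used):
            chosen.append(e)
            used |= region
            if len(chosen) == k:
                return chosen
    raise ValueError(f"could not find {k} disjoint clades with >= {min_edges} edges")


def random_tree(taxa: int, seed: int = 0, mean_branch_length: float = 0.1) -> ReferenceTree:
    """Random unrooted binary tree with a top-level trifurcation.

    Built by repeatedly splitting a uniformly chosen edge; branch
    lengths are exponential with the given mean.  The tree has
    ``2 * taxa - 3`` edges, numbered in preorder.
    """
    if taxa < 3:
        raise ValueError("need at least three taxa")
    rng = np.random.default_rng(seed)

    # grow tree as parent pointers; node 0 is the trifurcation "root"
    parent = {1: 0, 2: 0, 3: 0}
    children = {0: [1, 2, 3], 1: [], 2: [], 3: []}
    blen = {i: rng.exponential(mean_branch_length) for i in (1, 2, 3)}
    is_tip = {1: True, 2: True, 3: True}
    next_node = 4
    for _ in range(taxa - 3):
        v = int(rng.choice([w for w in parent]))  # edge above v is split
        u, t = next_node, next_node + 1
        next_node += 2
        p = parent[v]
        children[p][children[p].index(v)] = u
        split = rng.uniform(0.2, 0.8)
        parent[u], blen[u], is_tip[u] = p, blen[v] * split, False
        blen[v] = blen[v] * (1 - split)
        parent[v] = u
        parent[t], blen[t], is_tip[t] = u, rng.exponential(mean_branch_length), True
        children[u] = [v, t]
        children[t] = []

    # renumber nodes in preorder and assign preorder edge numbers
    order: list[int] = []
    stack = [0]
    while stack:
        v = stack.pop()
        order.append(v)
        stack.extend(reversed(children[v]))
    idx = {v: i for i, v in enumerate(order)}
    n = len(order)
    parent_arr = np.full(n, -1, dtype=np.intp)
    children_arr: list[list[int]] = [[] for _ in range(n)]
    labels: list[str | None] = [None] * n
    edge_num = np.full(n, -1, dtype=np.intp)
    blen_arr = np.zeros(n)
    tip_counter = 0
    e = 0
    for v in order:
        i = idx[v]
        if v != 0:
            parent_arr[i] = idx[parent[v]]
            blen_arr[i] = blen[v]
            edge_num[i] = e
            e += 1
        children_arr[i] = [idx[c] for c in children[v]]
        if is_tip.get(v, False):
            labels[i] = f"T{tip_counter}"
            tip_counter += 1
    return ReferenceTree(
        parent=parent_arr,
        children=children_arr,
        labels=labels,
        node_edge_num=edge_num,
        node_branch_length=blen_arr,
    )


@dataclass
class FixtureSpec:
    """Study conditions for a simulated set of placement samples.

    ``planted_clades`` lists edge numbers; each clade is the set of
    edges strictly below that edge.  ``clade_fractions`` gives, per
    sample and clade, the probability that a query's mass lands inside
    the clade (the remainder is spread uniformly over the whole tree).
    A ``None`` entry draws fractions uniformly from ``fraction_range``.
    Metadata features are ``alpha * fraction + Normal(0, noise_sd)``,
    one numeric feature per planted clade, plus a categorical ``group``
    column when ``group_labels`` is set.
    """

    n_samples: int = 40
    queries_per_sample: int = 100
    planted_clades: list[int] = field(default_factory=list)
    clade_fractions: np.ndarray | None = None
    fraction_range: tuple[float, float] = (0.1, 0.9)
    alpha: float = 1.0
    noise_sd: float = 0.05
    group_labels: list[str] | None = None
    multiplicity_range: tuple[int, int] = (1, 1)
    mass_loss: float = 0.0  # fraction of LWR discarded per query (sub-1 sums)
    seed: int = 0


def _edge_neighbors(tree: ReferenceTree, col: int) -> list[int]:
    v = tree.edge_child_node(col)
    out = []
    for c in tree.children[v]:
        out.append(tree.edge_column(int(tree.node_edge_num[c])))
    p = tree.parent[v] if v != 0 else -1
    if p >= 0:
        if p != 0 or tree.root_edge_num >= 0:
            if p != 0:
                out.append(tree.edge_column(int(tree.node_edge_num[p])))
        for sib in tree.children[p]:
            if sib != v:
                out.append(tree.edge_column(int(tree.node_edge_num[sib])))
    return out


def _make_pquery(tree, region, weights, name, rng, lens, multiplicity, mass_loss) -> Pquery:
    primary = int(region[rng.choice(len(region), p=weights)])
    region_set = set(int(r) for r in region)
    neighbors = [c for c in _edge_neighbors(tree, primary) if c in region_set]
    k = int(rng.choice([1, 2, 3], p=[0.5, 0.3, 0.2]))
    cols = [primary] + list(rng.permutation(neighbors))[: k - 1]
    lwrs = rng.dirichlet(np.ones(len(cols)))
    lwrs = np.sort(lwrs)[::-1] * (1.0 - mass_loss)
    placements = []
    for col, lwr in zip(cols, lwrs):
        pos = rng.uniform(0.0, lens[col]) if lens[col] > 0 else 0.0
        placements.append(
            Placement(
                edge_num=int(tree.edge_order[col]),
                like_weight_ratio=float(lwr),
                proximal_length=float(pos),
                pendant_length=float(rng.exponential(0.05)),
            )
        )
    return Pquery(names=[name], placements=placements, multiplicity=multiplicity)


def simulate_samples(
    tree: ReferenceTree, spec: FixtureSpec
) -> tuple[list[Sample], pd.DataFrame]:
    """Generate placement samples and matching metadata from a spec."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    k = len(spec.planted_clades)
    clade_cols = []
    for e in spec.planted_clades:
        if not tree.has_edge(e):
            raise ValueError(f"planted clade edge {e} not in tree")
        cols = tree.subtree_edge_columns(e)
        if cols.size == 0:
            raise ValueError(f"planted clade edge {e} is a tip edge")
        clade_cols.append(cols)

    if spec.clade_fractions is not None:
        fractions = np.asarray(spec.clade_fractions, dtype=float)
        if fractions.shape != (n, k):
            raise ValueError("clade_fractions must be n_samples x n_clades")
    else:
        lo, hi = spec.fraction_range
        fractions = rng.uniform(lo, hi, size=(n, k))
    if k and np.any(fractions.sum(axis=1) > 1.0):
        raise ValueError("per-sample clade fractions must sum to at most 1")

    lens = tree.branch_lengths
    all_cols = np.arange(tree.num_edges)
    samples = []
    for i in range(n):
        name = f"sample_{i:03d}"
        # Per-sample community composition: Dirichlet weights over each
        # region's edges, so the within-clade mass split varies between
        # samples while the clade total tracks the planted fraction.
        bg_weights = rng.dirichlet(np.ones(len(all_cols)))
        clade_weights = [rng.dirichlet(np.ones(len(c))) for c in clade_cols]
        pqueries = []
        for q in range(spec.queries_per_sample):
            u = rng.random()
            region, weights = all_cols, bg_weights
            acc = 0.0
            for ci in range(k):
                acc += fractions[i, ci]
                if u < acc:
                    region, weights = clade_cols[ci], clade_weights[ci]
                    break
            mult = (
                1.0
                if spec.multiplicity_range == (1, 1)
                else float(rng.integers(spec.multiplicity_range[0], spec.multiplicity_range[1] + 1))
            )
            pqueries.append(
                _make_pquery(
                    tree, region, weights, f"{name}_q{q}", rng, lens, mult, spec.mass_loss
                )
            )
        samples.append(Sample(name=name, tree=tree, pqueries=pqueries))

    meta = {}
    for ci in range(k):
        meta[f"feature_{ci}"] = spec.alpha * fractions[:, ci] + rng.normal(
            0.0, spec.noise_sd, size=n
        )
    if spec.group_labels is not None:
        if len(spec.group_labels) != n:
            raise ValueError("group_labels must have one entry per sample")
        meta["group"] = list(spec.group_labels)
    metadata = pd.DataFrame(meta, index=[s.name for s in samples])
    metadata.index.name = "sample"
    return samples, metadata


def write_fixture(samples: list[Sample], metadata: pd.DataFrame, out_dir) -> None:
    """Write samples as jplace files plus a metadata CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for s in samples:
        write_jplace(s, out / f"{s.name}.jplace")
    metadata.to_csv(out / "metadata.csv")
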