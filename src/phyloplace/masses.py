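"""Mass interpretation of placements: per-edge masses and transforms.

The likelihood weight ratios of all queries in a sample are read as
point masses on the edges of the reference tree.  Summing them per edge
gives a length-``m`` vector that summarizes a sample; the transforms in
this module (normalization, branch binning, squashing, imbalances)
operate on that representation and on the ``n x m`` sample-by-edge
matrices built from it.

All per-edge vectors use the tree's canonical preorder column layout
(see :attr:`ReferenceTree.edge_order`), so that vectors and matrix
columns are directly comparable across samples and runs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io import Sample
from .tree import ReferenceTree

__all__ = [
    "MassVector",
    "BinnedMassVector",
    "ImbalanceVector",
    "MassMatrix",
    "edge_masses",
    "normalize",
    "bin_masses",
    "squash",
    "edge_imbalances",
    "build_matrix",
]


@dataclass
class MassVector:
    """Per-edge accumulated mass of one sample (canonical column order)."""

    tree: ReferenceTree
    values: np.ndarray
    normalized: bool = False
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.tree.num_edges,):
            raise ValueError(
                f"mass vector length {self.values.shape} does not match "
                f"{self.tree.num_edges} tree edges"
            )
        if np.any(self.values < 0):
            raise ValueError("edge masses must be non-negative")

    def total(self) -> float:
        return float(self.values.sum())

    def __getitem__(self, edge_num: int) -> float:
        return float(self.values[self.tree.edge_column(edge_num)])


@dataclass
class BinnedMassVector:
    """Per-edge masses discretized into ``b`` equal-width bins.

    ``bins[col, i]`` is the mass in the *i*-th bin of the edge at
    canonical column ``col``; ``centers[col, i]`` is its position,
    ``(i + 0.5) * branch_length / b`` from the proximal node.
    """

    tree: ReferenceTree
    bins: np.ndarray
    centers: np.ndarray
    normalized: bool = False
    name: str = ""

    @property
    def b(self) -> int:
        return self.bins.shape[1]

    def edge_totals(self) -> np.ndarray:
        return self.bins.sum(axis=1)

    def total(self) -> float:
        return float(self.bins.sum())


@dataclass
class ImbalanceVector:
    """Per-edge imbalance: root-side mass minus non-root-side mass.

    Tip-edge entries are ``NaN`` unless tips were requested; for a
    normalized sample the defined entries lie in ``[-1, 1]``.
    """

    tree: ReferenceTree
    values: np.ndarray
    include_tips: bool = False
    name: str = ""

    def defined_mask(self) -> np.ndarray:
        return ~np.isnan(self.values)

    def __getitem__(self, edge_num: int) -> float:
        return float(self.values[self.tree.edge_column(edge_num)])


@dataclass
class MassMatrix:
    """``n x m`` matrix of per-edge values over samples.

    ``content`` tags what the rows hold (``"masses"``, ``"imbalances"``
    or ``"balances"``); columns follow the canonical edge order and are
    labeled by jplace edge numbers.
    """

    tree: ReferenceTree
    values: np.ndarray
    sample_names: list[str]
    edge_nums: np.ndarray
    content: str = "masses"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.sample_names), columns=[int(e) for e in self.edge_nums]
        )

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]


def edge_masses(sample: Sample) -> MassVector:
    """Accumulate ``multiplicity * LWR`` of every placement per edge.

    For a sample of fully placed, unit-multiplicity queries the total
    equals the number of queries in the sample.
    """
    tree = sample.tree
    c = np.zeros(tree.num_edges)
    for q in sample.pqueries:
        for p in q.placements:
            c[tree.edge_column(p.edge_num)] += q.multiplicity * p.like_weight_ratio
    return MassVector(tree=tree, values=c, normalized=False, name=sample.name)


def normalize(mass_vector: MassVector) -> MassVector:
    """Scale a mass vector to unit total mass (relative abundances)."""
    if mass_vector.normalized:
        return replace(mass_vector, values=mass_vector.values.copy())
    total = mass_vector.total()
    if total <= 0:
        raise ValueError("cannot normalize an all-zero mass vector")
    return replace(mass_vector, values=mass_vector.values / total, normalized=True)


def bin_masses(sample: Sample, b: int, normalized: bool = False) -> BinnedMassVector:
    """Accumulate each placement into the nearest of ``b`` bins per edge.

    Bin centers sit at ``(i + 0.5) * len / b``; a mass point at an exact
    midpoint between centers goes to the lower-index bin.  With ``b = 1``
    this reduces to the plain per-edge masses.
    """
    if b < 1:
        raise ValueError(f"bins per edge must be >= 1, got {b}")
    tree = sample.tree
    lens = tree.branch_lengths
    bins = np.zeros((tree.num_edges, b))
    for q in sample.pqueries:
        for p in q.placements:
            col = tree.edge_column(p.edge_num)
            length = lens[col]
            if length <= 0:
                i = 0
            else:
                # nearest center; exact midpoint ties resolve downward
                i = int(np.ceil(p.proximal_length * b / length - 1.0))
                i = min(max(i, 0), b - 1)
            bins[col, i] += q.multiplicity * p.like_weight_ratio
    centers = (np.arange(b) + 0.5)[None, :] * (lens / b)[:, None]
    out = BinnedMassVector(tree=tree, bins=bins, centers=centers, name=sample.name)
    if normalized:
        total = out.total()
        if total <= 0:
            raise ValueError("cannot normalize an all-zero sample")
        out.bins = out.bins / total
        out.normalized = True
    return out


def squash(
    mass_vectors: list[MassVector],
    weights=None,
    renormalize: bool = False,
) -> MassVector:
    """Weighted per-edge average of several mass vectors on one tree.

    Squashing summarizes a set of samples (or a cluster) by the average
    of their mass distributions; with ``renormalize`` the result is
    rescaled to unit mass.
    """
    if not mass_vectors:
        raise ValueError("need at least one mass vector to squash")
    tree = mass_vectors[0].tree
    for mv in mass_vectors[1:]:
        if not tree.same_topology_as(mv.tree):
            raise ValueError("cannot squash mass vectors on different trees")
    if weights is None:
        weights = np.ones(len(mass_vectors))
    w = np.asarray(weights, dtype=float)
    if w.shape != (len(mass_vectors),) or np.any(w < 0) or w.sum() == 0:
        raise ValueError("weights must be non-negative and not all zero")
    stacked = np.stack([mv.values for mv in mass_vectors])
    avg = (w[:, None] * stacked).sum(axis=0) / w.sum()
    out = MassVector(tree=tree, values=avg, normalized=False)
    if renormalize:
        out = normalize(out)
    else:
        out.normalized = all(mv.normalized for mv in mass_vectors)
    return out


def edge_imbalances(
    mass_vector: MassVector, include_tips: bool = False
) -> ImbalanceVector:
    """Root-side mass minus non-root-side mass for every edge.

    The edge's own mass is excluded from both sides.  Computed in a
    single children-before-parents pass: with ``S_e`` the mass strictly
    below edge ``e`` and ``M`` the total, the imbalance is
    ``(M - S_e - c_e) - S_e``.  Tip edges carry no clade information
    (their imbalance is just total mass minus own mass) and are masked
    with ``NaN`` unless requested.
    """
    tree = mass_vector.tree
    c = mass_vector.values
    total = c.sum()
    node_sub = np.zeros(tree.num_nodes)
    for v in tree.postorder_nodes():
        for w in tree.children[v]:
            node_sub[v] += node_sub[w] + c[tree.edge_column(int(tree.node_edge_num[w]))]
    imb = np.empty(tree.num_edges)
    for col in range(tree.num_edges):
        sub = node_sub[tree.edge_child_node(col)]
        imb[col] = total - 2.0 * sub - c[col]
    if not include_tips:
        imb = imb.copy()
        imb[tree.tip_edge_mask] = np.nan
    return ImbalanceVector(
        tree=tree, values=imb, include_tips=include_tips, name=mass_vector.name
    )


def build_matrix(
    samples: list[Sample],
    content: str = "masses",
    normalized: bool = True,
    include_tips: bool | None = None,
) -> MassMatrix:
    """Stack per-sample edge vectors into an ``n x m`` matrix.

    ``content="masses"`` stacks (optionally normalized) edge masses;
    ``content="imbalances"`` stacks imbalances of the (optionally
    normalized) masses.  For imbalances, tips default to excluded-as-NaN
    columns, matching their lack of clade information.
    """
    if content not in ("masses", "imbalances"):
        raise ValueError(f"unknown matrix content {content!r}")
    if not samples:
        raise ValueError("need at least one sample")
    tree = samples[0].tree
    for s in samples[1:]:
        if not tree.same_topology_as(s.tree):
            raise ValueError("samples must share one reference tree")
    rows = []
    for s in samples:
        mv = edge_masses(s)
        if normalized:
            mv = normalize(mv)
        if content == "masses":
            rows.append(mv.values)
        else:
            tips = False if include_tips is None else include_tips
            rows.append(edge_imbalances(mv, include_tips=tips).values)
    return MassMatrix(
        tree=tree,
        values=np.stack(rows),
        sample_names=[s.name for s in samples],
        edge_nums=tree.edge_order.copy(),
        content=content,
    )
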