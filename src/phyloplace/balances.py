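"""Placement adaptation of the phylogenetic ILR transform (balances).

A *balance* contrasts the placement mass in two disjoint sets of tree
edges R and S as a scaled log-ratio of (weighted) geometric means,

    y*(R, S) = sqrt(nu_R * nu_S / (nu_R + nu_S))
               * ln( gm(y_R, p_R) / gm(y_S, p_S) ),

where ``p`` is a per-edge weight vector (all ones = the plain ILR
transform, in which case nu_R and nu_S are the set cardinalities and
gm is the unweighted geometric mean), ``y = x / p`` is the weighted
("shifted") composition of the sample's relative edge masses ``x``, and
nu_R, nu_S are the weight sums over R and S.  The scaling term makes
the implicit ILR basis elements unit length.

Edge weights down-weigh edges with little placement mass.  The default
combines the geometric mean of the absolute masses per edge across
samples (with +1 pseudo-counts) and the Euclidean norm of the relative
masses:  p_j = (prod_i (c_ji + 1))^(1/n) * sqrt(sum_i x_ji^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import Sample
from .masses import MassMatrix, MassVector, edge_masses
from .tree import ReferenceTree

__all__ = [
    "EdgeWeights",
    "BalanceInput",
    "Balance",
    "compute_edge_weights",
    "weighted_geometric_mean",
    "shifted_composition",
    "balance",
    "per_edge_balances",
]

WEIGHT_FLOOR = 1e-12
DEFAULT_PSEUDO_FRACTION = 0.65


@dataclass
class EdgeWeights:
    """Per-edge ILR weights ``p`` (canonical column order), all > 0."""

    tree: ReferenceTree
    values: np.ndarray
    tendency: str = "geometric"
    norm: str = "euclidean"

    @classmethod
    def unit(cls, tree: ReferenceTree) -> "EdgeWeights":
        """No weighting: p = (1, ..., 1)."""
        return cls(tree=tree, values=np.ones(tree.num_edges), tendency="none", norm="none")


@dataclass
class BalanceInput:
    """Relative masses ``x`` and shifted composition ``y = x / p`` of one sample."""

    tree: ReferenceTree
    x: np.ndarray
    y: np.ndarray
    pseudo_mass: float


@dataclass
class Balance:
    value: float
    R: np.ndarray  # canonical columns
    S: np.ndarray
    nu_R: float
    nu_S: float


def _tendency(c_col: np.ndarray, how: str) -> float:
    if how == "geometric":
        # +1 pseudo-counts keep edges without placement mass from
        # collapsing the product
        return float(np.exp(np.mean(np.log(c_col + 1.0))))
    if how == "arithmetic":
        return float(np.mean(c_col))
    if how == "median":
        return float(np.median(c_col))
    raise ValueError(f"unknown central tendency {how!r}")


def _norm(x_col: np.ndarray, how: str) -> float:
    if how == "euclidean":
        return float(np.sqrt(np.sum(x_col**2)))
    if how == "manhattan":
        return float(np.sum(np.abs(x_col)))
    if how == "maximum":
        return float(np.max(np.abs(x_col)))
    if how == "aitchison":
        if np.any(x_col <= 0):
            raise ValueError("Aitchison norm requires strictly positive values")
        n = len(x_col)
        lx = np.log(x_col)
        diff = lx[:, None] - lx[None, :]
        return float(np.sqrt(np.sum(diff**2) / (2.0 * n)))
    raise ValueError(f"unknown norm {how!r}")


def compute_edge_weights(
    matrix_absolute: MassMatrix,
    matrix_relative: MassMatrix | None = None,
    tendency: str = "geometric",
    norm: str = "euclidean",
) -> EdgeWeights:
    """Per-edge weights from the columns of the edge-mass matrices.

    Each edge's weight is the product of a central tendency of its
    absolute masses across samples and a vector norm of its relative
    masses.  All-zero edges, whose norm vanishes, are floored at a tiny
    positive value so the shifted composition stays finite.
    """
    C = matrix_absolute.values
    if matrix_relative is None:
        X = C / C.sum(axis=1, keepdims=True)
    else:
        X = matrix_relative.values
    if C.shape != X.shape:
        raise ValueError("absolute and relative matrices must have the same shape")
    m = C.shape[1]
    p = np.empty(m)
    for j in range(m):
        p[j] = _tendency(C[:, j], tendency) * _norm(X[:, j], norm)
    p = np.maximum(p, WEIGHT_FLOOR)
    return EdgeWeights(tree=matrix_absolute.tree, values=p, tendency=tendency, norm=norm)


def weighted_geometric_mean(y, p) -> float:
    """``exp( sum p_r log y_r / sum p_r )``; unweighted when p is constant."""
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    if y.size == 0:
        raise ValueError("geometric mean of an empty set")
    if np.any(y <= 0):
        raise ValueError("geometric mean requires strictly positive values")
    if np.any(p <= 0):
        raise ValueError("weights must be strictly positive")
    return float(np.exp(np.sum(p * np.log(y)) / np.sum(p)))


def shifted_composition(
    c,
    weights: EdgeWeights,
    pseudo_fraction: float = DEFAULT_PSEUDO_FRACTION,
) -> BalanceInput:
    """Turn absolute edge masses into the shifted composition ``y = x / p``.

    Zero masses are replaced by a pseudo-mass (``pseudo_fraction`` times
    the smallest nonzero relative mass) before re-closure, so that every
    log in the geometric means is defined.
    """
    if isinstance(c, MassVector):
        tree, cv = c.tree, c.values
    else:
        tree, cv = weights.tree, np.asarray(c, dtype=float)
    total = cv.sum()
    if total <= 0:
        raise ValueError("sample has no placement mass")
    x = cv / total
    nz = x[x > 0]
    eps = pseudo_fraction * nz.min()
    x = np.where(x > 0, x, eps)
    x = x / x.sum()
    y = x / weights.values
    return BalanceInput(tree=tree, x=x, y=y, pseudo_mass=float(eps))


def balance(
    R,
    S,
    balance_input: BalanceInput,
    edge_weights: EdgeWeights,
) -> Balance:
    """Scaled log-ratio contrast between edge sets R and S.

    R and S are disjoint sets of canonical edge columns; swapping them
    flips the sign.  With unit weights this is the plain ILR balance.
    """
    R = np.asarray(sorted(R), dtype=np.intp)
    S = np.asarray(sorted(S), dtype=np.intp)
    if R.size == 0 or S.size == 0:
        raise ValueError("balance needs non-empty edge sets R and S")
    if np.intersect1d(R, S).size:
        raise ValueError("edge sets R and S must be disjoint")
    p = edge_weights.values
    y = balance_input.y
    nu_R = float(p[R].sum())
    nu_S = float(p[S].sum())
    scale = np.sqrt(nu_R * nu_S / (nu_R + nu_S))
    val = scale * np.log(
        weighted_geometric_mean(y[R], p[R]) / weighted_geometric_mean(y[S], p[S])
    )
    return Balance(value=float(val), R=R, S=S, nu_R=nu_R, nu_S=nu_S)


def per_edge_balances(
    samples: list[Sample],
    edge_weights: EdgeWeights | None = None,
    include_tips: bool = False,
    pseudo_fraction: float = DEFAULT_PSEUDO_FRACTION,
) -> MassMatrix:
    """Balance between the two subtrees induced by every edge, per sample.

    The root side of each edge is R and the non-root side is S (the
    edge's own column belongs to neither), matching the sign convention
    of edge imbalances.  Tip edges have an empty S and are NaN unless
    ``include_tips``  (where they stay NaN regardless, as no balance
    exists).  The resulting ``n x m`` matrix is the balance counterpart
    of the imbalance matrix.
    """
    if not samples:
        raise ValueError("need at least one sample")
    tree = samples[0].tree
    if edge_weights is None:
        edge_weights = EdgeWeights.unit(tree)
    all_cols = np.arange(tree.num_edges, dtype=np.intp)
    tip_mask = tree.tip_edge_mask
    rows = []
    for s in samples:
        bi = shifted_composition(edge_masses(s), edge_weights, pseudo_fraction)
        row = np.full(tree.num_edges, np.nan)
        for col in range(tree.num_edges):
            if tip_mask[col]:
                continue
            S = tree.subtree_edge_columns(int(tree.edge_order[col]))
            if S.size == 0:
                continue
            R = np.setdiff1d(all_cols, np.append(S, col))
            if R.size == 0:
                continue
            row[col] = balance(R, S, bi, edge_weights).value
        rows.append(row)
    return MassMatrix(
        tree=tree,
        values=np.stack(rows),
        sample_names=[s.name for s in samples],
        edge_nums=tree.edge_order.copy(),
        content="balances",
    )
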