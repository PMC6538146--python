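"""Per-edge summary statistics over sample-by-edge matrices.

Edge Dispersion summarizes how variable each edge's mass (or imbalance)
is across samples; Edge Correlation relates each edge to a numeric
per-sample metadata feature; Edge PCA is a principal component analysis
of the column-centered imbalance matrix whose loadings map back onto
tree edges.  All three produce per-edge scalars that can be painted
onto the reference tree (see :mod:`phyloplace.render`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .masses import MassMatrix
from .tree import ReferenceTree

__all__ = ["EdgeValues", "edge_dispersion", "edge_correlation", "edge_pca", "EdgePcaResult"]


@dataclass
class EdgeValues:
    """Per-edge scalar values; ``NaN`` marks edges where the value is undefined."""

    tree: ReferenceTree
    values: np.ndarray
    kind: str = ""
    scale: str = "linear"  # display hint only; stored values are never transformed

    def defined_mask(self) -> np.ndarray:
        return ~np.isnan(self.values)

    def __getitem__(self, edge_num: int) -> float:
        return float(self.values[self.tree.edge_column(edge_num)])

    def display_values(self) -> np.ndarray:
        """Values on the display scale (log10 with a small offset if requested)."""
        if self.scale != "log":
            return self.values
        v = self.values
        pos = v[np.isfinite(v) & (v > 0)]
        eps = pos.min() / 10.0 if pos.size else 1.0
        out = np.full_like(v, np.nan)
        ok = np.isfinite(v)
        out[ok] = np.log10(v[ok] + eps)
        return out


def _matrix_values(matrix) -> tuple[ReferenceTree, np.ndarray]:
    if isinstance(matrix, MassMatrix):
        return matrix.tree, matrix.values
    raise TypeError("expected a MassMatrix")


def edge_dispersion(
    matrix: MassMatrix,
    measure: str = "sd",
    log_scale: bool = False,
) -> EdgeValues:
    """Per-column dispersion of a sample-by-edge matrix.

    ``measure`` is one of ``sd``, ``variance`` (both with the n-1
    denominator) or ``index_of_dispersion`` (variance-mean ratio
    sigma^2/mu, which also surfaces heterogeneity on low-mass edges but
    is undefined for zero-mean columns).
    """
    tree, X = _matrix_values(matrix)
    if X.shape[0] < 2:
        raise ValueError("dispersion needs at least two samples")
    var = np.nanvar(X, axis=0, ddof=1)
    if measure == "variance":
        vals = var
    elif measure == "sd":
        vals = np.sqrt(var)
    elif measure == "index_of_dispersion":
        mean = np.nanmean(X, axis=0)
        vals = np.where(mean != 0, var / np.where(mean != 0, mean, 1.0), np.nan)
    else:
        raise ValueError(f"unknown dispersion measure {measure!r}")
    vals = np.where(np.isnan(X).any(axis=0), np.nan, vals)
    return EdgeValues(
        tree=tree,
        values=vals,
        kind=f"dispersion:{measure}",
        scale="log" if log_scale else "linear",
    )


def edge_correlation(
    matrix: MassMatrix,
    feature,
    method: str = "pearson",
    min_pairs: int = 3,
) -> EdgeValues:
    """Correlation of each edge column with a numeric metadata feature.

    Rows with a missing feature value are dropped pairwise.  Columns
    that are constant over the complete pairs (or have fewer than
    ``min_pairs`` of them) are marked undefined rather than emitting
    NaN-producing divisions.
    """
    tree, X = _matrix_values(matrix)
    f = np.asarray(pd.to_numeric(pd.Series(feature)), dtype=float)
    if f.shape[0] != X.shape[0]:
        raise ValueError("feature length does not match the number of samples")
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    vals = np.full(X.shape[1], np.nan)
    for j in range(X.shape[1]):
        ok = ~np.isnan(X[:, j]) & ~np.isnan(f)
        x, y = X[ok, j], f[ok]
        if ok.sum() < min_pairs or np.all(x == x[0]) or np.all(y == y[0]):
            continue
        if method == "pearson":
            vals[j] = stats.pearsonr(x, y).statistic
        else:
            vals[j] = stats.spearmanr(x, y).statistic
    return EdgeValues(tree=tree, values=vals, kind=f"correlation:{method}")


@dataclass
class EdgePcaResult:
    tree: ReferenceTree
    loadings: list[EdgeValues]  # one per component, mapped back to edges
    scores: np.ndarray  # n x components
    explained_variance_ratio: np.ndarray
    components: np.ndarray  # components x used-edges, on the reduced columns
    edge_nums: np.ndarray  # edge numbers of the columns used


def edge_pca(matrix: MassMatrix, components: int = 2, standardize: bool = False) -> EdgePcaResult:
    """PCA of the column-centered imbalance matrix (Edge PCA).

    Tip-edge columns (NaN) are excluded; loadings are unit-norm per
    component and mapped back to the remaining edges.  Columns are
    centered, not standardized, unless ``standardize`` is set.
    """
    from sklearn.decomposition import PCA

    tree, X = _matrix_values(matrix)
    keep = ~np.isnan(X).any(axis=0)
    Xr = X[:, keep]
    max_comp = min(X.shape[0] - 1, Xr.shape[1])
    if components > max_comp:
        raise ValueError(
            f"cannot extract {components} components from a {X.shape[0]} x "
            f"{Xr.shape[1]} matrix (max {max_comp})"
        )
    if standardize:
        sd = Xr.std(axis=0, ddof=1)
        Xr = (Xr - Xr.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    pca = PCA(n_components=components, svd_solver="full")
    scores = pca.fit_transform(Xr)
    edge_nums = np.asarray(
        [int(e) for e, k in zip(matrix.edge_nums, keep) if k], dtype=np.intp
    )
    loadings = []
    for c in range(components):
        full = np.full(X.shape[1], np.nan)
        full[keep] = pca.components_[c]
        loadings.append(EdgeValues(tree=tree, values=full, kind=f"pca:{c + 1}"))
    return EdgePcaResult(
        tree=tree,
        loadings=loadings,
        scores=scores,
        explained_variance_ratio=pca.explained_variance_ratio_,
        components=pca.components_,
        edge_nums=edge_nums,
    )
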