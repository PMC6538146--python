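"""Placement-Factorization: greedy phylofactorization of placement data.

The algorithm iteratively identifies *winning edges* of the reference
tree whose induced split best explains variation related to per-sample
metadata.  In each iteration, for every candidate edge ``e`` inside its
current subtree, the placement masses on the two sides of ``e`` are
aggregated and contrasted as an ILR balance (see
:mod:`phyloplace.balances`), and an objective

    omega_e = null deviance - residual deviance

of a GLM predicting the per-sample balances from the metadata is
evaluated; the edge maximizing omega wins and splits its subtree in
two.  After ``i`` iterations the tree edges are partitioned into
``i + 1`` disjoint subtrees, and later factors never contrast masses
across earlier winning edges, keeping the factors orthogonal.

Edges that lead to a tip separate off an empty edge set and are
therefore never candidates, mirroring the edge-imbalance convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .balances import (
    DEFAULT_PSEUDO_FRACTION,
    EdgeWeights,
    balance,
    compute_edge_weights,
    shifted_composition,
)
from .io import Sample
from .masses import build_matrix, edge_masses
from .metrics import EdgeValues
from .render import ColorMap, render_tree

__all__ = [
    "FactorConfig",
    "Factor",
    "FactorResult",
    "glm_objective",
    "placement_factorization",
    "factor_ordination",
    "grouped_ordination",
    "objective_map",
]


@dataclass
class FactorConfig:
    iterations: int = 1
    family: str = "gaussian"
    taxon_weights: bool = True  # mass-based edge weights vs. p = (1, ..., 1)
    tendency: str = "geometric"
    norm: str = "euclidean"
    pseudo_fraction: float = DEFAULT_PSEUDO_FRACTION
    # reverse mode: predict a metadata column from the contrasts instead
    reverse: bool = False
    response_column: str | None = None

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("need at least one iteration")


@dataclass
class Factor:
    iteration: int
    edge_num: int
    R: np.ndarray  # canonical columns on the root side, within the subtree
    S: np.ndarray  # canonical columns on the non-root side, within the subtree
    objective_values: dict  # edge_num -> omega for every candidate this iteration
    contrasts: np.ndarray  # per-sample balances at the winning edge
    deviance: float
    null_deviance: float
    coefficients: pd.Series


@dataclass
class FactorResult:
    factors: list[Factor]
    subtrees: list[np.ndarray]  # final partition of the tree's edge columns
    sample_names: list[str]
    edge_weights: EdgeWeights
    tree: object


def _design_matrix(metadata: pd.DataFrame) -> pd.DataFrame:
    """Dummy-code categoricals, add an intercept, drop collinear columns."""
    num = metadata.select_dtypes(include=[np.number])
    cat = metadata.select_dtypes(exclude=[np.number])
    parts = [num.astype(float)]
    if not cat.empty:
        parts.append(pd.get_dummies(cat.astype(str), drop_first=True, dtype=float))
    X = pd.concat(parts, axis=1)
    X.insert(0, "const", 1.0)
    keep: list[str] = []
    rank = 0
    for c in X.columns:
        r = np.linalg.matrix_rank(X[keep + [c]].to_numpy(dtype=float))
        if r > rank:
            keep.append(c)
            rank = r
    dropped = [c for c in X.columns if c not in keep]
    if dropped:
        warnings.warn(f"dropping collinear design columns: {dropped}")
    return X[keep]


_FAMILIES = {
    "gaussian": sm.families.Gaussian,
    "binomial": sm.families.Binomial,
    "poisson": sm.families.Poisson,
}


class _ConstantFit:
    """Stand-in fit object for a zero-variance response."""

    def __init__(self, value: float, n_params: int):
        self.deviance = 0.0
        self.null_deviance = 0.0
        self.params = np.zeros(n_params)
        self.params[0] = value


def _fit_glm(y: np.ndarray, X: np.ndarray, family: str):
    fam = _FAMILIES[family]()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sm.GLM(y, X, family=fam).fit()


def glm_objective(
    contrasts,
    metadata: pd.DataFrame | None = None,
    family: str = "gaussian",
    design: pd.DataFrame | None = None,
):
    """Deviance reduction of a GLM predicting contrasts from metadata.

    Returns ``(omega, fitted)`` where ``omega = null deviance - residual
    deviance >= 0``; for the gaussian family this is TSS - RSS of the
    linear fit.  Returns ``(None, None)`` when there are fewer complete
    cases than model parameters plus one, in which case the caller
    skips the edge.
    """
    y = np.asarray(contrasts, dtype=float)
    if design is None:
        if metadata is None:
            raise ValueError("need metadata or a prebuilt design matrix")
        design = _design_matrix(metadata)
    ok = ~np.isnan(y) & ~design.isna().any(axis=1).to_numpy()
    if ok.sum() < design.shape[1] + 1:
        return None, None
    if np.ptp(y[ok]) == 0.0:
        # constant response: no variance to explain, omega is exactly 0
        return 0.0, _ConstantFit(y[ok][0], design.shape[1])
    res = _fit_glm(y[ok], design.loc[ok].to_numpy(dtype=float), family)
    return float(res.null_deviance - res.deviance), res


def placement_factorization(
    samples: list[Sample],
    metadata: pd.DataFrame,
    config: FactorConfig | None = None,
) -> FactorResult:
    """Run the greedy winning-edge algorithm for a fixed number of iterations.

    Ties in the objective are broken toward the lowest edge number, so
    the result is deterministic for a given input order.
    """
    if config is None:
        config = FactorConfig()
    if not samples:
        raise ValueError("need samples")
    tree = samples[0].tree
    if len(metadata) != len(samples):
        raise ValueError("metadata rows must match samples 1:1")

    # Edge weights are computed once on the full dataset and then fixed
    # across the balance computations of all samples and iterations.
    if config.taxon_weights:
        abs_matrix = build_matrix(samples, content="masses", normalized=False)
        weights = compute_edge_weights(
            abs_matrix, tendency=config.tendency, norm=config.norm
        )
    else:
        weights = EdgeWeights.unit(tree)
    balance_inputs = [
        shifted_composition(edge_masses(s), weights, config.pseudo_fraction)
        for s in samples
    ]

    if config.reverse:
        if config.response_column is None:
            raise ValueError("reverse mode needs a response_column")
        resp = metadata[config.response_column]
        if resp.dtype == object or str(resp.dtype) == "category":
            resp = pd.Series(pd.factorize(resp)[0], index=resp.index)
        response = resp.to_numpy(dtype=float)
        design = None
    else:
        design = _design_matrix(metadata)

    subtree_cols = {
        col: set(int(c) for c in tree.subtree_edge_columns(int(tree.edge_order[col])))
        for col in range(tree.num_edges)
    }
    # Each group is the full column set of one current subtree (inner and
    # tip edges alike); winning edges leave the partition entirely.
    groups: list[set[int]] = [set(range(tree.num_edges))]

    factors: list[Factor] = []
    for it in range(1, config.iterations + 1):
        best = None  # (sort key, edge_num, group index, R, S, contrasts, fit)
        omega_map: dict[int, float] = {}
        for gi, group in enumerate(groups):
            for col in sorted(group):
                S = np.asarray(sorted(subtree_cols[col] & group), dtype=np.intp)
                R = np.asarray(sorted(group - subtree_cols[col] - {col}), dtype=np.intp)
                if S.size == 0 or R.size == 0:
                    continue  # tip edges and degenerate splits
                contrasts = np.array(
                    [balance(R, S, bi, weights).value for bi in balance_inputs]
                )
                if config.reverse:
                    X = pd.DataFrame({"const": 1.0, "contrast": contrasts})
                    omega, res = glm_objective(
                        response, family=config.family, design=X
                    )
                else:
                    omega, res = glm_objective(
                        contrasts, family=config.family, design=design
                    )
                if omega is None:
                    continue
                edge_num = int(tree.edge_order[col])
                omega_map[edge_num] = omega
                key = (-omega, edge_num)
                if best is None or key < best[0]:
                    best = (key, edge_num, gi, col, R, S, contrasts, res)
        if best is None:
            warnings.warn(f"no candidate edges remain; stopping after {it - 1} factors")
            break
        _, edge_num, gi, col, R, S, contrasts, res = best
        group = groups[gi]
        S_group = subtree_cols[col] & group
        R_group = group - S_group - {col}
        groups[gi : gi + 1] = [g for g in (R_group, S_group) if g]
        factors.append(
            Factor(
                iteration=it,
                edge_num=edge_num,
                R=R,
                S=S,
                objective_values=omega_map,
                contrasts=contrasts,
                deviance=float(res.deviance),
                null_deviance=float(res.null_deviance),
                coefficients=pd.Series(res.params),
            )
        )

    return FactorResult(
        factors=factors,
        subtrees=[np.asarray(sorted(g), dtype=np.intp) for g in groups],
        sample_names=[s.name for s in samples],
        edge_weights=weights,
        tree=tree,
    )


def factor_ordination(result: FactorResult, scale: bool = False) -> pd.DataFrame:
    """Per-sample balances at each winning edge, as an ordination table.

    With ``scale`` each factor column is min-max scaled into [-1, 1]
    while keeping 0 fixed (positive values divided by the column
    maximum, negative by the absolute minimum).
    """
    if not result.factors:
        raise ValueError("factorization produced no factors")
    data = {}
    for f in result.factors:
        col = f.contrasts.astype(float).copy()
        if scale:
            pos, neg = col[col > 0], col[col < 0]
            if pos.size:
                col[col > 0] = col[col > 0] / pos.max()
            if neg.size:
                col[col < 0] = col[col < 0] / abs(neg.min())
        data[f"factor_{f.iteration}"] = col
    return pd.DataFrame(data, index=result.sample_names)


def grouped_ordination(result: FactorResult, labels) -> pd.DataFrame:
    """Long-format table of factor balances per categorical label
    (the data behind per-factor violin/swarm plots)."""
    ord_df = factor_ordination(result)
    ord_df["label"] = list(labels)
    return ord_df.melt(id_vars="label", var_name="factor", value_name="balance")


def objective_map(
    result: FactorResult,
    iteration: int = 1,
    colormap: ColorMap | None = None,
    out_format: str = "csv",
    path=None,
):
    """Per-edge objective values of one iteration, rendered on the tree.

    Tip edges and edges already claimed by earlier factors are neutral;
    the winning edge carries the iteration's maximum value.
    """
    matching = [f for f in result.factors if f.iteration == iteration]
    if not matching:
        raise ValueError(f"no factor for iteration {iteration}")
    f = matching[0]
    tree = result.tree
    vals = np.full(tree.num_edges, np.nan)
    for e, w in f.objective_values.items():
        vals[tree.edge_column(e)] = w
    ev = EdgeValues(tree=tree, values=vals, kind="objective")
    return render_tree(tree, ev, colormap=colormap, out_format=out_format, path=path)
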