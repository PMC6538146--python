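"""Clustering of placement samples.

Two families of methods:

* **Squash Clustering** — agglomerative hierarchical clustering where a
  merged cluster is represented by the weighted average ("squash") of
  its members' mass distributions, and cluster distances are KR
  distances between those averages.  The result is a tree whose tips
  are samples and whose branch lengths are KR distances.

* **k-means** — Lloyd's algorithm with k-means++ initialization, in two
  variants: *phylogenetic* k-means uses the KR distance and mass
  averaging on the reference tree; *imbalance* k-means is plain
  Euclidean k-means on rows of the edge-imbalance matrix.  Both run
  through one generic Lloyd loop parameterized by a distance and an
  averaging function, so the empty-cluster repair and tie-break rules
  are identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import Sample
from .krdistance import MassPointsOnTree, kr_distance, squash_points
from .masses import MassMatrix, bin_masses

__all__ = [
    "ClusterResult",
    "SquashTree",
    "squash_clustering",
    "phylogenetic_kmeans",
    "imbalance_kmeans",
    "elbow_curve",
]


@dataclass
class ClusterResult:
    k: int
    assignments: np.ndarray
    centroids: list
    iterations: int
    variance: float  # average squared distance of samples to their centroid
    objective_trace: list  # within-cluster sum of squared distances per iteration


@dataclass
class SquashTree:
    newick: str
    sample_names: list[str]
    merges: list  # (i, j, dist, new_index) in scipy linkage-like indexing
    root_points: MassPointsOnTree


# ----------------------------------------------------------------------
# squash clustering


def squash_clustering(points: list[MassPointsOnTree], names: list[str] | None = None) -> SquashTree:
    """Agglomerative clustering by repeated squashing of mass distributions.

    At each step the two clusters at smallest KR distance are merged
    into their member-count-weighted average distribution.  The branch
    length from the merged node to each child is the KR distance between
    the child and the merged distribution (for a two-way merge of
    averages these two lengths sum to the distance between the
    children).  Ties are broken by lexicographic cluster index.
    """
    n = len(points)
    if n < 2:
        raise ValueError("squash clustering needs at least two samples")
    if names is None:
        names = [pt.name or f"S{i}" for i, pt in enumerate(points)]

    active: dict[int, MassPointsOnTree] = dict(enumerate(points))
    sizes: dict[int, int] = {i: 1 for i in range(n)}
    subtrees: dict[int, str] = {i: names[i] for i in range(n)}
    dist: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = kr_distance(points[i], points[j])

    merges = []
    next_id = n
    while len(active) > 1:
        best = min(dist, key=lambda ij: (dist[ij], ij))
        i, j = best
        merged = squash_points([active[i], active[j]], weights=[sizes[i], sizes[j]])
        bi = float(kr_distance(active[i], merged))
        bj = float(kr_distance(active[j], merged))
        subtrees[next_id] = f"({subtrees[i]}:{bi!r},{subtrees[j]}:{bj!r})"
        merges.append((i, j, dist[best], next_id))
        for k in (i, j):
            del active[k]
        for key in [ij for ij in dist if i in ij or j in ij]:
            del dist[key]
        for k in active:
            a, b = min(k, next_id), max(k, next_id)
            dist[(a, b)] = kr_distance(active[k], merged)
        active[next_id] = merged
        sizes[next_id] = sizes[i] + sizes[j]
        next_id += 1

    root = next(iter(active))
    return SquashTree(
        newick=subtrees[root] + ";",
        sample_names=list(names),
        merges=merges,
        root_points=active[root],
    )


# ----------------------------------------------------------------------
# generic Lloyd k-means


def _kmeans_pp_init(items, k, distance, rng):
    """k-means++ seeding: each next center is drawn with probability
    proportional to the squared distance to the nearest chosen center."""
    n = len(items)
    chosen = [int(rng.integers(n))]
    d2 = np.array([distance(items[i], items[chosen[0]]) ** 2 for i in range(n)])
    while len(chosen) < k:
        total = d2.sum()
        if total <= 0:
            # all remaining items coincide with a center; pick any unchosen
            remaining = [i for i in range(n) if i not in chosen]
            chosen.append(int(remaining[0]))
        else:
            r = rng.random() * total
            idx = int(np.searchsorted(np.cumsum(d2), r, side="right"))
            idx = min(idx, n - 1)
            chosen.append(idx)
        d2 = np.minimum(
            d2, np.array([distance(items[i], items[chosen[-1]]) ** 2 for i in range(n)])
        )
    return chosen


def _lloyd(items, k, distance, average, seed, max_iter, init="kmeans++"):
    n = len(items)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k = {k} exceeds the number of samples ({n})")
    rng = np.random.default_rng(seed)
    if init == "kmeans++":
        centers_idx = _kmeans_pp_init(items, k, distance, rng)
    elif init == "random":
        centers_idx = list(rng.choice(n, size=k, replace=False))
    else:
        raise ValueError(f"unknown init {init!r}")
    centroids = [items[i] for i in centers_idx]

    assignments = np.full(n, -1)
    trace = []
    iterations = 0
    for iterations in range(1, max_iter + 1):
        d = np.array([[distance(items[i], c) for c in centroids] for i in range(n)])
        new_assign = d.argmin(axis=1)

        # Empty-cluster repair: move the sample furthest from its centroid
        # out of the highest-variance cluster, once per empty cluster.
        for empty in [c for c in range(k) if not np.any(new_assign == c)]:
            variances = np.full(k, -1.0)
            for c in range(k):
                members = np.where(new_assign == c)[0]
                if len(members) > 1:
                    variances[c] = np.mean(d[members, c] ** 2)
            donor = int(variances.argmax())
            members = np.where(new_assign == donor)[0]
            far = members[int(d[members, donor].argmax())]
            new_assign[far] = empty

        trace.append(float(np.sum(d[np.arange(n), new_assign] ** 2)))
        if np.array_equal(new_assign, assignments):
            break
        assignments = new_assign
        centroids = [
            average([items[i] for i in np.where(assignments == c)[0]])
            for c in range(k)
        ]

    d_final = np.array(
        [distance(items[i], centroids[assignments[i]]) for i in range(n)]
    )
    return ClusterResult(
        k=k,
        assignments=assignments,
        centroids=centroids,
        iterations=iterations,
        variance=float(np.mean(d_final**2)),
        objective_trace=trace,
    )


# ----------------------------------------------------------------------
# variants


def phylogenetic_kmeans(
    samples: list[Sample],
    k: int,
    seed: int = 0,
    max_iter: int = 100,
    bins: int | None = None,
    init: str = "kmeans++",
) -> ClusterResult:
    """Lloyd k-means with the KR distance and mass-average centroids.

    Samples are normalized to unit mass.  With ``bins`` set, each
    sample's mass points are first accumulated into ``bins`` bins per
    edge, which shrinks the point sets without noticeably changing the
    distances.
    """
    if bins is not None:
        items = [
            MassPointsOnTree.from_binned(bin_masses(s, bins), normalized=True)
            for s in samples
        ]
    else:
        items = [MassPointsOnTree.from_sample(s, normalized=True) for s in samples]
    return _lloyd(
        items,
        k,
        distance=kr_distance,
        average=lambda members: squash_points(members),
        seed=seed,
        max_iter=max_iter,
        init=init,
    )


def imbalance_kmeans(
    matrix: MassMatrix | np.ndarray,
    k: int,
    seed: int = 0,
    max_iter: int = 100,
    init: str = "kmeans++",
) -> ClusterResult:
    """Euclidean Lloyd k-means on rows of the edge-imbalance matrix."""
    values = matrix.values if isinstance(matrix, MassMatrix) else np.asarray(matrix, float)
    values = values[:, ~np.isnan(values).any(axis=0)]  # drop masked tip columns
    items = [values[i] for i in range(values.shape[0])]
    return _lloyd(
        items,
        k,
        distance=lambda a, b: float(np.linalg.norm(a - b)),
        average=lambda members: np.mean(np.stack(members), axis=0),
        seed=seed,
        max_iter=max_iter,
        init=init,
    )


def elbow_curve(
    data,
    k_range,
    variant: str = "phylogenetic",
    seed: int = 0,
    restarts: int = 1,
    **kwargs,
) -> list[tuple[int, float]]:
    """Average squared distance to the assigned centroid for each k.

    With ``restarts > 1`` each k keeps the lowest variance over seeds
    ``seed .. seed + restarts - 1``, damping initialization noise.
    """
    run = phylogenetic_kmeans if variant == "phylogenetic" else imbalance_kmeans
    out = []
    for k in k_range:
        best = min(
            run(data, k, seed=seed + r, **kwargs).variance for r in range(restarts)
        )
        out.append((int(k), float(best)))
    return out
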