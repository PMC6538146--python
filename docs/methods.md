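# Methods

This note documents the models and procedures implemented in
`phyloplace`, the defaults that matter, the numerical conventions, and
what the synthetic fixtures do and do not establish.

## Data model

A placement study is a set of samples on one fixed, edge-numbered,
strictly bifurcating reference tree (an unrooted input keeps its
top-level trifurcation as the "root" junction). Each sample holds
pqueries — placed query sequences with a multiplicity (default 1) and a
list of placements, each with an edge number, a likelihood weight ratio
(LWR), and a position on the edge (`proximal_length`, measured from the
root-side node). `pendant_length` is read and preserved but never used:
all mass lives on reference-tree edges.

jplace dialects are absorbed on input: edge numbers in `{N}` or `[N]`
style (decided by first match), fields mapped by name, `n`/`nm` name
conventions, `distal_length` converted to `proximal = length − distal`,
and a `likelihood`-only column converted to LWRs with a stable softmax.
Pqueries whose LWRs sum to less than 1 are kept as-is — discarded
unlikely placements are meaningful mass loss — and are never
renormalized implicitly. Positions outside `[0, branch_length]` are
clamped with a warning.

All per-edge vectors and matrix columns follow one canonical order: the
preorder traversal of edges from the root. This makes matrices
comparable across runs and is the tie-break space for deterministic
choices.

## Masses, imbalances, binning, squashing

The edge mass vector is `c[e] = Σ_q Σ_{p on e} multiplicity(q)·LWR(p)`;
its total equals the (multiplicity-weighted) number of fully placed
queries. Normalization divides by the total, giving relative abundances
`x` (compositional data; downstream methods that assume unconstrained
coordinates use the balances below instead). `normalize` is strictly
idempotent: an already-normalized vector is returned unchanged rather
than re-divided by a total that is 1 up to rounding.

Binning accumulates each placement into the nearest of `b` equal-width
bins per edge, centers at `(i + 0.5)·len/b`; an exact midpoint tie goes
to the lower-index bin. `b = 1` reproduces the plain edge masses
exactly. Zero-length branches degenerate to a single position.

Squashing is the weighted per-edge (and per-mass-point) average of
several samples; it is the cluster-merge and centroid operation of the
clustering methods.

The imbalance of edge `e` is root-side mass minus non-root-side mass,
excluding `e`'s own mass; with `S_e` the mass strictly below `e` and `M`
the total it is `M − 2·S_e − c_e`, computed in one children-first pass.
Root side is the positive sign. Tip edges carry no clade information
(their imbalance is just `M − c_e`) and are masked as NaN by default,
available via `include_tips`.

## KR distance

The order-1 Kantorovich–Rubinstein (earth mover) distance between two
unit-mass distributions on the tree is computed exactly: on a tree the
optimal transport across any infinitesimal segment equals the net
signed mass on one side, so the distance is the integral of
`|net mass below|` over the tree, evaluated segment-by-segment between
consecutive mass points within each edge during a single post-order
pass. Inputs must agree in total mass to `1e-6`. Mass points sit at
their proximal positions; pendant lengths are ignored. The exponent is
fixed at 1. The test suite cross-checks this pass against a
transportation linear program over the pairwise path-distance matrix of
the mass points (tolerance `1e-8`).

## Clustering

Squash Clustering repeatedly merges the two clusters at smallest KR
distance into their member-count-weighted average; ties broken by
lexicographic cluster index. Branch lengths of the resulting tree are
the KR distances from each child to the merged distribution (for a
two-way merge of equal-weight averages these sum exactly to the
children's distance).

Both k-means variants share one Lloyd loop: k-means++ initialization
(next center drawn with probability proportional to squared distance to
the nearest chosen center; a uniform-init option exists but tends to
give worse optima), assignment to the nearest centroid, centroid update
by averaging, stop on unchanged assignments or `max_iter = 100`.
Empty clusters are repaired by moving the sample furthest from its
centroid out of the highest-variance cluster, once per empty cluster;
ties go to the lowest index. Fixed seed implies bit-identical results.

The phylogenetic variant uses the KR distance and squash averaging; the
imbalance variant is plain Euclidean k-means on rows of the imbalance
matrix. A caveat worth stating: the within-cluster sum of squared
distances is provably non-increasing only for the Euclidean variant,
where the mean minimizes squared distance. The mass-average centroid is
not the exact minimizer of squared KR distance, so the phylogenetic
variant can in principle tick upward late in a run; in practice we
observe monotone traces on structured data at matched `k`, and a
sub-0.1% oscillation only at deliberately mismatched `k`. The elbow
diagnostic reports per-`k` variance (optionally the best of several
seeds).

## Balances and edge weights

The placement ILR balance between disjoint edge sets `R` and `S` is

    y*(R,S) = sqrt(ν_R ν_S / (ν_R + ν_S)) · ln( gm(y_R, p_R) / gm(y_S, p_S) )

with `ν` the weight sums over each set, `gm` the weighted geometric
mean `exp(Σ p·log y / Σ p)`, and `y = x/p` the weighted composition.
Natural log throughout (the choice is irrelevant up to scale for
correlations and PCA but fixes numeric values). With `p = (1,…,1)` all
terms reduce to the unweighted ILR: `ν` are set cardinalities and `gm`
the plain geometric mean.

Default edge weights multiply a central tendency of the absolute
masses per edge across samples (geometric mean with +1 pseudo-counts)
by a norm of the relative masses (Euclidean):
`p_j = (∏_i (c_ji + 1))^{1/n} · sqrt(Σ_i x_ji²)`. Median/arithmetic
tendencies and Manhattan/maximum/Aitchison norms are available.
All-zero edges get a weight floor of `1e-12` so `x/p` stays finite.

Zeros inside a sample's composition are handled by a documented
pseudo-mass: zero entries are replaced by `0.65 ×` the smallest nonzero
relative mass and the vector re-closed. This is a multiplicative-
replacement-style heuristic; it is configurable, and analyses of sparse
samples should be aware that very small observed masses make the
implied detection limit noisy.

Per-edge balances contrast the root side (R) against the non-root side
(S) of every inner edge, matching the imbalance sign convention; tip
edges have an empty S and are masked. Unweighted balances are
deliberately not recommended for correlation/k-means style analyses —
the geometric mean is insensitive to single high-mass branches, which
are usually the interesting ones; the mass-based weighting exists to
counter exactly that. Branch-length-based weighting is not implemented.

## Placement-Factorization

Greedy winning-edge phylofactorization on placement masses. Per
iteration, every edge that splits its current subtree into two
non-empty edge sets is a candidate (tip edges never are); its
per-sample contrast is the balance between the two sides, computed only
within the subtree — never across earlier winning edges, which keeps
the factors orthogonal. The objective is the GLM deviance reduction
`ω_e = null deviance − residual deviance ≥ 0` of predicting the
contrasts from all metadata columns simultaneously (gaussian/identity
by default, so `ω = TSS − RSS`; binomial and Poisson families, and a
reverse mode predicting a metadata column from the contrasts, are
available). Categorical features are dummy-coded; collinear design
columns are dropped with a warning; edges with fewer complete cases
than parameters are skipped; a constant contrast scores exactly 0.
Ties in `ω` break toward the lowest edge number. Edge weights are
computed once on the full dataset and held fixed across iterations and
samples. The run executes a fixed number of iterations, producing
`i` factors and `i+1` disjoint subtrees; a distribution-based stopping
rule is not implemented.

The factor ordination table collects the winning-edge balances per
sample; optional scaling maps each column into `[-1, 1]` by dividing
positives by the column maximum and negatives by the absolute minimum,
preserving 0.

## Synthetic data

The generator is the package's study-condition bench: random unrooted
bifurcating trees (exponential branch lengths, mean 0.1, preorder edge
numbering), samples of pqueries whose LWR is spread over 1–3
neighboring edges by a Dirichlet draw (exact unit sums), uniform
positions along edges, and metadata `feature = α·fraction + N(0, σ)`
per planted clade plus optional group labels. Within each region
(background or planted clade) the per-edge composition is itself a
per-sample Dirichlet draw — community composition varies between
samples, which is both realistic and necessary for path-level claims:
with a fixed uniform within-clade split, every interior clade edge
correlates with the planted fraction exactly as well as the stem does,
and "the strongest signal sits on the clade path" would be decided by
sampling noise.

Default study conditions used by the tests: planted-partition
clustering fixtures with 2×20 samples, 50 queries each, 80% of mass on
disjoint clades; factorization fixtures with 30 samples and 300 queries
each, clade fractions spanning 0.1–0.6 (nested variant: a dominant
outer effect at 0.3–0.7 and a weaker clade at 0.05–0.15 planted at
least two edges deeper). 300 queries per sample is modest relative to
real placement studies (thousands of reads); the deviance-based
objective needs enough queries that most clade edges receive nonzero
mass, otherwise pseudo-mass noise in the geometric means blurs the
distinction between a clade's stem and its interior edges.

What passing these fixtures does *not* show: robustness to reference
trees that miss the true provenance of queries (placement uncertainty
here is local Dirichlet spread, not model misspecification),
to abundance biases of amplification, or to the heavy-tailed abundance
distributions of real communities. All randomness flows through a
single seeded PCG64 stream per fixture.

## Numerical conventions

- Sample statistics use the `n−1` denominator everywhere; Spearman uses
  average ranks for ties.
- Log display scaling for tree maps is `log10(v + ε)` with `ε` = one
  tenth of the smallest positive value, applied at render time only.
- Correlation maps use a divergent palette pinned at 0; dispersion maps
  a sequential palette; undefined edges render neutral gray.
- Edge PCA centers columns without standardizing (a standardize flag
  exists); tip-edge columns are excluded.
- KR equal-mass tolerance `1e-6`; imbalance bound and conservation
  checks at `1e-9`–`1e-12` as asserted in the tests.

## Known limitations

- Squash clustering is O(n²) KR computations; for very large studies
  use branch binning (`b = 2` already leaves planted cluster
  assignments unchanged) or the imbalance k-means.
- The phylogenetic k-means objective is not guaranteed monotone (see
  above); results at strongly mismatched `k` should be read with the
  elbow curve.
- Balances require strictly positive compositions; the pseudo-mass
  default is a heuristic, and conclusions that hinge on near-zero
  edges deserve a sensitivity check over the pseudo-mass fraction.
- The SVG heat-tree is a simple rectangular layout meant for quick
  inspection, not publication typography.
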