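import numpy as np
import pytest

from phyloplace import (
    FixtureSpec,
    ReferenceTree,
    disjoint_clades,
    random_tree,
    simulate_samples,
)

# Small hand-built tree used across modules:
#
#        root
#       /    \
#   e2 /      \ e3 (C)
#     inner
#    /     \
# e0 (A)  e1 (B)
SMALL_NEWICK = "((A:0.2{0},B:0.4{1}):0.7{2},C:0.5{3});"


@pytest.fixture
def small_tree() -> ReferenceTree:
    return ReferenceTree.from_newick(SMALL_NEWICK)


@pytest.fixture
def medium_tree() -> ReferenceTree:
    return random_tree(16, seed=7)


@pytest.fixture
def random_samples(medium_tree):
    spec = FixtureSpec(n_samples=6, queries_per_sample=40, seed=11)
    samples, _ = simulate_samples(medium_tree, spec)
    return samples


def two_group_fixture(seed: int, n_per_group: int = 20, queries: int = 50):
    """Planted-partition fixture: two groups of samples whose mass is
    concentrated on two disjoint clades."""
    tree = random_tree(24, seed=100)
    clade_a, clade_b = disjoint_clades(tree, k=2, min_edges=5)
    n = 2 * n_per_group
    fractions = np.zeros((n, 2))
    fractions[:n_per_group, 0] = 0.8
    fractions[n_per_group:, 1] = 0.8
    labels = ["A"] * n_per_group + ["B"] * n_per_group
    spec = FixtureSpec(
        n_samples=n,
        queries_per_sample=queries,
        planted_clades=[clade_a, clade_b],
        clade_fractions=fractions,
        group_labels=labels,
        seed=seed,
    )
    samples, metadata = simulate_samples(tree, spec)
    truth = np.array([0] * n_per_group + [1] * n_per_group)
    return tree, samples, metadata, truth


@pytest.fixture
def planted_groups():
    return two_group_fixture(seed=5)
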