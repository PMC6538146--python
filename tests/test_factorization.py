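"""Placement-Factorization: GLM objective and the greedy winning-edge loop."""

import numpy as np
import pandas as pd
import pytest

import phyloplace as pp
from phyloplace import (
    FactorConfig,
    factor_ordination,
    glm_objective,
    objective_map,
    placement_factorization,
)


class TestGlmObjective:
    def meta(self, f):
        return pd.DataFrame({"f": np.asarray(f, float)})

    def test_perfect_linear_fit_reaches_null_deviance(self):
        f = np.linspace(0, 1, 12)
        contrasts = 3.0 * f - 1.0
        omega, res = glm_objective(contrasts, self.meta(f))
        assert res.deviance == pytest.approx(0.0, abs=1e-12)
        assert omega == pytest.approx(res.null_deviance)

    def test_constant_contrasts_zero_objective(self):
        f = np.linspace(0, 1, 10)
        omega, _ = glm_objective(np.full(10, 2.5), self.meta(f))
        assert omega == pytest.approx(0.0, abs=1e-12)

    def test_matches_least_squares_oracle(self):
        """Gaussian omega = TSS - RSS from the normal equations."""
        rng = np.random.default_rng(3)
        f = rng.normal(size=30)
        g = rng.normal(size=30)
        y = 0.7 * f - 0.2 * g + rng.normal(0, 0.5, 30)
        meta = pd.DataFrame({"f": f, "g": g})
        omega, _ = glm_objective(y, meta)
        X = np.column_stack([np.ones(30), f, g])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        rss = np.sum((y - X @ beta) ** 2)
        tss = np.sum((y - y.mean()) ** 2)
        assert omega == pytest.approx(tss - rss, rel=1e-10)

    def test_categorical_feature_dummy_coded(self):
        meta = pd.DataFrame({"site": ["oral"] * 5 + ["fecal"] * 5})
        y = np.array([1.0] * 5 + [2.0] * 5)
        omega, res = glm_objective(y, meta)
        assert res.deviance == pytest.approx(0.0, abs=1e-12)
        assert omega > 0

    def test_collinear_columns_dropped_with_warning(self):
        f = np.linspace(0, 1, 10)
        meta = pd.DataFrame({"f": f, "f2": 2 * f})
        with pytest.warns(UserWarning, match="collinear"):
            omega, _ = glm_objective(f + 1.0, meta)
        assert omega is not None

    def test_too_few_cases_skipped(self):
        meta = pd.DataFrame({"f": [1.0, 2.0], "g": [0.0, 1.0]})
        omega, res = glm_objective(np.array([0.1, 0.2]), meta)
        assert omega is None and res is None


def planted_factor_fixture(seed, nested=False):
    """Samples whose mass inside one clade (optionally with a second clade
    nested well inside it) scales with a numeric metadata feature.

    The nested variant plants a dominant effect on the outer clade and a
    weaker, independent effect on a small clade at least two edges
    deeper, so the greedy factorization should first split at the outer
    stem and then dig toward the nested clade.
    """
    tree = pp.random_tree(20, seed=500)
    outer = pp.disjoint_clades(tree, k=1, min_edges=8)[0]
    rng = np.random.default_rng(seed)
    n = 30
    if nested:
        opath = set(tree.path_edge_nums(outer))
        cands = []
        for c in tree.subtree_edge_columns(outer):
            e = int(tree.edge_order[c])
            size = tree.subtree_edge_columns(e).size
            depth = len(set(tree.path_edge_nums(e)) - opath)
            if size >= 3 and depth >= 2:
                cands.append((size, e))
        inner = sorted(cands)[0][1]
        clades = [inner, outer]  # nested clade first so queries land inside it
        fr = np.column_stack(
            [rng.uniform(0.05, 0.15, size=n), rng.uniform(0.3, 0.7, size=n)]
        )
    else:
        clades = [outer]
        fr = rng.uniform(0.1, 0.6, size=(n, 1))
    spec = pp.FixtureSpec(
        n_samples=n, queries_per_sample=300, planted_clades=clades,
        clade_fractions=fr, noise_sd=0.02, seed=seed,
    )
    samples, metadata = pp.simulate_samples(tree, spec)
    return tree, samples, metadata, clades


class TestPlacementFactorization:
    def test_single_planted_clade_recovered(self):
        hits = 0
        for seed in range(10):
            tree, samples, metadata, (clade,) = planted_factor_fixture(600 + seed)
            result = placement_factorization(samples, metadata, FactorConfig(iterations=1))
            win = result.factors[0].edge_num
            if win in tree.path_edge_nums(clade):
                hits += 1
        assert hits >= 9

    def test_nested_clade_recovered_later(self):
        tree, samples, metadata, (inner, outer) = planted_factor_fixture(700, nested=True)
        result = placement_factorization(samples, metadata, FactorConfig(iterations=2))
        wins = [f.edge_num for f in result.factors]
        outer_path = tree.path_edge_nums(outer)
        assert wins[0] in outer_path
        # the second factor must dig into the outer clade toward the nested one
        inner_region = set(tree.path_edge_nums(inner)) - set(outer_path)
        assert wins[1] in inner_region

    def test_objectives_non_negative(self):
        _, samples, metadata, _ = planted_factor_fixture(800)
        result = placement_factorization(samples, metadata, FactorConfig(iterations=3))
        for f in result.factors:
            assert all(w >= -1e-9 for w in f.objective_values.values())

    def test_exhaustion_partitions_edges(self, random_samples):
        """Running until no candidates remain: winners are distinct and the
        final subtrees partition the tree's edge columns."""
        meta = pd.DataFrame(
            {"f": np.linspace(0, 1, len(random_samples))},
            index=[s.name for s in random_samples],
        )
        tree = random_samples[0].tree
        with pytest.warns(UserWarning, match="no candidate edges"):
            result = placement_factorization(
                random_samples, meta, FactorConfig(iterations=tree.num_edges)
            )
        wins = [f.edge_num for f in result.factors]
        assert len(wins) == len(set(wins))
        assert len(result.subtrees) == len(wins) + 1
        all_cols = np.concatenate(result.subtrees)
        win_cols = [tree.edge_column(e) for e in wins]
        assert sorted(list(all_cols) + win_cols) == list(range(tree.num_edges))

    def test_later_factors_stay_within_their_subtree(self):
        _, samples, metadata, _ = planted_factor_fixture(900)
        result = placement_factorization(samples, metadata, FactorConfig(iterations=3))
        f1 = result.factors[0]
        claimed = set(int(c) for c in f1.S) | set(int(c) for c in f1.R)
        for f in result.factors[1:]:
            sides = set(int(c) for c in f.R) | set(int(c) for c in f.S)
            # each later factor's sides sit entirely inside one side of factor 1
            assert sides <= set(int(c) for c in f1.R) or sides <= set(int(c) for c in f1.S)

    def test_two_level_label_swap_invariance(self):
        tree, samples, metadata, _ = planted_factor_fixture(1000)
        n = len(samples)
        labels = ["x" if i % 2 else "y" for i in range(n)]
        meta_a = pd.DataFrame({"site": labels}, index=metadata.index)
        meta_b = pd.DataFrame(
            {"site": ["y" if l == "x" else "x" for l in labels]}, index=metadata.index
        )
        cfg = FactorConfig(iterations=1, taxon_weights=False)
        ra = placement_factorization(samples, meta_a, cfg)
        rb = placement_factorization(samples, meta_b, cfg)
        assert ra.factors[0].edge_num == rb.factors[0].edge_num

    def test_deterministic(self):
        _, samples, metadata, _ = planted_factor_fixture(1100)
        r1 = placement_factorization(samples, metadata, FactorConfig(iterations=2))
        r2 = placement_factorization(samples, metadata, FactorConfig(iterations=2))
        assert [f.edge_num for f in r1.factors] == [f.edge_num for f in r2.factors]
        np.testing.assert_array_equal(r1.factors[0].contrasts, r2.factors[0].contrasts)


class TestOrdination:
    def test_single_factor_column_equals_contrasts(self):
        _, samples, metadata, _ = planted_factor_fixture(1200)
        result = placement_factorization(samples, metadata, FactorConfig(iterations=1))
        df = factor_ordination(result)
        np.testing.assert_array_equal(df["factor_1"].to_numpy(), result.factors[0].contrasts)

    def test_scaling_keeps_zero_and_bounds(self):
        _, samples, metadata, _ = planted_factor_fixture(1300)
        result = placement_factorization(samples, metadata, FactorConfig(iterations=2))
        df = factor_ordination(result, scale=True)
        vals = df.to_numpy()
        assert np.nanmax(vals) <= 1.0 + 1e-12
        assert np.nanmin(vals) >= -1.0 - 1e-12
        raw = factor_ordination(result).to_numpy()
        assert np.array_equal(np.sign(vals), np.sign(raw))

    def test_grouped_export(self):
        from phyloplace.factorization import grouped_ordination

        _, samples, metadata, _ = planted_factor_fixture(1400)
        result = placement_factorization(samples, metadata, FactorConfig(iterations=2))
        labels = ["a"] * 15 + ["b"] * 15
        long = grouped_ordination(result, labels)
        assert set(long.columns) == {"label", "factor", "balance"}
        assert len(long) == 2 * len(samples)

    def test_planted_groups_separable_by_factor_sign(self, planted_groups):
        _, samples, metadata, truth = planted_groups
        result = placement_factorization(
            samples, metadata[["group"]], FactorConfig(iterations=1)
        )
        signs = (result.factors[0].contrasts > 0).astype(int)
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(truth, signs) == pytest.approx(1.0)


class TestObjectiveMap:
    def test_winning_edge_has_max_value_and_tips_absent(self):
        tree, samples, metadata, _ = planted_factor_fixture(1500)
        result = placement_factorization(samples, metadata, FactorConfig(iterations=2))
        text = objective_map(result, iteration=1)
        rows = [l.split(",") for l in text.strip().splitlines()[1:]]
        vals = {int(e): float(v) for e, v, _ in rows}
        win = result.factors[0].edge_num
        assert vals[win] == pytest.approx(max(vals.values()))
        tip_nums = {
            int(e) for e, t in zip(tree.edge_order, tree.tip_edge_mask) if t
        }
        assert not tip_nums & set(vals)
        # the first winner is no candidate in iteration 2
        text2 = objective_map(result, iteration=2)
        edges2 = {int(l.split(",")[0]) for l in text2.strip().splitlines()[1:]}
        assert win not in edges2
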