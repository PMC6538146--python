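"""Edge dispersion, edge correlation, Edge PCA, and tree rendering."""

import numpy as np
import pytest

import phyloplace as pp
from phyloplace import (
    ColorMap,
    build_matrix,
    edge_correlation,
    edge_dispersion,
    edge_pca,
    render_tree,
)
from phyloplace.masses import MassMatrix
from phyloplace.metrics import EdgeValues


def matrix_on(tree, values, content="masses"):
    values = np.asarray(values, dtype=float)
    return MassMatrix(
        tree=tree,
        values=values,
        sample_names=[f"s{i}" for i in range(values.shape[0])],
        edge_nums=tree.edge_order.copy(),
        content=content,
    )


class TestDispersion:
    def test_constant_column_sd_zero(self, small_tree):
        X = np.ones((3, small_tree.num_edges))
        ev = edge_dispersion(matrix_on(small_tree, X), measure="sd")
        np.testing.assert_allclose(ev.values, 0.0)

    def test_two_value_column_sample_sd(self, small_tree):
        X = np.zeros((2, small_tree.num_edges))
        X[1, 0] = 1.0
        ev = edge_dispersion(matrix_on(small_tree, X), measure="sd")
        # sample sd of (0, 1) with the n-1 denominator
        assert ev.values[0] == pytest.approx(np.sqrt(0.5))

    def test_matches_column_recomputation(self, random_samples):
        matrix = build_matrix(random_samples, content="masses", normalized=True)
        for measure in ("sd", "variance", "index_of_dispersion"):
            ev = edge_dispersion(matrix, measure=measure)
            for j in range(matrix.m):
                col = matrix.values[:, j]
                var = np.sum((col - col.mean()) ** 2) / (len(col) - 1)
                expected = {
                    "sd": np.sqrt(var),
                    "variance": var,
                    "index_of_dispersion": var / col.mean() if col.mean() != 0 else np.nan,
                }[measure]
                if np.isnan(expected):
                    assert np.isnan(ev.values[j])
                else:
                    assert ev.values[j] == pytest.approx(expected, abs=1e-10)

    def test_zero_mean_index_undefined(self, small_tree):
        X = np.zeros((3, small_tree.num_edges))
        ev = edge_dispersion(matrix_on(small_tree, X), measure="index_of_dispersion")
        assert np.all(np.isnan(ev.values))

    def test_log_scale_affects_display_only(self, random_samples):
        matrix = build_matrix(random_samples, content="masses", normalized=True)
        lin = edge_dispersion(matrix, measure="variance")
        log = edge_dispersion(matrix, measure="variance", log_scale=True)
        np.testing.assert_array_equal(lin.values, log.values)
        assert not np.allclose(
            log.display_values()[lin.defined_mask()], lin.values[lin.defined_mask()]
        )


class TestCorrelation:
    def test_identical_column_pearson_one(self, small_tree):
        f = np.array([1.0, 2.0, 5.0, 7.0])
        X = np.tile(f[:, None], (1, small_tree.num_edges))
        ev = edge_correlation(matrix_on(small_tree, X), f, method="pearson")
        np.testing.assert_allclose(ev.values, 1.0)

    def test_monotone_map_spearman_one_pearson_below(self, small_tree):
        f = np.linspace(0, 3, 8)
        X = np.tile(np.exp(f)[:, None], (1, small_tree.num_edges))
        sp = edge_correlation(matrix_on(small_tree, X), f, method="spearman")
        pe = edge_correlation(matrix_on(small_tree, X), f, method="pearson")
        np.testing.assert_allclose(sp.values, 1.0)
        assert np.all(pe.values < 1.0)

    def test_constant_column_marked_undefined(self, small_tree):
        X = np.ones((5, small_tree.num_edges))
        ev = edge_correlation(matrix_on(small_tree, X), np.arange(5.0))
        assert np.all(np.isnan(ev.values))

    def test_missing_feature_rows_dropped_pairwise(self, small_tree):
        f = np.array([1.0, 2.0, np.nan, 4.0, 5.0])
        X = np.tile(np.array([1.0, 2.0, 99.0, 4.0, 5.0])[:, None], (1, small_tree.num_edges))
        ev = edge_correlation(matrix_on(small_tree, X), f, method="pearson")
        np.testing.assert_allclose(ev.values, 1.0)

    def test_bounded(self, random_samples):
        matrix = build_matrix(random_samples, content="masses", normalized=True)
        f = np.arange(float(matrix.n))
        for method in ("pearson", "spearman"):
            ev = edge_correlation(matrix, f, method=method)
            vals = ev.values[ev.defined_mask()]
            assert np.all(np.abs(vals) <= 1.0 + 1e-12)

    def test_spearman_invariant_under_monotone_feature_transform(self, random_samples):
        matrix = build_matrix(random_samples, content="masses", normalized=True)
        f = np.linspace(1.0, 2.0, matrix.n)
        a = edge_correlation(matrix, f, method="spearman")
        b = edge_correlation(matrix, np.exp(5 * f), method="spearman")
        np.testing.assert_allclose(
            a.values[a.defined_mask()], b.values[b.defined_mask()], atol=1e-12
        )

    def test_planted_signal_found_on_clade_path(self):
        """With one clade's mass linear in the feature, the strongest
        imbalance correlation lies on the path to that clade."""
        hits = 0
        for seed in range(10):
            tree = pp.random_tree(20, seed=300)
            clade = pp.disjoint_clades(tree, k=1, min_edges=4)[0]
            spec = pp.FixtureSpec(
                n_samples=25, queries_per_sample=60, planted_clades=[clade],
                fraction_range=(0.05, 0.9), noise_sd=0.02, seed=400 + seed,
            )
            samples, metadata = pp.simulate_samples(tree, spec)
            matrix = build_matrix(samples, content="imbalances", normalized=True)
            ev = edge_correlation(matrix, metadata["feature_0"], method="pearson")
            best = int(tree.edge_order[np.nanargmax(np.abs(ev.values))])
            if best in tree.path_edge_nums(clade):
                hits += 1
        assert hits >= 9


class TestEdgePca:
    def test_rank_one_matrix_single_component(self, small_tree):
        u = np.array([1.0, -1.0, 2.0, 0.5])
        v = np.zeros(small_tree.num_edges)
        v[0] = 1.0
        v[1] = -0.5
        X = np.outer(u, v)
        res = edge_pca(matrix_on(small_tree, X, content="imbalances"), components=2)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_loadings_unit_norm(self, random_samples):
        matrix = build_matrix(random_samples, content="imbalances", normalized=True)
        res = edge_pca(matrix, components=3)
        for load in res.loadings:
            vals = load.values[load.defined_mask()]
            assert np.sum(vals**2) == pytest.approx(1.0)

    def test_scores_invariant_to_column_shift(self, random_samples):
        matrix = build_matrix(random_samples, content="imbalances", normalized=True)
        res1 = edge_pca(matrix, components=2)
        shifted = matrix_on(matrix.tree, matrix.values + 0.37, content="imbalances")
        res2 = edge_pca(shifted, components=2)
        np.testing.assert_allclose(np.abs(res1.scores), np.abs(res2.scores), atol=1e-9)

    def test_too_many_components_rejected(self, random_samples):
        matrix = build_matrix(random_samples, content="imbalances", normalized=True)
        with pytest.raises(ValueError):
            edge_pca(matrix, components=matrix.n)

    def test_tip_columns_excluded(self, random_samples):
        matrix = build_matrix(random_samples, content="imbalances", normalized=True)
        res = edge_pca(matrix, components=2)
        tree = matrix.tree
        tip_nums = {int(e) for e, t in zip(tree.edge_order, tree.tip_edge_mask) if t}
        assert not tip_nums & {int(e) for e in res.edge_nums}


class TestRenderTree:
    def ev(self, tree, values, kind="dispersion:sd"):
        return EdgeValues(tree=tree, values=np.asarray(values, float), kind=kind)

    def test_equal_values_same_color(self, small_tree):
        text = render_tree(small_tree, self.ev(small_tree, np.ones(small_tree.num_edges)))
        colors = {line.split(",")[2] for line in text.strip().splitlines()[1:]}
        assert len(colors) == 1

    def test_extremes_hit_palette_endpoints(self, small_tree):
        vals = np.linspace(0, 1, small_tree.num_edges)
        cm = ColorMap(palette="viridis")
        text = render_tree(small_tree, self.ev(small_tree, vals), colormap=cm)
        from matplotlib import colormaps
        from matplotlib.colors import to_hex

        lines = text.strip().splitlines()[1:]
        colors = {int(l.split(",")[0]): l.split(",")[2] for l in lines}
        lo = int(small_tree.edge_order[np.argmin(vals)])
        hi = int(small_tree.edge_order[np.argmax(vals)])
        assert colors[lo] == to_hex(colormaps["viridis"](0.0))
        assert colors[hi] == to_hex(colormaps["viridis"](1.0))

    def test_csv_row_count_matches_defined_edges(self, small_tree):
        vals = np.full(small_tree.num_edges, 0.5)
        vals[0] = np.nan
        text = render_tree(small_tree, self.ev(small_tree, vals))
        assert len(text.strip().splitlines()) - 1 == small_tree.num_edges - 1

    def test_newick_and_svg_outputs(self, small_tree, tmp_path):
        vals = np.linspace(-1, 1, small_tree.num_edges)
        nwk = render_tree(
            small_tree, self.ev(small_tree, vals, kind="correlation:pearson"),
            out_format="newick",
        )
        assert "&!color=#" in nwk
        render_tree(
            small_tree, self.ev(small_tree, vals, kind="correlation:pearson"),
            out_format="svg", path=tmp_path / "t.svg",
        )
        assert (tmp_path / "t.svg").stat().st_size > 0

    def test_unknown_format_rejected(self, small_tree):
        with pytest.raises(ValueError):
            render_tree(small_tree, self.ev(small_tree, np.ones(small_tree.num_edges)),
                        out_format="png")
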