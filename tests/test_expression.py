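"""Single-cell QC, normalization, differential expression, and summaries."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from anndata import AnnData

from scaffoldomics.expression import (cluster_composition, dotplot_stats,
                                      percent_mtrna, population_fraction,
                                      qc_trim, size_factor_normalize,
                                      wilcoxon_de)
from scaffoldomics.synthetic import CountsSpec, simulate_counts

from conftest import exact_ranksum_pvalue


def make_adata(X, mito=None, **obs_cols):
    X = np.asarray(X)
    n_cells, n_genes = X.shape
    var = pd.DataFrame(index=[f"g{j}" for j in range(n_genes)])
    var["mito"] = mito if mito is not None else [False] * n_genes
    obs = pd.DataFrame(obs_cols, index=[f"c{i}" for i in range(n_cells)])
    return AnnData(X=sp.csr_matrix(X), obs=obs, var=var)


class TestQcTrim:
    def test_boundary_is_strict(self):
        X = np.zeros((3, 2))
        X[0, 0] = 40_000
        X[1, 0] = 40_001
        X[2, 0] = 100
        out = qc_trim(make_adata(X))
        assert out.n_obs == 2
        assert out.obs["total_counts"].max() == 40_000

    def test_no_removal_leaves_matrix_unchanged(self):
        X = np.arange(12).reshape(4, 3) + 1
        out = qc_trim(make_adata(X))
        assert out.n_obs == 4

    def test_all_removed_is_an_error(self):
        with pytest.raises(ValueError, match="every cell"):
            qc_trim(make_adata([[5.0]]), max_molecules=1)

    def test_planted_tail_fraction_is_removed(self, counts_fixture):
        spec, adata, truth = counts_fixture
        out = qc_trim(adata)
        removed = adata.n_obs - out.n_obs
        assert removed == truth["n_tail"]


class TestPercentMito:
    def test_simple_ratio(self):
        X = [[5, 45]]
        pct = percent_mtrna(make_adata(X, mito=[True, False]))
        assert pct[0] == pytest.approx(10.0)

    def test_no_mito_genes_gives_zero(self):
        pct = percent_mtrna(make_adata([[3, 4], [1, 2]]))
        assert (pct == 0).all()

    def test_zero_total_cell_is_an_error(self):
        with pytest.raises(ValueError, match="empty cell"):
            percent_mtrna(make_adata([[0, 0], [1, 1]]))

    def test_condition_means_match_targets(self, counts_fixture):
        spec, adata, _ = counts_fixture
        sub = adata[~adata.obs["tail"]].copy()
        pct = percent_mtrna(sub)
        for cond, target in spec.mito_fraction_by_condition.items():
            vals = pct[(sub.obs["condition"] == cond).to_numpy()]
            se = vals.std(ddof=1) / np.sqrt(vals.size)
            assert abs(vals.mean() - 100 * target) <= 3 * se


class TestNormalization:
    def test_forced_by_formula(self):
        X = np.diag([100.0, 200.0, 400.0])
        out = size_factor_normalize(make_adata(X))
        assert out.obs["size_factor"].tolist() == [0.5, 1.0, 2.0]
        totals = np.asarray(out.X.sum(axis=1)).ravel()
        assert np.allclose(totals, 200.0)

    def test_single_cell_is_unchanged(self):
        out = size_factor_normalize(make_adata([[3.0, 4.0]]))
        assert out.obs["size_factor"].iloc[0] == 1.0
        assert np.allclose(out.X.toarray(), [[3.0, 4.0]])

    def test_median_cell_unchanged(self):
        X = np.diag([10.0, 20.0, 30.0])
        out = size_factor_normalize(make_adata(X))
        assert np.allclose(out.X.toarray()[1], X[1])

    def test_all_totals_equal_median_raw_total(self, counts_fixture):
        _, adata, _ = counts_fixture
        out = size_factor_normalize(adata)
        totals = np.asarray(out.X.sum(axis=1)).ravel()
        median_raw = np.median(np.asarray(adata.X.sum(axis=1)).ravel())
        assert np.allclose(totals, median_raw, atol=1e-9)

    def test_zero_total_cell_is_an_error(self):
        with pytest.raises(ValueError, match="empty cell"):
            size_factor_normalize(make_adata([[0.0, 0.0], [1.0, 2.0]]))


class TestWilcoxonDe:
    def test_identical_groups_yield_zero_lfc(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.poisson(5, size=(4, 6))] * 2).astype(float)
        adata = make_adata(X)
        de = wilcoxon_de(adata, np.arange(4), np.arange(4, 8))
        assert np.allclose(de["lfc"], 0.0)
        assert not de["significant"].any()

    def test_small_groups_match_exact_enumeration(self):
        rng = np.random.default_rng(3)
        X = rng.normal(10, 2, size=(8, 5))
        adata = make_adata(X)
        de = wilcoxon_de(adata, np.arange(4), np.arange(4, 8), lfc_threshold=0.0)
        for j, row in de.iterrows():
            expected = exact_ranksum_pvalue(X[:4, j], X[4:, j])
            assert row["p"] == pytest.approx(expected)

    def test_swapping_groups_negates_lfc_and_preserves_p(self):
        rng = np.random.default_rng(5)
        X = rng.poisson(4, size=(20, 10)).astype(float) + rng.random((20, 10))
        adata = make_adata(X)
        a, b = np.arange(10), np.arange(10, 20)
        d1 = wilcoxon_de(adata, a, b, lfc_threshold=0.0)
        d2 = wilcoxon_de(adata, b, a, lfc_threshold=0.0)
        assert np.allclose(d1["lfc"], -d2["lfc"])
        assert np.allclose(d1["p"], d2["p"])

    def test_bonferroni_bounds(self):
        rng = np.random.default_rng(7)
        X = rng.poisson(3, size=(12, 30)).astype(float)
        X[:6, :10] *= 3
        de = wilcoxon_de(make_adata(X), np.arange(6), np.arange(6, 12),
                         lfc_threshold=0.0)
        tested = de[de["tested"]]
        assert (tested["p_adj"] >= tested["p"] - 1e-15).all()
        assert (tested["p_adj"] <= 1.0).all()
        m = int(de["tested"].sum())
        assert np.allclose(tested["p_adj"], np.minimum(1.0, tested["p"] * m))

    def test_overlapping_groups_is_an_error(self):
        adata = make_adata(np.ones((6, 3)))
        with pytest.raises(ValueError, match="overlap"):
            wilcoxon_de(adata, np.arange(4), np.arange(3, 6))

    def test_planted_markers_recovered(self, counts_fixture):
        _, adata, truth = counts_fixture
        sub = qc_trim(adata)
        norm = size_factor_normalize(sub)
        mask_a = norm.obs["stem"].to_numpy()
        de = wilcoxon_de(norm, mask_a, ~mask_a)
        sig = set(de.loc[de["significant"], "gene"])
        assert set(truth["markers"]) <= sig


class TestDotplotAndFractions:
    def test_dotplot_extremes(self):
        X = np.array([[0.0, 2.0], [0.0, 2.0], [0.0, 2.0]])
        adata = make_adata(X, cluster=["k"] * 3)
        df, skipped = dotplot_stats(adata, "cluster", ["g0", "g1", "nope"])
        row0 = df[df["gene"] == "g0"].iloc[0]
        row1 = df[df["gene"] == "g1"].iloc[0]
        assert row0["mean_expression"] == 0 and row0["pct_expressing"] == 0
        assert row1["mean_expression"] == 2 and row1["pct_expressing"] == 100
        assert skipped == ["nope"]

    def test_planted_stem_cluster_stands_out(self, counts_fixture):
        _, adata, truth = counts_fixture
        norm = size_factor_normalize(qc_trim(adata))
        df, _ = dotplot_stats(norm, "cluster", truth["markers"])
        by = df.groupby("cluster")["mean_expression"].mean()
        assert by["stem"] > by.drop("stem").max()

    def test_population_fraction_counting(self):
        obs = pd.DataFrame({"pct_mt": [5, 8, 12, 20], "grp": ["a"] * 4})
        frac = population_fraction(obs, "pct_mt", 10, "grp")
        assert frac["a"] == pytest.approx(0.5)

    def test_threshold_below_min_gives_zero(self):
        obs = pd.DataFrame({"pct_mt": [5, 8], "grp": ["a", "a"]})
        assert population_fraction(obs, "pct_mt", 1, "grp")["a"] == 0.0

    def test_condition_ordering_matches_planted_mito(self, counts_fixture):
        spec, adata, _ = counts_fixture
        sub = adata[~adata.obs["tail"]].copy()
        percent_mtrna(sub)
        frac = population_fraction(sub.obs, "pct_mt", 10.0, "condition")
        assert frac["control"] > frac["treated"]

    def test_cluster_composition_counts_cells(self, counts_fixture):
        _, adata, truth = counts_fixture
        comp = cluster_composition(adata.obs, "condition", "cluster")
        assert comp.to_numpy().sum() == adata.n_obs
        assert comp.loc["stem"].sum() == truth["n_stem"]
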