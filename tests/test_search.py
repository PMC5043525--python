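import numpy as np
import pytest
from scipy import stats

from cellmapper import (
    DegenerateDistributionError,
    ExpressionMatrix,
    adjust_bh,
    adjust_holm,
    cellmapper_search,
    mean_fisher_correlation,
    robust_standardize,
    scores_to_pvalues,
    search_platform,
    stouffer_pool,
)
import pandas as pd

from conftest import random_matrix


def profiles_with_correlation(rho, n=50, seed=0):
    """Two centered rows with exact Pearson correlation rho."""
    rng = np.random.default_rng(seed)
    a = rng.standard_normal(n)
    a -= a.mean()
    a /= np.linalg.norm(a)
    b = rng.standard_normal(n)
    b -= b.mean()
    b -= (b @ a) * a  # orthogonal to a, still centered
    b /= np.linalg.norm(b)
    return a, rho * a + np.sqrt(1 - rho**2) * b


class TestMeanFisherCorrelation:
    def test_uncorrelated_gene_gets_zero(self):
        x, y = profiles_with_correlation(0.0)
        zbar, _ = mean_fisher_correlation(np.vstack([x, y]), query_rows=[0])
        assert zbar[1] == pytest.approx(0.0, abs=1e-10)

    def test_rho_09_closed_form(self):
        # 0.5 * ln(1.9 / 0.1) = 1.472219...
        x, y = profiles_with_correlation(0.9)
        zbar, _ = mean_fisher_correlation(np.vstack([x, y]), query_rows=[0])
        assert zbar[1] == pytest.approx(0.5 * np.log(1.9 / 0.1), abs=1e-10)
        assert zbar[1] == pytest.approx(1.472219, abs=1e-6)

    def test_opposing_correlations_cancel(self):
        x, y = profiles_with_correlation(0.7)
        # queries +-rho with the same gene -> zbar = 0 by odd symmetry
        zbar, _ = mean_fisher_correlation(np.vstack([y, -y, x]), query_rows=[0, 1])
        assert zbar[2] == pytest.approx(0.0, abs=1e-10)

    def test_zero_variance_row_flagged_neutral(self):
        x, y = profiles_with_correlation(0.5)
        zbar, flagged = mean_fisher_correlation(
            np.vstack([x, y, np.zeros_like(x)]), query_rows=[0])
        assert flagged[2] and not flagged[0]
        assert zbar[2] == 0.0

    def test_perfect_duplicate_stays_finite(self):
        x, _ = profiles_with_correlation(0.5)
        zbar, _ = mean_fisher_correlation(np.vstack([x, x.copy()]), query_rows=[0])
        assert np.isfinite(zbar[1])

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="3 samples"):
            mean_fisher_correlation(np.ones((4, 2)), query_rows=[0])


class TestRobustStandardize:
    def test_outlier_closed_form(self):
        s = robust_standardize(np.array([1.0, 2.0, 3.0, 4.0, 100.0]))
        # median 3, MAD 1 -> (100 - 3) / 1.4826 = 65.4256...
        assert s[-1] == pytest.approx(97 / 1.4826)
        assert s[-1] == pytest.approx(65.4256, abs=1e-3)

    def test_symmetric_median_maps_to_zero(self):
        s = robust_standardize(np.array([-2.0, -1.0, 0.0, 1.0, 2.0]))
        assert s[2] == pytest.approx(0.0, abs=1e-12)

    def test_affine_invariance(self, rng):
        z = rng.standard_normal(101)
        np.testing.assert_allclose(robust_standardize(3.5 * z + 2.0),
                                   robust_standardize(z), atol=1e-10)

    def test_degenerate_mad_raises(self):
        with pytest.raises(DegenerateDistributionError):
            robust_standardize(np.array([1.0, 1.0, 1.0, 5.0]))


class TestScoresToPvalues:
    @pytest.mark.parametrize("s,expected,tol", [
        (0.0, 0.5, 1e-12),
        (1.644854, 0.05, 1e-4),
        (-2.0, 0.97725, 1e-5),
    ])
    def test_normal_tail(self, s, expected, tol):
        assert scores_to_pvalues(np.array([s]))[0] == pytest.approx(expected, abs=tol)

    def test_floored_positive(self):
        assert scores_to_pvalues(np.array([1e9]))[0] > 0.0


class TestStoufferPool:
    def table(self, genes, p):
        return pd.DataFrame({"gene_id": genes, "p": p})

    def test_two_platforms_p005(self):
        pooled = stouffer_pool([self.table(["g"], [0.05]), self.table(["g"], [0.05])])
        assert pooled.loc[0, "combined_z"] == pytest.approx(2.326174, abs=1e-5)
        assert pooled.loc[0, "combined_p"] == pytest.approx(0.0100, abs=1e-4)

    def test_single_platform_identity(self):
        pooled = stouffer_pool([self.table(["g"], [0.2])])
        assert pooled.loc[0, "combined_p"] == pytest.approx(0.2, abs=1e-10)

    def test_opposite_z_cancel(self):
        pooled = stouffer_pool([self.table(["g"], [0.05]), self.table(["g"], [0.95])])
        assert pooled.loc[0, "combined_z"] == pytest.approx(0.0, abs=1e-8)
        assert pooled.loc[0, "combined_p"] == pytest.approx(0.5, abs=1e-8)

    def test_stouffer_identity_k_copies(self):
        # combined z of k identical z values equals z * sqrt(k)
        z = stats.norm.isf(0.1)
        for k in (2, 3, 4):
            pooled = stouffer_pool([self.table(["g"], [0.1])] * k)
            assert pooled.loc[0, "combined_z"] == pytest.approx(z * np.sqrt(k), rel=1e-9)

    def test_unequal_coverage_counts_platforms(self):
        pooled = stouffer_pool([self.table(["a", "b"], [0.1, 0.2]),
                                self.table(["a"], [0.1])])
        by_gene = pooled.set_index("gene_id")
        assert by_gene.loc["a", "n_platforms_present"] == 2
        assert by_gene.loc["b", "n_platforms_present"] == 1

    def test_empty_input(self):
        with pytest.raises(ValueError):
            stouffer_pool([])


def bh_bruteforce(p):
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    out = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        out[i] = running
    return out


def holm_bruteforce(p):
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    out = np.empty(m)
    running = 0.0
    for rank in range(1, m + 1):
        i = order[rank - 1]
        running = max(running, min(1.0, p[i] * (m - rank + 1)))
        out[i] = running
    return out


class TestMultipleTesting:
    def test_bh_stepup_hand_example(self):
        np.testing.assert_allclose(adjust_bh([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_holm_stepdown_hand_example(self):
        np.testing.assert_allclose(adjust_holm([0.01, 0.04]), [0.02, 0.04])

    def test_constant_p_ties(self):
        np.testing.assert_allclose(adjust_bh([0.2] * 5), [0.2] * 5)
        np.testing.assert_allclose(adjust_holm([0.2] * 5), [1.0] * 5)

    def test_oracle_equivalence_random_vectors(self, rng):
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 30))
            np.testing.assert_allclose(adjust_bh(p), bh_bruteforce(p), atol=1e-12)
            np.testing.assert_allclose(adjust_holm(p), holm_bruteforce(p), atol=1e-12)


class TestSearchPlatform:
    def structured_matrix(self, rng, m=300, n=60):
        # one planted co-expression module of 20 genes
        vals = rng.standard_normal((m, n))
        signal = rng.standard_normal(n) * 2.0
        vals[:20] += signal
        return ExpressionMatrix([f"g{i}" for i in range(m)],
                                [f"s{j}" for j in range(n)], vals)

    def test_query_excluded_and_reported(self, rng):
        mx = self.structured_matrix(rng)
        res = search_platform(mx, ["g0"])
        assert "g0" not in set(res.table["gene_id"])
        assert list(res.query_report["gene_id"]) == ["g0"]

    def test_ranks_are_permutation_with_deterministic_ties(self, rng):
        mx = self.structured_matrix(rng)
        res = search_platform(mx, ["g0"])
        assert sorted(res.table["rank"]) == list(range(1, len(res.table) + 1))
        # fdr >= p, and fdr monotone in p-order
        by_p = res.table.sort_values("p")
        assert np.all(by_p["fdr"].to_numpy() >= by_p["p"].to_numpy() - 1e-15)
        assert np.all(np.diff(by_p["fdr"].to_numpy()) >= -1e-12)

    def test_module_genes_rank_top(self, rng):
        mx = self.structured_matrix(rng)
        res = search_platform(mx, ["g0"])
        top = set(res.table.head(19)["gene_id"])
        assert len(top & {f"g{i}" for i in range(1, 20)}) >= 17

    def test_sample_permutation_invariance(self, rng):
        mx = self.structured_matrix(rng)
        res1 = search_platform(mx, ["g0"])
        perm = rng.permutation(mx.n_samples)
        mx2 = ExpressionMatrix(mx.gene_ids, mx.sample_ids[perm], mx.values[:, perm])
        res2 = search_platform(mx2, ["g0"])
        np.testing.assert_allclose(res1.table["s"], res2.table["s"], atol=1e-10)

    def test_row_scale_invariance(self, rng):
        mx = self.structured_matrix(rng)
        res1 = search_platform(mx, ["g0"])
        vals = mx.values.copy()
        vals[5] *= 37.0
        mx2 = ExpressionMatrix(mx.gene_ids, mx.sample_ids, vals)
        res2 = search_platform(mx2, ["g0"])
        np.testing.assert_allclose(res1.table["s"], res2.table["s"], atol=1e-8)

    def test_absent_query_errors(self, rng):
        mx = self.structured_matrix(rng)
        with pytest.raises(KeyError, match="nope"):
            search_platform(mx, ["nope"])


class TestCellmapperSearch:
    def test_two_identical_platforms_sharpen_p(self, rng):
        from conftest import random_matrix
        mx = TestSearchPlatform().structured_matrix(rng)
        single = cellmapper_search([mx], ["g0"])
        double = cellmapper_search([mx, mx], ["g0"])
        s1 = single.pooled.set_index("gene_id")
        s2 = double.pooled.set_index("gene_id")
        enriched = single.platforms[0].table
        genes = enriched.loc[enriched["s"] > 0, "gene_id"].head(50)
        for g in genes:
            assert s2.loc[g, "combined_p"] <= s1.loc[g, "combined_p"] + 1e-15

    def test_platform_without_query_skipped(self, rng):
        mx = TestSearchPlatform().structured_matrix(rng)
        other = random_matrix(rng, 50, 30, prefix="X")
        res = cellmapper_search([mx, other], ["g0"])
        assert res.skipped_platforms == [1]
        assert len(res.platforms) == 1

    def test_query_absent_everywhere_errors(self, rng):
        mx = TestSearchPlatform().structured_matrix(rng)
        with pytest.raises(ValueError, match="absent"):
            cellmapper_search([mx], ["nope"])

    def test_deterministic_output_order(self, rng):
        mx = TestSearchPlatform().structured_matrix(rng)
        res = cellmapper_search([mx], ["g0"])
        p = res.pooled
        key = list(zip(p["combined_p"], p["gene_id"]))
        assert key == sorted(key)

    def test_fdr_threshold_flags(self, rng):
        mx = TestSearchPlatform().structured_matrix(rng)
        res = cellmapper_search([mx], ["g0"], fdr_threshold=0.01)
        flagged = res.pooled.loc[res.pooled["predicted"], "combined_fdr"]
        assert np.all(flagged <= 0.01)
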