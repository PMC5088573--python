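"""Inferential layer: rank tests, Mantel permutation test, covariance repair, GLS."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from colisurf.fingerprint import SimilarityMatrix
from colisurf.stats import (
    benjamini_hochberg,
    correlation_matrix,
    five_number_summary,
    habitat_report,
    kendall_tau,
    mantel,
    pgls_fit,
    similarity_to_covariance,
    wilcoxon_rank_sum,
)
from conftest import random_similarity


def enumeration_rank_sum_p(x, y):
    """Exact two-sided rank-sum p by brute enumeration over rank splits."""
    n1 = len(x)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    w_obs = ranks[:n1].sum()
    sums = [sum(c) for c in itertools.combinations(range(1, len(pooled) + 1), n1)]
    total = len(sums)
    cdf = sum(s <= w_obs + 1e-9 for s in sums) / total
    sf = sum(s >= w_obs - 1e-9 for s in sums) / total
    return min(1.0, 2.0 * min(cdf, sf))


class TestWilcoxon:
    def test_separated_groups_exact_p(self):
        res = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert res.p_value == pytest.approx(0.1)
        assert "exact" in res.method

    def test_identical_multisets_near_one(self):
        res = wilcoxon_rank_sum([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert res.p_value > 0.9

    def test_all_constant_is_one(self):
        assert wilcoxon_rank_sum([2.0, 2.0], [2.0, 2.0]).p_value == 1.0

    def test_large_shift_significant(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 30)
        y = rng.normal(5, 1, 30)
        assert wilcoxon_rank_sum(y, x).p_value < 1e-3

    def test_exact_path_matches_enumeration(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            n1 = int(rng.integers(2, 5))
            n2 = int(rng.integers(2, 5))
            pooled = rng.permutation(np.arange(1.0, n1 + n2 + 1))  # tie-free
            x, y = pooled[:n1], pooled[n1:]
            assert wilcoxon_rank_sum(x, y).p_value == pytest.approx(
                enumeration_rank_sum_p(x, y), abs=1e-12
            )

    def test_null_pvalues_uniform(self):
        # exchangeable null: KS test of the p-value distribution
        rng = np.random.default_rng(7)
        ps = []
        for _ in range(1000):
            z = rng.normal(size=40)
            ps.append(wilcoxon_rank_sum(z[:20], z[20:]).p_value)
        assert sps.kstest(ps, "uniform").pvalue > 0.01


def paircount_tau_b(x, y):
    """O(n^2) concordant/discordant pair counting with tie corrections."""
    n = len(x)
    c = d = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = x[i] - x[j]
            dy = y[i] - y[j]
            if dx == 0 and dy == 0:
                continue
            if dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif dx * dy > 0:
                c += 1
            else:
                d += 1
    n0 = n * (n - 1) / 2
    return (c - d) / math.sqrt((n0 - _tie_term(x)) * (n0 - _tie_term(y)))


def _tie_term(v):
    _, counts = np.unique(v, return_counts=True)
    return sum(t * (t - 1) / 2 for t in counts)


class TestKendall:
    def test_perfectly_concordant(self):
        assert kendall_tau([1, 2, 3, 4], [10, 20, 30, 40]).statistic == pytest.approx(1.0)

    def test_perfectly_discordant(self):
        assert kendall_tau([1, 2, 3, 4], [4, 3, 2, 1]).statistic == pytest.approx(-1.0)

    def test_matches_paircount_oracle_with_ties(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(5, 40))
            x = rng.integers(0, 8, n).astype(float)  # heavy ties
            y = rng.normal(size=n)
            assert kendall_tau(x, y).statistic == pytest.approx(
                paircount_tau_b(x, y), abs=1e-12
            )

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            kendall_tau([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=15, deadline=None)
    def test_antisymmetric_under_reversal(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.permutation(np.arange(10.0))
        y = rng.permutation(np.arange(10.0))
        assert kendall_tau(x, y).statistic == pytest.approx(
            -kendall_tau(x, -y).statistic, abs=1e-12
        )


class TestCorrelationMatrix:
    def test_identical_columns_give_unit_tau(self):
        df = pd.DataFrame({
            "habitat": ["sediment"] * 3 + ["water"] * 3,
            "a": [1.0, 2, 3, 4, 5, 6],
            "b": [1.0, 2, 3, 4, 5, 6],
            "c": [3.0, 1, 4, 1, 5, 9],
        })
        tau, p = correlation_matrix(df)
        assert tau.loc["a", "b"] == pytest.approx(1.0)
        assert p.loc["a", "b"] < 0.05

    def test_constant_column_marked_undefined(self):
        df = pd.DataFrame({
            "habitat": ["sediment"] * 4,
            "a": [1.0, 2, 3, 4],
            "b": [5.0, 5, 5, 5],
        })
        tau, _ = correlation_matrix(df)
        assert np.isnan(tau.loc["a", "b"])

    def test_ratio_column_structurally_correlated(self, small_table):
        tau, _ = correlation_matrix(small_table)
        assert tau.loc["eps_ratio", "eps_protein"] > 0


class TestMantel:
    def test_perfect_block_structure(self):
        # unequal group sizes large enough that a random permutation essentially
        # never reproduces the partition (a wholesale group swap would preserve
        # co-membership for equal sizes), so p attains its minimum 1/(1+n_perm)
        n1, n2 = 12, 8
        v = np.zeros((n1 + n2, n1 + n2))
        v[:n1, :n1] = 1.0
        v[n1:, n1:] = 1.0
        np.fill_diagonal(v, 1.0)
        s = SimilarityMatrix([f"S{i}" for i in range(n1 + n2)], v)
        hab = ["sediment"] * n1 + ["water"] * n2
        res = mantel(s, hab, n_perm=199, seed=0)
        assert res.statistic == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 200)

    def test_hand_computed_six_strain_r(self):
        vals = np.array([
            [1.0, 0.8, 0.6, 0.2, 0.3, 0.1],
            [0.8, 1.0, 0.5, 0.4, 0.2, 0.3],
            [0.6, 0.5, 1.0, 0.3, 0.1, 0.2],
            [0.2, 0.4, 0.3, 1.0, 0.7, 0.6],
            [0.3, 0.2, 0.1, 0.7, 1.0, 0.5],
            [0.1, 0.3, 0.2, 0.6, 0.5, 1.0],
        ])
        s = SimilarityMatrix(list("ABCDEF"), vals)
        hab = ["sediment"] * 3 + ["water"] * 3
        # explicit Pearson over the 15 upper-triangle pairs
        iu = np.triu_indices(6, 1)
        sv = vals[iu]
        hv = np.array([1, 1, 0, 0, 0, 1, 0, 0, 0, 0, 0, 0, 1, 1, 1], float)
        num = np.sum((sv - sv.mean()) * (hv - hv.mean()))
        den = math.sqrt(np.sum((sv - sv.mean()) ** 2) * np.sum((hv - hv.mean()) ** 2))
        res = mantel(s, hab, n_perm=99, seed=1)
        assert res.statistic == pytest.approx(num / den, abs=1e-12)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(5)
        s = random_similarity(rng, 10)
        hab = np.array(["sediment"] * 5 + ["water"] * 5)
        swapped = np.where(hab == "sediment", "water", "sediment")
        r1 = mantel(s, hab, n_perm=99, seed=2)
        r2 = mantel(s, swapped, n_perm=99, seed=2)
        assert r1.statistic == pytest.approx(r2.statistic)
        assert r1.p_value == r2.p_value

    def test_distance_coding_flips_sign(self):
        rng = np.random.default_rng(6)
        s = random_similarity(rng, 8)
        hab = ["sediment"] * 4 + ["water"] * 4
        r_co = mantel(s, hab, n_perm=49, seed=0)
        r_dist = mantel(s, hab, n_perm=49, seed=0, coding="distance")
        assert r_co.statistic == pytest.approx(-r_dist.statistic, abs=1e-12)

    def test_single_habitat_rejected(self):
        rng = np.random.default_rng(7)
        s = random_similarity(rng, 5)
        with pytest.raises(ValueError):
            mantel(s, ["sediment"] * 5)


class TestCovarianceRepair:
    def test_identity_unchanged(self):
        s = SimilarityMatrix(list("ABC"), np.eye(3))
        np.testing.assert_allclose(similarity_to_covariance(s), np.eye(3), atol=1e-12)

    def test_spd_input_unchanged(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(5, 8))
        c = a @ a.T / 8
        d = np.sqrt(np.diag(c))
        corr = c / np.outer(d, d)
        s = SimilarityMatrix(list("ABCDE"), corr)
        np.testing.assert_allclose(similarity_to_covariance(s), corr, atol=1e-12)

    def test_rank_deficient_repaired_to_floor(self):
        v = np.ones((3, 3))  # three identical strains
        s = SimilarityMatrix(list("ABC"), v)
        out, (before, after) = similarity_to_covariance(s, return_info=True)
        w = np.linalg.eigvalsh(out)
        assert before == pytest.approx(0.0, abs=1e-12)
        assert after == pytest.approx(1e-8 * 3.0, rel=1e-6)
        assert w.min() > 0
        np.testing.assert_allclose(out, out.T)


def ols_closed_form(y, x):
    """Textbook OLS: beta, se, t for comparison with the V = I limit."""
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ y
    resid = y - x @ beta
    sigma2 = resid @ resid / (len(y) - x.shape[1])
    se = np.sqrt(np.diag(sigma2 * xtx_inv))
    return beta, se, beta / se


class TestPgls:
    def test_identity_v_reduces_to_ols(self):
        rng = np.random.default_rng(0)
        n = 20
        hab = np.array(["sediment"] * 11 + ["water"] * 9)
        x = np.column_stack([np.ones(n), (hab == "sediment").astype(float)])
        for _ in range(20):
            y = rng.normal(size=n)
            fit = pgls_fit(y, hab, np.eye(n))
            beta, se, t = ols_closed_form(y, x)
            np.testing.assert_allclose(fit.beta, beta, atol=1e-10)
            np.testing.assert_allclose(fit.se, se, atol=1e-10)
            np.testing.assert_allclose(fit.t, t, atol=1e-10)

    def test_constant_response(self):
        hab = np.array(["sediment"] * 5 + ["water"] * 5)
        fit = pgls_fit(np.full(10, 3.7), hab, np.eye(10))
        assert fit.beta[0] == pytest.approx(3.7)
        assert fit.beta[1] == pytest.approx(0.0, abs=1e-12)

    def test_matches_statsmodels_gls(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(4)
        n = 16
        hab = np.array(["sediment"] * 8 + ["water"] * 8)
        x = np.column_stack([np.ones(n), (hab == "sediment").astype(float)])
        a = rng.normal(size=(n, 2 * n))
        v = a @ a.T / (2 * n)
        d = np.sqrt(np.diag(v))
        v = v / np.outer(d, d)
        y = rng.normal(size=n)
        fit = pgls_fit(y, hab, v)
        ref = sm.GLS(y, x, sigma=v).fit()
        np.testing.assert_allclose(fit.beta, ref.params, atol=1e-10)
        np.testing.assert_allclose(fit.se, ref.bse, atol=1e-10)
        np.testing.assert_allclose(fit.p, ref.pvalues, atol=1e-10)

    def test_shift_and_scale_equivariance(self):
        rng = np.random.default_rng(8)
        n = 14
        hab = np.array(["sediment"] * 7 + ["water"] * 7)
        a = rng.normal(size=(n, 3 * n))
        v = a @ a.T / (3 * n)
        d = np.sqrt(np.diag(v))
        v = v / np.outer(d, d)
        y = rng.normal(size=n)
        base = pgls_fit(y, hab, v)
        shifted = pgls_fit(y + 5.0, hab, v)
        scaled = pgls_fit(3.0 * y, hab, v)
        assert shifted.beta[0] == pytest.approx(base.beta[0] + 5.0)
        assert shifted.beta[1] == pytest.approx(base.beta[1])
        np.testing.assert_allclose(scaled.beta, 3.0 * base.beta, atol=1e-10)
        np.testing.assert_allclose(scaled.se, 3.0 * base.se, atol=1e-10)

    def test_single_habitat_fails(self):
        with pytest.raises(ValueError):
            pgls_fit(np.arange(6.0), np.array(["water"] * 6), np.eye(6))

    def test_naive_ols_anticonservative_under_relatedness(self):
        # strongly habitat-clustered relatedness with beta = 0: OLS rejects far
        # more often than nominal, GLS with the true V stays calibrated
        rng = np.random.default_rng(11)
        n1 = n2 = 15
        n = n1 + n2
        hab = np.array(["sediment"] * n1 + ["water"] * n2)
        x = np.column_stack([np.ones(n), (hab == "sediment").astype(float)])
        v = np.eye(n) * 0.2
        v[:n1, :n1] += 0.8
        v[n1:, n1:] += 0.8
        L = np.linalg.cholesky(v)
        rej_ols = rej_gls = 0
        reps = 400
        for _ in range(reps):
            y = L @ rng.normal(size=n)
            fit = pgls_fit(y, hab, v)
            rej_gls += fit.habitat_p < 0.05
            beta, se, t = ols_closed_form(y, x)
            p_ols = 2 * sps.t.sf(abs(t[1]), n - 2)
            rej_ols += p_ols < 0.05
        assert rej_ols / reps > 0.3
        assert rej_gls / reps < 0.12


class TestSummaries:
    def test_five_numbers_of_one_to_eight(self):
        s = five_number_summary(np.arange(1.0, 9.0))
        assert s["q25"] == pytest.approx(2.75)
        assert s["median"] == pytest.approx(4.5)
        assert s["q75"] == pytest.approx(6.25)
        assert s["whisker_low"] == pytest.approx(2.75 - 1.5 * 3.5)
        assert s["whisker_high"] == pytest.approx(6.25 + 1.5 * 3.5)
        assert s["outliers"] == []

    def test_outliers_beyond_fences(self):
        s = five_number_summary(np.array([1.0, 2, 3, 4, 5, 6, 7, 8, 50.0]))
        assert 50.0 in s["outliers"]

    def test_bh_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(2)
        p = rng.uniform(size=12)
        ours = benjamini_hochberg(p)
        _, ref, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(ours, ref, atol=1e-12)


class TestHabitatReport:
    def test_structure_and_content(self, small_cohort, small_table):
        rep = habitat_report(small_table, small_cohort.truth.similarity,
                             n_perm=199, seed=0)
        assert set(rep["properties"]) == {
            "hydrophobicity", "zeta_potential", "eps_protein", "eps_sugar",
            "eps_ratio", "net_charge_ph8", "total_acidity", "pzc",
        }
        entry = rep["properties"]["hydrophobicity"]
        assert entry["sediment"]["n"] == 12 and entry["water"]["n"] == 12
        assert 0 <= entry["wilcoxon"]["p_value"] <= 1
        assert len(entry["pgls"]["beta"]) == 2
        assert rep["mantel"]["p_value"] <= 1
        assert set(rep["correlations"]) == {"all", "sediment", "water"}
        assert "sediment" in rep["hydrophobicity_vs_eps_protein"]

    def test_failing_property_does_not_abort_others(self, small_cohort, small_table):
        broken = small_table.copy()
        broken["pzc"] = np.nan
        rep = habitat_report(broken, small_cohort.truth.similarity, n_perm=99, seed=0)
        assert "error" in rep["properties"]["pzc"]
        assert "wilcoxon" in rep["properties"]["hydrophobicity"]

    def test_mismatched_strains_rejected(self, small_cohort, small_table):
        with pytest.raises(ValueError):
            habitat_report(small_table.iloc[:-1], small_cohort.truth.similarity)
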