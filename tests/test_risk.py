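"""Risk stratification: clustering, rates, exact tests, regression."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import gammaln

from gmltwin import (
    ConfigurationError,
    cluster_kmeans,
    conversion_rates,
    embed_2d,
    fisher_exact_2x2,
    label_risk,
    pairwise_cluster_tests,
)
from gmltwin.risk import (
    RiskStratifier,
    TableError,
    biomarker_enrichment,
    exact_kx2_test,
    multinomial_membership_model,
    renumber_by_rate,
)


class TestFisher:
    def test_equal_proportions_give_p_one(self):
        assert fisher_exact_2x2([[2, 2], [2, 2]]) == 1.0

    def test_hand_enumerated_table(self):
        """[[3,1],[1,3]]: hypergeometric masses 1/70,16/70,36/70,16/70,1/70;
        two-sided p = (16+16+1+1)/70 = 34/70."""
        assert fisher_exact_2x2([[3, 1], [1, 3]]) == pytest.approx(34 / 70, abs=1e-12)

    @pytest.mark.parametrize("bad", [[[1, -2], [3, 4]], [[0.5, 1], [2, 3]],
                                     [[1, 2, 3], [4, 5, 6]]])
    def test_invalid_tables_rejected(self, bad):
        with pytest.raises(TableError):
            fisher_exact_2x2(bad)

    @settings(deadline=None, max_examples=150, derandomize=True)
    @given(st.integers(0, 12), st.integers(0, 12), st.integers(0, 12), st.integers(0, 12))
    def test_matches_enumeration_oracle(self, a, b, c, d):
        r1, r2, m, n = a + b, c + d, a + c, a + b + c + d

        def logp(x):
            return (gammaln(r1 + 1) - gammaln(x + 1) - gammaln(r1 - x + 1)
                    + gammaln(r2 + 1) - gammaln(m - x + 1) - gammaln(r2 - m + x + 1)
                    - gammaln(n + 1) + gammaln(m + 1) + gammaln(n - m + 1))

        xs = np.arange(max(0, m - r2), min(r1, m) + 1)
        lps = np.array([logp(x) for x in xs])
        expected = float(np.exp(lps[lps <= logp(a) + 1e-9]).sum())
        assert fisher_exact_2x2([[a, b], [c, d]]) == pytest.approx(expected, abs=1e-9)


class TestExactKx2:
    def test_reduces_to_fisher_for_two_rows(self):
        p, method = exact_kx2_test([[3, 1], [1, 3]])
        assert method == "exact" and p == pytest.approx(34 / 70, abs=1e-12)

    def test_total_probability_is_one_at_full_tail(self):
        # observed = least probable table => p sums every table = 1
        p, _ = exact_kx2_test([[4, 0], [0, 4], [4, 0]])
        assert p <= 1.0

    def test_agrees_with_chi2_asymptotically(self):
        t = [[30, 70], [50, 50], [40, 60], [60, 40]]
        p_exact, method = exact_kx2_test(t)
        from scipy.stats import chi2_contingency

        assert method == "exact"
        p_chi2 = chi2_contingency(t, correction=False).pvalue
        assert abs(p_exact - p_chi2) < 0.02

    def test_falls_back_to_chi2_when_enumeration_too_large(self):
        t = [[300, 700], [500, 500], [400, 600], [600, 400]]
        p, method = exact_kx2_test(t, max_tables=1000)
        assert method == "chi2" and 0 <= p <= 1


class TestRatesAndLabels:
    def test_count_arithmetic(self):
        out = conversion_rates([1] * 8, [1, 1, 0, 0, 0, 0, 0, 0], n_boot=100, seed=0)
        assert out.loc[1, "rate"] == pytest.approx(0.25)
        assert out.loc[1, "converters"] == 2

    def test_all_converters_degenerate_bootstrap(self):
        out = conversion_rates([1] * 6, [1] * 6, n_boot=200, seed=0)
        assert out.loc[1, "rate"] == 1.0
        assert out.loc[1, "ci_low"] == 1.0 and out.loc[1, "ci_high"] == 1.0

    def test_small_cluster_flagged_unstable(self):
        out = conversion_rates([1, 1, 1, 2, 2, 2, 2, 2], [0] * 8, n_boot=50, seed=0)
        assert bool(out.loc[1, "unstable"]) and not bool(out.loc[2, "unstable"])

    def test_risk_label_bands(self):
        assert label_risk([0.39, 0.25, 0.10, 0.09]) == ["red", "red", "orange", "low"]

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.floats(0, 1))
    def test_labels_consistent_with_thresholds(self, r):
        lab = label_risk([r])[0]
        assert lab == ("red" if r >= 0.25 else "orange" if r >= 0.10 else "low")


class TestClustering:
    def test_k1_puts_everyone_together(self):
        X = np.random.default_rng(0).normal(size=(10, 2))
        assert set(cluster_kmeans(X, k=1, seed=0)) == {0}

    def test_four_planted_blobs_recovered(self):
        rng = np.random.default_rng(4)
        centers = np.array([[0, 0], [10, 0], [0, 10], [10, 10]])
        truth = np.repeat(np.arange(4), 30)
        X = centers[truth] + rng.normal(0, 0.5, (120, 2))
        lab = cluster_kmeans(X, k=4, seed=1)
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(truth, lab) >= 0.9

    def test_embed_2d_deterministic_and_separable(self):
        rng = np.random.default_rng(7)
        X = np.vstack([rng.normal(0, 1, (40, 30)), rng.normal(8, 1, (40, 30))])
        c1 = embed_2d(X, seed=3)
        c2 = embed_2d(X, seed=3)
        assert np.array_equal(c1, c2)
        # planted blobs stay linearly separable in 2-D
        from sklearn.linear_model import LogisticRegression

        y = np.repeat([0, 1], 40)
        acc = LogisticRegression().fit(c1, y).score(c1, y)
        assert acc > 0.95

    def test_duplicated_rows_map_to_coincident_points(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 10))
        X[15:] = X[:15]
        c = embed_2d(X, seed=0, method="pca")
        assert np.allclose(c[:15], c[15:])

    def test_renumbering_makes_report_label_invariant(self):
        rng = np.random.default_rng(2)
        lab = rng.integers(0, 4, 120)
        y = rng.random(120) < (0.1 + 0.1 * lab)
        base = renumber_by_rate(lab, y)
        perm = np.array([2, 0, 3, 1])[lab]  # arbitrary relabeling
        assert np.array_equal(renumber_by_rate(perm, y), base)

    def test_pairwise_fisher_matrix_is_symmetric(self):
        lab = np.repeat([1, 2, 3], 20)
        y = np.concatenate([np.ones(10), np.zeros(10)] * 3).astype(bool)
        m = pairwise_cluster_tests(lab, y)
        assert np.allclose(m.to_numpy(), m.to_numpy().T, equal_nan=True)
        assert m.loc[1, 2] == 1.0  # identical proportions


class TestBiomarkers:
    def test_constant_biomarker_gives_p_one(self):
        rec = pd.DataFrame({"spinal_cord_lesion": ["yes"] * 40})
        out = biomarker_enrichment(np.repeat([1, 2], 20), rec,
                                   biomarkers=["spinal_cord_lesion"])
        assert out.loc["spinal_cord_lesion", "p_value"] == 1.0

    def test_denominator_counts_non_missing_only(self):
        rec = pd.DataFrame({"csf_positive": ["yes", "no", None, None, "yes", None]})
        out = biomarker_enrichment(np.array([1, 1, 1, 2, 2, 2]), rec,
                                   biomarkers=["csf_positive"])
        assert out.loc["csf_positive", "n_available"] == 3

    def test_planted_cluster_association_detected(self):
        rng = np.random.default_rng(6)
        lab = np.repeat([1, 2, 3, 4], 38)
        p_by_cluster = np.array([0.1, 0.6, 0.6, 0.1])[lab - 1]
        rec = pd.DataFrame({"spinal_cord_lesion":
                            np.where(rng.random(152) < p_by_cluster, "yes", "no")})
        out = biomarker_enrichment(lab, rec, biomarkers=["spinal_cord_lesion"])
        assert out.loc["spinal_cord_lesion", "p_value"] < 0.05


class TestMembershipModel:
    def test_intercept_only_reproduces_frequencies(self):
        rng = np.random.default_rng(0)
        lab = rng.integers(1, 4, 300)
        fit = multinomial_membership_model(lab, pd.DataFrame(index=range(300)))
        freq = np.bincount(lab)[1:] / 300
        assert np.allclose(fit.predicted.mean(axis=0), freq, atol=1e-6)

    def test_null_covariate_rarely_significant(self):
        rng = np.random.default_rng(12)
        rejections = 0
        for _ in range(40):
            lab = rng.integers(1, 4, 150)
            cov = pd.DataFrame({"x": rng.normal(size=150)})
            fit = multinomial_membership_model(lab, cov)
            ps = fit.coef_table.query("covariate == 'x'")["p_value"]
            rejections += int((ps < 0.05).any())
        # familywise over 2 slopes => expect ~10% of runs, allow binomial slack
        assert rejections <= 12

    def test_planted_effect_sign_recovered(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=152)
        logits = np.column_stack([np.zeros(152), 1.5 * x])
        p = np.exp(logits) / np.exp(logits).sum(1, keepdims=True)
        lab = 1 + (rng.random(152) < p[:, 1]).astype(int)
        fit = multinomial_membership_model(lab, pd.DataFrame({"x": x}))
        coef = fit.coef_table.query("cluster == 2 and covariate == 'x'")["coef"].iloc[0]
        assert coef > 0 and fit.converged


def test_stratifier_end_to_end_renumbers_by_rate():
    rng = np.random.default_rng(10)
    centers = np.zeros((4, 20))
    for i in range(4):
        centers[i, i * 5:(i + 1) * 5] = 6.0
    truth = np.repeat(np.arange(4), 35)
    X = centers[truth] + rng.normal(0, 1, (140, 20))
    risks = np.array([0.05, 0.15, 0.3, 0.6])
    y = rng.random(140) < risks[truth]
    res = RiskStratifier(X, y, k_clusters=4, n_boot=300, seed=5).fit()
    rates = res.rates["rate"].to_numpy()
    assert np.all(np.diff(rates) >= 0)  # clusters numbered by ascending risk
    assert res.rates["n"].sum() == 140
    assert (res.rates["ci_low"] <= res.rates["rate"]).all()
    assert (res.rates["rate"] <= res.rates["ci_high"]).all()
    with pytest.raises(ConfigurationError):
        RiskStratifier(X[:3], y[:3]).fit()


def test_silhouette_diagnostic_peaks_at_planted_k():
    rng = np.random.default_rng(9)
    centers = np.array([[0, 0], [12, 0], [0, 12], [12, 12]])
    X = centers[np.repeat(np.arange(4), 25)] + rng.normal(0, 0.6, (100, 2))
    from gmltwin.risk import silhouette_k_diagnostic

    scores = silhouette_k_diagnostic(X, k_range=range(2, 7), seed=1)
    assert scores.idxmax() == 4
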