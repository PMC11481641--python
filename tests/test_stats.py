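"""Tests for the statistical stage, with independent brute-force oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from gwquality.indices import IndexResult, QualityBreakdown
from gwquality.stats import (
    count_by_rank,
    descriptive_summary,
    lda_two_group,
    rank_agreement,
    spearman,
    wilcoxon_signed_rank,
)


def _result(rank_wqs, rank_cds, year=2013, well="W01", wqi=0.0, cd=0.0,
            period="pre_sewerage"):
    return IndexResult(
        well_id=well, year=year, wqi=wqi, cd=cd,
        breakdown=QualityBreakdown(k=1.0, wn={}),
        rank_wqs=rank_wqs, wqs_label="", rank_cds=rank_cds, cds_label="",
        period=period,
    )


# ------------------------------------------------------------- summaries


class TestDescriptiveSummary:
    def test_symmetric_odd_length(self):
        frame = pd.DataFrame({"year": [2013] * 5, "v": [1, 2, 3, 4, 5]})
        row = descriptive_summary(frame, ["v"]).iloc[0]
        assert (row["min"], row["q25"], row["mean"], row["q75"], row["max"]) == (
            1, 2, 3, 4, 5
        )
        assert row["n"] == 5

    def test_constant_values_collapse(self):
        frame = pd.DataFrame({"year": [2013] * 4, "v": [2.5] * 4})
        row = descriptive_summary(frame, ["v"]).iloc[0]
        assert row["min"] == row["q25"] == row["mean"] == row["q75"] == row["max"]

    def test_interpolated_quartiles_match_order_statistic_formula(self):
        vals = [0.23, 0.25, 0.43, 0.87, 1.89]
        frame = pd.DataFrame({"year": [2013] * 5, "v": vals})
        row = descriptive_summary(frame, ["v"]).iloc[0]
        # inclusive convention: index h = (n-1)p interpolated between
        # order statistics
        srt = sorted(vals)

        def q(p):
            h = (len(srt) - 1) * p
            lo = math.floor(h)
            return srt[lo] + (h - lo) * (srt[lo + 1] - srt[lo])

        assert row["q25"] == pytest.approx(q(0.25))
        assert row["q75"] == pytest.approx(q(0.75))

    def test_missing_values_excluded_from_n(self):
        frame = pd.DataFrame({"year": [2013] * 3, "v": [1.0, np.nan, 3.0]})
        assert descriptive_summary(frame, ["v"]).iloc[0]["n"] == 2


# ------------------------------------------------------------- Spearman


def _brute_force_spearman(x, y):
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / math.sqrt((rx @ rx) * (ry @ ry)))


class TestSpearman:
    def test_identity_is_plus_one(self):
        x = [3.0, 1.0, 4.0, 1.5, 9.0]
        r = spearman(x, x, exact=False)
        assert r.rho == pytest.approx(1.0)

    def test_reversal_is_minus_one(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 9.0])
        order = np.argsort(x)
        y = np.empty_like(x)
        y[order] = np.sort(x)[::-1]
        assert spearman(x, y, exact=False).rho == pytest.approx(-1.0)

    def test_exact_permutation_matches_enumeration(self, rng):
        x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        y = [2.0, 1.0, 4.0, 4.0, 6.0, 5.0]  # one tie
        res = spearman(x, y)
        assert res.method == "exact-permutation"
        assert res.rho == pytest.approx(_brute_force_spearman(x, y))
        ry = sps.rankdata(y)
        obs = abs(_brute_force_spearman(x, y))
        hits = sum(
            abs(_brute_force_spearman(x, ry[list(p)])) >= obs - 1e-12
            for p in itertools.permutations(range(6))
        )
        assert res.p_value == pytest.approx(hits / math.factorial(6))

    def test_invariant_under_monotone_transforms(self, rng):
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        base = spearman(x, y, exact=False)
        warped = spearman(np.exp(x), y**3, exact=False)
        assert warped.rho == pytest.approx(base.rho)
        assert warped.p_value == pytest.approx(base.p_value)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


# ------------------------------------------------------------- Wilcoxon


def _enumerate_wilcoxon_p(ranks, w):
    """Oracle: two-tailed P(min(W+, W-) <= w) over all sign masks."""
    n = len(ranks)
    total = ranks.sum()
    count = 0
    for mask in itertools.product([0, 1], repeat=n):
        w_plus = sum(r for r, m in zip(ranks, mask) if m)
        if min(w_plus, total - w_plus) <= w + 1e-9:
            count += 1
    return count / 2**n


class TestWilcoxon:
    def test_five_uniform_improvements(self):
        pre = np.array([10.0, 12.0, 9.0, 14.0, 11.0])
        post = pre - np.array([1.0, 2.0, 0.5, 3.0, 1.5])
        res = wilcoxon_signed_rank(pre, post)
        assert res.method == "exact"
        assert res.w == 0.0
        assert res.p_value == pytest.approx(2 / 32)
        assert res.z < 0  # post lower -> negative Z

    def test_antisymmetric_differences_null(self):
        pre = np.array([0.0, 0.0, 0.0, 0.0])
        post = np.array([1.0, -1.0, 2.0, -2.0])
        res = wilcoxon_signed_rank(pre, post)
        assert res.z == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_zero_differences_dropped(self):
        pre = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        post = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 5.0])
        res = wilcoxon_signed_rank(pre, post)
        assert res.n_effective == 4

    def test_all_zero_differences_degenerate(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])

    @pytest.mark.parametrize("seed", range(12))
    def test_exact_branch_equals_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 13))
        pre = rng.normal(size=n)
        post = pre + rng.normal(loc=-0.5, size=n)
        res = wilcoxon_signed_rank(pre, post)
        assert res.method == "exact"
        d = (post - pre)[post - pre != 0]
        ranks = sps.rankdata(np.abs(d))
        assert res.p_value == pytest.approx(
            min(1.0, _enumerate_wilcoxon_p(ranks, res.w))
        )

    def test_scipy_agrees_on_tie_free_exact_case(self):
        rng = np.random.default_rng(99)
        pre = rng.normal(size=10)
        post = pre + rng.normal(loc=-0.8, size=10)
        ours = wilcoxon_signed_rank(pre, post)
        ref = sps.wilcoxon(post, pre, mode="exact")
        assert ours.p_value == pytest.approx(ref.pvalue)
        assert ours.w == pytest.approx(ref.statistic)

    def test_normal_approximation_close_to_exact_at_n12(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            pre = rng.normal(size=12)
            post = pre + rng.normal(loc=-0.6, size=12)
            exact = wilcoxon_signed_rank(pre, post)
            approx = wilcoxon_signed_rank(pre, post, exact_limit=0)
            assert approx.method == "normal-approximation"
            assert abs(exact.p_value - approx.p_value) < 0.02


# ------------------------------------------------------------- LDA


class TestDiscriminant:
    def _separated(self, rng, gap=10.0, n=30, p=3):
        x1 = rng.normal(size=(n, p))
        x2 = rng.normal(size=(n, p)) + gap
        x = np.vstack([x1, x2])
        labels = np.array(["a"] * n + ["b"] * n)
        return x, labels

    def test_perfect_separation(self, rng):
        x, labels = self._separated(rng)
        res = lda_two_group(x, labels, group_order=("a", "b"))
        assert res.pct_correct_original == 100.0
        assert res.pct_correct_loo == 100.0
        assert res.wilks_lambda < 0.05
        assert res.p_value < 1e-10

    def test_null_data_near_chance(self):
        accs = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            x, labels = self._separated(rng, gap=0.0)
            accs.append(lda_two_group(x, labels).pct_correct_loo)
        # LOO accuracy on pure noise: mean ~50%, slight pessimistic bias
        se = 100 * 0.5 / math.sqrt(60 * 30)
        assert abs(np.mean(accs) - 50.0) < 5 * se + 5.0

    def test_null_data_lambda_near_one(self, rng):
        x, labels = self._separated(rng, gap=0.0, n=200)
        assert lda_two_group(x, labels).wilks_lambda > 0.9

    def test_affine_invariance(self, rng):
        x, labels = self._separated(rng, gap=2.0)
        res = lda_two_group(x, labels, group_order=("a", "b"))
        a = rng.normal(size=(3, 3)) + 3 * np.eye(3)
        xt = x @ a.T + rng.normal(size=3)
        res_t = lda_two_group(xt, labels, group_order=("a", "b"))
        assert np.array_equal(res.confusion_original, res_t.confusion_original)
        assert np.array_equal(res.confusion_loo, res_t.confusion_loo)
        assert res.wilks_lambda == pytest.approx(res_t.wilks_lambda)

    def test_lambda_decreases_with_separation(self):
        lams = []
        for gap in (0.5, 1.0, 2.0, 4.0):
            rng = np.random.default_rng(123)
            x, labels = self._separated(rng, gap=gap)
            lams.append(lda_two_group(x, labels).wilks_lambda)
        assert lams == sorted(lams, reverse=True)

    def test_confusion_rows_sum_to_group_sizes(self, rng):
        x1 = rng.normal(size=(25, 4))
        x2 = rng.normal(size=(35, 4)) + 1.0
        x = np.vstack([x1, x2])
        labels = np.array(["g1"] * 25 + ["g2"] * 35)
        res = lda_two_group(x, labels, group_order=("g1", "g2"))
        assert res.confusion_original.sum(axis=1).tolist() == [25, 35]
        assert res.confusion_loo.sum(axis=1).tolist() == [25, 35]

    def test_matches_sklearn_predictions(self, rng):
        sklearn = pytest.importorskip("sklearn.discriminant_analysis")
        x, labels = self._separated(rng, gap=1.5, n=40, p=4)
        res = lda_two_group(x, labels, group_order=("a", "b"))
        clf = sklearn.LinearDiscriminantAnalysis(priors=[0.5, 0.5]).fit(x, labels)
        pred = clf.predict(x)
        conf = np.zeros((2, 2), dtype=int)
        for t, p_ in zip(labels, pred):
            conf[int(t == "b"), int(p_ == "b")] += 1
        assert np.array_equal(res.confusion_original, conf)

    def test_degenerate_inputs_rejected(self, rng):
        with pytest.raises(ValueError):
            lda_two_group(rng.normal(size=(4, 8)),
                          np.array(["a", "a", "b", "b"]))


# ------------------------------------------------------------- rank tables


class TestRankTables:
    def test_agreement_all_equal(self):
        results = [_result(r, r) for r in (1, 2, 3, 4, 5)]
        tab = rank_agreement(results)
        assert tab.counts[0] == 5
        assert tab.percentages[0] == 100.0
        assert tab.share_within_2 == 100.0

    def test_agreement_extremes(self):
        tab = rank_agreement([_result(1, 5), _result(5, 1)])
        assert tab.counts[-4] == 1 and tab.counts[4] == 1
        assert tab.share_within_2 == 0.0

    def test_agreement_hand_tally(self):
        pairs = [(1, 1), (2, 1), (1, 2), (3, 3), (5, 2), (4, 4), (2, 2),
                 (5, 5), (3, 2), (4, 5)]
        tab = rank_agreement([_result(a, b) for a, b in pairs])
        assert tab.n == 10
        assert tab.counts == {-4: 0, -3: 0, -2: 0, -1: 2, 0: 5, 1: 2, 2: 0,
                              3: 1, 4: 0}
        assert sum(tab.percentages.values()) == pytest.approx(100.0)
        assert tab.share_within_2 == pytest.approx(90.0)

    def test_agreement_empty_rejected(self):
        with pytest.raises(ValueError):
            rank_agreement([])

    def test_count_by_rank_single_rank(self):
        results = [_result(5, 5, year=2013) for _ in range(7)]
        tab = count_by_rank(results, "wqs")
        assert tab.loc[2013].tolist() == [7, 0, 0, 0, 0, 7]

    def test_count_by_rank_empty_year_zero_row(self):
        results = [_result(2, 2, year=2013)]
        tab = count_by_rank(results, "wqs", years=[2013, 2020])
        assert tab.loc[2020].tolist() == [0, 0, 0, 0, 0, 0]

    def test_row_sums_match_study_shape(self):
        from gwquality.pipeline import compute_dataset_indices
        from gwquality.io import MonitoringDataset
        from gwquality.synthetic import barand_like_config, simulate_dataset

        samples = simulate_dataset(barand_like_config(seed=4))
        results = compute_dataset_indices(MonitoringDataset(samples))
        tab = count_by_rank(results, "cds")
        assert tab["n"].tolist() == [40, 40, 40, 40, 37, 34]
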