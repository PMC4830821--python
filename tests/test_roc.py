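"""ROC construction, cutoff selection and diagnostic arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import panelroc as pr
from panelroc.errors import DegenerateInputError, InvalidArgumentError

from conftest import two_group_values


def auc_pair_counting(cases, controls):
    """Brute-force oracle: (concordant + 0.5 * tied) / (n1 * n2)."""
    total = 0.0
    for c in cases:
        for k in controls:
            total += 1.0 if c > k else (0.5 if c == k else 0.0)
    return total / (len(cases) * len(controls))


class TestEmpiricalROC:
    def test_perfect_separation(self):
        curve = pr.empirical_roc([3, 4, 1, 2], [1, 1, 0, 0], "high_abnormal")
        assert curve.auc() == pytest.approx(1.0)

    def test_total_ties_give_half(self):
        curve = pr.empirical_roc([5.0] * 8, [1, 1, 1, 1, 0, 0, 0, 0])
        assert curve.auc() == pytest.approx(0.5)

    def test_endpoints_present(self, rng):
        v, y = two_group_values(rng, ties=True)
        curve = pr.empirical_roc(v, y)
        assert (curve.sens[0], curve.spec[0]) == (1.0, 0.0)
        assert (curve.sens[-1], curve.spec[-1]) == (0.0, 1.0)

    @pytest.mark.parametrize("ties", [False, True])
    @pytest.mark.parametrize("seed", range(10))
    def test_auc_equals_pair_counting_oracle(self, seed, ties):
        r = np.random.default_rng(seed)
        n1, n2 = r.integers(2, 26, size=2)
        v, y = two_group_values(r, int(n1), int(n2), shift=0.4, ties=ties)
        curve = pr.empirical_roc(v, y)
        expected = auc_pair_counting(v[y == 1], v[y == 0])
        assert curve.auc() == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_direction_flip_maps_auc_to_complement(self, seed):
        r = np.random.default_rng(seed)
        v, y = two_group_values(r, shift=0.8, ties=True)
        hi = pr.empirical_roc(v, y, "high_abnormal").auc()
        lo = pr.empirical_roc(v, y, "low_abnormal").auc()
        assert hi + lo == pytest.approx(1.0, abs=1e-12)

    def test_missing_excluded_pairwise(self):
        v = [np.nan, 3, 4, 1, 2, np.nan]
        y = [1, 1, 1, 0, 0, 0]
        curve = pr.empirical_roc(v, y)
        assert (curve.n_cases, curve.n_controls) == (2, 2)
        assert curve.auc() == pytest.approx(1.0)

    def test_single_class_raises(self):
        with pytest.raises(DegenerateInputError):
            pr.empirical_roc([1.0, 2.0], [1, 1])


class TestAUCPValue:
    def test_null_auc_gives_p_near_one(self):
        v = [1, 2, 3, 4, 1, 2, 3, 4]
        y = [1, 1, 1, 1, 0, 0, 0, 0]
        auc, p = pr.auc_with_pvalue(pr.empirical_roc(v, y))
        assert auc == pytest.approx(0.5)
        assert p == pytest.approx(1.0)

    def test_perfect_separation_highly_significant(self, rng):
        v = np.concatenate([rng.normal(10, 1, 20), rng.normal(0, 1, 20)])
        y = np.r_[np.ones(20, int), np.zeros(20, int)]
        _, p = pr.auc_with_pvalue(pr.empirical_roc(v, y))
        assert p < 1e-4

    def test_type_one_error_near_nominal(self):
        """Under the null the 5% test should reject ~5% of the time."""
        r = np.random.default_rng(7)
        y = np.r_[np.ones(50, int), np.zeros(50, int)]
        rejections = 0
        for _ in range(2000):
            _, p = pr.auc_with_pvalue(pr.empirical_roc(r.standard_normal(100), y))
            rejections += p < 0.05
        assert 0.035 <= rejections / 2000 <= 0.065


class TestCutoffSelection:
    def test_toy_perfect_cutoff(self):
        curve = pr.empirical_roc([3, 4, 1, 2], [1, 1, 0, 0])
        cutoff, sens, spec = pr.select_cutoff(curve)
        assert (cutoff, sens, spec) == (2.5, 1.0, 1.0)

    def test_overlapping_distributions_have_small_j(self):
        v = np.tile(np.arange(10.0), 2)
        y = np.r_[np.ones(10, int), np.zeros(10, int)]
        _, sens, spec = pr.select_cutoff(pr.empirical_roc(v, y))
        assert sens + spec - 1.0 == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_youden_matches_exhaustive_scan(self, seed):
        r = np.random.default_rng(seed)
        v, y = two_group_values(r, 30, 30, shift=0.7, ties=True)
        curve = pr.empirical_roc(v, y)
        _, sens, spec = pr.select_cutoff(curve)
        best_j = max(
            s + sp - 1.0 for s, sp in zip(curve.sens, curve.spec)
        )
        assert sens + spec - 1.0 == pytest.approx(best_j, abs=1e-12)

    def test_cutoff_is_midpoint_of_observed_values(self, rng):
        v, y = two_group_values(rng, 15, 15, shift=1.0)
        cutoff, _, _ = pr.select_cutoff(pr.empirical_roc(v, y))
        uniq = np.unique(v)
        mids = (uniq[:-1] + uniq[1:]) / 2
        assert np.isinf(cutoff) or np.any(np.isclose(mids, cutoff))


class TestDiagnosticOddsRatio:
    def test_uninformative(self):
        assert pr.diagnostic_odds_ratio(0.5, 0.5) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "sens,spec,published",
        [(0.900, 0.552, 11.1), (0.697, 0.642, 4.12)],
    )
    def test_published_marker_rows(self, sens, spec, published):
        assert pr.diagnostic_odds_ratio(sens, spec) == pytest.approx(
            published, rel=5e-3
        )

    def test_boundaries(self):
        assert pr.diagnostic_odds_ratio(1.0, 0.8) == np.inf
        assert pr.diagnostic_odds_ratio(0.0, 0.8) == 0.0

    def test_haldane_correction_is_finite_at_boundary(self):
        dor = pr.diagnostic_odds_ratio(1.0, 0.9, counts=(10, 0, 9, 1), haldane=True)
        assert np.isfinite(dor) and dor > 1

    def test_out_of_range(self):
        with pytest.raises(InvalidArgumentError):
            pr.diagnostic_odds_ratio(1.2, 0.5)


class TestPredictiveValues:
    def test_perfect_test(self):
        assert pr.predictive_values(1.0, 1.0, 0.1) == (1.0, 1.0)

    @pytest.mark.parametrize(
        "sens,spec,prev,ppv,npv",
        [(12 / 13, 12 / 13, 0.30, 0.837, 0.966), (11 / 14, 13 / 14, 0.0035, 0.037, 0.999)],
    )
    def test_published_fold_rows(self, sens, spec, prev, ppv, npv):
        got_ppv, got_npv = pr.predictive_values(sens, spec, prev)
        assert got_ppv == pytest.approx(ppv, abs=5e-4)
        assert got_npv == pytest.approx(npv, abs=5e-4)

    def test_monotone_in_prevalence(self):
        grid = np.linspace(0.01, 0.99, 25)
        ppv = [pr.predictive_values(0.8, 0.9, p)[0] for p in grid]
        npv = [pr.predictive_values(0.8, 0.9, p)[1] for p in grid]
        assert np.all(np.diff(ppv) > 0) and np.all(np.diff(npv) < 0)

    def test_sample_prevalence_reproduces_two_by_two_table(self, rng):
        v, y = two_group_values(rng, 40, 60, shift=1.2)
        res = pr.roc_result(v, y)
        pred = (v > res.cutoff).astype(int)
        tp = ((pred == 1) & (y == 1)).sum()
        fp = ((pred == 1) & (y == 0)).sum()
        tn = ((pred == 0) & (y == 0)).sum()
        fn = ((pred == 0) & (y == 1)).sum()
        pi = y.mean()
        ppv, npv = pr.predictive_values(res.sensitivity, res.specificity, pi)
        assert ppv == pytest.approx(tp / (tp + fp))
        assert npv == pytest.approx(tn / (tn + fn))

    def test_prevalence_out_of_range(self):
        with pytest.raises(InvalidArgumentError):
            pr.predictive_values(0.8, 0.9, 0.0)


class TestAccuracyAndSpearman:
    def test_accuracy_extremes_and_counting(self, rng):
        y = rng.integers(0, 2, 50)
        assert pr.accuracy_index(y, y) == 1.0
        assert pr.accuracy_index(1 - y, y) == 0.0
        pred = rng.integers(0, 2, 50)
        assert pr.accuracy_index(pred, y) == pytest.approx(
            sum(int(a == b) for a, b in zip(pred, y)) / 50
        )

    def test_spearman_extremes(self):
        x = np.arange(10.0)
        assert pr.spearman_rho(x, x**3)[0] == pytest.approx(1.0)
        assert pr.spearman_rho(x, -x)[0] == pytest.approx(-1.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_spearman_matches_midrank_pearson_with_ties(self, seed):
        r = np.random.default_rng(seed)
        x = r.integers(0, 5, 30).astype(float)
        y = r.integers(0, 5, 30).astype(float)
        if np.unique(x).size < 2 or np.unique(y).size < 2:
            pytest.skip("degenerate draw")
        rho, p = pr.spearman_rho(x, y)
        ref_rho, ref_p = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref_rho, abs=1e-12)
        assert p == pytest.approx(ref_p, abs=1e-9)

    def test_spearman_needs_three_pairs(self):
        with pytest.raises(DegenerateInputError):
            pr.spearman_rho([1, 2], [2, 1])


class TestROCProperties:
    """Randomised invariants over arbitrary tied/untied instances."""

    values_strategy = st.lists(
        st.integers(min_value=-5, max_value=5), min_size=2, max_size=50
    )

    @given(
        case_vals=values_strategy,
        ctrl_vals=values_strategy,
    )
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_auc_rank_sum_identity_and_flip(self, case_vals, ctrl_vals):
        v = np.array(case_vals + ctrl_vals, dtype=float)
        y = np.r_[np.ones(len(case_vals), int), np.zeros(len(ctrl_vals), int)]
        curve = pr.empirical_roc(v, y)
        assert curve.auc() == pytest.approx(
            auc_pair_counting(v[y == 1], v[y == 0]), abs=1e-12
        )
        flipped = pr.empirical_roc(v, y, "low_abnormal")
        assert curve.auc() + flipped.auc() == pytest.approx(1.0, abs=1e-12)

    @given(
        sens=st.floats(0.01, 0.99),
        spec=st.floats(0.01, 0.99),
        p1=st.floats(0.01, 0.98),
        dp=st.floats(0.001, 0.99),
    )
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_dor_prevalence_free_ppv_npv_monotone(self, sens, spec, p1, dp):
        p2 = min(p1 + dp, 0.999)
        dor = pr.diagnostic_odds_ratio(sens, spec)
        assert dor == pr.diagnostic_odds_ratio(sens, spec)  # no prevalence input
        ppv1, npv1 = pr.predictive_values(sens, spec, p1)
        ppv2, npv2 = pr.predictive_values(sens, spec, p2)
        assert ppv2 >= ppv1 - 1e-12
        assert npv2 <= npv1 + 1e-12
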