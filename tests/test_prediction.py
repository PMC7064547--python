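"""Tests for the classifier comparison machinery."""

import numpy as np
import pytest
from scipy.stats import binom

from gglearn.errors import DataError, DegenerateInputError, StratificationError
from gglearn.prediction import (
    CVConfig,
    binomial_vs_chance,
    compare_predictors,
    cv_elastic_net,
    delong_compare,
    dichotomize_dgi,
    roc_and_auc,
)


def pair_counting_auc(scores, labels):
    """O(n^2) Mann-Whitney oracle: concordant pairs + half ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (pos.size * neg.size)


class TestDichotomize:
    def test_tie_goes_low(self):
        labels, info = dichotomize_dgi([10, 20, 30])
        assert labels.tolist() == [0, 0, 1]
        assert info["median"] == 20

    def test_all_identical_rejected(self):
        with pytest.raises(DegenerateInputError):
            dichotomize_dgi([5, 5, 5])

    def test_balance_reported(self):
        labels, info = dichotomize_dgi([1, 2, 3, 4])
        assert info["n_above"] + info["n_at_or_below"] == 4


class TestBinomial:
    def test_at_chance(self):
        assert binomial_vs_chance(37, 74) == pytest.approx(1.0, abs=0.05)

    def test_perfect_closed_form(self):
        assert binomial_vs_chance(74, 74) == pytest.approx(2 * 0.5**74, rel=1e-9)

    def test_direct_summation_oracle(self):
        # two-sided exact: sum pmf over outcomes no more probable than 48
        pm = binom.pmf(np.arange(75), 74, 0.5)
        expected = pm[pm <= pm[48] * (1 + 1e-12)].sum()
        assert binomial_vs_chance(48, 74) == pytest.approx(expected, rel=1e-9)

    def test_errors(self):
        with pytest.raises(DataError):
            binomial_vs_chance(1, 0)
        with pytest.raises(DataError):
            binomial_vs_chance(5, 4)


class TestRocAuc:
    def test_four_point_example(self):
        *_, auc = roc_and_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert auc == 0.75

    def test_perfect_separation(self):
        *_, auc = roc_and_auc([0, 0, 1, 1], [0, 0, 1, 1])
        assert auc == 1.0

    def test_random_scores_near_half(self, rng):
        scores = rng.random(4000)
        labels = rng.integers(0, 2, 4000)
        *_, auc = roc_and_auc(scores, labels)
        assert auc == pytest.approx(0.5, abs=0.03)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_equals_pair_counting_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        scores = np.round(rng.random(60), 1)  # induce ties
        labels = rng.integers(0, 2, 60)
        fpr, tpr, _, auc = roc_and_auc(scores, labels)
        assert auc == pytest.approx(pair_counting_auc(scores, labels), abs=1e-12)
        assert fpr[0] == tpr[0] == 0.0 and fpr[-1] == tpr[-1] == 1.0
        assert np.all(np.diff(fpr) >= 0) and np.all(np.diff(tpr) >= 0)

    def test_monotone_transform_invariance(self, rng):
        scores = rng.normal(size=100)
        labels = rng.integers(0, 2, 100)
        *_, a = roc_and_auc(scores, labels)
        *_, b = roc_and_auc(np.exp(2 * scores), labels)
        assert a == pytest.approx(b, abs=1e-12)

    def test_one_class_rejected(self):
        with pytest.raises(DegenerateInputError):
            roc_and_auc([0.1, 0.2], [1, 1])


class TestDeLong:
    def test_identical_scores_degenerate(self):
        r = delong_compare([0.1, 0.4, 0.35, 0.8], [0.1, 0.4, 0.35, 0.8],
                           [0, 0, 1, 1])
        assert r.difference == 0.0 and r.degenerate and r.p_value == 1.0

    def test_variance_matches_bruteforce_oracle(self, rng):
        labels = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 1])
        sa, sb = rng.normal(size=10), rng.normal(size=10)
        r = delong_compare(sa, sb, labels)
        # oracle: explicit loops over placement values, then the
        # structural-components covariance estimator
        def placements(s):
            pos = s[labels == 1]; neg = s[labels == 0]
            v10 = np.array([np.mean([(1.0 if p > q else 0.5 if p == q else 0.0)
                                     for q in neg]) for p in pos])
            v01 = np.array([np.mean([(1.0 if p > q else 0.5 if p == q else 0.0)
                                     for p in pos]) for q in neg])
            return v10, v01
        va10, va01 = placements(sa)
        vb10, vb01 = placements(sb)
        var = (np.var(va10 - vb10, ddof=1) / va10.size
               + np.var(va01 - vb01, ddof=1) / va01.size)
        assert r.variance == pytest.approx(var, abs=1e-10)
        assert r.auc_a == pytest.approx(va10.mean(), abs=1e-12)

    def test_sidedness(self, rng):
        labels = rng.integers(0, 2, 100)
        labels[:2] = [0, 1]
        sa, sb = rng.normal(size=100), rng.normal(size=100)
        g = delong_compare(sa, sb, labels, "greater")
        l = delong_compare(sa, sb, labels, "less")
        t = delong_compare(sa, sb, labels, "two-sided")
        assert g.p_value + l.p_value == pytest.approx(1.0, abs=1e-12)
        assert t.p_value == pytest.approx(2 * min(g.p_value, l.p_value), abs=1e-12)


class TestCvElasticNet:
    def test_positive_control_separable(self, light_cv):
        rng = np.random.default_rng(2)
        y = np.array([0, 1] * 37)
        X = np.column_stack([y + 0.01 * rng.normal(size=74),
                             rng.normal(size=74)])
        ev = cv_elastic_net(X, y, light_cv)
        assert ev.accuracy >= 0.95
        assert ev.auc >= 0.99

    def test_seed_reproducible(self, light_cv, rng):
        X = rng.normal(size=(40, 3))
        y = np.array([0, 1] * 20)
        a = cv_elastic_net(X, y, light_cv)
        b = cv_elastic_net(X, y, light_cv)
        assert np.array_equal(a.scores, b.scores)
        assert a.accuracy == b.accuracy

    def test_stratification_guard(self, rng):
        X = rng.normal(size=(20, 2))
        y = np.array([1, 1, 1] + [0] * 17)
        with pytest.raises(StratificationError):
            cv_elastic_net(X, y, CVConfig(n_folds=5, n_repeats=1))

    def test_single_predictor_skips_penalty_search(self, light_cv, rng):
        x = rng.normal(size=60)
        y = (x + rng.normal(size=60) > 0).astype(int)
        ev = cv_elastic_net(x, y, light_cv)
        assert set(ev.diagnostics["chosen_C"]) == {1e6}
        assert ev.accuracy > 0.6


class TestComparePredictors:
    def _cohort_arrays(self, default_cohort):
        truth = default_cohort.truth
        wide = truth.pivot(index="patient_id", columns="stage",
                           values=["beta", "gamma", "tbar"])
        X = np.column_stack([wide[(p, s)].to_numpy()
                             for p in ("beta", "gamma", "tbar")
                             for s in (1, 2, 3)])
        clin = default_cohort.clinical
        return X, clin["moca_total"].to_numpy(), clin["dgi_total"].to_numpy()

    def test_fold_identity_and_report(self, default_cohort, light_cv):
        X, moca, dgi = self._cohort_arrays(default_cohort)
        rep = compare_predictors(X, moca, dgi, light_cv)
        assert np.array_equal(rep.gg.fold_assignments, rep.moca.fold_assignments)
        assert rep.delong.alternative == "greater"
        assert 0 <= rep.gg.accuracy <= 1 and 0 <= rep.moca.accuracy <= 1

    def test_robust_to_single_patient_removal(self, default_cohort, light_cv):
        X, moca, dgi = self._cohort_arrays(default_cohort)
        rep = compare_predictors(X[1:], moca[1:], dgi[1:], light_cv)
        assert rep.gg.n == 73
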