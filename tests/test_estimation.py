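"""Tests for the grid-quadrature posterior fitter and feature assembly."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from gglearn.errors import DataError
from gglearn.estimation import (
    FEATURE_COLUMNS,
    PriorConfig,
    QuadratureConfig,
    StageSeries,
    extract_features,
    fit_cohort,
    fit_stage,
    fit_stage_batch,
)
from gglearn.model import LearningCurveParams, simulate_stage


def oracle_posterior_means(outcomes, beta_scale=2.0, beta_max=8.0, n=200):
    """Independent brute-force quadrature: formulas re-derived inline."""
    outcomes = np.asarray(outcomes, dtype=float)
    beta = (np.arange(n) + 0.5) * beta_max / n
    gamma = 1 / 3 + (np.arange(n) + 0.5) * (2 / 3) / n
    B, G = np.meshgrid(beta, gamma, indexing="ij")
    post = np.exp(-0.5 * (B / beta_scale) ** 2)  # prior; gamma uniform
    for t, x in enumerate(outcomes, start=1):
        lam = (t - 1) * B - np.log(3 * G - 1)
        p = G / (1 + np.exp(-lam))
        post = post * np.where(x == 1, p, 1 - p)
    post = post / post.sum()
    return float((post * B).sum()), float((post * G).sum())


def make_series(outcomes, stage=2, pid="p1"):
    outcomes = np.asarray(outcomes)
    return StageSeries(pid, stage, outcomes, np.ones(outcomes.size))


class TestFitStage:
    @pytest.mark.parametrize("seed,T,beta,gamma", [
        (0, 20, 1.76, 0.64), (1, 50, 0.5, 0.9), (2, 100, 3.0, 0.5),
    ])
    def test_matches_quadrature_oracle(self, seed, T, beta, gamma):
        x = simulate_stage(LearningCurveParams(beta, gamma), T, seed=seed)
        fit = fit_stage(make_series(x))
        b_star, g_star = oracle_posterior_means(x)
        assert fit.beta_hat == pytest.approx(b_star, abs=0.01)
        assert fit.gamma_hat == pytest.approx(g_star, abs=0.01)

    def test_all_failures_weakly_identified(self):
        fit = fit_stage(make_series(np.zeros(20, dtype=int)))
        b_star, g_star = oracle_posterior_means(np.zeros(20))
        assert fit.gamma_hat == pytest.approx(g_star, abs=0.01)
        # posterior pulled toward the chance boundary, interval wide
        assert fit.gamma_hat < 0.5
        assert fit.diagnostics["gamma_interval_width"] > 0.2
        assert (fit.diagnostics["weak_identification_beta"]
                or fit.diagnostics["weak_identification_gamma"])

    def test_interval_contains_point_estimate(self):
        x = simulate_stage(LearningCurveParams(1.76, 0.64), 30, seed=3)
        fit = fit_stage(make_series(x))
        assert fit.beta_interval[0] <= fit.beta_hat <= fit.beta_interval[1]
        assert fit.gamma_interval[0] <= fit.gamma_hat <= fit.gamma_interval[1]
        assert 1 / 3 < fit.gamma_hat <= 1.0

    def test_empty_series_rejected(self):
        with pytest.raises(DataError):
            fit_stage(make_series(np.zeros(0, dtype=int)))

    def test_deterministic(self):
        x = simulate_stage(LearningCurveParams(1.0, 0.7), 25, seed=8)
        a, b = fit_stage(make_series(x)), fit_stage(make_series(x))
        assert a.beta_hat == b.beta_hat and a.gamma_hat == b.gamma_hat
        assert a.gamma_interval == b.gamma_interval

    def test_recovery_improves_with_length(self, coarse_quad):
        rng = np.random.default_rng(17)
        true = LearningCurveParams(1.76, 0.64)
        errs = []
        for T in (20, 100, 500):
            X = np.stack([simulate_stage(true, T, rng) for _ in range(40)])
            fits = fit_stage_batch(X, quad=coarse_quad)
            errs.append(np.mean([abs(f.gamma_hat - 0.64) for f in fits]))
        assert errs[0] > errs[1] > errs[2]

    def test_batch_agrees_with_single(self):
        rng = np.random.default_rng(4)
        X = np.stack([simulate_stage(LearningCurveParams(1.5, 0.7), 15, rng)
                      for _ in range(5)])
        batch = fit_stage_batch(X)
        for row, summ in zip(X, batch):
            single = fit_stage(make_series(row))
            assert single.gamma_hat == pytest.approx(summ.gamma_hat, abs=1e-12)


class TestExtractFeatures:
    def _patient(self, rng, c=2.5):
        out = []
        for stage, T in ((1, 5), (2, 20), (3, 5)):
            x = simulate_stage(LearningCurveParams(1.8, 0.7), T, rng)
            out.append(StageSeries("p1", stage, x, np.full(T, c)))
        return out

    def test_tbar_is_plain_mean(self, rng, coarse_quad):
        fv = extract_features(self._patient(rng, c=2.5), quad=coarse_quad)
        assert fv.tbar1 == fv.tbar2 == fv.tbar3 == 2.5
        assert fv.to_array().shape == (9,)

    def test_missing_stage_named_in_error(self, rng, coarse_quad):
        series = self._patient(rng)[:2]
        with pytest.raises(DataError, match="stage 3"):
            extract_features(series, quad=coarse_quad)


class TestFitCohort:
    def _trials(self, n_patients, rng):
        rows = []
        for i in range(n_patients):
            for stage, T in ((1, 5), (2, 20), (3, 5)):
                x = simulate_stage(LearningCurveParams(1.8, 0.7), T, rng)
                for t in range(T):
                    rows.append((f"P{i:03d}", stage, t + 1, int(x[t]), 1.0))
        return pd.DataFrame(rows, columns=[
            "patient_id", "stage", "trial_index", "outcome", "response_time_s"])

    def test_shape_contract(self, rng, coarse_quad):
        feats, diag = fit_cohort(self._trials(8, rng), quad=coarse_quad)
        assert feats.shape == (8, 10)
        assert list(feats.columns) == ["patient_id", *FEATURE_COLUMNS]
        assert (diag["status"] == "ok").all()

    def test_duplicate_keys_rejected(self, rng, coarse_quad):
        t = self._trials(2, rng)
        dup = pd.concat([t, t.iloc[[0]]], ignore_index=True)
        with pytest.raises(DataError, match="duplicate"):
            fit_cohort(dup, quad=coarse_quad)

    def test_invalid_stage_named(self, rng, coarse_quad):
        t = self._trials(2, rng)
        t.loc[3, "stage"] = 4
        with pytest.raises(DataError, match="stage"):
            fit_cohort(t, quad=coarse_quad)

    def test_missing_stage_skipped_not_fatal(self, rng, coarse_quad):
        t = self._trials(3, rng)
        t = t[~((t.patient_id == "P001") & (t.stage == 2))]
        feats, diag = fit_cohort(t, quad=coarse_quad)
        assert len(feats) == 2
        skipped = diag[diag["status"].str.startswith("skipped")]
        assert list(skipped["patient_id"]) == ["P001"]

    def test_empty_table_warns(self, coarse_quad):
        with pytest.warns(UserWarning):
            feats, _ = fit_cohort(pd.DataFrame(), quad=coarse_quad)
        assert feats.empty


def test_point_estimate_alternatives():
    """Median and mode point estimates are selectable and coherent."""
    x = simulate_stage(LearningCurveParams(1.76, 0.64), 100, seed=31)
    fits = {how: fit_stage(make_series(x),
                           quad=QuadratureConfig(point_estimate=how))
            for how in ("mean", "median", "mode")}
    ghats = {how: f.gamma_hat for how, f in fits.items()}
    # all three agree within the posterior spread for a well-identified fit
    width = fits["mean"].diagnostics["gamma_interval_width"]
    assert max(ghats.values()) - min(ghats.values()) < width / 2
    assert len({round(v, 6) for v in ghats.values()}) >= 2  # not aliases
    with pytest.raises(DataError):
        QuadratureConfig(point_estimate="midpoint")


def test_unconstrained_beta_sensitivity_fit():
    """With the sensitivity prior a forgetting curve gets a negative
    beta estimate; the default prior cannot represent it."""
    forget = LearningCurveParams(-0.4, 0.9, allow_negative_beta=True)
    x = simulate_stage(forget, 60, seed=13)
    series = make_series(x)
    wide = fit_stage(series, prior=PriorConfig(allow_negative_beta=True))
    constrained = fit_stage(series)
    assert wide.beta_hat < 0
    assert constrained.beta_hat >= 0


def test_credible_interval_calibration(coarse_quad):
    """90% intervals cover the truth for ~90% of simulated series."""
    rng = np.random.default_rng(29)
    true = LearningCurveParams(1.76, 0.64)
    X = np.stack([simulate_stage(true, 100, rng) for _ in range(200)])
    fits = fit_stage_batch(X, quad=coarse_quad)
    cover = np.mean([f.gamma_interval[0] <= 0.64 <= f.gamma_interval[1] for f in fits])
    assert 0.85 <= cover <= 0.95
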