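"""Synthetic cohort generator with known ground truth.

Emulates the data-generating structure the analysis assumes: a cohort of
Parkinson's-disease patients (default n=74) each playing the three
Goalkeeper Game stages (5 / 20 / 5 trials), with per-patient, per-stage
learning-curve parameters drawn from population distributions calibrated
to match published cohort-level means and standard deviations, lognormal
per-trial response times, and clinical scores tied to the game through a
single latent trait:

    z = sum_k w_k * standardized(true feature k) + noise

DGI (0-24) is produced by thresholding the standardized z into 25
ordered categories -- a proportional-odds construction, coherent with
the downstream ordinal analysis.  MoCA (truncated at >= 21 to mirror the
study's no-dementia inclusion rule) shares a weak dependence on z.  The
default link weights are calibrated so that the latent correlation of
the memory-stage asymptote gamma_3 with DGI is 0.39 and of MoCA with DGI
is 0.20, with secondary weights on gamma_1, tbar_1 and tbar_3 matching
the moderately associated variables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import root
from scipy.special import expit, logit
from scipy.stats import norm

from .errors import CalibrationError, ConfigError
from .model import LearningCurveParams, simulate_stage

__all__ = [
    "StagePopulation",
    "TimeModel",
    "CohortConfig",
    "SyntheticCohort",
    "generate_cohort",
    "calibrate_link",
    "null_config",
    "config_to_dict",
    "DEFAULT_CORRELATION_TARGETS",
    "DEFAULT_MOCA_TARGET",
]

_GAMMA_MIN = 1.0 / 3.0

#: Latent correlations with DGI targeted by the default link weights.
DEFAULT_CORRELATION_TARGETS = {
    "gamma3": 0.39,
    "gamma1": 0.24,
    "tbar1": -0.23,
    "tbar3": -0.24,
}
#: Latent MoCA-DGI correlation targeted by the default MoCA link.
DEFAULT_MOCA_TARGET = 0.20

# cohort-level (mean, sd) of the estimated parameters the populations
# are calibrated to reproduce, per stage 1..3
_BETA_MOMENTS = [(1.74, 0.53), (1.76, 0.38), (2.00, 0.37)]
_GAMMA_MOMENTS = [(0.68, 0.16), (0.64, 0.14), (0.78, 0.18)]
_TBAR_MEDIANS = [4.47, 3.28, 2.52]

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite_e.hermegauss(81)
_GH_WEIGHTS = _GH_WEIGHTS / np.sqrt(2.0 * np.pi)


def _gamma_from_latent(v: np.ndarray) -> np.ndarray:
    return _GAMMA_MIN + (1.0 - _GAMMA_MIN) * expit(v)


def _logitnormal_moments(mu: float, sigma: float) -> tuple[float, float]:
    """Mean and sd of gamma = 1/3 + (2/3) expit(N(mu, sigma))."""
    g = _gamma_from_latent(mu + sigma * _GH_NODES)
    m = float(np.dot(_GH_WEIGHTS, g))
    v = float(np.dot(_GH_WEIGHTS, (g - m) ** 2))
    return m, np.sqrt(v)


def _calibrate_logitnormal(target_mean: float, target_sd: float) -> tuple[float, float]:
    """Solve for (mu, sigma) of the latent normal matching gamma moments."""
    if not _GAMMA_MIN < target_mean < 1.0:
        raise ConfigError(f"gamma mean must be in (1/3, 1), got {target_mean}")
    p = (target_mean - _GAMMA_MIN) / (1.0 - _GAMMA_MIN)
    x0 = np.array([logit(p), target_sd / ((1.0 - _GAMMA_MIN) * p * (1.0 - p))])

    def eqs(x):
        m, s = _logitnormal_moments(x[0], abs(x[1]))
        return [m - target_mean, s - target_sd]

    sol = root(eqs, x0, method="hybr", tol=1e-12)
    if not sol.success:
        raise ConfigError(
            f"could not calibrate gamma population to mean={target_mean}, "
            f"sd={target_sd}: {sol.message}"
        )
    return float(sol.x[0]), float(abs(sol.x[1]))


def _lognormal_from_moments(mean: float, sd: float) -> tuple[float, float]:
    if mean <= 0 or sd <= 0:
        raise ConfigError("lognormal moments must be positive")
    s2 = np.log1p((sd / mean) ** 2)
    return float(np.log(mean) - s2 / 2.0), float(np.sqrt(s2))


@dataclass(frozen=True)
class StagePopulation:
    """Population distribution of (beta, gamma) for one stage.

    beta is lognormal (log-scale mean/sd ``beta_mu``, ``beta_sigma``);
    gamma is a shifted-scaled logit-normal supported on (1/3, 1).
    """

    beta_mu: float
    beta_sigma: float
    gamma_mu: float
    gamma_sigma: float

    @classmethod
    def from_moments(cls, beta_mean, beta_sd, gamma_mean, gamma_sd) -> "StagePopulation":
        bm, bs = _lognormal_from_moments(beta_mean, beta_sd)
        gm, gs = _calibrate_logitnormal(gamma_mean, gamma_sd)
        return cls(bm, bs, gm, gs)

    def moments(self) -> dict[str, float]:
        """Model-implied (mean, sd) of beta and gamma."""
        b_mean = np.exp(self.beta_mu + self.beta_sigma**2 / 2.0)
        b_sd = b_mean * np.sqrt(np.expm1(self.beta_sigma**2))
        g_mean, g_sd = _logitnormal_moments(self.gamma_mu, self.gamma_sigma)
        return {"beta_mean": float(b_mean), "beta_sd": float(b_sd),
                "gamma_mean": g_mean, "gamma_sd": g_sd}

    def draw(self, n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        beta = np.exp(rng.normal(self.beta_mu, self.beta_sigma, size=n))
        gamma = _gamma_from_latent(rng.normal(self.gamma_mu, self.gamma_sigma, size=n))
        return beta, gamma


@dataclass(frozen=True)
class TimeModel:
    """Lognormal per-trial response times; median = exp(mu) seconds."""

    mu: float
    sigma: float = 1.0

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return np.exp(rng.normal(self.mu, self.sigma, size=n))

    def tbar_moments(self, n_trials: int) -> tuple[float, float]:
        """Mean and sd of the average of ``n_trials`` iid draws."""
        m = np.exp(self.mu + self.sigma**2 / 2.0)
        v = np.expm1(self.sigma**2) * m**2 / n_trials
        return float(m), float(np.sqrt(v))


def _default_populations() -> tuple[StagePopulation, ...]:
    return tuple(
        StagePopulation.from_moments(bm, bs, gm, gs)
        for (bm, bs), (gm, gs) in zip(_BETA_MOMENTS, _GAMMA_MOMENTS)
    )


def _default_time_models() -> tuple[TimeModel, ...]:
    return tuple(TimeModel(mu=float(np.log(med)), sigma=1.0) for med in _TBAR_MEDIANS)


def calibrate_link(
    targets: dict[str, float],
    noise_sd: float = 1.0,
) -> dict[str, float]:
    """Link weights achieving the requested latent feature-DGI correlations.

    With ``z = sum_k w_k f~_k + noise_sd * eps`` over standardized,
    mutually independent true features, ``corr(f_k, z) = w_k / sd(z)``,
    which inverts in closed form:

        w_k = r_k * noise_sd / sqrt(1 - sum_j r_j^2)

    Raises :class:`CalibrationError` when the targets are jointly
    infeasible (sum of squared correlations >= 1) or individually
    outside (-1, 1).
    """
    valid = {f"{p}{s}" for p in ("beta", "gamma", "tbar") for s in (1, 2, 3)}
    unknown = set(targets) - valid
    if unknown:
        raise CalibrationError(f"unknown feature names in targets: {sorted(unknown)}")
    r = np.array(list(targets.values()), dtype=float)
    if np.any(np.abs(r) >= 1.0):
        raise CalibrationError("each target correlation must lie in (-1, 1)")
    ssq = float(np.sum(r**2))
    if ssq >= 1.0:
        raise CalibrationError(
            f"targets jointly infeasible: sum of squared correlations "
            f"{ssq:.3f} >= 1 at noise_sd={noise_sd}"
        )
    scale = noise_sd / np.sqrt(1.0 - ssq)
    return {k: float(v * scale) for k, v in targets.items()}


@dataclass(frozen=True)
class CohortConfig:
    """Everything that defines a synthetic cohort.

    Defaults reproduce the study conditions: 74 patients, 5/20/5 trials
    per stage, parameter populations matching the reported cohort-level
    moments, and clinical links dominated by the memory-stage asymptote.
    """

    n_patients: int = 74
    trials_per_stage: tuple[int, int, int] = (5, 20, 5)
    populations: tuple[StagePopulation, ...] = field(default_factory=_default_populations)
    time_models: tuple[TimeModel, ...] = field(default_factory=_default_time_models)
    dgi_link: dict[str, float] = field(
        default_factory=lambda: calibrate_link(DEFAULT_CORRELATION_TARGETS)
    )
    link_noise_sd: float = 1.0
    moca_link: float = DEFAULT_MOCA_TARGET
    dgi_marginal_mean: float = 19.0
    dgi_marginal_sd: float = 3.5
    moca_marginal_mean: float = 24.6
    moca_marginal_sd: float = 3.0
    moca_min: int = 21  # inclusion rule: no dementia (MoCA cut-off 21)
    with_covariates: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ConfigError(f"n_patients must be positive, got {self.n_patients}")
        if len(self.trials_per_stage) != 3 or any(t < 1 for t in self.trials_per_stage):
            raise ConfigError("trials_per_stage must be three positive counts")
        if len(self.populations) != 3 or len(self.time_models) != 3:
            raise ConfigError("need exactly three stage populations and time models")
        if not -1.0 < self.moca_link < 1.0:
            raise ConfigError("moca_link must be in (-1, 1)")
        if self.link_noise_sd <= 0:
            raise ConfigError("link_noise_sd must be positive")

    def feature_moments(self) -> dict[str, tuple[float, float]]:
        """Model-implied (mean, sd) of each of the 9 true features."""
        out = {}
        for s in (1, 2, 3):
            m = self.populations[s - 1].moments()
            out[f"beta{s}"] = (m["beta_mean"], m["beta_sd"])
            out[f"gamma{s}"] = (m["gamma_mean"], m["gamma_sd"])
            out[f"tbar{s}"] = self.time_models[s - 1].tbar_moments(
                self.trials_per_stage[s - 1]
            )
        return out


@dataclass(frozen=True)
class SyntheticCohort:
    """Trials, clinical and ground-truth tables for one generated cohort."""

    trials: pd.DataFrame
    clinical: pd.DataFrame
    truth: pd.DataFrame
    config: CohortConfig


def _discretized_normal_thresholds(
    mean: float, sd: float, lo: int, hi: int
) -> np.ndarray:
    """Latent-normal cutpoints reproducing a discretized-normal marginal.

    The marginal over integer categories lo..hi is a normal(mean, sd)
    mass-binned at half-integer edges and renormalized; the returned
    hi - lo strictly increasing thresholds map a standard normal latent
    onto that marginal.
    """
    edges = np.arange(lo, hi + 1) + 0.5
    cdf = norm.cdf((edges - mean) / sd)
    lo_mass = norm.cdf((lo - 0.5 - mean) / sd)
    cum = (cdf - lo_mass) / (cdf[-1] - lo_mass)
    cum = np.clip(cum[:-1], 1e-12, 1 - 1e-12)
    tau = norm.ppf(cum)
    if np.any(np.diff(tau) <= 0):
        raise ConfigError("marginal produces non-increasing thresholds")
    return tau


def generate_cohort(config: CohortConfig | None = None, seed: int | None = None) -> SyntheticCohort:
    """Draw a full synthetic cohort; byte-reproducible given (config, seed)."""
    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_patients
    pids = [f"P{i + 1:03d}" for i in range(n)]

    true_params: dict[str, np.ndarray] = {}
    for s in (1, 2, 3):
        beta, gamma = config.populations[s - 1].draw(n, rng)
        true_params[f"beta{s}"] = beta
        true_params[f"gamma{s}"] = gamma

    trial_rows = []
    tbars: dict[str, np.ndarray] = {f"tbar{s}": np.empty(n) for s in (1, 2, 3)}
    for i in range(n):
        for s in (1, 2, 3):
            T = config.trials_per_stage[s - 1]
            params = LearningCurveParams(
                float(true_params[f"beta{s}"][i]), float(true_params[f"gamma{s}"][i])
            )
            outcomes = simulate_stage(params, T, rng)
            times = config.time_models[s - 1].draw(T, rng)
            tbars[f"tbar{s}"][i] = times.mean()
            for t in range(T):
                trial_rows.append(
                    (pids[i], s, t + 1, int(outcomes[t]), float(times[t]))
                )
    trials = pd.DataFrame(
        trial_rows,
        columns=["patient_id", "stage", "trial_index", "outcome", "response_time_s"],
    )

    # latent trait: weighted standardized true features + noise
    moments = config.feature_moments()
    z = rng.normal(0.0, config.link_noise_sd, size=n)
    ssq = config.link_noise_sd**2
    for name, w in config.dgi_link.items():
        mean, sd = moments[name]
        feat = true_params[name] if name in true_params else tbars[name]
        z += w * (feat - mean) / sd
        ssq += w * w
    z_std = z / np.sqrt(ssq)

    dgi_tau = _discretized_normal_thresholds(
        config.dgi_marginal_mean, config.dgi_marginal_sd, 0, 24
    )
    dgi = np.searchsorted(dgi_tau, z_std, side="left")

    c = config.moca_link
    moca_latent = c * z_std + np.sqrt(1.0 - c * c) * rng.normal(size=n)
    moca_tau = _discretized_normal_thresholds(
        config.moca_marginal_mean, config.moca_marginal_sd, config.moca_min, 30
    )
    moca = config.moca_min + np.searchsorted(moca_tau, moca_latent, side="left")

    clinical = pd.DataFrame({"patient_id": pids, "dgi_total": dgi, "moca_total": moca})
    if config.with_covariates:
        # demographic decoration only; not linked to game performance
        clinical["age_years"] = np.round(
            np.clip(rng.normal(67.0, 9.0, size=n), 40, 90)
        ).astype(int)
        clinical["sex"] = np.where(rng.random(n) < 53 / 74, "M", "F")
        clinical["hy_stage"] = rng.choice(
            [1, 2, 3], size=n, p=np.array([23, 31, 20]) / 74.0
        )

    truth_rows = []
    for i in range(n):
        for s in (1, 2, 3):
            truth_rows.append(
                (pids[i], s, float(true_params[f"beta{s}"][i]),
                 float(true_params[f"gamma{s}"][i]), float(tbars[f"tbar{s}"][i]),
                 float(z_std[i]))
            )
    truth = pd.DataFrame(
        truth_rows,
        columns=["patient_id", "stage", "beta", "gamma", "tbar", "latent_z"],
    )
    return SyntheticCohort(trials=trials, clinical=clinical, truth=truth, config=config)


def null_config(**overrides) -> CohortConfig:
    """A cohort config whose clinical scores are independent of the game."""
    overrides.setdefault("dgi_link", {})
    overrides.setdefault("moca_link", 0.0)
    return CohortConfig(**overrides)


def config_to_dict(config: CohortConfig) -> dict:
    """Plain nested-dict form of a config (for manifests / YAML round-trips)."""
    return asdict(config)
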