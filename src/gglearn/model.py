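"""Trial-level Bernoulli learning-curve model.

Each Goalkeeper Game stage produces a sequence of binary outcomes
``X_t`` (correct / incorrect prediction of the kick direction among three
options).  The success probability follows a constrained logistic curve

    lambda_t = (t - 1) * beta - log(3 * gamma - 1)
    P(X_t = 1) = gamma * exp(lambda_t) / (1 + exp(lambda_t))

with two interpretable parameters: ``gamma`` is the asymptotic success
probability after many trials ("total learning", constrained above the
1/3 chance level), and ``beta`` is the per-trial learning rate that sets
how fast the curve approaches ``gamma``.  The parameterization pins the
probability at the very first trial to exactly 1/3 for every valid
(beta, gamma): before any feedback the player can only guess among the
three directions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, log_expit

from .errors import DataError, ParameterDomainError

__all__ = [
    "LearningCurveParams",
    "success_probability",
    "sequence_log_likelihood",
    "simulate_stage",
]

_GAMMA_MIN = 1.0 / 3.0


@dataclass(frozen=True)
class LearningCurveParams:
    """Parameters of the learning curve for one patient-stage.

    Parameters
    ----------
    beta
        Learning rate per trial (dimensionless).  Non-negative under the
        default parameterization; pass ``allow_negative_beta=True`` to
        permit "forgetting" curves in sensitivity analyses.
    gamma
        Asymptotic success probability, in the open-closed interval
        (1/3, 1].  Values at or below chance make ``log(3*gamma - 1)``
        undefined or place the asymptote below the t=1 pin.
    """

    beta: float
    gamma: float
    allow_negative_beta: bool = False

    def __post_init__(self) -> None:
        if not np.isfinite(self.beta):
            raise ParameterDomainError(f"beta must be finite, got {self.beta}")
        if self.beta < 0 and not self.allow_negative_beta:
            raise ParameterDomainError(
                f"beta must be >= 0 (learning, not forgetting), got {self.beta}; "
                "set allow_negative_beta=True for sensitivity analyses"
            )
        if not (self.gamma > _GAMMA_MIN and self.gamma <= 1.0):
            raise ParameterDomainError(
                f"gamma must lie in (1/3, 1], got {self.gamma}"
            )


def _curve_logits(beta, gamma, t):
    # lambda_t = (t-1) beta - log(3 gamma - 1); valid gamma keeps the log finite
    return (np.asarray(t, dtype=float) - 1.0) * beta - np.log(3.0 * gamma - 1.0)


def success_probability(params: LearningCurveParams, t) -> np.ndarray | float:
    """Probability of a correct prediction at trial ``t`` (1-based).

    Accepts a scalar trial index or an array of indices; returns the same
    shape.  At ``t=1`` the value is exactly 1/3 for every valid parameter
    pair; for ``beta > 0`` it increases strictly toward ``gamma``.
    """
    t_arr = np.asarray(t)
    if not np.issubdtype(t_arr.dtype, np.number):
        raise IndexError(f"trial index must be numeric, got {t_arr.dtype}")
    if np.any(t_arr < 1) or np.any(t_arr != np.floor(t_arr)):
        raise IndexError(f"trial indices must be integers >= 1, got {t!r}")
    p = params.gamma * expit(_curve_logits(params.beta, params.gamma, t_arr))
    return float(p) if np.isscalar(t) or t_arr.ndim == 0 else p


def sequence_log_likelihood(params: LearningCurveParams, outcomes) -> float:
    """Log-likelihood of a within-stage outcome sequence.

    Trials are conditionally independent Bernoulli draws given
    ``(beta, gamma)``, with trial ``t`` (1-based position in the
    sequence) succeeding with probability ``success_probability(params, t)``.
    An empty sequence has log-likelihood 0.
    """
    x = np.asarray(outcomes, dtype=float)
    if x.size == 0:
        return 0.0
    if x.ndim != 1:
        raise DataError(f"outcome sequence must be 1-D, got shape {x.shape}")
    if not np.all(np.isin(x, (0.0, 1.0))):
        raise DataError("outcomes must be binary 0/1 indicators")
    t = np.arange(1, x.size + 1)
    lam = _curve_logits(params.beta, params.gamma, t)
    # log p_t = log gamma + log expit(lam); log(1 - p_t) via explicit p_t
    log_p = np.log(params.gamma) + log_expit(lam)
    p = params.gamma * expit(lam)
    log_q = np.log1p(-p)
    return float(np.sum(x * log_p + (1.0 - x) * log_q))


def simulate_stage(
    params: LearningCurveParams,
    n_trials: int,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Draw one stage's outcome sequence from the learning curve.

    ``seed`` may be an integer or a ``numpy.random.Generator``; identical
    integer seeds reproduce identical sequences.
    """
    if n_trials < 0:
        raise DataError(f"n_trials must be >= 0, got {n_trials}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if n_trials == 0:
        return np.zeros(0, dtype=np.int64)
    p = success_probability(params, np.arange(1, n_trials + 1))
    return (rng.random(n_trials) < p).astype(np.int64)
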