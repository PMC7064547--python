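"""Latent-normal correlations and ordinal regression for clinical scores.

Ordinal clinical scales (DGI 0-24, MoCA 0-30) are treated as coarsened
views of latent normal traits.  Polyserial correlation links a continuous
variable to an ordinal one; polychoric links two ordinal variables.  Both
use the classical two-step maximum-likelihood estimator: thresholds are
set from each ordinal margin's cumulative proportions, then the latent
correlation is maximized one-dimensionally.  The proportional-odds
(cumulative-logit) model for DGI is fitted with statsmodels'
``OrderedModel``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import ndtr
from scipy.stats import chi2, norm

from ._bvn import bvn_cdf
from .errors import DataError, DegenerateInputError

__all__ = [
    "AssociationResult",
    "OrdinalFit",
    "polyserial_correlation",
    "polychoric_correlation",
    "proportional_odds_fit",
    "association_table",
    "TABLE_ORDER",
]

#: Row order of the association table: MoCA first, then the nine
#: Goalkeeper Game variables grouped by stage.
TABLE_ORDER = [
    "moca_total",
    "beta1", "gamma1", "tbar1",
    "beta2", "gamma2", "tbar2",
    "beta3", "gamma3", "tbar3",
]

_RHO_BOUND = 0.9995


@dataclass(frozen=True)
class AssociationResult:
    variable: str
    estimate: float
    p_value: float
    method: str
    boundary: bool = False


@dataclass(frozen=True)
class OrdinalFit:
    """Proportional-odds fit: one slope per predictor, shared cutpoints."""

    coefficients: pd.Series
    p_values: pd.Series
    thresholds: np.ndarray
    converged: bool
    log_likelihood: float
    diagnostics: dict = field(default_factory=dict)


def _ordinal_thresholds(y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Category codes, counts and normal-quantile thresholds of a margin."""
    cats, codes = np.unique(y, return_inverse=True)
    counts = np.bincount(codes)
    cum = np.cumsum(counts)[:-1] / y.size
    return codes, counts, norm.ppf(cum)


def _maximize_rho(negll) -> tuple[float, float]:
    res = minimize_scalar(
        negll, bounds=(-_RHO_BOUND, _RHO_BOUND), method="bounded",
        options={"xatol": 1e-7},
    )
    return float(res.x), float(-res.fun)


def _lr_pvalue(ll_hat: float, ll_null: float) -> float:
    stat = max(2.0 * (ll_hat - ll_null), 0.0)
    return float(chi2.sf(stat, df=1))


def polyserial_correlation(x, y, variable: str = "x") -> AssociationResult:
    """Two-step ML polyserial correlation of continuous ``x`` with ordinal ``y``.

    Assumes (x*, y*) latent bivariate normal with y obtained by
    thresholding y*.  Thresholds come from y's cumulative proportions;
    the correlation is then the 1-D maximizer of the conditional
    likelihood.  The p-value is a likelihood-ratio test of rho = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("x and y must be equal-length 1-D vectors")
    if x.size < 10:
        raise DataError(f"need at least 10 observations, got {x.size}")
    if np.std(x) == 0:
        raise DegenerateInputError("x is constant; polyserial correlation undefined")
    codes, _, tau = _ordinal_thresholds(y)
    if tau.size == 0:
        raise DegenerateInputError("y has a single category")
    z = (x - x.mean()) / x.std()
    tau_ext = np.concatenate(([-np.inf], tau, [np.inf]))
    upper = tau_ext[codes + 1]
    lower = tau_ext[codes]

    def negll(rho: float) -> float:
        s = np.sqrt(1.0 - rho * rho)
        cell = ndtr((upper - rho * z) / s) - ndtr((lower - rho * z) / s)
        return -np.sum(np.log(np.clip(cell, 1e-300, None)))

    rho_hat, ll_hat = _maximize_rho(negll)
    p = _lr_pvalue(ll_hat, -negll(0.0))
    return AssociationResult(
        variable=variable, estimate=rho_hat, p_value=p, method="polyserial",
        boundary=abs(rho_hat) >= 0.99 * _RHO_BOUND,
    )


def polychoric_correlation(y1, y2, variable: str = "y1") -> AssociationResult:
    """Two-step ML polychoric correlation of two ordinal vectors.

    Both margins are thresholded views of a latent bivariate normal;
    cell probabilities are rectangle masses of that distribution, so
    sparse or empty cells need no merging.
    """
    y1 = np.asarray(y1)
    y2 = np.asarray(y2)
    if y1.shape != y2.shape or y1.ndim != 1:
        raise DataError("y1 and y2 must be equal-length 1-D vectors")
    codes1, _, tau1 = _ordinal_thresholds(y1)
    codes2, _, tau2 = _ordinal_thresholds(y2)
    if tau1.size == 0 or tau2.size == 0:
        raise DegenerateInputError("an ordinal margin has a single category")
    k1, k2 = tau1.size + 1, tau2.size + 1
    table = np.zeros((k1, k2))
    np.add.at(table, (codes1, codes2), 1.0)
    a = np.concatenate(([-np.inf], tau1, [np.inf]))
    b = np.concatenate(([-np.inf], tau2, [np.inf]))
    A, B = np.meshgrid(a, b, indexing="ij")

    def negll(rho: float) -> float:
        F = bvn_cdf(A, B, rho)
        cell = F[1:, 1:] - F[:-1, 1:] - F[1:, :-1] + F[:-1, :-1]
        return -np.sum(table * np.log(np.clip(cell, 1e-300, None)))

    rho_hat, ll_hat = _maximize_rho(negll)
    p = _lr_pvalue(ll_hat, -negll(0.0))
    return AssociationResult(
        variable=variable, estimate=rho_hat, p_value=p, method="polychoric",
        boundary=abs(rho_hat) >= 0.99 * _RHO_BOUND,
    )


def proportional_odds_fit(X, y, standardize: bool = False) -> OrdinalFit:
    """Cumulative-logit proportional-odds fit of ordinal ``y`` on ``X``.

    Positive coefficients shift mass toward higher categories, so the
    sign convention matches 'larger predictor, better gait score'.
    Predictors are used raw by default (per-unit coefficients);
    ``standardize=True`` rescales columns to unit variance first.
    Non-convergence and quasi-separation are flagged, not silenced.
    """
    from statsmodels.miscmodels.ordinal_model import OrderedModel

    X = pd.DataFrame(X).copy()
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise DegenerateInputError("response has a single category")
    n_thresh = np.unique(y).size - 1
    if X.shape[0] <= X.shape[1] + n_thresh:
        raise DataError(
            f"n={X.shape[0]} too small for {X.shape[1]} predictors and "
            f"{n_thresh} thresholds"
        )
    if standardize:
        X = (X - X.mean()) / X.std(ddof=0)
    model = OrderedModel(y, X.to_numpy(dtype=float), distr="logit")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(method="bfgs", maxiter=1000, gtol=1e-8, disp=False)
    k = X.shape[1]
    names = [str(c) for c in X.columns]
    coefs = pd.Series(res.params[:k], index=names)
    pvals = pd.Series(res.pvalues[:k], index=names)
    thresholds = model.transform_threshold_params(res.params)[1:-1]
    converged = bool(res.mle_retvals.get("converged", False))
    return OrdinalFit(
        coefficients=coefs,
        p_values=pvals,
        thresholds=np.asarray(thresholds, dtype=float),
        converged=converged,
        log_likelihood=float(res.llf),
        diagnostics={"n_obs": int(X.shape[0]), "n_thresholds": int(n_thresh)},
    )


def association_table(
    features: pd.DataFrame,
    clinical: pd.DataFrame,
    max_missing_fraction: float = 0.2,
) -> pd.DataFrame:
    """Pairwise association of MoCA and the 9 GG variables with DGI.

    MoCA-DGI uses the polychoric estimator (both margins are discrete
    scores); each continuous GG variable uses the polyserial estimator
    against DGI.  Complete cases only; exclusions above
    ``max_missing_fraction`` trigger a warning.
    """
    merged = features.merge(clinical, on="patient_id", how="inner")
    needed = [c for c in TABLE_ORDER if c != "moca_total"] + ["moca_total", "dgi_total"]
    missing_cols = [c for c in needed if c not in merged.columns]
    if missing_cols:
        raise DataError(f"association inputs missing columns: {missing_cols}")
    complete = merged.dropna(subset=needed)
    n_excluded = len(merged) - len(complete)
    if len(merged) and n_excluded / len(merged) > max_missing_fraction:
        warnings.warn(
            f"{n_excluded}/{len(merged)} patients excluded for missing data"
        )
    dgi = complete["dgi_total"].to_numpy()
    rows = []
    for var in TABLE_ORDER:
        if var == "moca_total":
            r = polychoric_correlation(complete[var].to_numpy(), dgi, variable=var)
        else:
            r = polyserial_correlation(complete[var].to_numpy(), dgi, variable=var)
        rows.append(
            {"variable": var, "estimate": r.estimate, "p_value": r.p_value,
             "method": r.method}
        )
    return pd.DataFrame(rows)
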