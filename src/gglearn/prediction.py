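"""Classifier comparison: game features vs MoCA for dichotomized gait score.

DGI is split at its sample median ("above" strictly; ties go to the
lower class).  Each arm — the nine game variables, or the single MoCA
score — is evaluated by repeated stratified cross-validated elastic-net
logistic regression with the penalty strength chosen by nested inner
cross-validation on the training folds only.  Arms share identical fold
partitions so the comparison is paired: accuracy against a coin flip by
exact binomial test, and AUC difference by DeLong's placement-value test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binomtest, norm
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .errors import DataError, DegenerateInputError, StratificationError

__all__ = [
    "CVConfig",
    "ClassifierEvaluation",
    "DeLongResult",
    "ComparisonReport",
    "dichotomize_dgi",
    "cv_elastic_net",
    "binomial_vs_chance",
    "roc_and_auc",
    "delong_compare",
    "compare_predictors",
]


@dataclass(frozen=True)
class CVConfig:
    """Cross-validation settings for the elastic-net classifier."""

    n_folds: int = 10
    n_repeats: int = 10
    stratified: bool = True
    l1_ratio: float = 0.5
    c_grid: tuple[float, ...] = tuple(float(c) for c in np.logspace(-2, 2, 9))
    inner_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2 or self.inner_folds < 2:
            raise DataError("outer and inner fold counts must be >= 2")
        if not 0.0 <= self.l1_ratio <= 1.0:
            raise DataError("l1_ratio must be in [0, 1]")
        if self.n_repeats < 1:
            raise DataError("n_repeats must be >= 1")


@dataclass(frozen=True)
class ClassifierEvaluation:
    """Out-of-fold predictions and summary metrics for one arm."""

    scores: np.ndarray            # per-patient oof probability, averaged over repeats
    labels_pred: np.ndarray
    accuracy: float               # mean over repeats of pooled oof accuracy
    correct: int
    n: int
    binomial_p: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    per_repeat_accuracy: np.ndarray
    fold_assignments: np.ndarray  # (n_repeats, n) outer fold id per patient
    diagnostics: dict = field(default_factory=dict)


@dataclass(frozen=True)
class DeLongResult:
    auc_a: float
    auc_b: float
    difference: float
    variance: float
    z: float
    p_value: float
    alternative: str
    degenerate: bool = False


@dataclass(frozen=True)
class ComparisonReport:
    labels: np.ndarray
    median: float
    gg: ClassifierEvaluation
    moca: ClassifierEvaluation
    delong: DeLongResult


def dichotomize_dgi(dgi) -> tuple[np.ndarray, dict]:
    """Binary labels: 1 iff DGI strictly above its sample median.

    Ties at the median join the lower class.  Returns ``(labels, info)``
    with the median and class balance in ``info``; raises on degenerate
    one-class outcomes (e.g. all values identical).
    """
    dgi = np.asarray(dgi, dtype=float)
    if dgi.size == 0:
        raise DataError("empty DGI vector")
    med = float(np.median(dgi))
    labels = (dgi > med).astype(np.int64)
    balance = {"median": med, "n_above": int(labels.sum()),
               "n_at_or_below": int(dgi.size - labels.sum())}
    if labels.min() == labels.max():
        raise DegenerateInputError(
            f"dichotomization degenerate (single class): {balance}"
        )
    return labels, balance


def _make_estimator(C: float, l1_ratio: float) -> object:
    return make_pipeline(
        StandardScaler(),
        LogisticRegression(
            solver="saga", C=C, l1_ratio=l1_ratio, max_iter=5000, tol=1e-4,
            random_state=0,
        ),
    )


def _inner_select_C(X, y, config: CVConfig, rng_seed: int) -> float:
    """Pick the penalty strength by inner stratified CV mean log-loss.

    The grid is traversed in ascending order with a warm-started solver
    per inner fold (regularization path), which is both faster and the
    standard way to fit an elastic-net path.  Ties favour the smaller
    (more regularized) C.
    """
    inner = StratifiedKFold(
        n_splits=config.inner_folds, shuffle=True, random_state=rng_seed
    )
    grid = np.sort(np.asarray(config.c_grid, dtype=float))
    losses = np.zeros(grid.size)
    for tr, te in inner.split(X, y):
        scaler = StandardScaler().fit(X[tr])
        Xtr, Xte = scaler.transform(X[tr]), scaler.transform(X[te])
        # looser tolerance than the final fits: the path only has to rank
        # penalty strengths, not deliver polished coefficients
        lr = LogisticRegression(
            solver="saga", l1_ratio=config.l1_ratio, C=grid[0],
            max_iter=2000, tol=1e-3, random_state=0, warm_start=True,
        )
        for j, C in enumerate(grid):
            lr.set_params(C=C)
            lr.fit(Xtr, y[tr])
            p = np.clip(lr.predict_proba(Xte)[:, 1], 1e-12, 1 - 1e-12)
            losses[j] += -np.mean(y[te] * np.log(p) + (1 - y[te]) * np.log(1 - p))
    return float(grid[int(np.argmin(losses))])


def cv_elastic_net(X, y, config: CVConfig | None = None) -> ClassifierEvaluation:
    """Repeated stratified CV evaluation of the elastic-net classifier.

    Out-of-fold probabilities are produced per repeat and pooled;
    accuracy (0.5 threshold) is averaged over repeats, and the reported
    per-patient score is the repeat-average oof probability.  With a
    single predictor the penalty is inert, so the inner search is skipped
    and an effectively unpenalized fit is used.
    """
    config = config or CVConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=np.int64)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if y.shape != (n,):
        raise DataError("X and y sizes disagree")
    class_counts = np.bincount(y, minlength=2)
    if class_counts.min() < 2:
        raise DegenerateInputError(f"need >= 2 per class, got {class_counts.tolist()}")
    if config.stratified and class_counts.min() < config.n_folds:
        raise StratificationError(
            f"minority class ({class_counts.min()}) smaller than n_folds "
            f"({config.n_folds}); a class would vanish from some training fold"
        )

    all_scores = np.zeros((config.n_repeats, n))
    fold_ids = np.zeros((config.n_repeats, n), dtype=np.int64)
    rep_acc = np.zeros(config.n_repeats)
    chosen_C: list[float] = []
    for r in range(config.n_repeats):
        outer = StratifiedKFold(
            n_splits=config.n_folds, shuffle=True,
            random_state=(config.seed + 1000003 * r) % 2**31,
        )
        for k, (tr, te) in enumerate(outer.split(X, y)):
            if len(np.unique(y[tr])) < 2:
                raise StratificationError(f"fold {k} lost a class")
            if p == 1:
                C = 1e6
            else:
                C = _inner_select_C(
                    X[tr], y[tr], config,
                    rng_seed=(config.seed + 7919 * r + k) % 2**31,
                )
            chosen_C.append(C)
            est = _make_estimator(C, config.l1_ratio)
            est.fit(X[tr], y[tr])
            all_scores[r, te] = est.predict_proba(X[te])[:, 1]
            fold_ids[r, te] = k
        rep_acc[r] = np.mean((all_scores[r] > 0.5).astype(int) == y)

    scores = all_scores.mean(axis=0)
    accuracy = float(rep_acc.mean())
    correct = int(round(accuracy * n))
    fpr, tpr, thr, auc = roc_and_auc(scores, y)
    return ClassifierEvaluation(
        scores=scores,
        labels_pred=(scores > 0.5).astype(np.int64),
        accuracy=accuracy,
        correct=correct,
        n=n,
        binomial_p=binomial_vs_chance(correct, n),
        fpr=fpr, tpr=tpr, thresholds=thr, auc=auc,
        per_repeat_accuracy=rep_acc,
        fold_assignments=fold_ids,
        diagnostics={"chosen_C": chosen_C, "class_counts": class_counts.tolist()},
    )


def binomial_vs_chance(correct: int, n: int, alternative: str = "two-sided") -> float:
    """Exact binomial test of ``correct`` successes in ``n`` against 0.5."""
    if n <= 0:
        raise DataError("n must be positive")
    if not 0 <= correct <= n:
        raise DataError(f"correct={correct} outside [0, {n}]")
    return float(binomtest(correct, n, 0.5, alternative=alternative).pvalue)


def roc_and_auc(scores, labels) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Full-threshold-sweep ROC and its AUC.

    The AUC equals the Mann-Whitney pair-counting statistic (ties get
    half credit); the curve runs monotonically from (0, 0) to (1, 1).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=np.int64)
    if np.unique(labels).size < 2:
        raise DegenerateInputError("ROC needs both classes present")
    fpr, tpr, thr = roc_curve(labels, scores, drop_intermediate=False)
    return fpr, tpr, thr, float(roc_auc_score(labels, scores))


def _placements(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong placement values V10 (per positive) and V01 (per negative)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    cmp = (pos[:, None] > neg[None, :]).astype(float) + 0.5 * (
        pos[:, None] == neg[None, :]
    )
    return cmp.mean(axis=1), cmp.mean(axis=0)


def delong_compare(
    scores_a, scores_b, labels, alternative: str = "greater"
) -> DeLongResult:
    """DeLong's test for the paired AUC difference AUC(a) - AUC(b).

    ``alternative='greater'`` tests whether arm a's AUC exceeds arm b's
    (one-sided); 'two-sided' and 'less' are also available.  A
    zero-variance difference (e.g. identical scores) is flagged
    degenerate with an uninformative p-value of 1.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=np.int64)
    if not (scores_a.shape == scores_b.shape == labels.shape):
        raise DataError("paired scores and labels must share one shape")
    if np.unique(labels).size < 2:
        raise DegenerateInputError("DeLong needs both classes present")
    if alternative not in ("greater", "less", "two-sided"):
        raise DataError(f"unknown alternative {alternative!r}")
    v10_a, v01_a = _placements(scores_a, labels)
    v10_b, v01_b = _placements(scores_b, labels)
    auc_a, auc_b = float(v10_a.mean()), float(v10_b.mean())
    m, nn = v10_a.size, v01_a.size
    d10 = v10_a - v10_b
    d01 = v01_a - v01_b
    var = float(np.var(d10, ddof=1) / m + np.var(d01, ddof=1) / nn)
    diff = auc_a - auc_b
    if var <= 0.0:
        return DeLongResult(auc_a, auc_b, diff, 0.0, 0.0, 1.0, alternative, True)
    z = diff / np.sqrt(var)
    if alternative == "greater":
        p = float(norm.sf(z))
    elif alternative == "less":
        p = float(norm.cdf(z))
    else:
        p = float(2.0 * norm.sf(abs(z)))
    return DeLongResult(auc_a, auc_b, diff, var, float(z), p, alternative)


def compare_predictors(
    features, moca, dgi, config: CVConfig | None = None
) -> ComparisonReport:
    """Paired evaluation: 9 game variables vs the single MoCA score.

    Both arms use identical outer folds (same labels, same CV seed), so
    accuracies and DeLong's one-sided AUC comparison (game arm greater)
    are directly paired.
    """
    config = config or CVConfig()
    X_gg = np.asarray(
        features[[c for c in features.columns if c != "patient_id"]]
        if isinstance(features, pd.DataFrame) else features,
        dtype=float,
    )
    moca = np.asarray(moca, dtype=float)
    labels, _balance = dichotomize_dgi(dgi)
    gg_eval = cv_elastic_net(X_gg, labels, config)
    moca_eval = cv_elastic_net(moca[:, None], labels, config)
    if not np.array_equal(gg_eval.fold_assignments, moca_eval.fold_assignments):
        raise StratificationError("arms received different fold partitions")
    delong = delong_compare(gg_eval.scores, moca_eval.scores, labels, "greater")
    return ComparisonReport(
        labels=labels, median=_balance["median"],
        gg=gg_eval, moca=moca_eval, delong=delong,
    )
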