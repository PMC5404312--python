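"""Discrimination of diagnostic groups by their risk scores.

Logistic regression (IRLS via statsmodels), ROC curves with tie-corrected
midrank AUC, and Bonferroni-adjusted pairwise Wilcoxon rank-sum
comparison of score distributions.  The AUC is computed directly from
the scores, not from fitted probabilities: for a single monotone
predictor the two are identical and the direct route does not depend on
fit convergence.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

from .containers import ValidationError

logger = logging.getLogger(__name__)


class SeparationError(ValidationError):
    """Logistic fit aborted: classes perfectly separated."""


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic regression result."""

    intercept: float
    coef: np.ndarray
    fitted_probs: np.ndarray
    loglik: float
    pvalues: np.ndarray  # Wald p per coefficient, intercept first
    n_iter: int


@dataclass
class ROCResult:
    """ROC curve (thresholds descending) with tie-corrected AUC."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    one_minus_specificity: np.ndarray
    auc: float


@dataclass
class PairwiseTestMatrix:
    """Rank-sum tests for every group pair, Bonferroni-adjusted."""

    results: dict[tuple[str, str], dict[str, float]]
    n_pairs: int

    def get(self, a: str, b: str) -> dict[str, float]:
        key = tuple(sorted((a, b)))
        return self.results[key]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"group_a": a, "group_b": b, **vals}
            for (a, b), vals in sorted(self.results.items())
        ]
        return pd.DataFrame(rows, columns=["group_a", "group_b", "u_statistic",
                                           "raw_p", "adjusted_p"])


def fit_logistic(
    scores: Sequence[float] | np.ndarray, labels: Sequence[int]
) -> LogisticFit:
    """Fit labels ~ intercept + scores by IRLS maximum likelihood.

    ``scores`` may be a vector or an (n, k) matrix of predictors.
    Diverging coefficients (norm > 1e3) signal perfect separation and
    abort with :class:`SeparationError`.
    """
    import statsmodels.api as sm

    y = np.asarray(labels, dtype=float)
    X = np.asarray(scores, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if set(np.unique(y)) != {0.0, 1.0}:
        raise ValidationError("labels must contain both classes (0 and 1)")
    design = sm.add_constant(X, has_constant="add")
    model = sm.GLM(y, design, family=sm.families.Binomial())
    import warnings

    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            res = model.fit(maxiter=100, tol=1e-8)
    except (PerfectSeparationWarning, Exception) as exc:
        if "separation" in str(exc).lower() or "Separation" in type(exc).__name__:
            raise SeparationError(str(exc)) from exc
        raise
    params = np.asarray(res.params)
    if np.linalg.norm(params) > 1e3:
        raise SeparationError("coefficient norm exceeds 1e3: perfect separation")
    return LogisticFit(
        intercept=float(params[0]),
        coef=params[1:],
        fitted_probs=np.asarray(res.fittedvalues),
        loglik=float(res.llf),
        pvalues=np.asarray(res.pvalues),
        n_iter=int(getattr(res, "fit_history", {}).get("iteration", 0) or 0),
    )


def midrank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Tie-corrected Mann-Whitney AUC from midranks."""
    ranks = stats.rankdata(scores)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> ROCResult:
    """ROC curve over all distinct thresholds plus sentinels, with AUC.

    The AUC comes from midranks (equals the trapezoidal area under the
    tie-collapsed curve and the pairwise win fraction wins + ties/2).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if np.unique(labels).size < 2:
        raise ValidationError("labels must contain both classes")
    fpr, tpr, thresholds = _sk_roc_curve(labels, scores, drop_intermediate=False)
    return ROCResult(
        thresholds=thresholds,
        sensitivity=tpr,
        one_minus_specificity=fpr,
        auc=midrank_auc(scores, labels),
    )


def _ranksum_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided rank-sum p: exact enumeration when both n <= 10 and no
    ties; else normal approximation with continuity and tie correction."""
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if np.ptp(pooled) == 0:
        # all observations identical: no evidence of a shift
        u = a.size * b.size / 2.0
        return u, 1.0
    if a.size <= 10 and b.size <= 10 and not has_ties:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic",
            use_continuity=True,
        )
    return float(res.statistic), float(res.pvalue)


def pairwise_rank_tests(
    scores_by_group: Mapping[str, Sequence[float]],
) -> PairwiseTestMatrix:
    """Two-sided Wilcoxon rank-sum test for every pair of groups.

    Bonferroni adjusts over the number of pairs actually tested; groups
    with fewer than 2 observations are excluded with a warning.
    """
    usable = {}
    for name, vals in scores_by_group.items():
        arr = np.asarray(vals, dtype=float)
        if arr.size < 2:
            logger.warning("group %s has < 2 observations; excluded", name)
            continue
        usable[name] = arr
    if len(usable) < 2:
        raise ValidationError("need at least 2 usable groups")
    pairs = list(combinations(sorted(usable), 2))
    results: dict[tuple[str, str], dict[str, float]] = {}
    for a, b in pairs:
        u, p = _ranksum_p(usable[a], usable[b])
        results[(a, b)] = {
            "u_statistic": u,
            "raw_p": p,
            "adjusted_p": min(1.0, p * len(pairs)),
        }
    return PairwiseTestMatrix(results, n_pairs=len(pairs))
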