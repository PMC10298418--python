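"""ROC inference: AUROC, DeLong confidence intervals, binormal smoothing,
Youden operating points and the paired permutation test.

The estimator throughout is the empirical (Mann–Whitney) AUC

.. math::

    \\hat A = \\frac{1}{mn} \\sum_{i=1}^{m} \\sum_{j=1}^{n}
        \\left[ \\mathbf 1(x_i > y_j) + \\tfrac12 \\mathbf 1(x_i = y_j) \\right]

over the :math:`m` positive scores :math:`x_i` and :math:`n` negative scores
:math:`y_j`, with ties half-weighted.  Inference (variance, confidence
intervals, permutation p-values) is always on this empirical estimator; the
binormal smoothing is for display only.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

from .exceptions import InferenceError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "RocResult", "OperatingPoint", "ComparisonResult",
    "empirical_auc", "delong_ci", "smooth_roc", "youden_operating_point",
    "binomial_ci", "permutation_test_auc", "youden_j",
]


# --------------------------------------------------------------------------
# result containers
# --------------------------------------------------------------------------

@dataclass
class SmoothedCurve:
    """Binormal-smoothed ROC curve Phi^-1(TPR) = a + b * Phi^-1(FPR)."""
    fpr: np.ndarray
    tpr: np.ndarray
    a: float | None = None
    b: float | None = None
    fitted: bool = True

    @property
    def auc(self) -> float:
        """Area under the fitted binormal curve, Phi(a / sqrt(1 + b^2))."""
        if not self.fitted:
            return float(np.trapezoid(self.tpr, self.fpr))
        return float(stats.norm.cdf(self.a / np.sqrt(1.0 + self.b ** 2)))


@dataclass
class RocResult:
    """Empirical AUROC with a DeLong confidence interval."""
    auc: float
    auc_ci: tuple[float, float]
    variance: float
    curve: np.ndarray                      # columns fpr, tpr, threshold
    smoothed_curve: SmoothedCurve | None = None
    level: float = 0.95


@dataclass
class OperatingPoint:
    """Youden-optimal cut-off with exact binomial CIs on Se/Sp/Acc."""
    threshold: float
    sensitivity: float
    specificity: float
    accuracy: float
    sensitivity_ci: tuple[float, float]
    specificity_ci: tuple[float, float]
    accuracy_ci: tuple[float, float]
    youden_j: float
    level: float = 0.95


@dataclass
class ComparisonResult:
    """Paired permutation comparison of two AUROCs on the same cases."""
    delta_auc: float
    p_value: float
    n_permutations: int
    seed: int | None = None
    auc_a: float = field(default=np.nan)
    auc_b: float = field(default=np.nan)


# --------------------------------------------------------------------------
# helpers
# --------------------------------------------------------------------------

def _validate_scores_labels(scores, labels, min_per_class: int = 1):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValidationError("scores and labels must be 1-d and the same length")
    if not np.all(np.isfinite(scores)):
        raise ValidationError("scores must be finite")
    labels = labels.astype(int)
    if not np.isin(labels, (0, 1)).all():
        raise ValidationError("labels must be binary 0/1")
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos < min_per_class:
        raise InferenceError(f"need at least {min_per_class} positive case(s), got {n_pos}")
    if n_neg < min_per_class:
        raise InferenceError(f"need at least {min_per_class} negative case(s), got {n_neg}")
    return scores, labels, n_pos, n_neg


def _auc_from_ranks(scores: np.ndarray, labels: np.ndarray) -> float:
    # midrank form of the all-pairs estimator; exact with ties
    m = labels.sum()
    n = labels.size - m
    ranks = stats.rankdata(scores)
    return float((ranks[labels == 1].sum() - m * (m + 1) / 2.0) / (m * n))


def auc_rows(score_matrix: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Empirical AUC for every row of ``score_matrix`` against fixed labels."""
    labels = np.asarray(labels, dtype=int)
    m = labels.sum()
    n = labels.size - m
    ranks = stats.rankdata(score_matrix, axis=-1)
    pos_sum = ranks[..., labels == 1].sum(axis=-1)
    return (pos_sum - m * (m + 1) / 2.0) / (m * n)


# --------------------------------------------------------------------------
# point estimation
# --------------------------------------------------------------------------

def empirical_auc(scores, labels) -> float:
    """All-pairs (Mann–Whitney) AUC with ties counted one half.

    Raises
    ------
    InferenceError
        If either class is absent.
    """
    scores, labels, _, _ = _validate_scores_labels(scores, labels)
    return _auc_from_ranks(scores, labels)


def _placements(scores: np.ndarray, labels: np.ndarray):
    """DeLong placement values (V10 per positive, V01 per negative)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    all_ranks = stats.rankdata(scores)
    pos_ranks = stats.rankdata(pos)
    neg_ranks = stats.rankdata(neg)
    v10 = (all_ranks[labels == 1] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[labels == 0] - neg_ranks) / m
    return v10, v01


def delong_ci(scores, labels, level: float = 0.95,
              with_curve: bool = True, smoothed: bool = False) -> RocResult:
    """Empirical AUROC with its DeLong variance and normal-theory CI.

    The variance is the plug-in combination of the two placement components,
    ``var(V10)/m + var(V01)/n``.  Under perfect separation the variance is 0
    and a degenerate interval ``[auc, auc]`` is returned with a warning.
    """
    scores, labels, m, n = _validate_scores_labels(scores, labels, min_per_class=2)
    v10, v01 = _placements(scores, labels)
    auc = float(v10.mean())
    variance = float(np.var(v10) / m + np.var(v01) / n)
    if variance == 0.0:
        logger.warning("degenerate DeLong interval: zero variance "
                       "(perfect separation or constant placements)")
        lo = hi = auc
    else:
        z = stats.norm.ppf(0.5 + level / 2.0)
        half = z * np.sqrt(variance)
        lo = max(0.0, auc - half)
        hi = min(1.0, auc + half)
    curve = None
    if with_curve:
        fpr, tpr, thr = _sk_roc_curve(labels, scores, drop_intermediate=False)
        curve = np.column_stack([fpr, tpr, thr])
    smoothed_curve = smooth_roc(scores, labels) if smoothed else None
    return RocResult(auc=auc, auc_ci=(float(lo), float(hi)), variance=variance,
                     curve=curve, smoothed_curve=smoothed_curve, level=level)


# --------------------------------------------------------------------------
# smoothing (display only)
# --------------------------------------------------------------------------

def smooth_roc(scores, labels, grid_size: int = 199) -> SmoothedCurve:
    """Binormal smoothing of the empirical ROC curve.

    Fits ``probit(TPR) = a + b * probit(FPR)`` by least squares on the
    interior empirical points and returns the fitted curve on a fixed FPR
    grid.  Intended for plotting; never used for inference.  With fewer than
    two interior points the empirical curve is returned with a warning.
    """
    scores, labels, _, _ = _validate_scores_labels(scores, labels, min_per_class=2)
    fpr, tpr, _ = _sk_roc_curve(labels, scores, drop_intermediate=False)
    interior = (fpr > 0) & (fpr < 1) & (tpr > 0) & (tpr < 1)
    if interior.sum() < 2:
        warnings.warn("fewer than 2 interior ROC points; returning the "
                      "empirical curve unsmoothed", stacklevel=2)
        return SmoothedCurve(fpr=fpr, tpr=tpr, fitted=False)
    x = stats.norm.ppf(fpr[interior])
    y = stats.norm.ppf(tpr[interior])
    b, a = np.polyfit(x, y, 1)
    grid = np.linspace(0.0, 1.0, grid_size + 2)[1:-1]
    fitted = stats.norm.cdf(a + b * stats.norm.ppf(grid))
    grid = np.concatenate([[0.0], grid, [1.0]])
    fitted = np.concatenate([[0.0], fitted, [1.0]])
    return SmoothedCurve(fpr=grid, tpr=fitted, a=float(a), b=float(b))


# --------------------------------------------------------------------------
# operating point
# --------------------------------------------------------------------------

def binomial_ci(x: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact Clopper–Pearson interval for a binomial proportion.

    Uses the beta-quantile closed form; the lower bound is 0 when ``x == 0``
    and the upper bound is 1 when ``x == n``.
    """
    if n < 1 or x < 0 or x > n or int(x) != x or int(n) != n:
        raise ValidationError(f"invalid binomial counts x={x}, n={n}")
    alpha = 1.0 - level
    lo = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2.0, x, n - x + 1))
    hi = 1.0 if x == n else float(stats.beta.ppf(1.0 - alpha / 2.0, x + 1, n - x))
    return lo, hi


def youden_j(sensitivity: float, specificity: float) -> float:
    """Youden index J = Se + Sp - 1."""
    return sensitivity + specificity - 1.0


def youden_operating_point(scores, labels, level: float = 0.95) -> OperatingPoint:
    """Cut-off maximizing the Youden index J(t) = Se(t) + Sp(t) - 1.

    A case is predicted positive when ``score >= t``; candidate thresholds are
    the distinct observed scores.  Ties in J are broken toward the highest
    sensitivity (the lowest threshold).  Se, Sp and accuracy carry exact
    Clopper–Pearson intervals at ``level``.
    """
    scores, labels, m, n = _validate_scores_labels(scores, labels)
    thresholds = np.unique(scores)
    pos = np.sort(scores[labels == 1])
    neg = np.sort(scores[labels == 0])
    # counts via binary search: tp = #pos >= t, tn = #neg < t
    tp = m - np.searchsorted(pos, thresholds, side="left")
    tn = np.searchsorted(neg, thresholds, side="left")
    se = tp / m
    sp = tn / n
    j = se + sp - 1.0
    best_j = j.max()
    # lowest threshold among maximizers = highest sensitivity
    idx = int(np.flatnonzero(np.isclose(j, best_j, rtol=0, atol=1e-12))[0])
    t = float(thresholds[idx])
    x_se, x_sp = int(tp[idx]), int(tn[idx])
    x_acc = x_se + x_sp
    total = m + n
    return OperatingPoint(
        threshold=t,
        sensitivity=x_se / m,
        specificity=x_sp / n,
        accuracy=x_acc / total,
        sensitivity_ci=binomial_ci(x_se, m, level),
        specificity_ci=binomial_ci(x_sp, n, level),
        accuracy_ci=binomial_ci(x_acc, total, level),
        youden_j=float(j[idx]),
        level=level,
    )


# --------------------------------------------------------------------------
# paired permutation test
# --------------------------------------------------------------------------

def _rank_scale(x: np.ndarray) -> np.ndarray:
    return (stats.rankdata(x) - 0.5) / x.size


def _auc_rows_varlabel(score_rows: np.ndarray, label_rows: np.ndarray) -> np.ndarray:
    """Row-wise AUC where each row carries its own labels.

    Degenerate rows (one class only) get AUC 0.5, i.e. a null difference.
    """
    ranks = stats.rankdata(score_rows, axis=-1)
    m = label_rows.sum(axis=-1)
    n = label_rows.shape[-1] - m
    pos_sum = (ranks * label_rows).sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        auc = (pos_sum - m * (m + 1) / 2.0) / (m * n)
    return np.where((m == 0) | (n == 0), 0.5, auc)


def permutation_test_auc(scores_a, scores_b, labels,
                         n_permutations: int = 10_000,
                         seed: int | None = None,
                         method: str = "auto",
                         paired: bool = True,
                         case_ids_a=None, case_ids_b=None) -> ComparisonResult:
    """Permutation test for the difference of two AUROCs on the same cases.

    Both score vectors must cover the same cases in the same order (pass
    ``case_ids_a``/``case_ids_b`` to have the pairing checked).  Each arm is
    first mapped to its rank scale so the permutations are scale-free.  In
    the default paired scheme the null distribution of ``|AUC_a - AUC_b|`` is
    generated by swapping the pair ``(a_i, b_i)`` independently per case with
    probability 1/2; with ``paired=False`` the pooled rank-scaled scores are
    reassigned to the two arms at random instead.

    ``method`` is ``"exhaustive"`` (all ``2^n`` swap patterns, exact p;
    paired only), ``"monte_carlo"`` (add-one estimator
    ``p = (1 + #{>= obs}) / (B + 1)``), or ``"auto"`` (exhaustive when
    ``2^n <= n_permutations``).
    """
    if case_ids_a is not None or case_ids_b is not None:
        ids_a = list(case_ids_a) if case_ids_a is not None else None
        ids_b = list(case_ids_b) if case_ids_b is not None else None
        if ids_a is None or ids_b is None or ids_a != ids_b:
            sa, sb = set(ids_a or []), set(ids_b or [])
            unmatched = sorted(sa.symmetric_difference(sb)) or ["(order differs)"]
            raise ValidationError("unpaired inputs; unmatched case_ids: "
                                  + ", ".join(map(str, unmatched[:10])))
    a, labels_arr, m, n = _validate_scores_labels(scores_a, labels)
    b, _, _, _ = _validate_scores_labels(scores_b, labels)
    if a.size != b.size:
        raise ValidationError("scores_a and scores_b must have the same length")

    ra, rb = _rank_scale(a), _rank_scale(b)
    auc_a = _auc_from_ranks(ra, labels_arr)
    auc_b = _auc_from_ranks(rb, labels_arr)
    observed = abs(auc_a - auc_b)
    n_cases = a.size
    eps = 1e-12

    if method not in ("auto", "exhaustive", "monte_carlo"):
        raise ValidationError(f"unknown permutation method {method!r}")
    exhaustive = paired and (
        method == "exhaustive"
        or (method == "auto" and n_cases <= 20 and 2 ** n_cases <= n_permutations))
    if method == "exhaustive" and not paired:
        raise ValidationError("exhaustive enumeration is defined for the "
                              "paired scheme only")

    if exhaustive:
        if n_cases > 20:
            raise ValidationError("exhaustive enumeration limited to 20 cases")
        patterns = np.array(list(itertools.product([False, True], repeat=n_cases)))
        perm_a = np.where(patterns, rb, ra)
        perm_b = np.where(patterns, ra, rb)
        stat = np.abs(auc_rows(perm_a, labels_arr) - auc_rows(perm_b, labels_arr))
        count = int((stat >= observed - eps).sum())
        total = patterns.shape[0]
        p = count / total
        return ComparisonResult(delta_auc=float(auc_a - auc_b), p_value=float(p),
                                n_permutations=total, seed=seed,
                                auc_a=auc_a, auc_b=auc_b)

    rng = np.random.default_rng(seed)
    count = 0
    block = 2000  # bound peak memory for large n_permutations
    remaining = n_permutations
    pooled_scores = np.concatenate([ra, rb])
    pooled_labels = np.concatenate([labels_arr, labels_arr])
    while remaining > 0:
        k = min(block, remaining)
        if paired:
            swaps = rng.random((k, n_cases)) < 0.5
            perm_a = np.where(swaps, rb, ra)
            perm_b = np.where(swaps, ra, rb)
            stat = np.abs(auc_rows(perm_a, labels_arr)
                          - auc_rows(perm_b, labels_arr))
        else:
            # reassign pooled (score, case-label) observations to the arms
            order = np.argsort(rng.random((k, 2 * n_cases)), axis=1)
            stat = np.abs(_auc_rows_varlabel(pooled_scores[order[:, :n_cases]],
                                             pooled_labels[order[:, :n_cases]])
                          - _auc_rows_varlabel(pooled_scores[order[:, n_cases:]],
                                               pooled_labels[order[:, n_cases:]]))
        count += int((stat >= observed - eps).sum())
        remaining -= k
    p = (1.0 + count) / (n_permutations + 1.0)
    return ComparisonResult(delta_auc=float(auc_a - auc_b), p_value=float(p),
                            n_permutations=n_permutations, seed=seed,
                            auc_a=auc_a, auc_b=auc_b)
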