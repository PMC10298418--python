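"""Consensus scoring: reader-side ordinal aggregation and AI-side
calibration + ensembling.

Reader side
-----------
Each case collects several 5-point Likert ratings (1 = definitely without
pathology ... 5 = definitely with pathology, 3 = undefined).  A case is
excluded when strictly more than half of its ratings are "undefined"
(score 3); otherwise, when the minimum-response filter applies, it is
excluded with fewer than ``min_responses`` ratings (the filter is switched
off for the breast-imaging-specialist subgroup analysis).  Surviving cases
get the upper median of the ratings — the ⌈(n+1)/2⌉-th order statistic, so an
ambiguous even-n median resolves to the higher score — mapped to the
probability scale by ``(score - 1) / 4``.  A mode-based variant
(most frequent score, ties to the higher score) is available as
``rule="mode_high"`` for sensitivity analysis.

AI side
-------
Each model's scores are calibrated to a common (0, 1) scale with the
label-free midrank transform ``(rank - 0.5) / m`` (ties share their mean
rank), which leaves every model's ROC curve unchanged, and the per-case
consensus is the arithmetic mean of the calibrated scores.  No exclusion
rules apply on the AI side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "ExclusionReason", "ConsensusScore", "likert_to_probability",
    "reader_consensus", "reader_consensus_table",
    "calibrate_model_scores", "ai_ensemble_consensus",
]

UNDEFINED_SCORE = 3


class ExclusionReason(str, Enum):
    NONE = "none"
    UNDEFINED_MAJORITY = "undefined_majority"
    TOO_FEW_RESPONSES = "too_few_responses"


@dataclass
class ConsensusScore:
    """Per-case aggregated score on the probability-of-pathology scale."""
    case_id: str | None
    value: float | None
    n_responses: int
    excluded: bool
    exclusion_reason: ExclusionReason

    def __post_init__(self):
        assert self.excluded == (self.exclusion_reason != ExclusionReason.NONE)


def likert_to_probability(score):
    """Map an ordinal rating 1..5 to a probability of pathology, (s - 1)/4.

    Accepts a scalar or array; anything outside {1,...,5} raises
    :class:`ValidationError`.
    """
    arr = np.asarray(score)
    if not np.isin(arr, (1, 2, 3, 4, 5)).all():
        raise ValidationError(f"score(s) {score!r} outside the 1..5 scale")
    out = (arr - 1) / 4.0
    return float(out) if np.isscalar(score) else out


def _upper_median(sorted_scores: np.ndarray) -> int:
    # the ceil((n+1)/2)-th order statistic, i.e. index n//2 zero-based
    return int(sorted_scores[sorted_scores.size // 2])


def reader_consensus(scores, min_responses: int = 5,
                     apply_min_filter: bool = True,
                     rule: str = "upper_median",
                     case_id: str | None = None) -> ConsensusScore:
    """Aggregate one case's reader ratings into a consensus score.

    Exclusion rules are applied in order: undefined-majority first (> 50 % of
    ratings equal 3), then the minimum-response filter (when
    ``apply_min_filter``).  The consensus of a surviving case is the upper
    median (or the higher-tie mode under ``rule="mode_high"``) mapped by
    :func:`likert_to_probability`.
    """
    arr = np.asarray(scores, dtype=int)
    if arr.size == 0:
        raise ValidationError("empty rating set")
    if not np.isin(arr, (1, 2, 3, 4, 5)).all():
        raise ValidationError("ratings outside the 1..5 scale")
    n = arr.size
    if (arr == UNDEFINED_SCORE).sum() * 2 > n:
        return ConsensusScore(case_id, None, n, True,
                              ExclusionReason.UNDEFINED_MAJORITY)
    if apply_min_filter and n < min_responses:
        return ConsensusScore(case_id, None, n, True,
                              ExclusionReason.TOO_FEW_RESPONSES)
    if rule == "upper_median":
        score = _upper_median(np.sort(arr))
    elif rule == "mode_high":
        counts = np.bincount(arr, minlength=6)[1:]
        score = int(np.flatnonzero(counts == counts.max())[-1] + 1)
    else:
        raise ValidationError(f"unknown consensus rule {rule!r}")
    return ConsensusScore(case_id, likert_to_probability(score), n, False,
                          ExclusionReason.NONE)


def reader_consensus_table(ratings: pd.DataFrame, min_responses: int = 5,
                           apply_min_filter: bool = True,
                           rule: str = "upper_median") -> pd.DataFrame:
    """Apply :func:`reader_consensus` per case over a ratings table.

    Returns one row per case with columns ``case_id, value, n_responses,
    excluded, exclusion_reason``.
    """
    rows = []
    for case_id, grp in ratings.groupby("case_id", sort=True):
        cs = reader_consensus(grp["score"].to_numpy(), min_responses,
                              apply_min_filter, rule, case_id=case_id)
        rows.append((case_id, cs.value, cs.n_responses, cs.excluded,
                     cs.exclusion_reason.value))
    return pd.DataFrame(rows, columns=["case_id", "value", "n_responses",
                                       "excluded", "exclusion_reason"])


def calibrate_model_scores(probs) -> np.ndarray:
    """Midrank-calibrate one model's scores to a common (0, 1) scale.

    ``calibrated = (midrank - 0.5) / m`` over the model's ``m`` scores; ties
    share their mean rank.  Strictly increasing in the input up to ties, so
    the model's ROC curve is unchanged.  A degenerate model (all scores
    identical) calibrates to 0.5 everywhere with a logged warning.
    """
    arr = np.asarray(probs, dtype=float)
    if arr.size == 0:
        raise ValidationError("empty score set")
    if np.unique(arr).size == 1 and arr.size > 1:
        logger.warning("degenerate model: all %d scores identical; "
                       "calibrated output is constant 0.5", arr.size)
    return (stats.rankdata(arr) - 0.5) / arr.size


def ai_ensemble_consensus(model_scores: pd.DataFrame) -> pd.DataFrame:
    """Calibrate each model then average per case into the AI consensus.

    ``model_scores`` has columns ``model_id, case_id, prob``.  Every model is
    midrank-calibrated over its own scores; the consensus value for a case is
    the arithmetic mean of the calibrated scores of the models that scored
    it, with ``n_responses`` the number of contributing models.  No exclusion
    rules apply on the AI side.
    """
    if model_scores.empty:
        logger.warning("no model scores; AI consensus is empty")
        return pd.DataFrame(columns=["case_id", "value", "n_responses",
                                     "excluded", "exclusion_reason"])
    frame = model_scores.copy()
    frame["calibrated"] = np.nan
    for _, idx in frame.groupby("model_id").groups.items():
        frame.loc[idx, "calibrated"] = calibrate_model_scores(
            frame.loc[idx, "prob"].to_numpy())
    agg = (frame.groupby("case_id", sort=True)["calibrated"]
           .agg(["mean", "size"]).reset_index())
    agg.columns = ["case_id", "value", "n_responses"]
    agg["excluded"] = False
    agg["exclusion_reason"] = ExclusionReason.NONE.value
    return agg
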