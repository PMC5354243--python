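"""ROC curves, C-statistic, decision threshold and confusion summaries.

All tail probabilities are obtained by trapezoidal integration of the two
fitted score densities on a shared grid, so results are reproducible
bit-for-bit for a fixed grid convention.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .density import ScoreDistribution
from .fda import CVScores

_MERGED_GRID_POINTS = 2048


class ROCError(ValueError):
    pass


@dataclass(frozen=True)
class ROCResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    c_statistic: float
    flipped: bool = False


@dataclass(frozen=True)
class ConfusionSummary:
    """Counts and the four derived rates at a fixed threshold.

    Rates with a zero denominator are ``None`` (undefined), never 0.
    """

    threshold: float
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def n(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    @staticmethod
    def _rate(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    @property
    def TPR(self) -> float | None:
        return self._rate(self.TP, self.TP + self.FN)

    @property
    def FPR(self) -> float | None:
        return self._rate(self.FP, self.FP + self.TN)

    @property
    def PPV(self) -> float | None:
        return self._rate(self.TP, self.TP + self.FP)

    @property
    def NPV(self) -> float | None:
        return self._rate(self.TN, self.TN + self.FN)

    def to_json(self) -> str:
        return json.dumps(
            {
                "threshold": self.threshold,
                "TP": self.TP,
                "FP": self.FP,
                "TN": self.TN,
                "FN": self.FN,
                "TPR": self.TPR,
                "FPR": self.FPR,
                "PPV": self.PPV,
                "NPV": self.NPV,
            },
            indent=2,
        )


@dataclass(frozen=True)
class ThresholdResult:
    threshold: float
    fallback_midpoint: bool = False


def _merged_grid(pdf_a: ScoreDistribution, pdf_b: ScoreDistribution) -> np.ndarray:
    lo = min(pdf_a.grid[0], pdf_b.grid[0])
    hi = max(pdf_a.grid[-1], pdf_b.grid[-1])
    return np.linspace(lo, hi, _MERGED_GRID_POINTS)


def _tail_probabilities(density: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """P(score > t) for every t in grid, by trapezoid from the right."""
    dx = np.diff(grid)
    seg = 0.5 * (density[:-1] + density[1:]) * dx
    tail = np.concatenate([np.cumsum(seg[::-1])[::-1], [0.0]])
    total = tail[0]
    if total <= 0:
        raise ROCError("degenerate (zero-mass) PDF")
    return np.clip(tail / total, 0.0, 1.0)


def roc_c_statistic(
    pdf_pos: ScoreDistribution, pdf_neg: ScoreDistribution
) -> ROCResult:
    """ROC curve and area from the two fitted densities.

    Orientation is auto-corrected so the area is >= 0.5; the ``flipped``
    flag records when the correction fired.
    """
    grid = _merged_grid(pdf_pos, pdf_neg)
    dens_pos = pdf_pos.pdf(grid)
    dens_neg = pdf_neg.pdf(grid)
    tpr = _tail_probabilities(dens_pos, grid)
    fpr = _tail_probabilities(dens_neg, grid)
    # thresholds descend left-to-right in (fpr, tpr) space; integrate tpr d(fpr)
    c = float(np.trapezoid(tpr[::-1], fpr[::-1]))
    flipped = False
    if c < 0.5:
        tpr, fpr = 1.0 - tpr, 1.0 - fpr
        c = 1.0 - c
        flipped = True
    return ROCResult(thresholds=grid, fpr=fpr, tpr=tpr, c_statistic=c, flipped=flipped)


def decision_threshold(
    pdf_pos: ScoreDistribution, pdf_neg: ScoreDistribution
) -> ThresholdResult:
    """Equal-density crossing between the two cohort score means.

    Among multiple crossings the one closest to the midpoint of the means is
    taken; with no crossing in the inter-mean interval the midpoint itself is
    returned with a fallback flag.
    """
    m_pos, m_neg = pdf_pos.mean, pdf_neg.mean
    lo, hi = min(m_pos, m_neg), max(m_pos, m_neg)
    mid = 0.5 * (m_pos + m_neg)
    if hi - lo <= 0:
        return ThresholdResult(threshold=mid, fallback_midpoint=True)
    grid = np.linspace(lo, hi, _MERGED_GRID_POINTS)
    diff = pdf_pos.pdf(grid) - pdf_neg.pdf(grid)
    sign = np.sign(diff)
    idx = np.nonzero(np.diff(sign) != 0)[0]
    crossings = []
    for i in idx:
        x0, x1 = grid[i], grid[i + 1]
        d0, d1 = diff[i], diff[i + 1]
        if d1 == d0:
            crossings.append(0.5 * (x0 + x1))
        else:
            crossings.append(x0 - d0 * (x1 - x0) / (d1 - d0))
    exact_zero = grid[diff == 0]
    crossings.extend(float(z) for z in exact_zero)
    if not crossings:
        return ThresholdResult(threshold=mid, fallback_midpoint=True)
    best = min(crossings, key=lambda t: abs(t - mid))
    return ThresholdResult(threshold=float(best), fallback_midpoint=False)


def confusion_at(
    scores: CVScores, positive: str, threshold: float
) -> ConfusionSummary:
    """Counts with the rule score > threshold => positive; ties negative."""
    if len(scores.scores) == 0:
        raise ROCError("no scores")
    if not np.isfinite(threshold):
        raise ROCError("threshold must be finite")
    pred_pos = scores.scores > threshold
    is_pos = np.array([c == positive for c in scores.cohorts])
    TP = int(np.sum(pred_pos & is_pos))
    FP = int(np.sum(pred_pos & ~is_pos))
    TN = int(np.sum(~pred_pos & ~is_pos))
    FN = int(np.sum(~pred_pos & is_pos))
    return ConfusionSummary(threshold=float(threshold), TP=TP, FP=FP, TN=TN, FN=FN)


@dataclass(frozen=True)
class ErrorCurves:
    thresholds: np.ndarray
    type_i: np.ndarray  # false positive rate at each threshold
    type_ii: np.ndarray  # false negative rate at each threshold


def error_curves(
    scores: CVScores, positive: str, thresholds: Sequence[float] | np.ndarray
) -> ErrorCurves:
    """Empirical Type I (FPR) and Type II (FNR) error rates per threshold."""
    thresholds = np.asarray(thresholds, dtype=float)
    s = scores.scores
    is_pos = np.array([c == positive for c in scores.cohorts])
    n_pos = int(is_pos.sum())
    n_neg = int((~is_pos).sum())
    type_i = np.empty(len(thresholds))
    type_ii = np.empty(len(thresholds))
    for i, t in enumerate(thresholds):
        pred_pos = s > t
        type_i[i] = np.sum(pred_pos & ~is_pos) / n_neg if n_neg else np.nan
        type_ii[i] = np.sum(~pred_pos & is_pos) / n_pos if n_pos else np.nan
    return ErrorCurves(thresholds=thresholds, type_i=type_i, type_ii=type_ii)
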