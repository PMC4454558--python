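"""Evaluation protocol: correlation, error, deviation-bin and score-range
analyses, plus inter-annotator agreement statistics."""

from __future__ import annotations

import logging
import math
from collections import OrderedDict
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

#: Deviation bins: first interval closed on both ends, the rest half-open
#: (a, b], so a deviation of exactly 0 falls in (-0.5, 0].
ERROR_BIN_EDGES = [(-2.5, -2.0)] + [
    (lo, lo + 0.5) for lo in np.arange(-2.0, 2.5, 0.5)
]
SCORE_RANGES = ((1.0, 2.0), (2.0, 3.0), (3.0, 4.0), (4.0, 5.0))


def _bin_label(lo: float, hi: float, closed_left: bool) -> str:
    left = "[" if closed_left else "("
    return f"{left}{lo:g}, {hi:g}]"


def pearson(pred, gold) -> float:
    """Product-moment correlation; raises on constant input."""
    pred = np.asarray(pred, dtype=float)
    gold = np.asarray(gold, dtype=float)
    if pred.shape != gold.shape:
        raise ValueError("prediction and gold vectors differ in length")
    if pred.size < 2:
        raise ValueError("need at least 2 points for a correlation")
    if np.ptp(pred) == 0 or np.ptp(gold) == 0:
        raise ValueError("undefined correlation for a constant vector")
    return float(stats.pearsonr(pred, gold)[0])


def mse(pred, gold) -> float:
    """Mean squared deviation."""
    pred = np.asarray(pred, dtype=float)
    gold = np.asarray(gold, dtype=float)
    if pred.shape != gold.shape:
        raise ValueError("prediction and gold vectors differ in length")
    return float(np.mean((pred - gold) ** 2))


def error_distribution(pred, gold) -> "OrderedDict[str, int]":
    """Counts of prediction deviations (pred - gold) over the ten intervals
    [-2.5, -2], (-2, -1.5], ..., (2, 2.5].  Deviations outside [-2.5, 2.5]
    are collected in an ``overflow`` bin with a warning."""
    dev = np.asarray(pred, dtype=float) - np.asarray(gold, dtype=float)
    counts: "OrderedDict[str, int]" = OrderedDict()
    for i, (lo, hi) in enumerate(ERROR_BIN_EDGES):
        closed_left = i == 0
        if closed_left:
            mask = (dev >= lo) & (dev <= hi)
        else:
            mask = (dev > lo) & (dev <= hi)
        counts[_bin_label(lo, hi, closed_left)] = int(mask.sum())
    overflow = int(((dev < -2.5) | (dev > 2.5)).sum())
    if overflow:
        logger.warning("%d deviations outside [-2.5, 2.5]", overflow)
        counts["overflow"] = overflow
    assert sum(counts.values()) == dev.size
    return counts


@dataclass(frozen=True)
class RangeStatistics:
    """Per score-range prediction behaviour."""

    count: int
    pearson: float | None     # None when undefined (constant gold in range)
    n_underestimated: int     # pred < gold
    n_overestimated: int      # pred >= gold
    min_deviation: float
    max_deviation: float


def range_split_analysis(pred, gold) -> "OrderedDict[str, RangeStatistics]":
    """Split pairs by gold score into [1,2), [2,3), [3,4), [4,5] and report
    count, Pearson, under-/over-estimation counts and deviation extremes."""
    pred = np.asarray(pred, dtype=float)
    gold = np.asarray(gold, dtype=float)
    if np.min(gold) < 1 or np.max(gold) > 5:
        raise ValueError("gold scores must lie in [1, 5]")
    out: "OrderedDict[str, RangeStatistics]" = OrderedDict()
    for lo, hi in SCORE_RANGES:
        last = hi == 5.0
        mask = (gold >= lo) & ((gold <= hi) if last else (gold < hi))
        label = f"[{lo:g}, {hi:g}{']' if last else ')'}"
        if not np.any(mask):
            out[label] = RangeStatistics(0, None, 0, 0, math.nan, math.nan)
            continue
        p, g = pred[mask], gold[mask]
        dev = p - g
        try:
            r = pearson(p, g)
        except ValueError:
            logger.warning("Pearson undefined in range %s", label)
            r = None
        out[label] = RangeStatistics(
            count=int(mask.sum()),
            pearson=r,
            n_underestimated=int((p < g).sum()),
            n_overestimated=int((p >= g).sum()),
            min_deviation=float(dev.min()),
            max_deviation=float(dev.max()),
        )
    return out


@dataclass(frozen=True)
class AgreementReport:
    pairwise: np.ndarray            # annotator x annotator Pearson, nan diagonal
    per_annotator: np.ndarray       # mean of off-diagonal entries per row
    overall: float                  # mean over distinct annotator pairs
    inverse_agreement: float        # mean per-item rating standard deviation


def annotator_agreement(scores, population_sd: bool = True) -> AgreementReport:
    """Agreement statistics for an annotator x item rating matrix.

    The pairwise matrix holds Pearson correlations between annotators (nan
    on the diagonal and for undefined pairs); the inverse agreement is the
    mean over items of the per-item standard deviation of ratings
    (population formula by default, ``ddof=1`` when ``population_sd`` is
    False).
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[0] < 2 or scores.shape[1] < 2:
        raise ValueError("need a matrix of >= 2 annotators x >= 2 items")
    n = scores.shape[0]
    pairwise = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i + 1, n):
            try:
                r = pearson(scores[i], scores[j])
            except ValueError:
                logger.warning("constant annotator: correlation (%d, %d) undefined", i, j)
                r = np.nan
            pairwise[i, j] = pairwise[j, i] = r
    import warnings

    upper = pairwise[np.triu_indices(n, k=1)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-nan rows
        per_annotator = np.nanmean(pairwise, axis=1)
        overall = float(np.nanmean(upper))
    sd = scores.std(axis=0, ddof=0 if population_sd else 1)
    return AgreementReport(
        pairwise=pairwise,
        per_annotator=per_annotator,
        overall=overall,
        inverse_agreement=float(sd.mean()),
    )


def report_tables(pred, gold) -> dict:
    """Machine-readable evaluation report (JSON-serialisable)."""
    ranges = range_split_analysis(pred, gold)
    return {
        "pearson": pearson(pred, gold),
        "mse": mse(pred, gold),
        "error_distribution": dict(error_distribution(pred, gold)),
        "range_split": {
            label: {
                "count": s.count,
                "pearson": s.pearson,
                "n_underestimated": s.n_underestimated,
                "n_overestimated": s.n_overestimated,
                "min_deviation": s.min_deviation,
                "max_deviation": s.max_deviation,
            }
            for label, s in ranges.items()
        },
    }
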