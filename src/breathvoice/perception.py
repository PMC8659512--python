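"""Perceptual-rating handling and feature-vs-rating correlation analysis.

Two raters score each 2-second sample on a 9-point discrete scale (0 to 4
in half-point steps).  The two scores are averaged, giving a 17-value
0.25-step grid, and the averages are binned into five breathiness classes
(boundaries <0.75, <=1.5, <=2.25, <=3.25, <=4; the first and last class
cover exactly three grid values each).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import SignalError

CLASS_UPPER_BOUNDS = (0.75, 1.5, 2.25, 3.25, 4.0)

#: absolute inter-rater deviation bins, counted in half-point grid steps
AGREEMENT_BINS = ((0, 0), (1, 1), (2, 3), (4, 5), (6, 8))
AGREEMENT_LABELS = ("exact", "1 step", "2-3 steps", "4-5 steps", "6-8 steps")


def _check_half_point(score: float) -> float:
    s = float(score)
    if not 0.0 <= s <= 4.0 or round(s * 2) != s * 2:
        raise SignalError(f"score {score!r} is not on the 0-4 half-point grid")
    return s


def classify(average: float) -> int:
    """Map a 0.25-step averaged rating onto the 0-4 class taxonomy."""
    if average < CLASS_UPPER_BOUNDS[0]:
        return 0
    for cls, bound in enumerate(CLASS_UPPER_BOUNDS[1:], start=1):
        if average <= bound:
            return cls
    raise SignalError(f"average {average} outside the 0-4 range")


@dataclass(frozen=True)
class RatingRecord:
    rater1: float
    rater2: float
    average: float
    cls: int
    sample_id: str = ""


def average_and_classify(r1: float, r2: float, sample_id: str = "") -> RatingRecord:
    """Average two half-point scores and assign the breathiness class."""
    r1, r2 = _check_half_point(r1), _check_half_point(r2)
    avg = (r1 + r2) / 2.0
    return RatingRecord(rater1=r1, rater2=r2, average=avg,
                        cls=classify(avg), sample_id=sample_id)


def score_grid() -> np.ndarray:
    """All attainable averaged scores: 0.00, 0.25, ..., 4.00 (17 values)."""
    return np.round(np.arange(0, 17) * 0.25, 2)


def grid_class_counts() -> list[int]:
    """Grid values per class under the taxonomy (3, 4, 3, 4, 3)."""
    classes = [classify(v) for v in score_grid()]
    return [classes.count(c) for c in range(5)]


def agreement_distribution(pairs) -> pd.DataFrame:
    """Inter-rater absolute deviation distribution.

    Deviations are counted in half-point grid steps (so the largest
    possible disagreement, 0 vs 4, is 8 steps) and binned as exact / 1 /
    2-3 / 4-5 / 6-8 steps.  Percentages are rounded to one decimal.
    """
    pairs = list(pairs)
    if not pairs:
        raise SignalError("empty rating set")
    steps = np.array([
        int(round(abs(_check_half_point(a) - _check_half_point(b)) / 0.5))
        for a, b in pairs
    ])
    counts = [int(np.sum((steps >= lo) & (steps <= hi))) for lo, hi in AGREEMENT_BINS]
    n = len(pairs)
    return pd.DataFrame({
        "bin": AGREEMENT_LABELS,
        "count": counts,
        "percent": [round(100.0 * c / n, 1) for c in counts],
    })


def _clean_pair(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise SignalError("need at least 3 paired finite observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise SignalError("zero variance in one of the variables")
    return x, y


def pearson(x, y) -> tuple[float, float]:
    """Product-moment correlation with its t-distribution p-value
    (n - 2 degrees of freedom)."""
    x, y = _clean_pair(x, y)
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def spearman(x, y) -> tuple[float, float]:
    """Rank correlation (tie-corrected) with its p-value."""
    x, y = _clean_pair(x, y)
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def correlation_table(features: pd.DataFrame, ratings,
                      feature_names=None) -> pd.DataFrame:
    """Pearson and Spearman correlations of each feature against the
    averaged breathiness ratings.

    Samples with flagged (NaN) features are excluded pairwise; the n used
    for each feature is reported.
    """
    ratings = np.asarray(ratings, dtype=float)
    if feature_names is None:
        feature_names = [c for c in features.columns
                         if features[c].dtype.kind in "fi"]
    rows = []
    for name in feature_names:
        x = features[name].to_numpy(dtype=float)
        keep = np.isfinite(x) & np.isfinite(ratings)
        r, p_r = pearson(x[keep], ratings[keep])
        rho, p_rho = spearman(x[keep], ratings[keep])
        rows.append({"feature": name, "r": r, "p_r": p_r,
                     "rho": rho, "p_rho": p_rho, "n": int(keep.sum())})
    return pd.DataFrame(rows)


def class_descriptives(rows: pd.DataFrame, class_col: str = "cls",
                       feature_names=None) -> pd.DataFrame:
    """Per-class arithmetic feature means (one row per observed class).

    Empty classes are absent from the output rather than filled with
    placeholders.
    """
    if feature_names is None:
        feature_names = [c for c in rows.columns
                         if c != class_col and rows[c].dtype.kind in "fi"]
    out = (rows.groupby(class_col)[list(feature_names)]
           .mean().reset_index().sort_values(class_col))
    return out.reset_index(drop=True)
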