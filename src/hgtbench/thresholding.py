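"""Uniform boxplot threshold protocol and ROC-like evaluation.

A method's per-gene scores are summarized by a boxplot: with Q1 and Q3
the first and third quartiles and IQR = Q3 - Q1, the whisker fences are

    S_inf = Q1 - r * IQR        S_sup = Q3 + r * IQR

and any score beyond the fence on the method's atypical side is called
an outlier, i.e. a putative horizontal transfer.  Sweeping the whisker
factor r from 0.5 to 4.0 in steps of 0.5 traces a ROC-like curve of
type I error (100 - sensitivity) against type II error
(100 - specificity); the optimal r minimizes the mean of the two
errors, and a method is considered stable when the standard deviation
of its optimal r across replicate genomes stays below 0.5 (one grid
step).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from hgtbench.detector import Direction, GeneScores
from hgtbench.genome_io import NATIVE_LABEL

DEFAULT_R_GRID: tuple[float, ...] = tuple(np.arange(0.5, 4.01, 0.5))

#: classical boxplot fence, used when no tuning has been done
DEFAULT_R: float = 1.5


@dataclass(frozen=True)
class ThresholdResult:
    Q1: float
    Q3: float
    r: float
    S_inf: float
    S_sup: float


@dataclass
class RocCurve:
    """(r, type I error %, type II error %) triples for one method on one
    genome."""

    method: str
    points: list[tuple[float, float, float]]

    def mean_errors(self) -> list[tuple[float, float]]:
        return [(r, (t1 + t2) / 2.0) for r, t1, t2 in self.points]


def quartiles(scores: Sequence[float]) -> tuple[float, float]:
    """First and third quartile by linear interpolation between order
    statistics (the default convention of mainstream statistical
    software)."""
    arr = np.asarray(scores, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 2:
        raise ValueError("need at least 2 finite scores")
    q1, q3 = np.percentile(arr, [25, 75], method="linear")
    return float(q1), float(q3)


def whisker_bounds(q1: float, q3: float, r: float) -> tuple[float, float]:
    """Boxplot whisker fences S_inf = Q1 - r*IQR, S_sup = Q3 + r*IQR."""
    if q3 < q1:
        raise ValueError("Q3 < Q1")
    if r < 0:
        raise ValueError("r must be >= 0")
    iqr = q3 - q1
    return q1 - r * iqr, q3 + r * iqr


def threshold_result(scores: Sequence[float], r: float) -> ThresholdResult:
    q1, q3 = quartiles(scores)
    s_inf, s_sup = whisker_bounds(q1, q3, r)
    return ThresholdResult(q1, q3, r, s_inf, s_sup)


def _classify_component(
    scores: Mapping[str, float], r: float, direction: Direction
) -> dict[str, bool]:
    t = threshold_result(list(scores.values()), r)
    if direction is Direction.UPPER:
        return {gid: s > t.S_sup for gid, s in scores.items()}
    if direction is Direction.LOWER:
        return {gid: s < t.S_inf for gid, s in scores.items()}
    return {gid: s < t.S_inf or s > t.S_sup for gid, s in scores.items()}


def classify(gs: GeneScores, r: float, direction: Direction) -> dict[str, bool]:
    """Boxplot outlier calls for one method at whisker factor r.

    For the two-component GC1/GC3 method each component gets its own
    two-sided fences and a gene is atypical only when both components
    lie outside theirs.
    """
    calls = _classify_component(gs.scores, r, direction)
    if gs.scores2 is not None:
        calls2 = _classify_component(gs.scores2, r, Direction.TWO_SIDED)
        calls = {gid: calls[gid] and calls2.get(gid, False) for gid in calls}
    return calls


def mean_error(sensitivity: float, specificity: float) -> float:
    """Mean of type I (100 - sensitivity) and type II (100 - specificity)
    errors, all in percent."""
    if not (0 <= sensitivity <= 100 and 0 <= specificity <= 100):
        raise ValueError("sensitivity/specificity must be in [0, 100]")
    return ((100.0 - sensitivity) + (100.0 - specificity)) / 2.0


def _confusion(
    calls: Mapping[str, bool], truth: Mapping[str, str]
) -> tuple[int, int, int, int]:
    tp = fp = tn = fn = 0
    for gid, called in calls.items():
        is_ht = truth[gid] != NATIVE_LABEL
        if called and is_ht:
            tp += 1
        elif called:
            fp += 1
        elif is_ht:
            fn += 1
        else:
            tn += 1
    return tp, fp, tn, fn


def roc_sweep(
    gs: GeneScores,
    truth: Mapping[str, str],
    direction: Direction,
    r_grid: Sequence[float] = DEFAULT_R_GRID,
) -> RocCurve:
    """Type I / type II errors over the whisker-factor grid."""
    missing = set(gs.scores) - set(truth)
    if missing:
        raise ValueError(f"truth missing scored genes: {sorted(missing)[:5]}")
    points = []
    for r in r_grid:
        calls = classify(gs, r, direction)
        tp, fp, tn, fn = _confusion(calls, truth)
        sens = 100.0 * tp / (tp + fn) if tp + fn else 100.0
        spec = 100.0 * tn / (tn + fp) if tn + fp else 100.0
        points.append((float(r), 100.0 - sens, 100.0 - spec))
    return RocCurve(gs.method, points)


def optimal_r(curves: Sequence[RocCurve]) -> tuple[float, bool]:
    """Mean optimal whisker factor over replicate genomes and stability.

    Per replicate the optimum is the r minimizing the mean error (ties
    broken toward the smallest, most sensitive, r); a method is stable
    when the population standard deviation of the per-replicate optima
    is below 0.5.
    """
    if not curves:
        raise ValueError("need at least one curve")
    optima = []
    for curve in curves:
        errs = curve.mean_errors()
        best_r, _ = min(errs, key=lambda p: (p[1], p[0]))
        optima.append(best_r)
    arr = np.asarray(optima)
    return float(arr.mean()), bool(arr.std(ddof=0) < 0.5)
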