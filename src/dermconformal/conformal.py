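"""Split conformal prediction with a finite-sample marginal coverage guarantee.

Given a held-out calibration set never touched during training or testing,
split conformal prediction turns any classifier's probabilities into
prediction sets with the distribution-free guarantee

    1 - α  ≤  P(Y_test ∈ C(X_test))  ≤  1 - α + 1/(n+1)

under exchangeability of calibration and test samples, where α is the
user-chosen error rate and n the calibration size.  The nonconformity score
used here is the deviation of the prediction from the truth, s = 1 - p̂(y);
the threshold is the ⌈(n+1)(1-α)⌉-th smallest calibration score (the
finite-sample-corrected 1-α quantile).  A test label enters the set iff
1 - p̂(label) ≤ threshold; set length is a per-sample difficulty signal.

Also here: empirical coverage, expected-vs-observed coverage curves, and the
expected / maximum calibration error (ECE / MCE) of the set confidences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "CalibrationResult",
    "PredictionSet",
    "build_set",
    "build_sets",
    "calibrate",
    "coverage_curve",
    "ece_mce",
    "empirical_coverage",
    "nonconformity_scores",
]


@dataclass(frozen=True)
class CalibrationResult:
    """Calibration scores, error rate, and the corrected quantile threshold."""

    alpha: float
    n: int
    scores: np.ndarray
    q_hat: float


@dataclass(frozen=True)
class PredictionSet:
    """Labels surviving the score threshold for one test sample.

    ``entries`` are (label, confidence) pairs in strictly descending
    confidence (ties broken by ascending label index); confidences are the
    classifier's raw probabilities, not renormalised within the set.
    """

    sample_id: str
    entries: tuple[tuple[int, float], ...]
    truth: int | None = None

    @property
    def labels(self) -> tuple[int, ...]:
        return tuple(lbl for lbl, _ in self.entries)

    @property
    def size(self) -> int:
        return len(self.entries)

    def contains_truth(self) -> bool:
        if self.truth is None:
            raise ValueError(f"set {self.sample_id} has no ground truth attached")
        return self.truth in self.labels

    def truth_rank(self) -> int | None:
        """1-based rank of the truth within the set, or None if absent."""
        if self.truth is None:
            raise ValueError(f"set {self.sample_id} has no ground truth attached")
        for rank, (lbl, _) in enumerate(self.entries, start=1):
            if lbl == self.truth:
                return rank
        return None

    def truth_confidence(self) -> float | None:
        for lbl, conf in self.entries:
            if lbl == self.truth:
                return conf
        return None


def nonconformity_scores(prob_matrix: np.ndarray, truth: Sequence[int]) -> np.ndarray:
    """Per-sample score s_i = 1 - p̂(true label of i), in [0, 1]."""
    prob_matrix = np.asarray(prob_matrix, dtype=np.float64)
    truth = np.asarray(truth, dtype=int)
    n, n_classes = prob_matrix.shape
    if truth.size != n:
        raise ValueError(f"got {truth.size} labels for {n} probability rows")
    if (truth < 0).any() or (truth >= n_classes).any():
        raise ValueError(f"labels must lie in [0, {n_classes}); got out-of-range values")
    return 1.0 - prob_matrix[np.arange(n), truth]


def calibrate(scores: Sequence[float], alpha: float) -> CalibrationResult:
    """Finite-sample-corrected quantile of the calibration scores.

    The threshold is the ⌈(n+1)(1-α)⌉-th smallest score.  The rank is
    clamped to [1, n+1]: α = 1 would give rank 0, which is clamped to 1 (the
    minimum score); a rank of n+1 (e.g. α = 0, or any α < 1/(n+1)) exceeds
    the sample and yields q_hat = +inf, i.e. every set is the full label
    space.
    """
    scores = np.asarray(scores, dtype=np.float64)
    if scores.size == 0:
        raise ValueError("calibration scores are empty")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    n = scores.size
    rank = math.ceil((n + 1) * (1.0 - alpha))
    rank = min(max(rank, 1), n + 1)
    if rank > n:
        q_hat = math.inf
    else:
        q_hat = float(np.sort(scores)[rank - 1])
    return CalibrationResult(alpha=alpha, n=n, scores=scores, q_hat=q_hat)


def build_set(
    prob_row: np.ndarray,
    calib: CalibrationResult,
    sample_id: str = "",
    truth: int | None = None,
    allow_empty: bool = False,
) -> PredictionSet:
    """Prediction set for one probability row.

    A label enters iff its score 1 - p̂(label) ≤ q_hat.  If no label
    qualifies the argmax label is included alone — a documented deviation
    from the pure procedure guaranteeing nonempty sets; pass
    ``allow_empty=True`` for the strict behaviour.
    """
    p = np.asarray(prob_row, dtype=np.float64)
    keep = (1.0 - p) <= calib.q_hat
    labels = np.flatnonzero(keep)
    if labels.size == 0 and not allow_empty:
        labels = np.array([int(p.argmax())])
    # descending confidence, stable ascending-label tie-break
    order = np.lexsort((labels, -p[labels]))
    entries = tuple((int(lbl), float(p[lbl])) for lbl in labels[order])
    return PredictionSet(sample_id=sample_id, entries=entries, truth=truth)


def build_sets(
    prob_matrix: np.ndarray,
    calib: CalibrationResult,
    sample_ids: Sequence[str] | None = None,
    truths: Sequence[int] | None = None,
    allow_empty: bool = False,
) -> list[PredictionSet]:
    """Vector form of :func:`build_set` over a probability matrix."""
    prob_matrix = np.asarray(prob_matrix, dtype=np.float64)
    n = prob_matrix.shape[0]
    if sample_ids is None:
        sample_ids = [str(i) for i in range(n)]
    return [
        build_set(
            prob_matrix[i],
            calib,
            sample_id=sample_ids[i],
            truth=None if truths is None else int(truths[i]),
            allow_empty=allow_empty,
        )
        for i in range(n)
    ]


def empirical_coverage(sets: Sequence[PredictionSet], truths: Sequence[int] | None = None) -> float:
    """Fraction of prediction sets containing the true label."""
    if truths is not None:
        hits = [t in s.labels for s, t in zip(sets, truths, strict=True)]
    else:
        hits = [s.contains_truth() for s in sets]
    if not hits:
        raise ValueError("no prediction sets given")
    return float(np.mean(hits))


def ece_mce(
    confidences: Sequence[float],
    correctness: Sequence[bool],
    n_bins: int = 10,
) -> tuple[float, float]:
    """Expected and maximum calibration error over equal-width bins.

    Per nonempty bin, the gap is |mean correctness - mean confidence|; the
    ECE is the sample-weighted mean gap and the MCE the maximum gap.  In the
    conformal audit the confidences are the per-set top-label confidences and
    correctness is whether the set contains the truth.
    """
    conf = np.asarray(confidences, dtype=np.float64)
    corr = np.asarray(correctness, dtype=np.float64)
    if conf.size != corr.size:
        raise ValueError("confidences and correctness must have equal length")
    if conf.size == 0:
        raise ValueError("no samples to bin")
    if (conf < 0).any() or (conf > 1).any():
        raise ValueError("confidences must lie in [0, 1]")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    # bin i covers ((i)/n_bins, (i+1)/n_bins]; confidence 0 joins the first bin
    idx = np.clip(np.ceil(conf * n_bins).astype(int) - 1, 0, n_bins - 1)
    ece = 0.0
    mce = 0.0
    for b in range(n_bins):
        mask = idx == b
        if not mask.any():
            continue
        gap = abs(corr[mask].mean() - conf[mask].mean())
        ece += mask.mean() * gap
        mce = max(mce, gap)
    return float(ece), float(mce)


def coverage_curve(
    prob_cal: np.ndarray,
    truth_cal: Sequence[int],
    prob_test: np.ndarray,
    truth_test: Sequence[int],
    alphas: Sequence[float],
) -> list[tuple[float, float]]:
    """(expected, observed) coverage pairs over a grid of error rates.

    For each α the calibration quantile is recomputed and the empirical test
    coverage measured; on exchangeable data the observed curve should track
    the diagonal from above.
    """
    alphas = list(alphas)
    if any(not 0.0 < a < 1.0 for a in alphas):
        raise ValueError("alphas must lie in (0, 1)")
    scores = nonconformity_scores(prob_cal, truth_cal)
    truth_test = np.asarray(truth_test, dtype=int)
    out = []
    for a in alphas:
        calib = calibrate(scores, a)
        sets = build_sets(prob_test, calib, truths=truth_test)
        out.append((1.0 - a, empirical_coverage(sets)))
    return out
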