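"""Challenge-regulated F1-score sampling for highly imbalanced datasets.

Class-imbalanced dermatology datasets (max:min ratios up to ~48:1) starve
minority classes during training.  The dynamic sampler here counteracts that
by drawing each epoch's training stream with per-class probabilities that are

* initialised from inverse class frequency,
      w_i = (1/n_i) / sum_j (1/n_j),
* periodically refreshed from inverse mean classwise F1 on the validation
  set (mean over k stratified folds),
      w_i = (1/x̄_i) / sum_j (1/x̄_j),
* and regulated by two parameters: a threshold λ deciding which classes are
  F1-weight sampled versus baseline sampled, and a minimum weight β bounding
  how hard any single class can dominate the stream.

λ and β are expressed in population standard deviations above the mean
weight (default 1 and 2 respectively, refresh every 4 epochs).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from sklearn.metrics import f1_score
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "ClassWeights",
    "SamplerConfig",
    "f1_weights",
    "frequency_weights",
    "kfold_mean_f1",
    "regulate_weights",
    "sample_epoch",
]

logger = logging.getLogger(__name__)

_NORM_TOL = 1e-9


@dataclass(frozen=True)
class ClassWeights:
    """Per-class sampling weights; nonnegative and summing to one."""

    weights: np.ndarray
    origin: Literal["frequency", "f1", "regulated"]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=np.float64)
        if (w < 0).any():
            raise ValueError("class weights must be nonnegative")
        total = w.sum()
        if not np.isclose(total, 1.0, atol=_NORM_TOL):
            raise ValueError(f"class weights must sum to 1, got {total}")
        object.__setattr__(self, "weights", w)

    @property
    def n_classes(self) -> int:
        return self.weights.size


@dataclass(frozen=True)
class SamplerConfig:
    """Regulation and refresh parameters of the dynamic sampler.

    ``lambda_multiplier`` / ``beta_multiplier`` are the number of population
    standard deviations above the mean weight defining the threshold λ and
    the minimum weight β.  ``beta_role`` selects between the two readings of
    β — a cap on the F1-weighted (minority) classes, or a floor under the
    baseline-sampled (majority) classes; "cap" is the default and the one the
    rest of the package documents.  ``refresh_period`` is in epochs;
    ``k_folds`` is the fold count for the mean classwise F1; ``f1_floor``
    replaces zero (or undefined) F1 scores so inverse weights stay finite.
    """

    lambda_multiplier: float = 1.0
    beta_multiplier: float = 2.0
    beta_role: Literal["cap", "floor"] = "cap"
    refresh_period: int = 4
    k_folds: int = 10
    f1_floor: float = 1e-3

    def __post_init__(self) -> None:
        if self.refresh_period < 1:
            raise ValueError("refresh_period must be >= 1")
        if self.k_folds < 1:
            raise ValueError("k_folds must be >= 1")
        if self.f1_floor <= 0:
            raise ValueError("f1_floor must be > 0")


def frequency_weights(class_counts: Sequence[int]) -> ClassWeights:
    """Inverse-frequency initial weights: w_i = (1/n_i) / sum_j (1/n_j)."""
    counts = np.asarray(class_counts, dtype=np.float64)
    if (counts <= 0).any():
        bad = np.flatnonzero(counts <= 0).tolist()
        raise ValueError(f"class counts must be positive (inverse undefined); classes {bad}")
    inv = 1.0 / counts
    return ClassWeights(weights=inv / inv.sum(), origin="frequency")


def f1_weights(mean_f1: Sequence[float], f1_floor: float = 1e-3) -> ClassWeights:
    """Inverse-mean-F1 weights: w_i = (1/x̄_i) / sum_j (1/x̄_j).

    F1 values below ``f1_floor`` (including exact zeros and NaNs for classes
    never seen in validation) are replaced by the floor, so a class the model
    completely fails on gets a large but finite weight.
    """
    x = np.asarray(mean_f1, dtype=np.float64)
    with np.errstate(invalid="ignore"):
        if np.nanmax(x, initial=0.0) > 1.0 or np.nanmin(x, initial=0.0) < 0.0:
            raise ValueError("mean F1 values must lie in [0, 1]")
    x = np.where(np.isnan(x) | (x < f1_floor), f1_floor, x)
    inv = 1.0 / x
    return ClassWeights(weights=inv / inv.sum(), origin="f1")


def regulate_weights(raw: ClassWeights, cfg: SamplerConfig) -> ClassWeights:
    """Apply the λ/β regulation rule and renormalise.

    With m = mean(w) and s = population SD(w):
    λ = m + lambda_multiplier·s, β = m + beta_multiplier·s.  Classes at or
    above λ are the challenging, F1-weight-sampled ones: they keep their
    weight, capped at β (``beta_role="cap"``).  Classes below λ are baseline
    sampled at the mean weight m.  With ``beta_role="floor"`` the
    below-threshold classes instead receive max(w_i, m) and β is unused.
    The result is renormalised to sum to one.
    """
    w = raw.weights
    m = w.mean()
    s = w.std()  # population SD: stable for small class counts
    lam = m + cfg.lambda_multiplier * s
    beta = m + cfg.beta_multiplier * s
    out = w.copy()
    above = w >= lam
    if cfg.beta_role == "cap":
        out[above] = np.minimum(w[above], beta)
        out[~above] = m
    else:
        out[~above] = np.maximum(w[~above], m)
    return ClassWeights(weights=out / out.sum(), origin="regulated")


def sample_epoch(
    weights: ClassWeights,
    labels: Sequence[int],
    n_draws: int,
    seed: int,
) -> np.ndarray:
    """Draw one epoch's record indices, with replacement.

    Each record's probability is w_{label} / n_{label}, so the expected class
    share of the draws equals the class weight exactly.  Deterministic given
    ``seed``.
    """
    labels = np.asarray(labels, dtype=int)
    counts = np.bincount(labels, minlength=weights.n_classes).astype(float)
    missing = np.flatnonzero((weights.weights > 0) & (counts == 0)).tolist()
    if missing:
        raise ValueError(f"classes {missing} have positive weight but no records")
    with np.errstate(divide="ignore", invalid="ignore"):
        per_class = np.where(counts > 0, weights.weights / counts, 0.0)
    p = per_class[labels]
    p = p / p.sum()
    rng = np.random.default_rng(seed)
    return rng.choice(labels.size, size=n_draws, replace=True, p=p)


def kfold_mean_f1(
    prob_matrix: np.ndarray,
    labels: Sequence[int],
    k: int,
    seed: int,
) -> np.ndarray:
    """Mean classwise F1 of argmax predictions over k stratified folds.

    The validation set is partitioned into k stratified folds and the current
    model's predictions are re-scored per fold; no retraining happens here.
    A class absent from a fold's truth contributes no term for that fold; a
    class absent from every fold comes back as NaN (downstream weighting
    floors it).  ``k`` larger than the smallest class count is reduced with a
    warning; ``k=1`` falls back to whole-set classwise F1.
    """
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        raise ValueError("validation set is empty")
    prob_matrix = np.asarray(prob_matrix, dtype=np.float64)
    n_classes = prob_matrix.shape[1]
    preds = prob_matrix.argmax(axis=1)
    class_ids = np.arange(n_classes)

    min_count = np.bincount(labels, minlength=n_classes)
    min_present = min_count[min_count > 0].min()
    if k > min_present:
        logger.warning("k=%d exceeds smallest class count %d; reducing", k, min_present)
        k = int(min_present)

    if k <= 1:
        folds = [np.arange(labels.size)]
    else:
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        folds = [test_idx for _, test_idx in skf.split(prob_matrix, labels)]

    sums = np.zeros(n_classes)
    present = np.zeros(n_classes)
    for idx in folds:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # classes with no predicted samples
            fold_f1 = f1_score(labels[idx], preds[idx], labels=class_ids, average=None,
                               zero_division=0.0)
        in_fold = np.isin(class_ids, labels[idx])
        sums[in_fold] += fold_f1[in_fold]
        present[in_fold] += 1
    with np.errstate(invalid="ignore"):
        return np.where(present > 0, sums / np.maximum(present, 1), np.nan)
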