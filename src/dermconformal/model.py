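"""Model / Results objects tying the pipeline together.

``ConformalLesionModel`` is built from a cohort of embedding records (or the
on-disk ISIC-style files); ``fit()`` trains the MLP head with the dynamic
sampler, calibrates the split-conformal threshold on the held-out
calibration split, builds prediction sets for the test split, and returns a
``ConformalLesionResults`` carrying the estimates, their uncertainty
(set sizes, coverage, calibration errors) and a ``summary()`` table.
Stratified fairness audits and coverage curves hang off the results object.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from . import conformal
from .audit import AuditReport, build_audit_report
from .cohort import DatasetSplit, EmbeddingRecord, split_cohort
from .mlp import MLPConfig, MLPHead, classwise_metrics, predict_proba, train_head

__all__ = ["ConformalLesionModel", "ConformalLesionResults"]


class ConformalLesionModel:
    """Embedding classifier + split-conformal calibration as one model.

    Parameters
    ----------
    records
        The full cohort of embedding records.
    alpha
        User-chosen conformal error rate; the fitted prediction sets carry a
        1 - alpha marginal coverage guarantee.
    config
        MLP head configuration (architecture, optimiser, sampler).
    split
        Optional pre-computed train/validation/test/calibration split; by
        default :func:`split_cohort` is applied with the model seed.
    """

    def __init__(
        self,
        records: Sequence[EmbeddingRecord],
        alpha: float = 0.2,
        config: MLPConfig | None = None,
        split: DatasetSplit | None = None,
        seed: int = 0,
        allow_empty_sets: bool = False,
    ):
        if not 0.0 < alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {alpha}")
        self.records = list(records)
        self.alpha = alpha
        self.allow_empty_sets = allow_empty_sets
        dim = self.records[0].vector.size
        self.config = config or MLPConfig(input_dim=dim, seed=seed)
        self.split = split or split_cohort(self.records, seed=seed)
        self.n_classes = max(r.label for r in self.records) + 1
        self._by_id = {r.id: r for r in self.records}

    @classmethod
    def from_files(
        cls,
        embeddings_path,
        ground_truth_path,
        metadata_path=None,
        **kwargs,
    ) -> "ConformalLesionModel":
        from .io import records_from_files

        return cls(records_from_files(embeddings_path, ground_truth_path, metadata_path),
                   **kwargs)

    def _subset(self, ids: Sequence[str]) -> list[EmbeddingRecord]:
        return [self._by_id[i] for i in ids]

    def fit(self) -> "ConformalLesionResults":
        """Train, calibrate, and build test prediction sets."""
        train = self._subset(self.split.train)
        val = self._subset(self.split.validation)
        cal = self._subset(self.split.calibration)
        test = self._subset(self.split.test)

        head, log = train_head(train, val, self.config, n_classes=self.n_classes)

        prob_cal = predict_proba(head, cal)
        truth_cal = np.array([r.label for r in cal])
        scores = conformal.nonconformity_scores(prob_cal, truth_cal)
        calib = conformal.calibrate(scores, self.alpha)

        prob_test = predict_proba(head, test)
        truth_test = np.array([r.label for r in test])
        sets = conformal.build_sets(
            prob_test,
            calib,
            sample_ids=[r.id for r in test],
            truths=truth_test,
            allow_empty=self.allow_empty_sets,
        )
        return ConformalLesionResults(
            model=self,
            head=head,
            training_log=log,
            calibration=calib,
            prob_cal=prob_cal,
            truth_cal=truth_cal,
            prob_test=prob_test,
            truth_test=truth_test,
            sets=sets,
        )


class ConformalLesionResults:
    """Fitted head, conformal calibration, and test prediction sets."""

    def __init__(
        self,
        model: ConformalLesionModel,
        head: MLPHead,
        training_log: pd.DataFrame,
        calibration: conformal.CalibrationResult,
        prob_cal: np.ndarray,
        truth_cal: np.ndarray,
        prob_test: np.ndarray,
        truth_test: np.ndarray,
        sets: list[conformal.PredictionSet],
    ):
        self.model = model
        self.head = head
        self.training_log = training_log
        self.calibration = calibration
        self.prob_cal = prob_cal
        self.truth_cal = truth_cal
        self.prob_test = prob_test
        self.truth_test = truth_test
        self.sets = sets

    # -- point predictions --------------------------------------------------
    @property
    def predicted_labels(self) -> np.ndarray:
        return self.prob_test.argmax(axis=1)

    @property
    def accuracy(self) -> float:
        """Overall top-1 test accuracy of the head."""
        return float((self.predicted_labels == self.truth_test).mean())

    def classwise(self) -> pd.DataFrame:
        """Per-class accuracy (= recall), F1 and one-vs-rest AUC on the test split."""
        return classwise_metrics(self.truth_test, self.prob_test)

    # -- conformal diagnostics ----------------------------------------------
    @property
    def coverage(self) -> float:
        """Empirical marginal coverage: fraction of sets containing the truth."""
        return conformal.empirical_coverage(self.sets)

    @property
    def mean_set_size(self) -> float:
        return float(np.mean([s.size for s in self.sets]))

    def set_sizes(self) -> np.ndarray:
        return np.array([s.size for s in self.sets])

    def calibration_errors(self, n_bins: int = 10) -> tuple[float, float]:
        """(ECE, MCE) of the top-label set confidences vs set correctness."""
        top_conf = np.array([s.entries[0][1] for s in self.sets])
        hit = np.array([s.contains_truth() for s in self.sets])
        return conformal.ece_mce(top_conf, hit, n_bins=n_bins)

    def coverage_curve(
        self, alphas: Sequence[float] = (0.05, 0.1, 0.2, 0.3, 0.4)
    ) -> list[tuple[float, float]]:
        return conformal.coverage_curve(
            self.prob_cal, self.truth_cal, self.prob_test, self.truth_test, alphas
        )

    # -- fairness audit -----------------------------------------------------
    def audit(
        self, attributes: Sequence[str] = ("sex", "age_band", "site")
    ) -> AuditReport:
        metadata = {r.id: dict(r.demographics) for r in self.model.records}
        return build_audit_report(
            self.sets,
            metadata,
            attributes=attributes,
            n_classes=self.model.n_classes,
            calibration=self.calibration_errors(),
            coverage_curve=self.coverage_curve(),
        )

    def summary(self) -> str:
        """Human-readable fit, calibration, and coverage summary."""
        split = self.model.split
        ece, mce = self.calibration_errors()
        lines = [
            "Conformal Lesion Classification Results",
            "=" * 55,
            f"Classes:            {self.model.n_classes}",
            f"Split sizes:        train={len(split.train)} val={len(split.validation)} "
            f"cal={len(split.calibration)} test={len(split.test)}",
            f"Alpha (error rate): {self.calibration.alpha:.3f}  "
            f"(target coverage {1 - self.calibration.alpha:.1%})",
            f"Quantile q_hat:     {self.calibration.q_hat:.4f}  "
            f"(n_cal={self.calibration.n})",
            f"Top-1 accuracy:     {self.accuracy:.2%}",
            f"Empirical coverage: {self.coverage:.2%}",
            f"Mean set size:      {self.mean_set_size:.3f}",
            f"ECE / MCE:          {ece:.5f} / {mce:.5f}",
            "-" * 55,
            "Per-class (test):",
            self.classwise().to_string(float_format=lambda v: f"{v:.4f}"),
        ]
        return "\n".join(lines)
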