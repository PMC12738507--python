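"""Replicated desk-scale studies: coverage guarantee, sampler efficacy, audit power.

These are the package's own empirical checks, run on the synthetic cohort
generator at fixed study conditions:

* ``coverage_study`` — the marginal coverage guarantee of the conformal
  pipeline at α = 0.2 over replicate seeds (8 imbalanced classes, ~8,000
  records, 64-dim embeddings, 500 calibration samples).  Coverage is
  measured on the strict conformal sets (empty sets allowed): the
  nonempty-argmax fallback used for reporting inflates coverage above the
  finite-sample band.
* ``sampler_efficacy_study`` — paired with/without-sampler training on a
  cohort with one rare, under-learned minority class, comparing minority
  recall.
* ``audit_detection_study`` / ``audit_specificity_study`` — power and
  false-alarm behaviour of the set-size fairness audit under a planted
  subgroup difficulty (class-signal attenuation on one sex).

Seeds for each replicate are derived from one master seed via
``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics import recall_score

from .audit import set_size_permutation_test
from .cohort import (
    IMBALANCED_8CLASS_COUNTS,
    CohortSpec,
    SubgroupEffect,
    generate_cohort,
    split_cohort,
)
from .conformal import (
    build_sets,
    calibrate,
    empirical_coverage,
    nonconformity_scores,
)
from .mlp import MLPConfig, predict_proba, train_head
from .model import ConformalLesionModel
from .sampler import SamplerConfig

__all__ = [
    "audit_detection_study",
    "audit_specificity_study",
    "coverage_study",
    "sampler_efficacy_study",
]

#: Criterion-5 study cohort: 4 classes, moderate imbalance, 16-dim embeddings.
AUDIT_CLASS_COUNTS = (2100, 1500, 900, 450)
AUDIT_ATTENUATION = 0.25
AUDIT_SEPARATION = 4.0


def _replicate_seeds(master_seed: int, n: int, k: int = 3) -> list[tuple[int, ...]]:
    ss = np.random.SeedSequence(master_seed)
    return [tuple(int(x) for x in c.generate_state(k) % (2**31)) for c in ss.spawn(n)]


def coverage_study(
    master_seed: int,
    n_replicates: int = 20,
    alpha: float = 0.2,
    n_cal: int = 500,
    epochs: int = 20,
) -> dict:
    """Mean empirical coverage of the full pipeline over replicate seeds.

    Each replicate generates a fresh cohort, splits it, trains the MLP head
    with the dynamic sampler, calibrates on ``n_cal`` held-out samples and
    measures the fraction of strict test prediction sets containing the
    truth.  Returns per-replicate coverages, their mean, the Monte-Carlo
    standard error, and mean top-1 accuracy.
    """
    coverages, accuracies = [], []
    for s_cohort, s_split, s_train in _replicate_seeds(master_seed, n_replicates):
        spec = CohortSpec(
            class_counts=IMBALANCED_8CLASS_COUNTS, embed_dim=64, seed=s_cohort
        )
        records = generate_cohort(spec)
        split = split_cohort(records, seed=s_split)
        by_id = {r.id: r for r in records}
        cfg = MLPConfig(input_dim=64, n_blocks=3, epochs=epochs, seed=s_train)
        model, _ = train_head(
            [by_id[i] for i in split.train],
            [by_id[i] for i in split.validation],
            cfg,
            n_classes=spec.n_classes,
        )
        cal = [by_id[i] for i in split.calibration[:n_cal]]
        test = [by_id[i] for i in split.test]
        scores = nonconformity_scores(
            predict_proba(model, cal), [r.label for r in cal]
        )
        calib = calibrate(scores, alpha)
        prob_test = predict_proba(model, test)
        truth_test = np.array([r.label for r in test])
        sets = build_sets(prob_test, calib, truths=truth_test, allow_empty=True)
        coverages.append(empirical_coverage(sets))
        accuracies.append(float((prob_test.argmax(axis=1) == truth_test).mean()))
    coverages = np.array(coverages)
    return {
        "coverages": coverages,
        "mean_coverage": float(coverages.mean()),
        "mc_sem": float(coverages.std(ddof=1) / np.sqrt(len(coverages))),
        "n_cal": min(n_cal, len(split.calibration)),
        "n_test": len(test),
        "mean_accuracy": float(np.mean(accuracies)),
        "alpha": alpha,
    }


def sampler_efficacy_study(
    master_seed: int,
    n_seeds: int = 5,
    epochs: int = 20,
) -> dict:
    """Paired minority-class recall, with vs without the dynamic sampler.

    The cohort has one rare minority class (80 of 2,780 records) at a
    separation where the plain head under-learns it; seeds are matched
    between arms.
    """
    counts = (1200, 900, 600, 80)
    minority = len(counts) - 1
    with_s, without_s = [], []
    for s_cohort, s_split, s_train in _replicate_seeds(master_seed, n_seeds):
        spec = CohortSpec(
            class_counts=counts, embed_dim=16, class_separation=2.0, seed=s_cohort
        )
        records = generate_cohort(spec)
        split = split_cohort(records, seed=s_split)
        by_id = {r.id: r for r in records}
        train = [by_id[i] for i in split.train]
        val = [by_id[i] for i in split.validation]
        test = [by_id[i] for i in split.test]
        truth = np.array([r.label for r in test])
        for use_sampler, sink in ((True, with_s), (False, without_s)):
            cfg = MLPConfig(
                input_dim=16,
                n_blocks=2,
                epochs=epochs,
                seed=s_train,
                sampler=SamplerConfig() if use_sampler else None,
            )
            model, _ = train_head(train, val, cfg, n_classes=len(counts))
            preds = predict_proba(model, test).argmax(axis=1)
            sink.append(
                float(
                    recall_score(
                        truth, preds, labels=[minority], average=None, zero_division=0.0
                    )[0]
                )
            )
    return {
        "minority_recall_with_sampler": with_s,
        "minority_recall_without_sampler": without_s,
        "mean_with": float(np.mean(with_s)),
        "mean_without": float(np.mean(without_s)),
    }


def _audit_replicate(seeds: tuple[int, ...], attenuation: float, epochs: int):
    effects = (
        {("sex", "female"): SubgroupEffect(signal_attenuation=attenuation)}
        if attenuation < 1.0
        else {}
    )
    spec = CohortSpec(
        class_counts=AUDIT_CLASS_COUNTS,
        embed_dim=16,
        class_separation=AUDIT_SEPARATION,
        subgroup_effects=effects,
        seed=seeds[0],
    )
    records = generate_cohort(spec)
    model = ConformalLesionModel(
        records,
        alpha=0.2,
        config=MLPConfig(input_dim=16, n_blocks=2, epochs=epochs, seed=seeds[2]),
        seed=seeds[1],
    )
    res = model.fit()
    groups = [model._by_id[s.sample_id].demographics["sex"] for s in res.sets]
    return res.sets, groups


def audit_detection_study(
    master_seed: int, n_replicates: int = 20, epochs: int = 20
) -> dict:
    """Fraction of replicates where the planted subgroup shows larger mean sets."""
    diffs = []
    for seeds in _replicate_seeds(master_seed, n_replicates):
        sets, groups = _audit_replicate(seeds, AUDIT_ATTENUATION, epochs)
        sizes = np.array([s.size for s in sets])
        mask = np.array([g == "female" for g in groups])
        diffs.append(float(sizes[mask].mean() - sizes[~mask].mean()))
    diffs = np.array(diffs)
    return {
        "size_differences": diffs,
        "detection_rate": float((diffs > 0).mean()),
    }


def audit_specificity_study(
    master_seed: int, n_seeds: int = 5, epochs: int = 20, n_permutations: int = 1000
) -> dict:
    """Permutation p-values for group set-size differences with no planted effect."""
    pvals = []
    for seeds in _replicate_seeds(master_seed, n_seeds):
        sets, groups = _audit_replicate(seeds, 1.0, epochs)
        _, p = set_size_permutation_test(
            sets, groups, "female", n_permutations=n_permutations, seed=seeds[1]
        )
        pvals.append(p)
    return {"p_values": pvals, "min_p": float(min(pvals))}
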