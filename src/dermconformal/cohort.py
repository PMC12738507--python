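"""Synthetic embedding cohorts with demographics, imbalance, and planted effects.

Real inputs to the pipeline are frozen foundation-model embeddings keyed by
image ID, plus ISIC-style ground-truth and metadata tables.  This module
generates a drop-in stand-in: class-conditional isotropic Gaussian clusters in
embedding space, severe (configurable) class imbalance, independently sampled
demographic attributes, and explicit knobs to plant subgroup difficulty gaps
or a covariate shift between cohorts.  Everything is reproducible from a
single integer seed, so downstream training, calibration and auditing can be
tested without any external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "AGE_BANDS",
    "IMBALANCED_8CLASS_COUNTS",
    "CohortSpec",
    "CohortSpecError",
    "DatasetSplit",
    "EmbeddingRecord",
    "SubgroupEffect",
    "generate_cohort",
    "split_cohort",
]

#: Age bands used throughout the audit; edges inclusive on the left.
AGE_BANDS = ("<30", "30-60", ">60")

#: Desk-scale 8-class study cohort (~8,000 samples, 14.5:1 imbalance).  At the
#: default class_separation this yields ~70% top-1 accuracy for the MLP head,
#: the difficulty regime of real lesion-embedding classification.
IMBALANCED_8CLASS_COUNTS = (2900, 1800, 1100, 750, 550, 400, 300, 200)

DEFAULT_MARGINALS: dict[str, dict[str, float]] = {
    "sex": {"male": 0.52, "female": 0.45, "unknown": 0.03},
    "age_band": {"<30": 0.15, "30-60": 0.50, ">60": 0.35},
    "site": {
        "anterior torso": 0.30,
        "posterior torso": 0.18,
        "lower extremity": 0.17,
        "head/neck": 0.15,
        "upper extremity": 0.13,
        "palms/soles": 0.04,
        "oral/genital": 0.02,
        "unknown": 0.01,
    },
    "cohort": {"cohort_a": 1.0},
}


class CohortSpecError(ValueError):
    """A cohort specification field failed validation."""


@dataclass(frozen=True)
class SubgroupEffect:
    """Planted difficulty for one (attribute, level) subgroup.

    ``noise_scale`` adds isotropic Gaussian noise of that standard deviation
    on top of the unit base noise; ``mean_shift`` translates the subgroup
    along a fixed random unit direction; ``signal_attenuation`` (in (0, 1])
    scales down the class-mean component of the subgroup's vectors, pulling
    them into the between-class overlap region — the stand-in for lesions
    that are intrinsically harder to discriminate in one subgroup (e.g.
    lower contrast).  Attenuation degrades attainable accuracy *and* makes
    the learned posterior diffuse, so prediction sets grow; extra isotropic
    noise degrades accuracy but pushes samples off-manifold, where
    discriminative heads tend to stay (over)confident.
    """

    noise_scale: float = 0.0
    mean_shift: float = 0.0
    signal_attenuation: float = 1.0


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one synthetic cohort.

    Class means sit on random orthonormal directions scaled by
    ``class_separation``; base noise is unit isotropic Gaussian, so
    separation directly controls the attainable F1 of any classifier.
    Demographics are sampled independently of class by default — fairness
    gaps must be planted via ``subgroup_effects``, never accidental.
    """

    class_counts: Sequence[int]
    embed_dim: int = 64
    class_separation: float = 2.75
    subgroup_effects: Mapping[tuple[str, str], SubgroupEffect] = field(
        default_factory=dict
    )
    cohort_shift: float = 0.0
    shifted_cohort: str | None = None
    demographic_marginals: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_MARGINALS.items()}
    )
    seed: int = 0

    @property
    def n_classes(self) -> int:
        return len(self.class_counts)

    def validate(self) -> None:
        if len(self.class_counts) < 2:
            raise CohortSpecError("class_counts: need at least 2 classes")
        for i, c in enumerate(self.class_counts):
            if int(c) != c or c < 1:
                raise CohortSpecError(f"class_counts: count for class {i} must be >= 1, got {c}")
        if self.embed_dim < 1:
            raise CohortSpecError(f"embed_dim: must be >= 1, got {self.embed_dim}")
        if self.embed_dim < self.n_classes:
            raise CohortSpecError(
                f"embed_dim: must be >= n_classes ({self.n_classes}) so class means "
                f"can be orthogonal, got {self.embed_dim}"
            )
        if self.class_separation < 0:
            raise CohortSpecError(
                f"class_separation: must be >= 0, got {self.class_separation}"
            )
        for attr, marginal in self.demographic_marginals.items():
            total = sum(marginal.values())
            if any(p < 0 for p in marginal.values()):
                raise CohortSpecError(f"demographic_marginals[{attr}]: negative probability")
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise CohortSpecError(
                    f"demographic_marginals[{attr}]: probabilities sum to {total}, expected 1"
                )
        for (attr, level), eff in self.subgroup_effects.items():
            if attr not in self.demographic_marginals:
                raise CohortSpecError(f"subgroup_effects: unknown attribute {attr!r}")
            if eff.noise_scale < 0:
                raise CohortSpecError(
                    f"subgroup_effects[{attr},{level}]: noise_scale must be >= 0"
                )
            if not 0.0 < eff.signal_attenuation <= 1.0:
                raise CohortSpecError(
                    f"subgroup_effects[{attr},{level}]: signal_attenuation must be in (0, 1]"
                )


@dataclass(frozen=True)
class EmbeddingRecord:
    """One sample: image ID, embedding vector, class label, demographics."""

    id: str
    vector: np.ndarray
    label: int
    demographics: Mapping[str, str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "vector", np.asarray(self.vector, dtype=np.float64))


@dataclass(frozen=True)
class DatasetSplit:
    """Disjoint train / validation / test / calibration ID lists."""

    train: list[str]
    validation: list[str]
    test: list[str]
    calibration: list[str]

    def all_ids(self) -> list[str]:
        return self.train + self.validation + self.test + self.calibration


def _class_means(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    # QR of a Gaussian matrix -> orthonormal columns; all pairwise mean
    # distances equal class_separation * sqrt(2).
    raw = rng.normal(size=(spec.embed_dim, spec.n_classes))
    q, _ = np.linalg.qr(raw)
    return spec.class_separation * q.T  # (n_classes, embed_dim)


def _unit_direction(dim: int, rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=dim)
    return v / np.linalg.norm(v)


def generate_cohort(spec: CohortSpec) -> list[EmbeddingRecord]:
    """Generate ``sum(class_counts)`` records, reproducibly from ``spec.seed``.

    Class ``c`` vectors are drawn from an isotropic unit-variance Gaussian
    centred on a class mean of norm ``class_separation``.  Subgroup effects
    and the cohort shift are applied after the base draw.  Record IDs follow
    the pattern ``SYN_<zero-padded index>`` in a globally shuffled order, so
    ID order carries no class information.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    means = _class_means(spec, rng)

    labels = np.repeat(np.arange(spec.n_classes), np.asarray(spec.class_counts, dtype=int))
    n = labels.size
    vectors = means[labels] + rng.normal(size=(n, spec.embed_dim))

    attrs = list(spec.demographic_marginals)
    demo = {}
    for attr in attrs:
        marginal = spec.demographic_marginals[attr]
        levels = list(marginal)
        probs = np.array([marginal[lv] for lv in levels], dtype=float)
        demo[attr] = rng.choice(levels, size=n, p=probs / probs.sum())

    # Planted subgroup effects: extra noise and/or a mean shift along a fixed
    # random direction, applied to every record matching (attribute, level).
    for (attr, level), eff in spec.subgroup_effects.items():
        mask = demo[attr] == level
        if not mask.any():
            continue
        if eff.signal_attenuation < 1.0:
            vectors[mask] -= (1.0 - eff.signal_attenuation) * means[labels[mask]]
        if eff.noise_scale > 0:
            vectors[mask] += rng.normal(
                scale=eff.noise_scale, size=(int(mask.sum()), spec.embed_dim)
            )
        if eff.mean_shift != 0.0:
            vectors[mask] += eff.mean_shift * _unit_direction(spec.embed_dim, rng)

    if spec.cohort_shift != 0.0:
        cohort_levels = list(spec.demographic_marginals.get("cohort", {}))
        target = spec.shifted_cohort or (cohort_levels[-1] if len(cohort_levels) > 1 else None)
        if target is not None:
            mask = demo["cohort"] == target
            vectors[mask] += spec.cohort_shift * _unit_direction(spec.embed_dim, rng)

    order = rng.permutation(n)
    width = max(6, len(str(n)))
    records = [
        EmbeddingRecord(
            id=f"SYN_{pos:0{width}d}",
            vector=vectors[i],
            label=int(labels[i]),
            demographics={attr: str(demo[attr][i]) for attr in attrs},
        )
        for pos, i in enumerate(order)
    ]
    return records


def split_cohort(records: Sequence[EmbeddingRecord], seed: int) -> DatasetSplit:
    """Split into train / validation / test / calibration by ID.

    The test split takes 20% of each class (floored, remainder staying in the
    training pool); validation takes 10% of the overall cohort from the
    remaining pool; calibration is then carved out as 10% of the post-split
    training set.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    by_class: dict[int, list[str]] = {}
    for rec in records:
        by_class.setdefault(rec.label, []).append(rec.id)

    small = sorted(c for c, ids in by_class.items() if len(ids) < 10)
    if small:
        raise ValueError(
            f"each class needs >= 10 records to split; classes {small} are too small"
        )

    test: list[str] = []
    pool: list[str] = []
    for c in sorted(by_class):
        ids = np.array(by_class[c])
        rng.shuffle(ids)
        n_test = int(math.floor(0.2 * len(ids)))
        test.extend(ids[:n_test].tolist())
        pool.extend(ids[n_test:].tolist())

    pool_arr = np.array(pool)
    rng.shuffle(pool_arr)
    n_val = int(math.floor(0.1 * len(records)))
    validation = pool_arr[:n_val].tolist()
    train_pool = pool_arr[n_val:]
    n_cal = int(math.floor(0.1 * len(train_pool)))
    calibration = train_pool[:n_cal].tolist()
    train = train_pool[n_cal:].tolist()
    return DatasetSplit(train=train, validation=validation, test=test, calibration=calibration)
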