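"""Demographic-stratified uncertainty and fairness reporting.

Conformal set length and set confidence are per-sample uncertainty signals;
stratifying them over protected attributes (sex, age band, anatomical site,
cohort/ethnicity) turns them into a fairness audit of the underlying
classifier and embeddings.  The report covers:

* A2 accuracy — per class, the fraction of test samples whose true label is
  among the two most probable labels of their prediction set;
* set-size histograms per demographic level (difficulty distributions);
* ground-truth confidence distributions (violin-plot data), from each set
  containing the truth;
* top-2 guarantee values — truth confidences restricted to sets where the
  truth ranks first or second;
* per-class region-of-occurrence rankings among top-2-correct samples;
* ECE / MCE of the set confidences and the expected-vs-observed coverage
  curve.

"Two most probable labels" always means the top two by reported confidence
within the prediction set, not the global top-2 of the probability row.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .conformal import PredictionSet

__all__ = [
    "AuditReport",
    "a2_accuracy",
    "build_audit_report",
    "gt_confidence_values",
    "region_table",
    "set_size_distribution",
    "set_size_permutation_test",
    "top2_guarantee",
]


def _check_ordered(sets: Sequence[PredictionSet]) -> None:
    for s in sets:
        confs = [c for _, c in s.entries]
        if any(confs[i] < confs[i + 1] for i in range(len(confs) - 1)):
            raise ValueError(f"set {s.sample_id}: entries are not ordered by confidence")


def _n_classes(sets: Sequence[PredictionSet], n_classes: int | None) -> int:
    if n_classes is not None:
        return n_classes
    return max(s.truth for s in sets) + 1


def a2_accuracy(
    sets: Sequence[PredictionSet],
    groups: Sequence[str] | None = None,
    n_classes: int | None = None,
) -> dict:
    """Per-class A2 accuracy in percent, optionally stratified by group.

    A2 accuracy for a class is the number of its test samples whose ground
    truth lies among the two most probable labels of their prediction set,
    over the total number of test samples of that class.  Classes (or
    group/class cells) with zero samples come back as NaN — undefined, not
    zero.
    """
    _check_ordered(sets)
    nc = _n_classes(sets, n_classes)
    if groups is None:
        return _a2_one_group(sets, nc)
    out: dict[str, dict[int, float]] = {}
    for level in sorted(set(groups)):
        members = [s for s, g in zip(sets, groups, strict=True) if g == level]
        out[level] = _a2_one_group(members, nc)
    return out


def _a2_one_group(sets: Sequence[PredictionSet], n_classes: int) -> dict[int, float]:
    total = Counter(s.truth for s in sets)
    hits = Counter(s.truth for s in sets if (s.truth_rank() or 99) <= 2)
    return {
        c: (100.0 * hits[c] / total[c]) if total[c] else float("nan")
        for c in range(n_classes)
    }


def set_size_distribution(
    sets: Sequence[PredictionSet],
    metadata: Mapping[str, Mapping[str, str]],
    attribute: str,
) -> dict[str, dict[int, int]]:
    """Histogram of prediction-set sizes per level of one attribute.

    Samples whose metadata lacks the attribute fall under "unknown".
    """
    out: dict[str, Counter] = {}
    for s in sets:
        level = metadata.get(s.sample_id, {}).get(attribute, "unknown")
        out.setdefault(level, Counter())[s.size] += 1
    return {level: dict(sorted(hist.items())) for level, hist in sorted(out.items())}


def gt_confidence_values(
    sets: Sequence[PredictionSet],
    groups: Sequence[str] | None = None,
    n_classes: int | None = None,
) -> dict:
    """Ground-truth confidences per class, from sets containing the truth.

    The raw data behind the classwise violin plots: one value per set whose
    label list includes the ground truth, namely the classifier's probability
    reported for that label.  Sets missing the truth contribute nothing.
    """
    nc = _n_classes(sets, n_classes)
    if groups is None:
        return _gt_conf_one_group(sets, nc)
    return {
        level: _gt_conf_one_group(
            [s for s, g in zip(sets, groups, strict=True) if g == level], nc
        )
        for level in sorted(set(groups))
    }


def _gt_conf_one_group(sets: Sequence[PredictionSet], n_classes: int) -> dict[int, list[float]]:
    out: dict[int, list[float]] = {c: [] for c in range(n_classes)}
    for s in sets:
        conf = s.truth_confidence()
        if conf is not None:
            out[s.truth].append(conf)
    return out


def top2_guarantee(
    sets: Sequence[PredictionSet], n_classes: int | None = None
) -> dict[int, list[float]]:
    """Truth confidences restricted to sets where the truth ranks in the top 2."""
    _check_ordered(sets)
    nc = _n_classes(sets, n_classes)
    out: dict[int, list[float]] = {c: [] for c in range(nc)}
    for s in sets:
        rank = s.truth_rank()
        if rank is not None and rank <= 2:
            out[s.truth].append(s.truth_confidence())
    return out


def region_table(
    sets: Sequence[PredictionSet],
    metadata: Mapping[str, Mapping[str, str]],
    site_attribute: str = "site",
    n_classes: int | None = None,
) -> dict[int, list[tuple[str, float]]]:
    """Per class, ranked anatomical regions among top-2-correct samples.

    Denominators are the per-class counts of samples whose truth lies in the
    top two predictions of the set; percentages per class sum to 100 when
    every such sample has a known site.
    """
    _check_ordered(sets)
    nc = _n_classes(sets, n_classes)
    counts: dict[int, Counter] = {c: Counter() for c in range(nc)}
    for s in sets:
        rank = s.truth_rank()
        if rank is None or rank > 2:
            continue
        site = metadata.get(s.sample_id, {}).get(site_attribute, "unknown")
        counts[s.truth][site] += 1
    out: dict[int, list[tuple[str, float]]] = {}
    for c, ctr in counts.items():
        total = sum(ctr.values())
        ranked = sorted(ctr.items(), key=lambda kv: (-kv[1], kv[0]))
        out[c] = [(site, 100.0 * k / total) for site, k in ranked] if total else []
    return out


def set_size_permutation_test(
    sets: Sequence[PredictionSet],
    groups: Sequence[str],
    level: str,
    n_permutations: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """Two-sided permutation test on mean set size, ``level`` vs the rest.

    Returns (observed mean difference, p-value).  The auditor's no-false-alarm
    check: on a cohort with no planted subgroup effect the p-value should be
    unremarkable.
    """
    sizes = np.array([s.size for s in sets], dtype=float)
    mask = np.array([g == level for g in groups])
    if not mask.any() or mask.all():
        raise ValueError(f"level {level!r} must split the samples into two nonempty groups")
    obs = sizes[mask].mean() - sizes[~mask].mean()
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(mask)
        diff = sizes[perm].mean() - sizes[~perm].mean()
        if abs(diff) >= abs(obs) - 1e-12:
            count += 1
    return float(obs), (count + 1) / (n_permutations + 1)


@dataclass
class AuditReport:
    """Machine-readable fairness-audit bundle over one set of predictions."""

    n_samples: int
    a2_overall: dict[int, float]
    a2_by_group: dict[str, dict[str, dict[int, float]]]
    setsize_hist: dict[str, dict[str, dict[int, int]]]
    gt_confidences: dict[int, list[float]]
    top2_guarantees: dict[int, list[float]]
    region_table: dict[int, list[tuple[str, float]]]
    calibration: tuple[float, float] | None = None
    coverage_curve: list[tuple[float, float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_samples": self.n_samples,
            "a2_overall": {str(c): v for c, v in self.a2_overall.items()},
            "a2_by_group": {
                attr: {lvl: {str(c): v for c, v in d.items()} for lvl, d in levels.items()}
                for attr, levels in self.a2_by_group.items()
            },
            "setsize_hist": {
                attr: {lvl: {str(k): v for k, v in d.items()} for lvl, d in levels.items()}
                for attr, levels in self.setsize_hist.items()
            },
            "gt_confidences": {str(c): v for c, v in self.gt_confidences.items()},
            "top2_guarantees": {str(c): v for c, v in self.top2_guarantees.items()},
            "region_table": {
                str(c): [[site, pct] for site, pct in rows]
                for c, rows in self.region_table.items()
            },
            "calibration": (
                {"ece": self.calibration[0], "mce": self.calibration[1]}
                if self.calibration is not None
                else None
            ),
            "coverage_curve": [[e, o] for e, o in self.coverage_curve],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, allow_nan=True)

    def write_csvs(self, outdir) -> None:
        """Plot-ready CSVs: set sizes, A2, violin data, top-2, regions."""
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        rows = [
            {"attribute": attr, "level": lvl, "set_size": size, "count": cnt}
            for attr, levels in self.setsize_hist.items()
            for lvl, hist in levels.items()
            for size, cnt in hist.items()
        ]
        pd.DataFrame(rows).to_csv(outdir / "fig3_setsize.csv", index=False)
        rows = [
            {"attribute": attr, "level": lvl, "class": c, "a2_percent": v}
            for attr, levels in self.a2_by_group.items()
            for lvl, d in levels.items()
            for c, v in d.items()
        ] + [
            {"attribute": "overall", "level": "all", "class": c, "a2_percent": v}
            for c, v in self.a2_overall.items()
        ]
        pd.DataFrame(rows).to_csv(outdir / "fig4_a2.csv", index=False)
        rows = [
            {"class": c, "gt_confidence": v}
            for c, vals in self.gt_confidences.items()
            for v in vals
        ]
        pd.DataFrame(rows, columns=["class", "gt_confidence"]).to_csv(
            outdir / "fig5_violin.csv", index=False
        )
        rows = [
            {"class": c, "gt_confidence": v}
            for c, vals in self.top2_guarantees.items()
            for v in vals
        ]
        pd.DataFrame(rows, columns=["class", "gt_confidence"]).to_csv(
            outdir / "fig6_top2.csv", index=False
        )
        rows = [
            {"class": c, "rank": i + 1, "region": site, "percent": pct}
            for c, ranked in self.region_table.items()
            for i, (site, pct) in enumerate(ranked)
        ]
        pd.DataFrame(rows, columns=["class", "rank", "region", "percent"]).to_csv(
            outdir / "table10_regions.csv", index=False
        )


def build_audit_report(
    sets: Sequence[PredictionSet],
    metadata: Mapping[str, Mapping[str, str]],
    attributes: Sequence[str] = ("sex", "age_band", "site"),
    n_classes: int | None = None,
    calibration: tuple[float, float] | None = None,
    coverage_curve: Sequence[tuple[float, float]] = (),
) -> AuditReport:
    """Assemble the full stratified audit from prediction sets and metadata."""
    _check_ordered(sets)
    nc = _n_classes(sets, n_classes)

    def levels_of(attr: str) -> list[str]:
        return [metadata.get(s.sample_id, {}).get(attr, "unknown") for s in sets]

    return AuditReport(
        n_samples=len(sets),
        a2_overall=a2_accuracy(sets, n_classes=nc),
        a2_by_group={
            attr: a2_accuracy(sets, groups=levels_of(attr), n_classes=nc)
            for attr in attributes
        },
        setsize_hist={
            attr: set_size_distribution(sets, metadata, attr) for attr in attributes
        },
        gt_confidences=gt_confidence_values(sets, n_classes=nc),
        top2_guarantees=top2_guarantee(sets, n_classes=nc),
        region_table=region_table(sets, metadata, n_classes=nc),
        calibration=calibration,
        coverage_curve=list(coverage_curve),
    )
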