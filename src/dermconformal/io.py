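"""Readers and writers for the pipeline's on-disk formats, plus orchestration.

Formats mirror the ISIC conventions: embeddings live in a JSON file mapping
image ID to a fixed-length float vector; ground truth is a CSV with one-hot
class columns (a long ``id,label`` dialect is auto-detected too); metadata is
a CSV with age, sex, anatomical site and cohort columns.  Rows labelled
'UNK' are dropped with a logged count; samples without metadata get
"unknown" demographic levels, so metadata-free cohorts still audit.

``run_pipeline`` chains simulate → split → train → calibrate → predict-sets
→ audit into one run directory, each stage leaving a re-readable artifact;
the whole run is deterministic given the master seed (per-stage seeds are
derived from it and logged).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import conformal
from .audit import build_audit_report
from .cohort import (
    CohortSpec,
    DatasetSplit,
    EmbeddingRecord,
    SubgroupEffect,
    generate_cohort,
    split_cohort,
)
from .mlp import MLPConfig, MLPHead, predict_proba, train_head
from .sampler import SamplerConfig

__all__ = [
    "RunConfig",
    "age_to_band",
    "load_model",
    "load_sets",
    "read_embeddings",
    "read_labels_metadata",
    "records_from_files",
    "run_pipeline",
    "save_model",
    "write_cohort",
    "write_sets",
]

logger = logging.getLogger(__name__)

_BAND_REPRESENTATIVE_AGE = {"<30": 25, "30-60": 45, ">60": 70, "unknown": ""}


def age_to_band(age) -> str:
    """Map a numeric age to the audit's bands: <30, 30-60 (left-inclusive), >60."""
    try:
        a = float(age)
    except (TypeError, ValueError):
        return "unknown"
    if np.isnan(a):
        return "unknown"
    if a < 30:
        return "<30"
    if a < 60:
        return "30-60"
    return ">60"


# ---------------------------------------------------------------------------
# embeddings JSON


def _reject_duplicate_keys(pairs):
    seen = set()
    for k, _ in pairs:
        if k in seen:
            raise ValueError(f"duplicate image ID in embeddings file: {k!r}")
        seen.add(k)
    return dict(pairs)


def read_embeddings(path) -> dict[str, np.ndarray]:
    """Read an ID → vector JSON mapping; all vectors must share one length."""
    with open(path) as fh:
        raw = json.load(fh, object_pairs_hook=_reject_duplicate_keys)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a JSON object mapping ID to vector")
    out = {k: np.asarray(v, dtype=np.float64) for k, v in raw.items()}
    lengths = {v.shape for v in out.values()}
    if len(lengths) > 1:
        by_len: dict[tuple, list[str]] = {}
        for k, v in out.items():
            by_len.setdefault(v.shape, []).append(k)
        detail = "; ".join(
            f"length {shape[0] if shape else 0}: {ids[:3]}" for shape, ids in sorted(by_len.items())
        )
        raise ValueError(f"{path}: ragged embedding vectors ({detail})")
    return out


def write_embeddings(records: Sequence[EmbeddingRecord], path) -> None:
    payload = {r.id: [float(x) for x in r.vector] for r in records}
    with open(path, "w") as fh:
        json.dump(payload, fh)


# ---------------------------------------------------------------------------
# ground-truth + metadata CSVs


def read_labels_metadata(
    gt_path, meta_path=None
) -> tuple[pd.DataFrame, list[str]]:
    """Parse ground truth (one-hot or long CSV) and optional metadata.

    Returns (frame indexed by image ID with columns label, class_name, sex,
    age_band, site, cohort; list of class names defining the label order).
    'UNK'-labelled rows are dropped with a logged count.  IDs missing from
    the metadata — or an absent metadata file — yield "unknown" levels.
    """
    gt = pd.read_csv(gt_path)
    id_col = gt.columns[0]
    if gt[id_col].duplicated().any():
        dups = gt.loc[gt[id_col].duplicated(), id_col].tolist()
        raise ValueError(f"{gt_path}: duplicate image IDs: {dups[:5]}")

    cols = [c.lower() for c in gt.columns]
    if len(gt.columns) == 2 and cols[1] in {"label", "class", "diagnosis"}:
        # long dialect: ID,label
        class_names = sorted(gt.iloc[:, 1].astype(str).unique())
        name_to_idx = {n: i for i, n in enumerate(class_names)}
        frame = pd.DataFrame(
            {
                "label": gt.iloc[:, 1].astype(str).map(name_to_idx).values,
                "class_name": gt.iloc[:, 1].astype(str).values,
            },
            index=gt[id_col].astype(str),
        )
    else:
        class_cols = [c for c in gt.columns[1:]]
        onehot = gt[class_cols].to_numpy(dtype=float)
        row_sums = onehot.sum(axis=1)
        bad = np.flatnonzero(~np.isclose(row_sums, 1.0))
        if bad.size:
            ids = gt[id_col].iloc[bad].tolist()
            raise ValueError(
                f"{gt_path}: rows must be exactly one-hot; offending IDs: {ids[:5]}"
            )
        label_idx = onehot.argmax(axis=1)
        names = [class_cols[i] for i in label_idx]
        frame = pd.DataFrame(
            {"label": label_idx, "class_name": names}, index=gt[id_col].astype(str)
        )
        unk_mask = frame["class_name"].str.upper() == "UNK"
        if unk_mask.any():
            logger.info("dropping %d 'UNK'-labelled rows", int(unk_mask.sum()))
            frame = frame[~unk_mask]
        class_names = [c for c in class_cols if c.upper() != "UNK"]
        # re-index labels over the surviving classes
        remap = {class_cols.index(n): i for i, n in enumerate(class_names)}
        frame["label"] = frame["label"].map(remap)

    for col in ("sex", "age_band", "site", "cohort"):
        frame[col] = "unknown"
    if meta_path is not None and Path(meta_path).exists():
        meta = pd.read_csv(meta_path)
        meta = meta.set_index(meta.columns[0])
        meta.index = meta.index.astype(str)
        if meta.index.duplicated().any():
            dups = meta.index[meta.index.duplicated()].tolist()
            raise ValueError(f"{meta_path}: duplicate image IDs: {dups[:5]}")
        lower = {c.lower(): c for c in meta.columns}
        age_col = lower.get("age") or lower.get("age_approx")
        sex_col = lower.get("sex")
        site_col = lower.get("site") or lower.get("anatom_site_general") or lower.get(
            "anatom_site"
        )
        cohort_col = lower.get("cohort") or lower.get("ethnicity")
        common = frame.index.intersection(meta.index)
        if age_col:
            frame.loc[common, "age_band"] = meta.loc[common, age_col].map(age_to_band)
        if sex_col:
            vals = meta.loc[common, sex_col].astype(str).str.lower()
            frame.loc[common, "sex"] = vals.where(vals.isin(["male", "female"]), "unknown")
        if site_col:
            vals = meta.loc[common, site_col].astype(str)
            frame.loc[common, "site"] = vals.where(
                ~vals.isin(["nan", ""]), "unknown"
            )
        if cohort_col:
            frame.loc[common, "cohort"] = meta.loc[common, cohort_col].astype(str)
    return frame, class_names


def write_ground_truth(
    records: Sequence[EmbeddingRecord], path, class_names: Sequence[str] | None = None
) -> None:
    """One-hot ISIC-dialect ground-truth CSV."""
    n_classes = max(r.label for r in records) + 1
    if class_names is None:
        class_names = [f"class_{i}" for i in range(n_classes)]
    rows = []
    for r in records:
        row = {"image": r.id}
        for i, name in enumerate(class_names):
            row[name] = 1.0 if i == r.label else 0.0
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_metadata(records: Sequence[EmbeddingRecord], path) -> None:
    rows = [
        {
            "image": r.id,
            "age_approx": _BAND_REPRESENTATIVE_AGE.get(
                r.demographics.get("age_band", "unknown"), ""
            ),
            "sex": r.demographics.get("sex", "unknown"),
            "anatom_site_general": r.demographics.get("site", "unknown"),
            "cohort": r.demographics.get("cohort", "unknown"),
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_cohort(records: Sequence[EmbeddingRecord], outdir,
                 class_names: Sequence[str] | None = None) -> None:
    """Write embeddings.json, ground_truth.csv and metadata.csv for a cohort."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_embeddings(records, outdir / "embeddings.json")
    write_ground_truth(records, outdir / "ground_truth.csv", class_names)
    write_metadata(records, outdir / "metadata.csv")


def records_from_files(embeddings_path, gt_path, meta_path=None) -> list[EmbeddingRecord]:
    """Join embeddings with labels and demographics into records."""
    vectors = read_embeddings(embeddings_path)
    frame, _ = read_labels_metadata(gt_path, meta_path)
    missing = [i for i in frame.index if i not in vectors]
    if missing:
        raise ValueError(f"IDs in ground truth without embeddings: {missing[:5]}")
    return [
        EmbeddingRecord(
            id=i,
            vector=vectors[i],
            label=int(frame.at[i, "label"]),
            demographics={
                "sex": frame.at[i, "sex"],
                "age_band": frame.at[i, "age_band"],
                "site": frame.at[i, "site"],
                "cohort": frame.at[i, "cohort"],
            },
        )
        for i in frame.index
    ]


# ---------------------------------------------------------------------------
# model and prediction-set artifacts


def save_model(model: MLPHead, path) -> None:
    arrays = {f"param_{k}": v for k, v in model.params.items()}
    arrays.update({f"running_{k}": v for k, v in model.running.items()})
    meta = json.dumps(
        {"config": dataclasses.asdict(model.cfg), "n_classes": model.n_classes}
    )
    np.savez(path, _meta=np.array(meta), **arrays)


def load_model(path) -> MLPHead:
    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["_meta"]))
    cfg_dict = meta["config"]
    sampler = cfg_dict.pop("sampler", None)
    cfg = MLPConfig(
        **cfg_dict, sampler=SamplerConfig(**sampler) if sampler else None
    )
    model = MLPHead(cfg, meta["n_classes"])
    for key in data.files:
        if key.startswith("param_"):
            model.params[key[len("param_"):]] = data[key]
        elif key.startswith("running_"):
            model.running[key[len("running_"):]] = data[key]
    model.fitted = True
    return model


def write_sets(sets: Sequence[conformal.PredictionSet], path) -> None:
    """Serialise prediction sets as JSON lines: {id, entries, truth}."""
    with open(path, "w") as fh:
        for s in sets:
            fh.write(
                json.dumps(
                    {
                        "id": s.sample_id,
                        "entries": [[int(l), float(c)] for l, c in s.entries],
                        "truth": s.truth,
                    }
                )
                + "\n"
            )


def load_sets(path) -> list[conformal.PredictionSet]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            d = json.loads(line)
            out.append(
                conformal.PredictionSet(
                    sample_id=d["id"],
                    entries=tuple((int(l), float(c)) for l, c in d["entries"]),
                    truth=d.get("truth"),
                )
            )
    return out


# ---------------------------------------------------------------------------
# run configuration and orchestration


def mlp_config_from_dict(mlp_raw, sampler_raw="default") -> MLPConfig:
    """Build an MLPConfig from YAML-style dicts; sampler ``None`` disables it."""
    kwargs = dict(mlp_raw or {})
    if sampler_raw is None:
        kwargs["sampler"] = None
    elif sampler_raw != "default":
        kwargs["sampler"] = SamplerConfig(**sampler_raw)
    return MLPConfig(**kwargs)


@dataclass
class RunConfig:
    """One end-to-end run: data source, model, sampler, conformal settings."""

    seed: int = 0
    alpha: float = 0.2
    cohort: CohortSpec | None = None
    embeddings_path: str | None = None
    ground_truth_path: str | None = None
    metadata_path: str | None = None
    mlp: MLPConfig = field(default_factory=MLPConfig)
    audit_attributes: tuple[str, ...] = ("sex", "age_band", "site")
    alphas_curve: tuple[float, ...] = (0.05, 0.1, 0.2, 0.3, 0.4)

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.cohort is None:
            for name in ("embeddings_path", "ground_truth_path"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise ValueError(
                        f"real-data mode requires an existing {name}, got {p!r}"
                    )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "RunConfig":
        raw = dict(raw)
        cohort = raw.pop("cohort", None)
        if cohort is not None:
            effects = {
                (e["attribute"], e["level"]): SubgroupEffect(
                    noise_scale=e.get("noise_scale", 0.0),
                    mean_shift=e.get("mean_shift", 0.0),
                )
                for e in cohort.pop("subgroup_effects", [])
            }
            cohort = CohortSpec(**cohort, subgroup_effects=effects)
        mlp = mlp_config_from_dict(
            raw.pop("mlp", None), raw.pop("sampler", "default")
        )
        if "audit_attributes" in raw:
            raw["audit_attributes"] = tuple(raw["audit_attributes"])
        if "alphas_curve" in raw:
            raw["alphas_curve"] = tuple(raw["alphas_curve"])
        return cls(cohort=cohort, mlp=mlp, **raw)


def _stage_seeds(master: int) -> dict[str, int]:
    ss = np.random.SeedSequence(master)
    names = ("cohort", "split", "train", "calibrate")
    children = ss.spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2**31)) for n, c in zip(names, children)}


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run simulate → split → train → calibrate → predict-sets → audit.

    Every stage writes its artifact under ``outdir``; the returned dict holds
    the in-memory results (records, split, model, calibration, sets, report).
    Deterministic given ``config.seed``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    (outdir / "stage_seeds.json").write_text(json.dumps(seeds, indent=2))

    stage = "simulate"
    try:
        if config.cohort is not None:
            spec = dataclasses.replace(config.cohort, seed=seeds["cohort"])
            records = generate_cohort(spec)
            write_cohort(records, outdir)
        else:
            records = records_from_files(
                config.embeddings_path, config.ground_truth_path, config.metadata_path
            )

        stage = "split"
        split = split_cohort(records, seed=seeds["split"])
        (outdir / "split.json").write_text(json.dumps(dataclasses.asdict(split), indent=2))
        by_id = {r.id: r for r in records}
        train = [by_id[i] for i in split.train]
        val = [by_id[i] for i in split.validation]
        cal = [by_id[i] for i in split.calibration]
        test = [by_id[i] for i in split.test]
        n_classes = max(r.label for r in records) + 1

        stage = "train"
        cfg = dataclasses.replace(config.mlp, seed=seeds["train"])
        model, log = train_head(train, val, cfg, n_classes=n_classes)
        log.to_csv(outdir / "training_log.csv", index=False)
        save_model(model, outdir / "model.npz")

        stage = "calibrate"
        prob_cal = predict_proba(model, cal)
        truth_cal = np.array([r.label for r in cal])
        scores = conformal.nonconformity_scores(prob_cal, truth_cal)
        calib = conformal.calibrate(scores, config.alpha)
        (outdir / "calibration.json").write_text(
            json.dumps(
                {
                    "alpha": calib.alpha,
                    "n": calib.n,
                    "q_hat": calib.q_hat,
                    "scores": calib.scores.tolist(),
                }
            )
        )

        stage = "predict-sets"
        prob_test = predict_proba(model, test)
        truth_test = np.array([r.label for r in test])
        sets = conformal.build_sets(
            prob_test, calib, sample_ids=[r.id for r in test], truths=truth_test
        )
        write_sets(sets, outdir / "sets.jsonl")

        stage = "audit"
        metadata = {r.id: dict(r.demographics) for r in records}
        top_conf = np.array([s.entries[0][1] for s in sets])
        hit = np.array([s.contains_truth() for s in sets])
        calibration_errors = conformal.ece_mce(top_conf, hit)
        curve = conformal.coverage_curve(
            prob_cal, truth_cal, prob_test, truth_test, config.alphas_curve
        )
        report = build_audit_report(
            sets,
            metadata,
            attributes=config.audit_attributes,
            n_classes=n_classes,
            calibration=calibration_errors,
            coverage_curve=curve,
        )
        report.to_json(outdir / "report.json")
        report.write_csvs(outdir)
    except Exception as exc:  # noqa: BLE001 - annotate failures with the stage
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return {
        "records": records,
        "split": split,
        "model": model,
        "training_log": log,
        "calibration": calib,
        "sets": sets,
        "coverage": conformal.empirical_coverage(sets),
        "report": report,
    }
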