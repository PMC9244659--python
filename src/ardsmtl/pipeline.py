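"""Stage orchestration: reproducible artifact pipeline with manifests.

Stages (in dependency order): simulate -> preprocess -> label -> train /
baseline -> evaluate / interpret / cluster, plus benefit (needs label only).
Every stage writes its artifacts under the configured work directory together
with a manifest recording the SHA-256 of each artifact, the seed and the
package version; identical config and seed reproduce identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .baseline_gbt import BaselineConfig, predict_proba as gbt_predict, train_one_vs_all
from .benefit_estimation import benefit_report, format_report
from .evaluation import ablation_curve, compare_models, evaluate_model
from .interpretability import attention_heatmap_data, heatmap_to_tsv
from .io import (
    read_cohort,
    read_labels,
    read_tensors,
    write_cohort,
    write_labels,
    write_tensors,
)
from .multitask_rnn import ModelConfig, load_model, save_model, train as train_rnn
from .outcome_labels import LABEL_NAMES, LabelSet, derive_labels
from .phenotype_clustering import cluster_report
from .preprocessing import tensors_for_cohort
from .synthetic_ehr import CohortConfig, generate_cohort

STAGES = [
    "simulate",
    "preprocess",
    "label",
    "train",
    "baseline",
    "evaluate",
    "interpret",
    "cluster",
    "benefit",
]

_DEPENDENCIES: dict[str, list[str]] = {
    "simulate": [],
    "preprocess": ["cohort/patients.csv"],
    "label": ["cohort/patients.csv", "tensors_train.json"],
    "train": ["tensors_train.npz", "labels.csv"],
    "baseline": ["tensors_train.npz", "labels.csv"],
    "evaluate": ["model.npz", "baseline_predictions.csv"],
    "interpret": ["model.npz", "tensors_test.npz"],
    "cluster": ["model.npz", "tensors_test.npz", "labels.csv"],
    "benefit": ["labels.csv"],
}


class DependencyError(RuntimeError):
    """A required upstream artifact is missing."""


@dataclass
class PipelineConfig:
    """All pipeline settings; ``from_yaml`` overlays a config file on defaults."""

    workdir: str = "ardsmtl_run"
    seed: int = 0
    n_patients: int = 2000
    train_frac: float = 0.6
    val_frac: float = 0.2
    model: ModelConfig = field(default_factory=ModelConfig)
    baseline: BaselineConfig = field(default_factory=BaselineConfig)
    bootstrap_resamples: int = 200
    target_sensitivity: float = 0.65
    heatmap_sample: int = 50

    @classmethod
    def from_yaml(cls, path: str | Path | None, **overrides) -> "PipelineConfig":
        data: dict = {}
        if path is not None:
            data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        model = ModelConfig(**data.pop("model", {}))
        baseline = BaselineConfig(**data.pop("baseline", {}))
        return cls(model=model, baseline=baseline, **data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(workdir: Path, stage: str, outputs: list[Path], seed: int) -> None:
    manifest = {
        "stage": stage,
        "seed": seed,
        "version": __version__,
        "artifacts": {
            str(p.relative_to(workdir)): _sha256(p) for p in sorted(outputs)
        },
    }
    (workdir / f"manifest_{stage}.json").write_text(json.dumps(manifest, indent=2))


def _require(workdir: Path, stage: str) -> None:
    for rel in _DEPENDENCIES[stage]:
        if not (workdir / rel).exists():
            for candidate, outs in _STAGE_OUTPUT_HINTS.items():
                if any(rel.startswith(o) for o in outs):
                    raise DependencyError(
                        f"stage {stage!r} needs {rel!r}; run {candidate!r} first"
                    )
            raise DependencyError(f"stage {stage!r} needs missing artifact {rel!r}")


_STAGE_OUTPUT_HINTS = {
    "simulate": ["cohort/"],
    "preprocess": ["tensors_"],
    "label": ["labels.csv"],
    "train": ["model"],
    "baseline": ["baseline_"],
}


def _split_ids(patient_ids: list[str], config: PipelineConfig) -> dict[str, list[str]]:
    """Deterministic train/val/test split by shuffled patient index."""
    rng = np.random.default_rng(config.seed + 17)
    order = rng.permutation(len(patient_ids))
    n_train = int(round(config.train_frac * len(order)))
    n_val = int(round(config.val_frac * len(order)))
    splits = {
        "train": order[:n_train],
        "val": order[n_train : n_train + n_val],
        "test": order[n_train + n_val :],
    }
    return {k: [patient_ids[i] for i in v] for k, v in splits.items()}


def run_stage(stage: str, config: PipelineConfig) -> list[Path]:
    """Run one stage; returns the artifact paths it wrote."""
    workdir = Path(config.workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    _require(workdir, stage)
    fn = _STAGE_FUNCS[stage]
    outputs = fn(config, workdir)
    _write_manifest(workdir, stage, outputs, config.seed)
    return outputs


def run_pipeline(config: PipelineConfig, stages: list[str] | None = None) -> None:
    for stage in stages or STAGES:
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}")
        run_stage(stage, config)


# --- stage implementations -------------------------------------------------


def _stage_simulate(config: PipelineConfig, workdir: Path) -> list[Path]:
    cohort_cfg = CohortConfig(n_patients=config.n_patients, seed=config.seed)
    records = generate_cohort(cohort_cfg)
    write_cohort(records, workdir / "cohort")
    return [workdir / "cohort" / f for f in ("patients.csv", "observations.csv", "diagnoses.csv")]


def _stage_preprocess(config: PipelineConfig, workdir: Path) -> list[Path]:
    records = read_cohort(workdir / "cohort")
    by_id = {r.patient_id: r for r in records}
    splits = _split_ids([r.patient_id for r in records], config)
    outputs = []
    excluded_all: dict[str, list[str]] = {}
    for split, ids in splits.items():
        recs = [by_id[i] for i in ids]
        sem = "test" if split == "test" else "train_val"
        tensors, kept, algotimes, excluded = tensors_for_cohort(recs, split=sem)
        write_tensors(tensors, kept, algotimes, workdir / f"tensors_{split}")
        excluded_all[split] = excluded
        outputs += [workdir / f"tensors_{split}.npz", workdir / f"tensors_{split}.json"]
    p = workdir / "excluded.json"
    p.write_text(json.dumps(excluded_all, indent=2))
    outputs.append(p)
    return outputs


def _labels_for_split(workdir: Path, split: str) -> tuple[np.ndarray, pd.DataFrame]:
    tensors, meta = read_tensors(workdir / f"tensors_{split}")
    labels = read_labels(workdir / "labels.csv").set_index("patient_id")
    frame = labels.loc[[m["patient_id"] for m in meta]].reset_index()
    return tensors, frame


def _stage_label(config: PipelineConfig, workdir: Path) -> list[Path]:
    from datetime import datetime

    records = {r.patient_id: r for r in read_cohort(workdir / "cohort")}
    ids: list[str] = []
    label_sets: list[LabelSet] = []
    for split in ("train", "val", "test"):
        _, meta = read_tensors(workdir / f"tensors_{split}")
        for m in meta:
            record = records[m["patient_id"]]
            algotime = datetime.strptime(m["algotime"], "%Y-%m-%dT%H:%M:%S")
            ids.append(m["patient_id"])
            label_sets.append(derive_labels(record, algotime))
    write_labels(ids, label_sets, workdir / "labels.csv")
    return [workdir / "labels.csv"]


def _stage_train(config: PipelineConfig, workdir: Path) -> list[Path]:
    train_x, train_f = _labels_for_split(workdir, "train")
    val_x, val_f = _labels_for_split(workdir, "val")
    subset = config.model.target_subset
    model = train_rnn(
        train_x,
        train_f[subset].to_numpy(),
        val_x,
        val_f[subset].to_numpy(),
        config.model,
    )
    save_model(model, workdir / "model")
    return [workdir / "model.npz", workdir / "model.json"]


def _stage_baseline(config: PipelineConfig, workdir: Path) -> list[Path]:
    train_x, train_f = _labels_for_split(workdir, "train")
    val_x, val_f = _labels_for_split(workdir, "val")
    test_x, test_f = _labels_for_split(workdir, "test")
    targets = config.model.target_subset
    scorers = train_one_vs_all(
        train_x,
        {t: train_f[t].to_numpy() for t in targets},
        val_x,
        {t: val_f[t].to_numpy() for t in targets},
        config.baseline,
    )
    preds = gbt_predict(scorers, test_x)
    frame = pd.DataFrame({"patient_id": test_f["patient_id"]})
    for t in targets:
        frame[t] = preds[t]
    frame.to_csv(workdir / "baseline_predictions.csv", index=False)
    grid = {
        t: {"max_depth": s.chosen_depth, "learning_rate": s.chosen_lr}
        for t, s in scorers.items()
    }
    (workdir / "baseline_grid.json").write_text(json.dumps(grid, indent=2))
    return [workdir / "baseline_predictions.csv", workdir / "baseline_grid.json"]


def _stage_evaluate(config: PipelineConfig, workdir: Path) -> list[Path]:
    test_x, test_f = _labels_for_split(workdir, "test")
    model = load_model(workdir / "model")
    targets = model.config.target_subset
    probs = model.predict_proba(test_x)
    rnn_probs = {t: probs[:, j] for j, t in enumerate(targets)}
    labels = {t: test_f[t].to_numpy() for t in targets}
    rnn_report = evaluate_model(
        rnn_probs,
        labels,
        model_name=f"rnn{len(targets)}",
        n_resamples=config.bootstrap_resamples,
        target_sensitivity=config.target_sensitivity,
        seed=config.seed,
    )
    base_frame = pd.read_csv(workdir / "baseline_predictions.csv")
    base_probs = {t: base_frame[t].to_numpy() for t in targets}
    base_report = evaluate_model(
        base_probs,
        labels,
        model_name="xgb",
        n_resamples=config.bootstrap_resamples,
        target_sensitivity=config.target_sensitivity,
        seed=config.seed,
    )
    rnn_report.rows.to_csv(workdir / "report_rnn.tsv", sep="\t")
    base_report.rows.to_csv(workdir / "report_xgb.tsv", sep="\t")
    comparison = compare_models(rnn_report, base_report)
    comparison.to_csv(workdir / "report_comparison.tsv", sep="\t")
    (workdir / "report.json").write_text(
        json.dumps(
            {
                "rnn": rnn_report.rows.to_dict(orient="index"),
                "xgb": base_report.rows.to_dict(orient="index"),
            },
            indent=2,
        )
    )
    return [
        workdir / "report_rnn.tsv",
        workdir / "report_xgb.tsv",
        workdir / "report_comparison.tsv",
        workdir / "report.json",
    ]


def _stage_interpret(config: PipelineConfig, workdir: Path) -> list[Path]:
    test_x, test_f = _labels_for_split(workdir, "test")
    model = load_model(workdir / "model")
    n_sample = min(config.heatmap_sample, len(test_x))
    idx, weights = attention_heatmap_data(model, test_x, n_sample, seed=config.seed)
    heatmap_to_tsv(weights, workdir / "attention_heatmap.tsv")
    pd.DataFrame(
        {"patient_id": test_f["patient_id"].to_numpy()[idx]}
    ).to_csv(workdir / "attention_sample.csv", index=False)
    return [workdir / "attention_heatmap.tsv", workdir / "attention_sample.csv"]


def _stage_cluster(config: PipelineConfig, workdir: Path) -> list[Path]:
    # phenotypes are sought across the ARDS population of the entire data set
    xs, frames = [], []
    for split in ("train", "val", "test"):
        x, f = _labels_for_split(workdir, split)
        xs.append(x)
        frames.append(f)
    all_x = np.concatenate(xs)
    all_f = pd.concat(frames, ignore_index=True)
    model = load_model(workdir / "model")
    report = cluster_report(
        model,
        all_x,
        all_f[LABEL_NAMES],
        list(all_f["patient_id"]),
        seed=config.seed,
    )
    pd.DataFrame(
        {
            "patient_id": report.patient_ids,
            "cluster": report.assignments,
            "pc1": report.coordinates[:, 0],
            "pc2": report.coordinates[:, 1],
        }
    ).to_csv(workdir / "clusters.csv", index=False)
    report.incidence.to_csv(workdir / "cluster_incidence.tsv", sep="\t")
    return [workdir / "clusters.csv", workdir / "cluster_incidence.tsv"]


def _stage_benefit(config: PipelineConfig, workdir: Path) -> list[Path]:
    frame = read_labels(workdir / "labels.csv")
    label_sets = [
        LabelSet(
            **{name: bool(row[name]) for name in LABEL_NAMES},
            diagnosis_timing=row["diagnosis_timing"],
        )
        for _, row in frame.iterrows()
    ]
    report = benefit_report(label_sets)
    t = report.table
    payload = {
        "table": {"early_died": t.a, "early_survived": t.b, "late_died": t.c, "late_survived": t.d},
        "early_mortality_pct": report.early_mortality_pct,
        "late_mortality_pct": report.late_mortality_pct,
        "no_ards_mortality_pct": report.no_ards_mortality_pct,
        "ards_mortality_pct": report.ards_mortality_pct,
        "fisher_p": report.fisher_p,
        "warning": report.warning,
    }
    (workdir / "benefit.json").write_text(json.dumps(payload, indent=2))
    (workdir / "benefit.txt").write_text(format_report(report) + "\n")
    return [workdir / "benefit.json", workdir / "benefit.txt"]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "label": _stage_label,
    "train": _stage_train,
    "baseline": _stage_baseline,
    "evaluate": _stage_evaluate,
    "interpret": _stage_interpret,
    "cluster": _stage_cluster,
    "benefit": _stage_benefit,
}
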