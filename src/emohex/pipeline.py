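"""Configuration-driven pipeline: simulate -> score -> residualize ->
classify -> report.

A pipeline run is described by a YAML/JSON config (see
:func:`default_config`) and a master seed. Every stage writes delimited
text (comma separator, header row, UTF-8); the run ends with a JSON
manifest listing each artifact with a SHA-256 content hash, so reruns with
the same config and seed are verifiably byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import hexagon, residualize, synthetic
from .angle_glvq import TrainingConfig
from .errors import EmohexError, ValidationError
from .evaluation import (
    TASKS,
    aggregate_relevance,
    run_task,
    runs_frame,
    summarize_runs,
)

log = logging.getLogger("emohex")

FEATURE_SETS = ("accuracy12", "confusion_full", "confusion_subset")


def default_config() -> dict:
    return {
        "seed": 0,
        "output_dir": "results/run",
        "simulate": {
            "group_sizes": {"HCU": 248, "LCU": 230, "TD": 785},
            "reps_per_blend": 5,
        },
        "feature_set": "accuracy12",
        "confusion_columns": None,
        "residualize": {"mode": "pooled"},
        "training": {},
        "evaluation": {
            "n_repeats": 100,
            "train_fraction": 0.75,
            "threshold": 0.5,
        },
        "tasks": ["CD-TD", "HCU-TD", "LCU-TD", "HCU-LCU"],
    }


def load_config(path: str | Path) -> dict:
    import yaml

    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)  # JSON is a subset of YAML
    if not isinstance(doc, dict):
        raise ValidationError(f"config {path} is not a mapping")
    merged = default_config()
    for key, val in doc.items():
        if isinstance(val, dict) and isinstance(merged.get(key), dict):
            merged[key] = {**merged[key], **val}
        else:
            merged[key] = val
    return merged


def cohort_spec_from_config(config: dict) -> synthetic.CohortSpec:
    sim = dict(config.get("simulate", {}))
    sim.setdefault("seed", config.get("seed", 0))
    known = {f.name for f in dataclasses.fields(synthetic.CohortSpec)}
    unknown = set(sim) - known
    if unknown:
        raise ValidationError(f"unknown simulate keys: {sorted(unknown)}")
    if "group_sizes" in sim:
        sim["group_sizes"] = {k: int(v) for k, v in sim["group_sizes"].items()}
    return synthetic.CohortSpec(**sim)


def training_config_from_config(config: dict) -> TrainingConfig:
    tc = dict(config.get("training", {}))
    known = {f.name for f in dataclasses.fields(TrainingConfig)}
    unknown = set(tc) - known
    if unknown:
        raise ValidationError(f"unknown training keys: {sorted(unknown)}")
    return TrainingConfig(**tc)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=index, encoding="utf-8", float_format="%.10g")


def derive_features(trials: pd.DataFrame, config: dict) -> pd.DataFrame:
    feature_set = config.get("feature_set", "accuracy12")
    if feature_set not in FEATURE_SETS:
        raise ValidationError(f"unknown feature_set {feature_set!r}")
    if feature_set == "accuracy12":
        return hexagon.accuracy_features(trials)
    confusion = hexagon.confusion_features(trials)
    if feature_set == "confusion_full":
        return confusion
    cols = config.get("confusion_columns")
    if not cols:
        raise ValidationError(
            "feature_set 'confusion_subset' requires confusion_columns"
        )
    return hexagon.select_confusion_subset(confusion, list(cols))


def run_pipeline(
    config: dict,
    seed: int | None = None,
    output_dir: str | Path | None = None,
) -> dict:
    """Run every stage and return the artifact manifest.

    ``seed``/``output_dir`` override the corresponding config entries.
    Deterministic: identical config + seed give identical content hashes.
    """
    if seed is not None:
        config = {**config, "seed": int(seed)}
    out = Path(output_dir or config.get("output_dir", "results/run"))
    out.mkdir(parents=True, exist_ok=True)
    master_seed = int(config.get("seed", 0))
    log.info("pipeline start: seed=%d out=%s", master_seed, out)

    spec = cohort_spec_from_config(config)
    participants = synthetic.generate_participants(spec)
    _write_csv(participants, out / "participants.csv")
    trials = synthetic.generate_trials(participants, spec)
    _write_csv(trials, out / "trials.csv")
    log.info(
        "simulated %d participants, %d trials", len(participants), len(trials)
    )

    features = derive_features(trials, config)
    _write_csv(features, out / "features.csv", index=True)

    design = residualize.build_design(
        participants.set_index("participant_id").loc[features.index].reset_index()
    )
    mode = config.get("residualize", {}).get("mode", "pooled")
    residuals = residualize.residualize_features(features, design, mode=mode)
    _write_csv(residuals, out / "residual_features.csv", index=True)
    log.info("residualized %d feature columns (mode=%s)", residuals.shape[1], mode)

    tcfg = training_config_from_config(config)
    ev = config.get("evaluation", {})
    n_repeats = int(ev.get("n_repeats", 100))
    train_fraction = float(ev.get("train_fraction", 0.75))
    threshold = float(ev.get("threshold", 0.5))
    task_names = config.get("tasks") or []
    if not task_names:
        raise ValidationError("task list is empty")
    for t in task_names:
        if t not in TASKS:
            raise ValidationError(
                f"unknown task {t!r}; choose from {sorted(TASKS)}"
            )

    summaries = {}
    for name in task_names:
        task = TASKS[name]
        runs = run_task(
            residuals,
            participants,
            task,
            config=tcfg,
            n_repeats=n_repeats,
            train_fraction=train_fraction,
            master_seed=master_seed,
        )
        _write_csv(runs_frame(runs), out / f"metrics_{name}.csv")
        summary = summarize_runs(runs)
        summary.insert(0, "task", name)
        summaries[name] = summary
        _write_csv(summary, out / f"summary_{name}.csv")
        agg = aggregate_relevance(
            runs, threshold=threshold, feature_names=tuple(residuals.columns)
        )
        rel = pd.DataFrame(
            {
                "feature": residuals.columns,
                "mean_relevance": agg.mean_relevance,
            }
        )
        rel.attrs["retained"] = agg.retained
        _write_csv(rel, out / f"relevance_{name}.csv")
        log.info(
            "task %s: mean macro accuracy %.3f (binomial p=%.3g, "
            "%d/%d runs retained for relevance)",
            name,
            summary.loc[summary["metric"] == "macro_accuracy", "mean"].iloc[0],
            summary.attrs["binomial_p_vs_chance"],
            agg.retained,
            agg.total,
        )

    table = pd.concat(summaries.values(), ignore_index=True)
    _write_csv(table, out / "summary_all_tasks.csv")

    manifest = {
        "seed": master_seed,
        "config_hash": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "threshold": threshold,
        "n_repeats": n_repeats,
        "files": {
            p.name: _sha256(p)
            for p in sorted(out.iterdir())
            if p.suffix == ".csv"
        },
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2), encoding="utf-8"
    )
    log.info("pipeline done: %d artifacts", len(manifest["files"]))
    return manifest
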