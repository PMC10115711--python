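"""Resampled evaluation protocol and feature-relevance aggregation.

Four two-class comparisons are run: CD-TD (both conduct-disorder subtypes
merged against typically developing youths), HCU-TD, LCU-TD and HCU-LCU.
For each, 100 stratified random 75/25 train/test splits are drawn, a
classifier is trained and tested on each, and performance is summarized as
macro-averaged accuracy — the mean of the per-class accuracies, which is
not inflated by the much larger TD class — plus PPV, NPV, TPR and TNR.
Above-chance performance is assessed with an exact binomial test on the
test classifications pooled across runs. Relevance profiles from runs
whose macro accuracy falls below a retention threshold (default 50%) are
discarded before averaging, since a classifier at or below chance carries
no information about which features matter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .angle_glvq import (
    AngleGMLVQModel,
    TrainingConfig,
    feature_relevances,
    fit,
    predict,
)
from .errors import (
    EmptyAggregateError,
    StratificationError,
    UndefinedMetricError,
    ValidationError,
    ZeroVarianceError,
)


@dataclass(frozen=True)
class ModelTask:
    """One two-class comparison: a group-to-class mapping plus which class
    counts as 'positive' (the clinical group) in the confusion table."""

    name: str
    positive: str
    negative: str
    mapping: dict

    def classes(self, groups: pd.Series) -> pd.Series:
        return groups.map(self.mapping)


TASKS: dict[str, ModelTask] = {
    t.name: t
    for t in (
        ModelTask(
            "CD-TD", "CD", "TD", {"HCU": "CD", "LCU": "CD", "TD": "TD"}
        ),
        ModelTask("HCU-TD", "HCU", "TD", {"HCU": "HCU", "TD": "TD"}),
        ModelTask("LCU-TD", "LCU", "TD", {"LCU": "LCU", "TD": "TD"}),
        ModelTask("HCU-LCU", "HCU", "LCU", {"HCU": "HCU", "LCU": "LCU"}),
    )
}


@dataclass
class RunResult:
    """Metrics and relevance profile of one train/test repeat."""

    run_index: int
    seed: int
    tp: int
    fp: int
    tn: int
    fn: int
    macro_accuracy: float
    ppv: float | None
    npv: float | None
    tpr: float | None
    tnr: float | None
    relevance: np.ndarray


@dataclass
class RelevanceAggregate:
    retained: int
    total: int
    threshold: float
    mean_relevance: np.ndarray
    feature_names: tuple[str, ...] | None = None


def split_resample(
    labels,
    n_repeats: int,
    train_fraction: float = 0.75,
    master_seed: int = 0,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Repeated stratified random train/test splits.

    Per class, the training count is the class size times ``train_fraction``
    rounded half-up; every class must land in both partitions. Per-run RNGs
    are spawned deterministically from ``master_seed``.
    """
    labels = np.asarray(labels)
    if not 0.0 < train_fraction < 1.0:
        raise ValidationError("train_fraction must lie strictly in (0, 1)")
    if n_repeats < 1:
        raise ValidationError("n_repeats must be >= 1")
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise StratificationError("need at least two classes to stratify")
    n_train = {}
    for c, n in zip(classes, counts):
        k = int(np.floor(n * train_fraction + 0.5))  # round half up
        if k < 1 or k >= n:
            raise StratificationError(
                f"class {c!r} (n={n}) cannot appear in both train and test "
                f"partitions at train_fraction={train_fraction}"
            )
        n_train[c] = k
    children = np.random.SeedSequence(master_seed).spawn(n_repeats)
    splits = []
    for child in children:
        rng = np.random.default_rng(child)
        train, test = [], []
        for c in classes:
            idx = np.flatnonzero(labels == c)
            perm = rng.permutation(idx)
            train.append(perm[: n_train[c]])
            test.append(perm[n_train[c] :])
        splits.append(
            (np.sort(np.concatenate(train)), np.sort(np.concatenate(test)))
        )
    return splits


def confusion_counts(y_true, y_pred, positive, negative) -> tuple[int, int, int, int]:
    """(TP, FP, TN, FN) with respect to the task's positive class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    tp = int(((y_true == positive) & (y_pred == positive)).sum())
    fn = int(((y_true == positive) & (y_pred != positive)).sum())
    tn = int(((y_true == negative) & (y_pred == negative)).sum())
    fp = int(((y_true == negative) & (y_pred != negative)).sum())
    return tp, fp, tn, fn


def macro_accuracy(tp: int, fp: int, tn: int, fn: int) -> float:
    """(TPR + TNR) / 2 — the mean of the two per-class accuracies."""
    if tp + fn == 0 or tn + fp == 0:
        raise UndefinedMetricError(
            "macro accuracy undefined: a class has no test members"
        )
    return ((tp / (tp + fn)) + (tn / (tn + fp))) / 2.0


def predictive_values(tp: int, fp: int, tn: int, fn: int) -> dict:
    """PPV, NPV, TPR, TNR; a zero-denominator metric is None (missing),
    never silently zero."""

    def ratio(num, den):
        return num / den if den > 0 else None

    return {
        "ppv": ratio(tp, tp + fp),
        "npv": ratio(tn, tn + fn),
        "tpr": ratio(tp, tp + fn),
        "tnr": ratio(tn, tn + fp),
    }


def binomial_chance_test(correct: int, total: int, p0: float = 0.5) -> float:
    """Exact two-sided binomial p-value against chance performance ``p0``
    (sums the probabilities of all outcomes no more likely than the one
    observed)."""
    if total < 1 or not 0 <= correct <= total:
        raise ValidationError(
            f"invalid counts: correct={correct}, total={total}"
        )
    return float(stats.binomtest(correct, total, p0).pvalue)


def kruskal_wallis(score_groups: list) -> tuple[float, float]:
    """Kruskal-Wallis H (mid-ranks, tie-corrected) and its chi-squared
    p-value on len(groups)-1 degrees of freedom."""
    if len(score_groups) < 2:
        raise ValidationError("need at least two groups")
    for g in score_groups:
        if len(g) == 0:
            raise ValidationError("empty group")
    flat = np.concatenate([np.asarray(g, float) for g in score_groups])
    if np.ptp(flat) == 0:
        raise ZeroVarianceError("all observations are identical")
    h, p = stats.kruskal(*score_groups)
    return float(h), float(p)


def run_task(
    features: pd.DataFrame,
    participants: pd.DataFrame,
    task: ModelTask,
    config: TrainingConfig | None = None,
    n_repeats: int = 100,
    train_fraction: float = 0.75,
    master_seed: int = 0,
) -> list[RunResult]:
    """Train/test one two-class model over ``n_repeats`` resamples.

    ``features`` are the (residualized) per-participant features indexed by
    participant id; ``participants`` supplies the group column. Each run
    fits on its training split with a seed derived from ``master_seed`` and
    reports confusion counts, macro accuracy, predictive values and the
    normalized relevance profile.
    """
    config = config or TrainingConfig()
    groups = participants.set_index("participant_id")["group"]
    groups = groups.reindex(features.index)
    if groups.isna().any():
        raise ValidationError(
            "feature rows without a matching participant record"
        )
    mask = groups.isin(list(task.mapping)).to_numpy()
    if mask.sum() == 0:
        raise StratificationError(
            f"task {task.name}: no participants in its groups"
        )
    X = features.to_numpy(float)[mask]
    y = task.classes(groups[mask]).to_numpy()
    names = tuple(features.columns)
    try:
        splits = split_resample(y, n_repeats, train_fraction, master_seed)
    except StratificationError as exc:
        raise StratificationError(f"task {task.name}: {exc}") from exc
    run_seeds = np.random.SeedSequence(master_seed + 1).generate_state(n_repeats)
    results = []
    for r, (tr, te) in enumerate(splits):
        seed = int(run_seeds[r] % (2**31))
        model = fit(X[tr], y[tr], replace(config, seed=seed), feature_names=names)
        pred = predict(model, X[te])
        tp, fp, tn, fn = confusion_counts(y[te], pred, task.positive, task.negative)
        pv = predictive_values(tp, fp, tn, fn)
        results.append(
            RunResult(
                run_index=r,
                seed=seed,
                tp=tp,
                fp=fp,
                tn=tn,
                fn=fn,
                macro_accuracy=macro_accuracy(tp, fp, tn, fn),
                relevance=feature_relevances(model).scores,
                **pv,
            )
        )
    return results


def runs_frame(runs: list[RunResult]) -> pd.DataFrame:
    """Per-run metric table (one row per resample)."""
    return pd.DataFrame(
        {
            "run": [r.run_index for r in runs],
            "seed": [r.seed for r in runs],
            "tp": [r.tp for r in runs],
            "fp": [r.fp for r in runs],
            "tn": [r.tn for r in runs],
            "fn": [r.fn for r in runs],
            "macro_accuracy": [r.macro_accuracy for r in runs],
            "ppv": [r.ppv for r in runs],
            "npv": [r.npv for r in runs],
            "tpr": [r.tpr for r in runs],
            "tnr": [r.tnr for r in runs],
        }
    )


def summarize_runs(runs: list[RunResult]) -> pd.DataFrame:
    """Mean and normal-approximation 95% CI of each metric across runs,
    plus the pooled-count exact binomial test against 50% chance."""
    df = runs_frame(runs)
    rows = []
    for metric in ("macro_accuracy", "ppv", "npv", "tpr", "tnr"):
        vals = df[metric].dropna().to_numpy(float)
        mean = vals.mean()
        half = (
            1.959963984540054 * vals.std(ddof=1) / np.sqrt(len(vals))
            if len(vals) > 1
            else np.nan
        )
        rows.append((metric, mean, mean - half, mean + half, len(vals)))
    out = pd.DataFrame(
        rows, columns=["metric", "mean", "ci95_low", "ci95_high", "n_runs"]
    )
    correct = int(df["tp"].sum() + df["tn"].sum())
    total = int(df[["tp", "fp", "tn", "fn"]].to_numpy().sum())
    out.attrs["binomial_p_vs_chance"] = binomial_chance_test(correct, total)
    out.attrs["pooled_correct"] = correct
    out.attrs["pooled_total"] = total
    return out


def aggregate_relevance(
    runs: list[RunResult],
    threshold: float = 0.5,
    feature_names: tuple[str, ...] | None = None,
) -> RelevanceAggregate:
    """Mean relevance profile over runs with macro accuracy >= threshold.

    Raises :class:`EmptyAggregateError` if no run clears the threshold —
    an uninformative relevance average is never returned silently.
    """
    if not runs:
        raise ValidationError("no runs to aggregate")
    kept = [r for r in runs if r.macro_accuracy >= threshold]
    if not kept:
        raise EmptyAggregateError(
            f"no run reached macro accuracy {threshold}; "
            "relevance aggregate undefined"
        )
    mean = np.mean([r.relevance for r in kept], axis=0)
    return RelevanceAggregate(
        retained=len(kept),
        total=len(runs),
        threshold=threshold,
        mean_relevance=mean,
        feature_names=feature_names,
    )
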