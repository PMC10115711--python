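"""Emotion Hexagon task layout and trial scoring.

The task presents morphed blends of two emotions that sit on adjacent
vertices of a hexagon; each vertex neighbours the emotions it is most
easily confused with. A blend mixes the two vertex emotions in one of
five ratios (90:10, 70:30, 50:50, 30:70, 10:90). The majority ("dominant")
emotion is the correct answer; 50:50 blends have no correct answer and are
never scored. Per participant, recognition accuracy is summarized as the
percentage correct for each emotion at its 90% ("high intensity") and 70%
("low intensity") presentations, giving the 12 features the downstream
classifier consumes. Confusion features (which wrong label was chosen) and
remote-error counts (wrong labels that are not even hexagon neighbours of
the target) are derived from the same scored trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import MissingCellError, ValidationError

#: Standard cyclic arrangement: each emotion adjoins its most easily
#: confused neighbours; anger-happiness adjoin to close the hexagon.
DEFAULT_ORDER: tuple[str, ...] = (
    "happiness",
    "surprise",
    "fear",
    "sadness",
    "disgust",
    "anger",
)

#: Blend ratio levels, expressed as the percentage of the continuum's first
#: emotion (A) in an A:B morph.
RATIO_LEVELS: tuple[int, ...] = (90, 70, 50, 30, 10)

#: Dominant-emotion share -> intensity label. 50:50 blends are unscored.
INTENSITY_OF_SHARE = {90: "high", 70: "low"}

INTENSITIES: tuple[str, str] = ("high", "low")

TRIAL_COLUMNS = ["participant_id", "emotion_a", "emotion_b", "ratio_a", "response"]


@dataclass(frozen=True)
class HexagonLayout:
    """Cyclic arrangement of the six basic emotions.

    The adjacency relation (and hence the set of legal blend continua and
    the notion of a "remote" error) is derived from ``order``.
    """

    order: tuple[str, ...] = DEFAULT_ORDER

    def __post_init__(self) -> None:
        if len(self.order) != 6 or len(set(self.order)) != 6:
            raise ValidationError("hexagon layout requires six distinct emotions")

    @property
    def emotions(self) -> tuple[str, ...]:
        return self.order

    def neighbours(self, emotion: str) -> tuple[str, str]:
        """The two hexagon-adjacent emotions of ``emotion``."""
        try:
            i = self.order.index(emotion)
        except ValueError:
            raise ValidationError(f"unknown emotion label: {emotion!r}") from None
        n = len(self.order)
        return self.order[(i - 1) % n], self.order[(i + 1) % n]

    def continua(self) -> list[tuple[str, str]]:
        """The six blend continua: consecutive (A, B) pairs around the hexagon."""
        n = len(self.order)
        return [(self.order[i], self.order[(i + 1) % n]) for i in range(n)]

    def is_adjacent(self, a: str, b: str) -> bool:
        return b in self.neighbours(a)


DEFAULT_LAYOUT = HexagonLayout()


def dominant_emotion(emotion_a: str, emotion_b: str, ratio_a: int) -> str | None:
    """Majority emotion of an A:B blend, or ``None`` for a 50:50 blend."""
    if ratio_a not in RATIO_LEVELS:
        raise ValidationError(f"ratio_a must be one of {RATIO_LEVELS}, got {ratio_a}")
    if ratio_a == 50:
        return None
    return emotion_a if ratio_a > 50 else emotion_b


def score_trial(trial, layout: HexagonLayout = DEFAULT_LAYOUT) -> str:
    """Score one trial as ``"correct"``, ``"incorrect"`` or ``"unscored"``.

    ``trial`` is any mapping with keys ``emotion_a``, ``emotion_b``,
    ``ratio_a`` and ``response`` (e.g. a ``pandas`` row). The dominant
    emotion is the correct response; 50:50 blends are unscored.
    """
    a, b = trial["emotion_a"], trial["emotion_b"]
    response = trial["response"]
    for label in (a, b, response):
        if label not in layout.emotions:
            raise ValidationError(f"unknown emotion label: {label!r}")
    if not layout.is_adjacent(a, b):
        raise ValidationError(f"continuum ({a}, {b}) is not hexagon-adjacent")
    dom = dominant_emotion(a, b, int(trial["ratio_a"]))
    if dom is None:
        return "unscored"
    return "correct" if response == dom else "incorrect"


def feature_columns(layout: HexagonLayout = DEFAULT_LAYOUT) -> list[str]:
    """The 12 accuracy-feature column keys, emotion-major, high before low."""
    return [f"{emo}_{inten}" for emo in layout.order for inten in INTENSITIES]


def _annotated(trials: pd.DataFrame, layout: HexagonLayout) -> pd.DataFrame:
    """Validate a trial table and annotate dominant emotion / intensity.

    Returns a copy with ``dominant``, ``intensity`` and ``correct`` columns;
    unscored (50:50) rows carry ``dominant`` = NaN.
    """
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValidationError(f"trial table missing columns: {missing}")
    df = trials.copy()
    emoset = set(layout.emotions)
    for col in ("emotion_a", "emotion_b", "response"):
        bad = set(df[col].unique()) - emoset
        if bad:
            raise ValidationError(f"unknown emotion labels in {col}: {sorted(bad)}")
    ratio = df["ratio_a"].to_numpy()
    if not np.isin(ratio, RATIO_LEVELS).all():
        bad_r = sorted(set(ratio) - set(RATIO_LEVELS))
        raise ValidationError(f"ratio_a outside {RATIO_LEVELS}: {bad_r}")
    pairs = set(zip(df["emotion_a"], df["emotion_b"]))
    for a, b in pairs:
        if not layout.is_adjacent(a, b):
            raise ValidationError(f"continuum ({a}, {b}) is not hexagon-adjacent")
    a_dom = ratio > 50
    df["dominant"] = np.where(
        ratio == 50, None, np.where(a_dom, df["emotion_a"], df["emotion_b"])
    )
    share = np.where(a_dom, ratio, 100 - ratio)
    df["intensity"] = np.where(
        ratio == 50, None, np.where(share == 90, "high", "low")
    )
    df["correct"] = df["response"].to_numpy() == df["dominant"].to_numpy()
    return df


def _cell_counts(scored: pd.DataFrame) -> pd.DataFrame:
    g = scored.groupby(["participant_id", "dominant", "intensity"], sort=True)
    out = g["correct"].agg(n="size", n_correct="sum").reset_index()
    return out


def _check_complete(
    counts: pd.DataFrame, participants: np.ndarray, layout: HexagonLayout
) -> None:
    expected = len(participants) * 12
    if len(counts) != expected:
        have = set(
            zip(counts["participant_id"], counts["dominant"], counts["intensity"])
        )
        want = {
            (p, e, i)
            for p in participants
            for e in layout.order
            for i in INTENSITIES
        }
        missing = sorted(want - have)[:10]
        raise MissingCellError(
            f"{expected - len(counts)} participant feature cell(s) have zero "
            f"scored presentations; first missing: {missing}"
        )


def accuracy_features(
    trials: pd.DataFrame, layout: HexagonLayout = DEFAULT_LAYOUT
) -> pd.DataFrame:
    """Per-participant percent-correct for each (emotion, intensity) cell.

    Aggregates over both continua on which an emotion is dominant at a given
    intensity (each emotion is dominant on exactly two). Values are percent
    in [0, 100], unrounded. Raises :class:`MissingCellError` if any
    participant lacks scored presentations for any of the 12 cells.
    """
    if len(trials) == 0:
        raise ValidationError("empty trial table")
    df = _annotated(trials, layout)
    scored = df[df["ratio_a"] != 50]
    counts = _cell_counts(scored)
    pids = trials["participant_id"].unique()
    _check_complete(counts, pids, layout)
    counts = counts.assign(pct=100.0 * counts["n_correct"] / counts["n"])
    counts["column"] = counts["dominant"] + "_" + counts["intensity"]
    wide = counts.pivot(index="participant_id", columns="column", values="pct")
    wide = wide.loc[pids, feature_columns(layout)]
    wide.columns.name = None
    return wide


def confusion_features(
    trials: pd.DataFrame, layout: HexagonLayout = DEFAULT_LAYOUT
) -> pd.DataFrame:
    """Percent of scored presentations of each (target, intensity) labelled
    as each non-target emotion: 60 off-diagonal cells per participant.

    Column keys are ``{target}_{intensity}_as_{response}``. For every
    (target, intensity) the confusion percentages plus the accuracy
    percentage sum to exactly 100.
    """
    if len(trials) == 0:
        raise ValidationError("empty trial table")
    df = _annotated(trials, layout)
    scored = df[df["ratio_a"] != 50]
    counts = _cell_counts(scored)
    pids = trials["participant_id"].unique()
    _check_complete(counts, pids, layout)
    totals = counts.set_index(["participant_id", "dominant", "intensity"])["n"]

    errs = scored[~scored["correct"]]
    g = (
        errs.groupby(["participant_id", "dominant", "intensity", "response"])
        .size()
        .rename("n_err")
        .reset_index()
    )
    keys = list(zip(g["participant_id"], g["dominant"], g["intensity"]))
    g["pct"] = 100.0 * g["n_err"].to_numpy() / totals.loc[keys].to_numpy()
    g["column"] = (
        g["dominant"] + "_" + g["intensity"] + "_as_" + g["response"]
    )
    cols = [
        f"{target}_{inten}_as_{resp}"
        for target in layout.order
        for inten in INTENSITIES
        for resp in layout.order
        if resp != target
    ]
    wide = g.pivot(index="participant_id", columns="column", values="pct")
    wide = wide.reindex(index=pids, columns=cols).fillna(0.0)
    wide.columns.name = None
    return wide


def count_remote_errors(
    trials: pd.DataFrame, layout: HexagonLayout = DEFAULT_LAYOUT
) -> pd.Series:
    """Per-participant count of scored errors whose response is neither the
    dominant emotion nor one of its two hexagon neighbours.

    The non-dominant blend emotion is always a neighbour of the dominant one
    (continua are adjacent pairs), so a remote error is a response from the
    three vertices unrelated to the presented blend.
    """
    if len(trials) == 0:
        raise ValidationError("empty trial table")
    df = _annotated(trials, layout)
    scored = df[df["ratio_a"] != 50]
    near = {
        emo: {emo, *layout.neighbours(emo)} for emo in layout.order
    }
    remote = [
        resp not in near[dom]
        for dom, resp in zip(scored["dominant"], scored["response"])
    ]
    out = (
        scored[np.asarray(remote)]
        .groupby("participant_id")
        .size()
        .reindex(trials["participant_id"].unique(), fill_value=0)
    )
    out.name = "remote_errors"
    return out


def select_confusion_subset(
    confusion: pd.DataFrame, columns: list[str]
) -> pd.DataFrame:
    """User-supplied subset of the full 60-cell confusion feature set."""
    missing = [c for c in columns if c not in confusion.columns]
    if missing:
        raise ValidationError(f"unknown confusion feature columns: {missing}")
    return confusion[columns]
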