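"""Synthetic cohort and trial-response generator.

The study data (a multi-site European youth cohort assessed with the
Emotion Hexagon task) are restricted, so this module generates cohorts
with the same statistical shape: three groups (CD/HCU, CD/LCU, TD) with
realistic sizes, covariates whose group means mirror the published
demographics, ICU callous-unemotional totals compatible with the 39/29
tertile cut-offs, and trial-level forced-choice responses with a small
group effect on accuracy, a high > low intensity advantage, and a
group x intensity interaction.

Responses follow a simple psychometric model: on scored blends the
participant answers the dominant emotion with probability
``logit^-1(logit(p_correct[group, emotion, intensity]) + covariate terms)``;
otherwise an error label is drawn with most of its mass on the dominant
emotion's two hexagon neighbours. 50:50 blends split their mass between
the two blended labels plus a little uniform noise; they carry no correct
answer and are never scored downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

from .errors import SpecificationError, ValidationError
from .hexagon import DEFAULT_LAYOUT, HexagonLayout, RATIO_LEVELS

GROUPS = ("HCU", "LCU", "TD")

PARTICIPANT_COLUMNS = [
    "participant_id",
    "group",
    "sex",
    "age",
    "iq",
    "ses",
    "site",
    "icu_total",
]

ICU_MIN, ICU_MAX = 0, 72
HCU_CUTOFF, LCU_CUTOFF = 39, 29

# Baseline per-emotion recognition probability at high intensity, ordered
# roughly happiness > sadness ~ surprise > anger ~ disgust ~ fear, with a
# uniform drop at low intensity.
_BASE_HIGH = {
    "happiness": 0.95,
    "sadness": 0.88,
    "surprise": 0.87,
    "anger": 0.82,
    "disgust": 0.80,
    "fear": 0.78,
}
_INTENSITY_DROP = 0.06

# Small group deficits (probability scale). Deficits are larger at high
# intensity, reproducing the published group x intensity interaction in
# which the TD group benefits most from increased expression intensity.
_GROUP_OFFSET = {
    "TD": {"high": 0.0, "low": 0.0},
    "LCU": {"high": -0.025, "low": -0.012},
    "HCU": {"high": -0.045, "low": -0.022},
}


def default_p_correct(groups: tuple[str, ...] = GROUPS) -> dict:
    """Default (group, emotion, intensity) -> recognition probability map."""
    table = {}
    for g in groups:
        for emo, base in _BASE_HIGH.items():
            for inten in ("high", "low"):
                p = base - (0.0 if inten == "high" else _INTENSITY_DROP)
                p += _GROUP_OFFSET.get(g, _GROUP_OFFSET["TD"])[inten]
                table[(g, emo, inten)] = p
    return table


@dataclass(frozen=True)
class CovariateParams:
    """Per-group covariate distributions (means mirror the published Table 1
    demographics; SDs back-computed from the reported confidence intervals)."""

    age: dict = field(
        default_factory=lambda: {
            "HCU": (14.14, 2.2), "LCU": (14.30, 2.4), "TD": (13.95, 2.5)
        }
    )
    age_bounds: tuple[float, float] = (9.0, 18.0)
    iq: dict = field(
        default_factory=lambda: {
            "HCU": (95.3, 12.0), "LCU": (94.9, 13.0), "TD": (103.7, 13.4)
        }
    )
    iq_bounds: tuple[float, float] = (70.0, 145.0)
    ses: dict = field(
        default_factory=lambda: {
            "HCU": (-0.38, 1.0), "LCU": (-0.29, 1.0), "TD": (0.33, 0.9)
        }
    )
    sex_female: dict = field(
        default_factory=lambda: {"HCU": 0.617, "LCU": 0.565, "TD": 0.666}
    )
    sites: tuple[str, ...] = tuple(f"site{i}" for i in range(1, 8))
    site_probs: tuple[float, ...] | None = None  # None -> uniform


@dataclass(frozen=True)
class CohortSpec:
    """Full specification of a synthetic cohort.

    ``covariate_slopes`` act additively on the logit of the per-trial
    correct-response probability, per unit of the mean-centred covariate
    (keys: ``age``, ``iq``, ``ses``, ``sex`` with female = 1).
    """

    group_sizes: dict = field(
        default_factory=lambda: {"HCU": 248, "LCU": 230, "TD": 785}
    )
    p_correct: dict = field(default_factory=default_p_correct)
    confusion_bias: float = 0.6
    covariate_params: CovariateParams = field(default_factory=CovariateParams)
    covariate_slopes: dict = field(default_factory=dict)
    icu_params: dict = field(
        default_factory=lambda: {
            "HCU": (46.0, 6.0, HCU_CUTOFF, ICU_MAX),
            "LCU": (22.0, 5.0, ICU_MIN, LCU_CUTOFF),
            "TD": (17.0, 8.0, ICU_MIN, ICU_MAX),
        }
    )
    reps_per_blend: int = 5
    fifty_fifty_noise: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        for g, n in self.group_sizes.items():
            if g not in GROUPS:
                raise SpecificationError(f"unknown group label {g!r}")
            if not isinstance(n, (int, np.integer)) or n < 0:
                raise SpecificationError(f"group size for {g} must be >= 0, got {n}")
        if self.reps_per_blend < 1:
            raise SpecificationError("reps_per_blend must be >= 1")
        if not 0.0 <= self.confusion_bias <= 1.0:
            raise SpecificationError("confusion_bias must lie in [0, 1]")
        if not 0.0 <= self.fifty_fifty_noise <= 1.0:
            raise SpecificationError("fifty_fifty_noise must lie in [0, 1]")
        groups = [g for g, n in self.group_sizes.items() if n > 0]
        for g in groups:
            for emo in _BASE_HIGH:
                for inten in ("high", "low"):
                    key = (g, emo, inten)
                    if key not in self.p_correct:
                        raise SpecificationError(f"p_correct missing entry {key}")
        for key, p in self.p_correct.items():
            if not 0.0 <= p <= 1.0:
                raise SpecificationError(f"p_correct{key} = {p} outside [0, 1]")

    def with_seed(self, seed: int) -> "CohortSpec":
        return replace(self, seed=seed)


def assign_cu_group(icu_total: int, has_cd: bool) -> str:
    """Group membership from the ICU total and a conduct-disorder diagnosis.

    CD youths with an ICU total of 39 or above form the high-CU subtype
    (HCU), 29 or below the low-CU subtype (LCU); mid-range CD youths are
    excluded. Non-CD youths are typically developing (TD) regardless of ICU.
    """
    if not ICU_MIN <= icu_total <= ICU_MAX:
        raise ValidationError(
            f"icu_total must lie in [{ICU_MIN}, {ICU_MAX}], got {icu_total}"
        )
    if not has_cd:
        return "TD"
    if icu_total >= HCU_CUTOFF:
        return "HCU"
    if icu_total <= LCU_CUTOFF:
        return "LCU"
    return "excluded"


def _truncnorm(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_participants(spec: CohortSpec) -> pd.DataFrame:
    """Draw a participant table with exactly the requested group sizes.

    Deterministic given ``spec.seed``; group order (HCU, LCU, TD) and the
    participant-id sequence are fixed.
    """
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(2)[0])
    cov = spec.covariate_params
    site_probs = cov.site_probs
    if site_probs is None:
        site_probs = tuple(1.0 / len(cov.sites) for _ in cov.sites)
    frames = []
    offset = 0
    for g in GROUPS:
        n = int(spec.group_sizes.get(g, 0))
        if n == 0:
            continue
        age = _truncnorm(rng, *cov.age[g], *cov.age_bounds, n)
        iq = _truncnorm(rng, *cov.iq[g], *cov.iq_bounds, n)
        ses = rng.normal(cov.ses[g][0], cov.ses[g][1], n)
        sex = np.where(rng.random(n) < cov.sex_female[g], "female", "male")
        site = rng.choice(cov.sites, size=n, p=site_probs)
        m, s, lo, hi = spec.icu_params[g]
        icu = np.clip(np.rint(_truncnorm(rng, m, s, lo, hi, n)), lo, hi).astype(int)
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": [f"P{offset + i + 1:04d}" for i in range(n)],
                    "group": g,
                    "sex": sex,
                    "age": age,
                    "iq": iq,
                    "ses": ses,
                    "site": site,
                    "icu_total": icu,
                }
            )
        )
        offset += n
    if not frames:
        return pd.DataFrame(columns=PARTICIPANT_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def _logit_adjustment(participants: pd.DataFrame, slopes: dict) -> np.ndarray:
    """Per-participant additive logit term from mean-centred covariates."""
    adj = np.zeros(len(participants))
    if not slopes:
        return adj
    values = {
        "age": participants["age"].to_numpy(float),
        "iq": participants["iq"].to_numpy(float),
        "ses": participants["ses"].to_numpy(float),
        "sex": (participants["sex"] == "female").to_numpy(float),
    }
    for name, slope in slopes.items():
        if name not in values:
            raise SpecificationError(f"unknown covariate slope {name!r}")
        x = values[name]
        adj += slope * (x - x.mean())
    return adj


def generate_trials(
    participants: pd.DataFrame,
    spec: CohortSpec,
    layout: HexagonLayout = DEFAULT_LAYOUT,
) -> pd.DataFrame:
    """Simulate forced-choice responses for every participant.

    Each participant contributes ``reps_per_blend`` presentations of each of
    the 6 continua x 5 ratio levels (trial count identity:
    ``n_participants * 30 * reps_per_blend``). Deterministic given the spec
    seed and participant ordering.
    """
    spec.validate()
    for g in sorted(set(participants["group"])):
        for emo in _BASE_HIGH:
            for inten in ("high", "low"):
                if (g, emo, inten) not in spec.p_correct:
                    raise SpecificationError(
                        f"p_correct missing entry {(g, emo, inten)}"
                    )
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(2)[1])
    n_p = len(participants)
    continua = layout.continua()
    reps = spec.reps_per_blend
    block = len(continua) * len(RATIO_LEVELS) * reps  # trials per participant

    pid = np.repeat(participants["participant_id"].to_numpy(), block)
    group = np.repeat(participants["group"].to_numpy(), block)
    adj = np.repeat(_logit_adjustment(participants, spec.covariate_slopes), block)

    em_a = np.tile(
        np.repeat([a for a, _ in continua], len(RATIO_LEVELS) * reps), n_p
    )
    em_b = np.tile(
        np.repeat([b for _, b in continua], len(RATIO_LEVELS) * reps), n_p
    )
    ratio = np.tile(np.tile(np.repeat(RATIO_LEVELS, reps), len(continua)), n_p)

    scored = ratio != 50
    a_dom = ratio > 50
    dom = np.where(a_dom, em_a, em_b)
    other = np.where(a_dom, em_b, em_a)
    share = np.where(a_dom, ratio, 100 - ratio)
    inten = np.where(share == 90, "high", "low")

    p_base = np.empty(len(pid))
    p_base[~scored] = np.nan
    keys = pd.MultiIndex.from_arrays([group[scored], dom[scored], inten[scored]])
    lut = pd.Series(spec.p_correct)
    p_base[scored] = lut.loc[keys].to_numpy()

    with np.errstate(divide="ignore"):
        p_eff = expit(logit(p_base) + adj)
    # exact endpoints survive any finite covariate adjustment
    p_eff = np.where(p_base == 0.0, 0.0, np.where(p_base == 1.0, 1.0, p_eff))

    response = np.empty(len(pid), dtype=object)
    u = rng.random(len(pid))

    correct = scored & (u < p_eff)
    response[correct] = dom[correct]

    # error responses: confusion_bias split equally between the dominant
    # emotion's two neighbours, remainder uniform over the other three labels
    wrong = scored & ~correct
    for emo in layout.order:
        mask = wrong & (dom == emo)
        if not mask.any():
            continue
        n1, n2 = layout.neighbours(emo)
        rest = [e for e in layout.order if e not in (emo, n1, n2)]
        labels = np.array([n1, n2, *rest], dtype=object)
        probs = np.array(
            [spec.confusion_bias / 2] * 2 + [(1 - spec.confusion_bias) / 3] * 3
        )
        response[mask] = rng.choice(labels, size=int(mask.sum()), p=probs)

    # 50:50 blends: equal mass on the two blended labels, small uniform noise
    fifty = ~scored
    if fifty.any():
        noise = spec.fifty_fifty_noise
        v = rng.random(int(fifty.sum()))
        fa, fb = em_a[fifty], em_b[fifty]
        resp50 = np.where(v < (1 - noise) / 2, fa, np.where(v < 1 - noise, fb, None))
        need = resp50 == None  # noqa: E711 - object-array comparison
        if need.any():
            resp50[need] = rng.choice(
                np.array(layout.order, dtype=object), size=int(need.sum())
            )
        response[fifty] = resp50

    return pd.DataFrame(
        {
            "participant_id": pid,
            "emotion_a": em_a,
            "emotion_b": em_b,
            "ratio_a": ratio,
            "response": response,
        }
    )
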