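import numpy as np
import pandas as pd
import pytest

from emohex import synthetic
from emohex.hexagon import DEFAULT_LAYOUT, RATIO_LEVELS


def null_p_correct():
    """Group-blind recognition probabilities (every group at the TD level)."""
    p = synthetic.default_p_correct()
    return {(g, e, i): p[("TD", e, i)] for (g, e, i) in p}


@pytest.fixture(scope="session")
def small_cohort():
    """A 40-participant cohort with trials, shared across read-only tests."""
    spec = synthetic.CohortSpec(
        group_sizes={"HCU": 10, "LCU": 10, "TD": 20}, reps_per_blend=5, seed=42
    )
    participants = synthetic.generate_participants(spec)
    trials = synthetic.generate_trials(participants, spec)
    return spec, participants, trials


def perfect_trial_grid(participant_ids, reps=1, layout=DEFAULT_LAYOUT):
    """A full 6-continua x 5-ratio trial grid where every scored response is
    the dominant emotion (50:50 responses get the first blend emotion)."""
    rows = []
    for pid in participant_ids:
        for a, b in layout.continua():
            for ratio in RATIO_LEVELS:
                for _ in range(reps):
                    if ratio == 50:
                        resp = a
                    else:
                        resp = a if ratio > 50 else b
                    rows.append((pid, a, b, ratio, resp))
    return pd.DataFrame(
        rows,
        columns=["participant_id", "emotion_a", "emotion_b", "ratio_a", "response"],
    )
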