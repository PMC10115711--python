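"""Score trials into per-participant features.

Derives the 12 accuracy features (percent correct for each emotion at its
high/70%-low intensity), the full 60-cell confusion set, and remote-error
counts (errors landing on a non-adjacent hexagon vertex). Writes
features.csv, confusion_features.csv and remote_errors.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from emohex.hexagon import (
    accuracy_features,
    confusion_features,
    count_remote_errors,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results/analysis"))
    args = ap.parse_args()
    trials = pd.read_csv(args.results / "trials.csv")
    feats = accuracy_features(trials)
    feats.to_csv(args.results / "features.csv")
    conf = confusion_features(trials)
    conf.to_csv(args.results / "confusion_features.csv")
    remote = count_remote_errors(trials)
    remote.to_csv(args.results / "remote_errors.csv")
    print(
        f"scored {len(trials)} trials into {feats.shape[0]} x "
        f"{feats.shape[1]} accuracy features "
        f"(grand mean {feats.to_numpy().mean():.1f}% correct), "
        f"{conf.shape[1]} confusion cells, remote-error mean "
        f"{remote.mean():.2f}/participant"
    )


if __name__ == "__main__":
    main()
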