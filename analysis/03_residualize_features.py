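"""Regress covariates out of the accuracy features.

Each of the 12 features is OLS-residualized against age, total IQ, SES,
sex and site (whole-sample fit, the study's adjust-then-classify order)
and standardized; the classifier never sees raw accuracies. Writes
residual_features.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from emohex.residualize import build_design, residualize_features


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results/analysis"))
    ap.add_argument("--mode", choices=["pooled", "fold_safe"], default="pooled")
    args = ap.parse_args()
    feats = pd.read_csv(args.results / "features.csv", index_col=0)
    participants = pd.read_csv(args.results / "participants.csv")
    aligned = (
        participants.set_index("participant_id").loc[feats.index].reset_index()
    )
    design = build_design(aligned)
    res = residualize_features(feats, design, mode=args.mode)
    res.to_csv(args.results / "residual_features.csv")
    print(
        f"residualized {res.shape[1]} features against design columns "
        f"{list(design.columns)} (mode={args.mode})"
    )


if __name__ == "__main__":
    main()
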