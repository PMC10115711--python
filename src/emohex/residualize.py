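"""Covariate residualization of the feature matrix.

Covariates cannot be entered into a prototype classifier directly, so their
shared variance is removed beforehand: each feature column is regressed by
OLS on age, total IQ, SES (mean-centred), sex, and site of data collection,
and the residuals are standardized to unit SD. Two modes are provided:

``pooled``
    Coefficients and the residual SD are estimated on the whole sample
    before any train/test splitting (the default, matching a whole-sample
    adjust-then-classify order). Output columns have mean 0, SD 1.

``fold_safe``
    Coefficients and scale come from a training index set only and are
    applied unchanged to held-out rows, avoiding test-set leakage at the
    cost of held-out columns no longer being exactly standardized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    DegenerateFeatureError,
    SingularDesignError,
    ValidationError,
)

CONTINUOUS_COVARIATES = ("age", "iq", "ses")


@dataclass(frozen=True)
class CovariateDesign:
    """An OLS design matrix aligned row-for-row with a feature matrix."""

    matrix: np.ndarray
    columns: tuple[str, ...]
    index: pd.Index

    def __post_init__(self) -> None:
        if np.linalg.matrix_rank(self.matrix) < self.matrix.shape[1]:
            raise SingularDesignError(
                f"design matrix is rank deficient (columns: {list(self.columns)})"
            )

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.index, columns=self.columns)


def build_design(participants: pd.DataFrame) -> CovariateDesign:
    """Intercept + centred age/IQ/SES + sex (female=1) + site indicators.

    Site indicators drop the alphabetically first level as reference.
    Missing covariate values are rejected (imputation is out of scope).
    """
    required = [*CONTINUOUS_COVARIATES, "sex", "site"]
    missing = [c for c in required if c not in participants.columns]
    if missing:
        raise ValidationError(f"participant table missing covariates: {missing}")
    sub = participants[required]
    if sub.isna().any().any():
        bad = sub.columns[sub.isna().any()].tolist()
        raise ValidationError(f"missing covariate values in columns: {bad}")
    cols: list[str] = ["intercept"]
    parts = [np.ones(len(participants))]
    for c in CONTINUOUS_COVARIATES:
        x = participants[c].to_numpy(float)
        parts.append(x - x.mean())
        cols.append(c)
    sexes = set(participants["sex"])
    if not sexes <= {"male", "female"}:
        raise ValidationError(f"unknown sex labels: {sorted(sexes - {'male', 'female'})}")
    parts.append((participants["sex"] == "female").to_numpy(float))
    cols.append("sex_female")
    levels = sorted(set(participants["site"]))
    for lev in levels[1:]:
        parts.append((participants["site"] == lev).to_numpy(float))
        cols.append(f"site_{lev}")
    index = (
        participants["participant_id"]
        if "participant_id" in participants.columns
        else participants.index
    )
    return CovariateDesign(
        matrix=np.column_stack(parts),
        columns=tuple(cols),
        index=pd.Index(index),
    )


def residualize_features(
    features: pd.DataFrame,
    design: CovariateDesign,
    mode: str = "pooled",
    train_index: np.ndarray | None = None,
) -> pd.DataFrame:
    """OLS-residualize and standardize every feature column.

    In ``pooled`` mode each output column has mean 0 and SD 1 (n-1
    denominator) and is orthogonal to every design column. In ``fold_safe``
    mode ``train_index`` gives the integer row positions used to estimate
    coefficients and residual scale.
    """
    if mode not in ("pooled", "fold_safe"):
        raise ValidationError(f"unknown residualization mode {mode!r}")
    if len(features) != design.matrix.shape[0]:
        raise ValidationError(
            f"feature rows ({len(features)}) do not align with design rows "
            f"({design.matrix.shape[0]})"
        )
    if features.isna().any().any():
        raise ValidationError("feature matrix contains missing cells")
    D = design.matrix
    F = features.to_numpy(float)
    if mode == "pooled":
        fit_rows = np.arange(len(F))
    else:
        if train_index is None:
            raise ValidationError("fold_safe mode requires train_index")
        fit_rows = np.asarray(train_index, dtype=int)
        if len(fit_rows) <= D.shape[1]:
            raise ValidationError(
                "training set smaller than the number of design columns"
            )
    Dt = D[fit_rows]
    if np.linalg.matrix_rank(Dt) < Dt.shape[1]:
        raise SingularDesignError("design matrix rank deficient on training rows")
    beta, *_ = np.linalg.lstsq(Dt, F[fit_rows], rcond=None)
    resid = F - D @ beta
    sd = resid[fit_rows].std(axis=0, ddof=1)
    tiny = sd < 1e-8
    if tiny.any():
        bad = features.columns[tiny].tolist()
        raise DegenerateFeatureError(
            f"feature column(s) fully explained by covariates: {bad}"
        )
    out = pd.DataFrame(
        resid / sd, index=features.index, columns=features.columns
    )
    return out
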