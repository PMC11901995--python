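"""Ancestry adjustment of raw PRS by principal-component residualization.

Within each ancestry group the raw score is regressed on the leading
genotype principal components (PC1–PC4 by default); the residual

    adjusted_i = raw_i - (intercept + sum_k coef_k * PC_ki)

is then standardized to mean 0 / SD 1 within the group.  A pooled,
non-ancestry-aware variant (single regression over all samples, single
global standardization) is provided for contrast experiments: it leaves
residual between-group differences whenever per-group score/PC structure
differs.

Standardization uses the sample standard deviation (ddof=1).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MIN_GROUP_SIZE = 10


@dataclass
class PcAdjustmentModel:
    """OLS fit of a raw score on an intercept plus principal components."""

    ancestry: str
    intercept: float
    coefficients: np.ndarray
    n_fit: int

    def predict(self, pcs: pd.DataFrame) -> pd.Series:
        x = pcs.iloc[:, : len(self.coefficients)].to_numpy(dtype=np.float64)
        return pd.Series(
            self.intercept + x @ self.coefficients, index=pcs.index
        )


@dataclass
class AdjustedScoreVector:
    """Per-sample ancestry-adjusted standardized scores for one panel."""

    panel_name: str
    scores: pd.Series
    ancestry: pd.Series
    models: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.scores = self.scores.rename(self.panel_name)


def fit_pc_model(
    raw: pd.Series,
    pcs: pd.DataFrame,
    subset: pd.Index | np.ndarray | None = None,
    ancestry: str = "ALL",
) -> PcAdjustmentModel:
    """Ordinary least squares of raw score on intercept + PCs in a subset."""
    if subset is None:
        subset = raw.index
    y = raw.loc[subset].to_numpy(dtype=np.float64)
    x = pcs.loc[subset].to_numpy(dtype=np.float64)
    n, p = x.shape
    if n < MIN_GROUP_SIZE:
        raise ValueError(f"subset has {n} < {MIN_GROUP_SIZE} individuals")
    design = np.column_stack([np.ones(n), x])
    rank = np.linalg.matrix_rank(design)
    if rank < p + 1:
        bad = _collinear_columns(x, pcs.columns)
        raise ValueError(f"rank-deficient PC design; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return PcAdjustmentModel(
        ancestry=ancestry,
        intercept=float(beta[0]),
        coefficients=beta[1:],
        n_fit=n,
    )


def _collinear_columns(x: np.ndarray, names) -> list[str]:
    bad = [str(n) for n, col in zip(names, x.T) if col.std() == 0]
    if not bad:
        corr = np.corrcoef(x, rowvar=False)
        iu = np.triu_indices_from(corr, k=1)
        for i, j in zip(*iu):
            if abs(corr[i, j]) > 1 - 1e-10:
                bad.extend([str(names[i]), str(names[j])])
    return sorted(set(bad))


def apply_adjustment(
    raw: pd.Series, pcs: pd.DataFrame, model: PcAdjustmentModel
) -> pd.Series:
    """Residual score: raw minus the model-predicted PC component.

    Samples missing from the PC table come back as NaN.
    """
    common = raw.index.intersection(pcs.index)
    pred = model.predict(pcs.loc[common])
    resid = pd.Series(np.nan, index=raw.index, name=raw.name)
    resid.loc[common] = raw.loc[common] - pred
    n_missing = raw.index.difference(pcs.index).size
    if n_missing:
        warnings.warn(
            f"{n_missing} sample(s) lack PCs; adjusted score set missing",
            stacklevel=2,
        )
    return resid


def normalize(residuals: pd.Series, subset=None) -> pd.Series:
    """Standardize to mean 0 / SD 1 (sample SD) within a subset.

    Parameters estimated on ``subset`` (default: all non-missing entries)
    are applied to every entry of the series.
    """
    if subset is None:
        subset = residuals.dropna().index
    vals = residuals.loc[subset].to_numpy(dtype=np.float64)
    sd = vals.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("zero variance in residual scores; degenerate panel")
    return (residuals - vals.mean()) / sd


def adjust_by_ancestry(
    raw: pd.Series,
    pcs: pd.DataFrame,
    labels: pd.Series,
    mode: str = "per-ancestry",
    min_group_size: int = MIN_GROUP_SIZE,
    panel_name: str | None = None,
) -> AdjustedScoreVector:
    """Fit, residualize and standardize, separately per ancestry group.

    ``mode='per-ancestry'`` (the default) runs the full per-group
    composition.  ``mode='pooled'`` fits one regression over all samples
    and applies one global standardization — the non-ancestry-aware
    contrast.  Groups smaller than ``min_group_size`` cannot support a
    stable per-group fit; their samples receive the pooled model's
    adjustment and global standardization, with a warning.
    """
    if mode not in ("per-ancestry", "pooled"):
        raise ValueError("mode must be 'per-ancestry' or 'pooled'")
    labels = labels.reindex(raw.index)
    if labels.isna().any():
        raise ValueError("every sample must carry an ancestry label")
    name = panel_name or (raw.name if raw.name is not None else "score")

    if mode == "pooled":
        model = fit_pc_model(raw, pcs, ancestry="POOLED")
        adjusted = normalize(apply_adjustment(raw, pcs, model))
        return AdjustedScoreVector(
            panel_name=str(name),
            scores=adjusted,
            ancestry=labels,
            models={"POOLED": model},
        )

    adjusted = pd.Series(np.nan, index=raw.index, name=name)
    models: dict[str, PcAdjustmentModel] = {}
    small_groups = []
    for group in pd.unique(labels):
        idx = labels.index[labels == group]
        if len(idx) < min_group_size:
            small_groups.append(group)
            continue
        model = fit_pc_model(raw, pcs, subset=idx, ancestry=str(group))
        resid = apply_adjustment(raw.loc[idx], pcs, model)
        adjusted.loc[idx] = normalize(resid)
        models[str(group)] = model
    if small_groups:
        warnings.warn(
            f"groups {small_groups} below {min_group_size} samples; "
            "falling back to the pooled adjustment for them",
            stacklevel=2,
        )
        pooled = fit_pc_model(raw, pcs, ancestry="POOLED")
        pooled_adj = normalize(apply_adjustment(raw, pcs, pooled))
        for group in small_groups:
            idx = labels.index[labels == group]
            adjusted.loc[idx] = pooled_adj.loc[idx]
        models["POOLED"] = pooled
    return AdjustedScoreVector(
        panel_name=str(name), scores=adjusted, ancestry=labels, models=models
    )
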