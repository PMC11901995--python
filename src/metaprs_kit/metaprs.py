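"""metaPRS composition: cross-validated panel betas and weighted sums.

Within one ancestry group, per-panel log-odds weights ("panel betas") are
estimated by k-fold cross-validation: on each training fold a joint
logistic regression of the outcome on all standardized panel scores plus
age, sex and PC1–PC4 is fitted; the metaPRS of a held-out sample is the
beta-weighted sum of its panel scores using betas from folds that did not
contain it.  Final betas are the arithmetic mean across folds, with
fold-level values retained.

Two standard compositions are supported: ``risk_factors`` (lipids, Lp(a),
blood pressure, type 2 diabetes, atrial fibrillation panels) and
``risk_factors_plus_cad`` (the same panels plus direct CAD panels).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

RISK_FACTOR_DEFINITION = ("LDL", "HDL", "TG", "LPA", "HT", "T2DM", "AF")

STANDARD_DEFINITIONS = {
    "risk_factors": RISK_FACTOR_DEFINITION,
    "risk_factors_plus_cad": RISK_FACTOR_DEFINITION + ("CAD",),
}


@dataclass
class PanelBetaSet:
    """Cross-validated per-panel logistic weights for one ancestry group."""

    ancestry: str
    betas: pd.Series               # mean across folds, per panel
    standard_errors: pd.Series     # mean across folds
    fold_betas: pd.DataFrame       # folds x panels
    folds: pd.Series               # fold id per sample
    covariate_coefficients: pd.DataFrame  # folds x covariates

    @property
    def panels(self) -> list[str]:
        return list(self.betas.index)


def make_folds(samples: pd.Index | np.ndarray, k: int = 5, seed: int = 0) -> pd.Series:
    """Deterministic k-fold partition; fold sizes differ by at most one."""
    if k < 2:
        raise ValueError("k must be >= 2")
    samples = pd.Index(samples)
    n = len(samples)
    if n < k:
        raise ValueError(f"need at least k={k} samples, got {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    fold = np.empty(n, dtype=int)
    fold[order] = np.arange(n) % k
    return pd.Series(fold, index=samples, name="fold")


def _logit_fit(y: np.ndarray, x: np.ndarray, colnames, context: str):
    model = sm.Logit(y, x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(disp=0, maxiter=200)
        except Exception as exc:  # separation, singular design
            raise RuntimeError(f"logistic fit failed for {context}: {exc}") from exc
    if not res.mle_retvals.get("converged", True):
        raise RuntimeError(f"logistic fit did not converge for {context}")
    return res


def estimate_panel_betas(
    panel_scores: pd.DataFrame,
    outcome: pd.Series,
    covariates: pd.DataFrame,
    folds: pd.Series,
    ancestry: str = "ALL",
) -> PanelBetaSet:
    """Joint logistic regression of outcome on panels + covariates per fold.

    ``panel_scores`` holds one standardized column per panel; samples with
    any missing value among scores, outcome or covariates are excluded
    before fitting.  Betas are averaged over folds.
    """
    idx = folds.index
    data = pd.concat(
        [panel_scores.reindex(idx), covariates.reindex(idx), outcome.reindex(idx)],
        axis=1,
    )
    ok = data.notna().all(axis=1)
    if not ok.all():
        logger.info("excluding %d sample(s) with missing values", int((~ok).sum()))
    idx = idx[ok]
    panels = list(panel_scores.columns)
    covs = list(covariates.columns)

    fold_betas, fold_ses, cov_coefs = [], [], []
    fold_ids = sorted(folds.unique())
    for f in fold_ids:
        train = idx[folds.loc[idx] != f]
        y = outcome.loc[train].to_numpy(dtype=float)
        if y.sum() < 10:
            warnings.warn(
                f"{ancestry} fold {f}: fewer than 10 cases in training portion",
                stacklevel=2,
            )
        x = np.column_stack(
            [
                np.ones(len(train)),
                panel_scores.loc[train, panels].to_numpy(dtype=float),
                covariates.loc[train, covs].to_numpy(dtype=float),
            ]
        )
        res = _logit_fit(y, x, panels, f"{ancestry} fold {f}")
        fold_betas.append(res.params[1 : 1 + len(panels)])
        fold_ses.append(res.bse[1 : 1 + len(panels)])
        cov_coefs.append(res.params[1 + len(panels) :])

    fb = pd.DataFrame(fold_betas, index=fold_ids, columns=panels)
    fs = pd.DataFrame(fold_ses, index=fold_ids, columns=panels)
    cc = pd.DataFrame(cov_coefs, index=fold_ids, columns=covs)
    return PanelBetaSet(
        ancestry=ancestry,
        betas=fb.mean(axis=0),
        standard_errors=fs.mean(axis=0),
        fold_betas=fb,
        folds=folds,
        covariate_coefficients=cc,
    )


def compose_metaprs(
    panel_scores: pd.DataFrame,
    beta_set: PanelBetaSet,
    mode: str = "cv",
    name: str = "metaPRS",
) -> pd.Series:
    """Beta-weighted sum of panel scores, standardized to mean 0 / SD 1.

    ``mode='cv'`` gives each sample the betas estimated on folds that did
    not contain it (held-out composition, the evaluation default);
    ``mode='mean'`` applies the fold-averaged betas to everyone.  Samples
    with any missing panel score come back NaN.
    """
    if mode not in ("cv", "mean"):
        raise ValueError("mode must be 'cv' or 'mean'")
    panels = beta_set.panels
    missing = [p for p in panels if p not in panel_scores.columns]
    if missing:
        raise ValueError(f"panel scores missing columns {missing}")
    x = panel_scores[panels]
    if mode == "mean":
        raw = x @ beta_set.betas
    else:
        raw = pd.Series(np.nan, index=x.index)
        folds = beta_set.folds.reindex(x.index)
        for f in beta_set.fold_betas.index:
            mask = folds == f
            raw[mask] = x.loc[mask] @ beta_set.fold_betas.loc[f]
        unassigned = folds.isna()
        if unassigned.any():
            raw[unassigned] = x.loc[unassigned] @ beta_set.betas
    sd = raw.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("degenerate metaPRS: zero variance")
    return ((raw - raw.mean()) / sd).rename(name)


def fit_metaprs_by_ancestry(
    panel_scores: pd.DataFrame,
    outcome: pd.Series,
    covariates: pd.DataFrame,
    labels: pd.Series,
    definition: tuple[str, ...] | str = "risk_factors",
    k: int = 5,
    seed: int = 0,
    mode: str = "cv",
    name: str | None = None,
) -> tuple[pd.Series, dict[str, PanelBetaSet]]:
    """Estimate betas and compose the metaPRS independently per ancestry.

    Returns the combined per-ancestry-standardized metaPRS series over
    all samples and the per-group beta sets.
    """
    if isinstance(definition, str):
        panels = STANDARD_DEFINITIONS[definition]
        name = name or definition
    else:
        panels = tuple(definition)
        name = name or "metaPRS"
    labels = labels.reindex(panel_scores.index)
    meta = pd.Series(np.nan, index=panel_scores.index, name=name)
    beta_sets: dict[str, PanelBetaSet] = {}
    for group in pd.unique(labels.dropna()):
        idx = labels.index[labels == group]
        folds = make_folds(idx, k=k, seed=seed)
        bs = estimate_panel_betas(
            panel_scores.loc[idx, list(panels)],
            outcome.loc[idx],
            covariates.loc[idx],
            folds,
            ancestry=str(group),
        )
        meta.loc[idx] = compose_metaprs(
            panel_scores.loc[idx, list(panels)], bs, mode=mode, name=name
        )
        beta_sets[str(group)] = bs
    return meta, beta_sets
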