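"""Association and risk-stratification statistics.

* OR per SD: odds ratio for a one-SD increase of a standardized score,
  from logistic regression of the outcome on score + age + sex + PC1–PC4,
  with a Wald 95% CI on the log-odds scale.
* AUC: rank-based probability that a random case outranks a random
  control, with a stratified-bootstrap percentile CI.
* High-risk fraction: the share of the population whose model-implied
  odds are at least r-fold those of an individual at the score mean.  For
  a standard-normal score with odds ratio ``OR`` per SD, the odds ratio of
  an individual at score z relative to the mean is ``OR**z``, so the share
  with at least r-fold odds is ``1 - Phi(ln r / ln OR)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.metrics import roc_auc_score

from .metaprs import _logit_fit


@dataclass
class AssociationResult:
    """OR-per-SD and AUC summary for one score/outcome/ancestry cell."""

    name: str
    ancestry: str
    n_cases: int
    n_controls: int
    or_per_sd: float
    or_ci: tuple[float, float]
    auc: float | None = None
    auc_ci: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.or_per_sd <= 0:
            raise ValueError("odds ratio must be positive")
        if self.or_ci[0] > self.or_ci[1]:
            raise ValueError("CI bounds out of order")


@dataclass
class HighRiskFraction:
    """Share of the population with >= r-fold odds versus the mean."""

    or_per_sd: float
    risk_ratio: float
    fraction: float

    @property
    def percent(self) -> float:
        return 100.0 * self.fraction


def _drop_missing(*series: pd.Series | pd.DataFrame) -> list:
    joined = pd.concat(series, axis=1)
    ok = joined.notna().all(axis=1)
    return [s.loc[ok[ok].index] for s in series]


def or_per_sd(
    score: pd.Series,
    outcome: pd.Series,
    covariates: pd.DataFrame | None = None,
    name: str | None = None,
    ancestry: str = "ALL",
) -> AssociationResult:
    """Fit outcome ~ score + covariates; report exp(beta_score) with CI."""
    pieces = [score, outcome] + ([covariates] if covariates is not None else [])
    cleaned = _drop_missing(*pieces)
    score, outcome = cleaned[0], cleaned[1]
    covariates = cleaned[2] if covariates is not None else None
    y = outcome.to_numpy(dtype=float)
    n_cases = int(y.sum())
    if n_cases < 10:
        warnings.warn(f"only {n_cases} cases available for {name}", stacklevel=2)
    cols = [np.ones(len(y)), score.to_numpy(dtype=float)]
    if covariates is not None:
        cols.append(covariates.to_numpy(dtype=float))
    x = np.column_stack(cols)
    res = _logit_fit(y, x, None, name or str(score.name))
    beta, se = res.params[1], res.bse[1]
    return AssociationResult(
        name=name or str(score.name),
        ancestry=ancestry,
        n_cases=n_cases,
        n_controls=len(y) - n_cases,
        or_per_sd=float(np.exp(beta)),
        or_ci=(float(np.exp(beta - 1.96 * se)), float(np.exp(beta + 1.96 * se))),
    )


def auc(
    score: pd.Series,
    outcome: pd.Series,
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, tuple[float, float]]:
    """Rank-based AUC with a stratified-bootstrap percentile 95% CI.

    Ties count one half; cases and controls are resampled separately so
    every bootstrap replicate keeps both classes.
    """
    score, outcome = _drop_missing(score, outcome)
    y = outcome.to_numpy(dtype=int)
    s = score.to_numpy(dtype=float)
    if y.min() == y.max():
        raise ValueError("both classes must be present for AUC")
    point = float(roc_auc_score(y, s))
    rng = np.random.default_rng(seed)
    case_scores = s[y == 1]
    ctrl_scores = s[y == 0]
    stats = np.empty(n_boot)
    for b in range(n_boot):
        cs = rng.choice(case_scores, size=len(case_scores), replace=True)
        ks = rng.choice(ctrl_scores, size=len(ctrl_scores), replace=True)
        yy = np.concatenate([np.ones(len(cs)), np.zeros(len(ks))])
        stats[b] = roc_auc_score(yy, np.concatenate([cs, ks]))
    lo, hi = np.percentile(stats, [2.5, 97.5])
    return point, (float(lo), float(hi))


def high_risk_fraction_analytic(
    or_per_sd: float, r: float = 2.0
) -> HighRiskFraction:
    """Analytic share of a standard-normal score population with >= r-fold
    odds relative to an individual at the score mean.

    An individual at score z carries odds ``OR**z`` relative to the mean,
    so the condition ``OR**z >= r`` holds for ``z >= ln r / ln OR`` and the
    fraction is ``1 - Phi(ln r / ln OR)``.
    """
    if r < 1:
        raise ValueError("risk ratio threshold must be >= 1")
    if or_per_sd <= 0:
        raise ValueError("odds ratio must be positive")
    if or_per_sd <= 1.0:
        warnings.warn(
            "OR per SD <= 1: no one reaches the risk-ratio threshold",
            stacklevel=2,
        )
        return HighRiskFraction(or_per_sd, r, 0.0)
    if r == 1.0:
        frac = 0.5
    else:
        frac = float(1.0 - norm.cdf(np.log(r) / np.log(or_per_sd)))
    return HighRiskFraction(or_per_sd, r, frac)


def high_risk_fraction_empirical(
    score: pd.Series | np.ndarray, beta: float, r: float = 2.0
) -> HighRiskFraction:
    """Empirical twin of the analytic statistic, for observed score
    distributions: fraction of samples with ``exp(beta * z) >= r``."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    z = np.asarray(score, dtype=float)
    z = z[np.isfinite(z)]
    frac = float(np.mean(np.exp(beta * z) >= r))
    return HighRiskFraction(float(np.exp(beta)), r, frac)


def evaluate_association(
    score: pd.Series,
    outcome: pd.Series,
    covariates: pd.DataFrame | None = None,
    name: str | None = None,
    ancestry: str = "ALL",
    n_boot: int = 2000,
    seed: int = 0,
    auc_with_covariates: bool = False,
) -> AssociationResult:
    """OR per SD plus AUC in one result.

    By default the AUC is computed on the score alone; with
    ``auc_with_covariates`` it uses the full fitted linear predictor.
    """
    res = or_per_sd(score, outcome, covariates, name=name, ancestry=ancestry)
    if auc_with_covariates and covariates is not None:
        cleaned = _drop_missing(score, outcome, covariates)
        s, y, c = cleaned
        x = np.column_stack(
            [np.ones(len(y)), s.to_numpy(float), c.to_numpy(float)]
        )
        fit = _logit_fit(y.to_numpy(float), x, None, name or "auc")
        pred = pd.Series(x @ fit.params, index=y.index)
        a, ci = auc(pred, y, n_boot=n_boot, seed=seed)
    else:
        a, ci = auc(score, outcome, n_boot=n_boot, seed=seed)
    res.auc, res.auc_ci = a, ci
    return res


def evaluate_by_ancestry(
    score: pd.Series,
    outcome: pd.Series,
    covariates: pd.DataFrame,
    labels: pd.Series,
    name: str | None = None,
    n_boot: int = 2000,
    seed: int = 0,
    r: float = 2.0,
) -> pd.DataFrame:
    """Per-ancestry evaluation table in the shape of a published results
    table: cases, controls, AUC (CI), OR per SD (CI), high-risk fraction."""
    rows = []
    labels = labels.reindex(score.index)
    for group in pd.unique(labels.dropna()):
        idx = labels.index[labels == group]
        res = evaluate_association(
            score.loc[idx],
            outcome.loc[idx],
            covariates.loc[idx],
            name=name,
            ancestry=str(group),
            n_boot=n_boot,
            seed=seed,
        )
        if res.or_per_sd > 1:
            hrf = high_risk_fraction_analytic(res.or_per_sd, r=r).percent
        else:
            hrf = 0.0
        rows.append(
            {
                "PRS": res.name,
                "Ancestry": res.ancestry,
                "Cases": res.n_cases,
                "Controls": res.n_controls,
                "AUC": res.auc,
                "AUC_CI_low": res.auc_ci[0],
                "AUC_CI_high": res.auc_ci[1],
                "OR_per_SD": res.or_per_sd,
                "OR_CI_low": res.or_ci[0],
                "OR_CI_high": res.or_ci[1],
                "high_risk_percent": hrf,
            }
        )
    return pd.DataFrame(rows)
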