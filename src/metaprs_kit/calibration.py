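"""Quintile-binned calibration with binomial CIs and spline smoothing.

Predicted probabilities come from a logistic model of the outcome on the
score plus covariates, either refit in-sample or cross-validated (each
person predicted by a model that never saw them).  Predictions are cut
into quantile bins (quintiles by default), the observed event rate per
bin is paired with a Wilson 95% interval, and a monotone cubic
interpolant through (mean predicted, observed rate) gives the smooth
calibration curve.  On the calibration plot the diagonal is perfect
calibration; points above it mark under-prediction, points below it
over-prediction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from statsmodels.stats.proportion import proportion_confint

from .metaprs import _logit_fit, make_folds


@dataclass
class CalibrationCurve:
    """Binned calibration statistics plus the smoothed curve.

    ``bins`` has one row per bin, ordered by predicted probability, with
    columns ``count, mean_predicted, observed_rate, ci_low, ci_high``.
    ``grid``/``smooth`` hold the spline evaluated on a probability grid.
    """

    ancestry: str
    model: str
    bins: pd.DataFrame
    grid: np.ndarray | None = None
    smooth: np.ndarray | None = None

    @property
    def mean_signed_miscalibration(self) -> float:
        """Count-weighted mean of (observed rate - mean predicted)."""
        b = self.bins
        w = b["count"] / b["count"].sum()
        return float((w * (b["observed_rate"] - b["mean_predicted"])).sum())


def predict_probabilities(
    score: pd.Series,
    outcome: pd.Series,
    covariates: pd.DataFrame | None = None,
    mode: str = "cv",
    k: int = 5,
    seed: int = 0,
) -> pd.Series:
    """Per-person predicted probability from a logistic model.

    ``mode='refit'`` fits once on everyone; ``mode='cv'`` (default) fits k
    models, each predicting only the held-out fold.
    """
    if mode not in ("cv", "refit"):
        raise ValueError("mode must be 'cv' or 'refit'")
    pieces = [score, outcome] + ([covariates] if covariates is not None else [])
    joined = pd.concat(pieces, axis=1)
    ok = joined.notna().all(axis=1)
    idx = score.index[ok]

    def design(sub: pd.Index) -> np.ndarray:
        cols = [np.ones(len(sub)), score.loc[sub].to_numpy(float)]
        if covariates is not None:
            cols.append(covariates.loc[sub].to_numpy(float))
        return np.column_stack(cols)

    probs = pd.Series(np.nan, index=score.index, name="predicted")
    if mode == "refit":
        res = _logit_fit(outcome.loc[idx].to_numpy(float), design(idx), None, "refit")
        probs.loc[idx] = _expit(design(idx) @ res.params)
        return probs
    folds = make_folds(idx, k=k, seed=seed)
    for f in sorted(folds.unique()):
        train = idx[folds != f]
        test = idx[folds == f]
        res = _logit_fit(
            outcome.loc[train].to_numpy(float), design(train), None, f"fold {f}"
        )
        probs.loc[test] = _expit(design(test) @ res.params)
    return probs


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def bin_predictions(probs: pd.Series, n_bins: int = 5) -> pd.Series:
    """Quantile-based bin assignment with equal counts (+/- 1).

    Ties are broken by the stable ordering of the input, so the
    assignment is deterministic.  If the predictions have fewer distinct
    values than bins, the effective number of bins shrinks with a warning.
    """
    probs = probs.dropna()
    n = len(probs)
    if n < n_bins:
        raise ValueError(f"need at least {n_bins} predictions, got {n}")
    n_distinct = probs.nunique()
    if n_distinct < n_bins:
        warnings.warn(
            f"only {n_distinct} distinct values; merging to {n_distinct} bins",
            stacklevel=2,
        )
        n_bins = max(int(n_distinct), 1)
    order = np.argsort(probs.to_numpy(), kind="stable")
    bins = np.empty(n, dtype=int)
    sizes = np.full(n_bins, n // n_bins)
    sizes[: n % n_bins] += 1
    bins[order] = np.repeat(np.arange(n_bins), sizes)
    return pd.Series(bins, index=probs.index, name="bin")


def observed_rates_with_ci(
    bins: pd.Series,
    outcome: pd.Series,
    probs: pd.Series | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-bin count, mean prediction, observed rate and Wilson interval."""
    df = pd.DataFrame({"bin": bins, "y": outcome.reindex(bins.index)})
    if probs is not None:
        df["p"] = probs.reindex(bins.index)
    rows = []
    for b, grp in df.groupby("bin", sort=True):
        count = len(grp)
        cases = int(grp["y"].sum())
        lo, hi = proportion_confint(cases, count, alpha=alpha, method="wilson")
        rows.append(
            {
                "bin": b,
                "count": count,
                "mean_predicted": float(grp["p"].mean()) if probs is not None else np.nan,
                "observed_rate": cases / count,
                "ci_low": float(lo),
                "ci_high": float(hi),
            }
        )
    return pd.DataFrame(rows).set_index("bin")


def spline_curve(
    bins: pd.DataFrame, n_grid: int = 100
) -> tuple[np.ndarray, np.ndarray]:
    """Monotone-preserving cubic interpolant through the bin points.

    Evaluated on ``n_grid`` points spanning the bin means and clamped to
    [0, 1].  With fewer than 3 bins the curve degrades to linear
    interpolation with a warning.
    """
    x = bins["mean_predicted"].to_numpy(dtype=float)
    y = bins["observed_rate"].to_numpy(dtype=float)
    order = np.argsort(x)
    x, y = x[order], y[order]
    grid = np.linspace(x[0], x[-1], n_grid)
    if len(x) < 3:
        warnings.warn("fewer than 3 bins; using linear interpolation", stacklevel=2)
        smooth = np.interp(grid, x, y)
    else:
        smooth = PchipInterpolator(x, y)(grid)
    return grid, np.clip(smooth, 0.0, 1.0)


def calibration_curve(
    probs: pd.Series,
    outcome: pd.Series,
    n_bins: int = 5,
    ancestry: str = "ALL",
    model: str = "model",
) -> CalibrationCurve:
    """Bin, rate and smooth in one call."""
    bins = bin_predictions(probs, n_bins=n_bins)
    table = observed_rates_with_ci(bins, outcome, probs)
    grid, smooth = spline_curve(table)
    return CalibrationCurve(
        ancestry=ancestry, model=model, bins=table, grid=grid, smooth=smooth
    )


def calibration_report(
    curves: list[CalibrationCurve],
    out_path=None,
    title: str | None = None,
) -> pd.DataFrame:
    """One calibration panel per curve plus a miscalibration summary.

    Each panel shows the diagonal, bin points with Wilson error bars and
    the spline.  Returns a summary table of count-weighted mean signed
    miscalibration (observed - predicted) per (ancestry, model); a
    negative value means the model overestimates risk for that group.
    """
    if not curves:
        raise ValueError("need at least one calibration curve")
    if out_path is not None:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        n = len(curves)
        ncol = min(3, n)
        nrow = int(np.ceil(n / ncol))
        fig, axes = plt.subplots(
            nrow, ncol, figsize=(4 * ncol, 3.5 * nrow), squeeze=False
        )
        for ax, curve in zip(axes.ravel(), curves):
            b = curve.bins
            lim = max(b["ci_high"].max(), b["mean_predicted"].max()) * 1.1
            ax.plot([0, lim], [0, lim], "k--", lw=1, label="perfect")
            yerr = np.vstack(
                [
                    b["observed_rate"] - b["ci_low"],
                    b["ci_high"] - b["observed_rate"],
                ]
            )
            ax.errorbar(
                b["mean_predicted"],
                b["observed_rate"],
                yerr=yerr,
                fmt="o",
                ms=4,
                capsize=3,
                color="tab:blue",
            )
            if curve.grid is not None:
                ax.plot(curve.grid, curve.smooth, color="tab:blue", lw=1.5)
            ax.set_title(f"{curve.ancestry} — {curve.model}", fontsize=9)
            ax.set_xlabel("mean predicted probability")
            ax.set_ylabel("observed event rate")
        for ax in axes.ravel()[len(curves):]:
            ax.set_visible(False)
        if title:
            fig.suptitle(title)
        fig.tight_layout()
        fig.savefig(out_path, dpi=120)
        plt.close(fig)
    summary = pd.DataFrame(
        [
            {
                "ancestry": c.ancestry,
                "model": c.model,
                "n": int(c.bins["count"].sum()),
                "mean_signed_miscalibration": c.mean_signed_miscalibration,
            }
            for c in curves
        ]
    )
    return summary
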