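"""Sliding-window encoding regression of firing rate.

Per 100-ms bin (stepped every 10 ms) an OLS model regresses the trial's
firing rate on previous/current choice and outcome, all coded -1/0/+1 in
the ipsi/contra frame; significance per bin is CI-excludes-zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import codings
from .io import SpikeTrain

BIN_WIDTH_S = 0.100
STEP_S = 0.010

ALIGN_EVENTS = ("valve_open", "odor_port_entry", "odor_port_exit",
                "reward_port_entry")

COEF_NAMES = ("intercept", "choice_prev", "outcome_prev",
              "choice_cur", "outcome_cur")


@dataclass
class AlignedRateMatrix:
    unit_id: str
    align_event: str
    bin_centers: np.ndarray  # seconds relative to event
    rates: np.ndarray  # trials x bins, spikes/s
    bin_width_s: float
    step_s: float
    trial_rows: np.ndarray  # rows of the trial table retained


@dataclass
class SlidingFit:
    unit_id: str
    align_event: str
    bin_centers: np.ndarray
    coefficients: dict[str, np.ndarray]  # name -> per-bin estimate
    ci_low: dict[str, np.ndarray]
    ci_high: dict[str, np.ndarray]
    significant: dict[str, np.ndarray]  # name -> per-bin bool
    undefined: dict[str, np.ndarray]  # per-bin flag for unfittable terms
    n_trials: int


def bin_rates(
    spikes: SpikeTrain,
    trials: pd.DataFrame,
    align_event: str,
    window: tuple[float, float] = (-0.5, 1.0),
    bin_width_s: float = BIN_WIDTH_S,
    step_s: float = STEP_S,
) -> AlignedRateMatrix:
    """Event-aligned trial x bin rate matrix with overlapping bins.

    Bin centers run from ``window[0] + bin_width/2`` every ``step_s``;
    each bin covers the half-open interval [center - w/2, center + w/2).
    Trials lacking the align event are dropped with a warning.
    """
    if align_event not in trials.columns:
        raise ValueError(f"unknown align event {align_event!r}")
    anchors = trials[align_event].to_numpy(dtype=float)
    keep = np.flatnonzero(np.isfinite(anchors))
    if keep.size < len(trials):
        warnings.warn(
            f"{len(trials) - keep.size} trial(s) lack event '{align_event}'; dropped"
        )
    centers = np.arange(
        window[0] + bin_width_s / 2.0,
        window[1] - bin_width_s / 2.0 + step_s / 2.0,
        step_s,
    )
    rates = np.empty((keep.size, centers.size))
    half = bin_width_s / 2.0
    for i, t in enumerate(keep):
        rel = spikes.spike_times - anchors[t]
        lo = np.searchsorted(rel, centers - half, side="left")
        hi = np.searchsorted(rel, centers + half, side="left")
        rates[i] = (hi - lo) / bin_width_s
    return AlignedRateMatrix(
        unit_id=spikes.unit_id,
        align_event=align_event,
        bin_centers=centers,
        rates=rates,
        bin_width_s=bin_width_s,
        step_s=step_s,
        trial_rows=keep,
    )


def code_regressors(trials: pd.DataFrame, recorded_side: str) -> pd.DataFrame:
    """Ipsi/contra-frame regressors for previous and current trial."""
    xc1, xo1 = codings.neural_lag_columns(trials, 1, recorded_side)
    xc0, xo0 = codings.neural_lag_columns(trials, 0, recorded_side)
    return pd.DataFrame(
        {
            "choice_prev": xc1,
            "outcome_prev": xo1,
            "choice_cur": xc0,
            "outcome_cur": xo0,
        }
    )


def fit_sliding(
    matrix: AlignedRateMatrix, regressors: pd.DataFrame, alpha: float = 0.05
) -> SlidingFit:
    """Per-bin OLS of rate on the four trial regressors, with t-based CIs.

    Regressors constant across the retained trials cannot be estimated;
    their per-bin values are flagged undefined (NaN estimates).
    """
    reg = regressors.iloc[matrix.trial_rows].reset_index(drop=True)
    names = list(COEF_NAMES)
    X_full = np.column_stack(
        [np.ones(len(reg))] + [reg[c].to_numpy(dtype=float) for c in names[1:]]
    )
    n, p_full = X_full.shape
    variable = [True] + [
        np.unique(X_full[:, j]).size >= 2 for j in range(1, p_full)
    ]
    usable = [j for j in range(p_full) if variable[j]]
    X = X_full[:, usable]
    if n < X.shape[1] + 1:
        raise ValueError("need more trials than regressors")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # drop to an independent subset, flag the rest undefined
        keep = [0]
        for j in range(1, X.shape[1]):
            trial_set = keep + [j]
            if np.linalg.matrix_rank(X[:, trial_set]) == len(trial_set):
                keep.append(j)
        usable = [usable[j] for j in keep]
        X = X_full[:, usable]

    Y = matrix.rates  # n x bins
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Y  # p x bins
    resid = Y - X @ beta
    df = n - X.shape[1]
    sigma2 = (resid**2).sum(axis=0) / df
    se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)

    n_bins = Y.shape[1]
    coef = {nm: np.full(n_bins, np.nan) for nm in names}
    lo = {nm: np.full(n_bins, np.nan) for nm in names}
    hi = {nm: np.full(n_bins, np.nan) for nm in names}
    sig = {nm: np.zeros(n_bins, dtype=bool) for nm in names}
    undef = {nm: np.ones(n_bins, dtype=bool) for nm in names}
    for row, j in enumerate(usable):
        nm = names[j]
        coef[nm] = beta[row]
        lo[nm] = beta[row] - tcrit * se[row]
        hi[nm] = beta[row] + tcrit * se[row]
        sig[nm] = (lo[nm] > 0) | (hi[nm] < 0)
        undef[nm] = np.zeros(n_bins, dtype=bool)
    return SlidingFit(
        unit_id=matrix.unit_id,
        align_event=matrix.align_event,
        bin_centers=matrix.bin_centers,
        coefficients=coef,
        ci_low=lo,
        ci_high=hi,
        significant=sig,
        undefined=undef,
        n_trials=n,
    )


def population_timecourse(fits: list[SlidingFit]) -> dict[str, dict[str, np.ndarray]]:
    """Mean +/- s.e.m. coefficient traces and fraction-significant per bin.

    All fits must share alignment and bin grid.
    """
    if not fits:
        raise ValueError("empty fit set")
    centers = fits[0].bin_centers
    for f in fits[1:]:
        if f.align_event != fits[0].align_event or not np.array_equal(
            f.bin_centers, centers
        ):
            raise ValueError("fits must share align event and bin grid")
    out: dict[str, dict[str, np.ndarray]] = {"bin_centers": centers}
    for nm in COEF_NAMES:
        stack = np.vstack([f.coefficients[nm] for f in fits])
        sig = np.vstack([f.significant[nm] for f in fits])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(stack, axis=0)
            n_valid = np.sum(np.isfinite(stack), axis=0)
            sem = np.nanstd(stack, axis=0, ddof=1) / np.sqrt(
                np.maximum(n_valid, 1)
            )
        out[nm] = {
            "mean": mean,
            "sem": sem,
            "frac_significant": sig.mean(axis=0),
        }
    return out


def fit_table(fit: SlidingFit) -> pd.DataFrame:
    """Long-format per-bin coefficient table for one unit."""
    rows = []
    for nm in COEF_NAMES:
        rows.append(
            pd.DataFrame(
                {
                    "unit_id": fit.unit_id,
                    "align_event": fit.align_event,
                    "bin_center_s": fit.bin_centers,
                    "coefficient": nm,
                    "estimate": fit.coefficients[nm],
                    "ci_low": fit.ci_low[nm],
                    "ci_high": fit.ci_high[nm],
                    "significant": fit.significant[nm],
                    "undefined": fit.undefined[nm],
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
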