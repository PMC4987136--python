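"""Trial-by-trial linkage between pre-stimulus rate and upcoming choice.

For units selective for the previous choice, the pre-stimulus firing rate
(max-normalized within each previous-choice condition) is regressed on an
indicator of whether the mouse chose the unit's preferred port, on
ambiguous-mixture trials only; slope significance is by permutation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from . import codings
from .io import SpikeTrain
from .preference import PRE_STIMULUS, EpochSpec, epoch_rate

AMBIGUOUS_FRACTIONS = (0.40, 0.50, 0.60)


@dataclass
class SlopeResult:
    unit_id: str
    slope: float
    p_value: float | None
    sign_class: str  # positive | negative | ns
    n_trials: int


def link_trials(
    spikes: SpikeTrain,
    trials: pd.DataFrame,
    preferred_side: str,
    epoch: EpochSpec = PRE_STIMULUS,
) -> tuple[np.ndarray, np.ndarray]:
    """(normalized rate, preferred-choice indicator) pairs for one unit.

    Rates are normalized to the maximum across all trials of the same
    previous-choice condition; only ambiguous current trials (40/50/60%
    left odor) with a valid choice are returned. ``preferred_side`` is
    'L' or 'R' (the port whose choice the unit fires more for).
    """
    if preferred_side not in (codings.CHOICE_LEFT, codings.CHOICE_RIGHT):
        raise ValueError("preferred_side must be 'L' or 'R'")
    rates = epoch_rate(spikes, trials, epoch)
    prev_choice, _ = codings.lagged_choice_outcome(trials, 1)
    cur_choice, _ = codings.lagged_choice_outcome(trials, 0)
    f_left = trials["odor_left_fraction"].to_numpy(dtype=float)
    ambiguous = np.isin(np.round(f_left, 2), AMBIGUOUS_FRACTIONS)

    norm = np.full(len(trials), np.nan)
    for cond in (codings.CHOICE_LEFT, codings.CHOICE_RIGHT):
        sel = (prev_choice == cond) & np.isfinite(rates)
        if not sel.any():
            continue
        peak = np.max(rates[sel])
        if peak <= 0:
            warnings.warn(
                f"unit {spikes.unit_id}: zero peak rate in previous-{cond} "
                "condition; those trials dropped"
            )
            continue
        norm[sel] = rates[sel] / peak

    keep = (
        ambiguous
        & np.isfinite(norm)
        & ((cur_choice == codings.CHOICE_LEFT) | (cur_choice == codings.CHOICE_RIGHT))
    )
    indicator = (cur_choice[keep] == preferred_side).astype(float)
    return norm[keep], indicator


def _ls_slope(x: np.ndarray, y: np.ndarray) -> float:
    """Least-squares slope of y on x (covariance over variance)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    vx = np.var(x)
    if vx == 0:
        return 0.0
    return float(np.mean((x - x.mean()) * (y - y.mean())) / vx)


def _logistic_slope(x: np.ndarray, y: np.ndarray) -> float:
    """Slope coefficient of a univariate logistic fit (IRLS)."""
    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    for _ in range(50):
        mu = expit(X @ beta)
        w = np.maximum(mu * (1 - mu), 1e-12)
        try:
            step = np.linalg.solve((X * w[:, None]).T @ X, X.T @ (y - mu))
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.max(np.abs(step)) < 1e-8:
            break
    return float(np.clip(beta[1], -50.0, 50.0))


def slope_test(
    norm_rates: np.ndarray,
    indicators: np.ndarray,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
    fit: str = "line",
    alpha: float = 0.05,
) -> SlopeResult:
    """Two-sided permutation test of the rate-to-preferred-choice slope.

    The indicator vector is shuffled against the rates ``n_perm`` times;
    p is the add-one-corrected fraction of |permuted slope| >= |observed|.
    A constant indicator (all preferred or all antipreferred) yields
    slope 0 with the test skipped.
    """
    if fit not in ("line", "logistic"):
        raise ValueError("fit must be 'line' or 'logistic'")
    x = np.asarray(norm_rates, dtype=float)
    y = np.asarray(indicators, dtype=float)
    if x.size != y.size:
        raise ValueError("rates and indicators must align")
    slope_fn = _ls_slope if fit == "line" else _logistic_slope
    n = x.size
    if np.unique(y).size < 2 or np.unique(x).size < 2:
        return SlopeResult("", 0.0, None, "ns", n)
    observed = slope_fn(x, y)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if fit == "line":
        # slope = cov(x, y) / var(x); only sum(x*y_perm) varies under shuffles
        xc = x - x.mean()
        denom = np.var(x) * n
        perms = rng.permuted(np.tile(y, (n_perm, 1)), axis=1)
        null = (perms @ xc) / denom
    else:
        null = np.empty(n_perm)
        for i in range(n_perm):
            null[i] = slope_fn(x, rng.permutation(y))
    k = int(np.sum(np.abs(null) >= abs(observed) - 1e-12))
    p = (k + 1) / (n_perm + 1)
    if p < alpha:
        sign_class = "positive" if observed > 0 else "negative"
    else:
        sign_class = "ns"
    return SlopeResult("", float(observed), p, sign_class, n)


def unit_slope(
    spikes: SpikeTrain,
    trials: pd.DataFrame,
    preference: float,
    epoch: EpochSpec = PRE_STIMULUS,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
    fit: str = "line",
) -> SlopeResult:
    """Full per-unit pipeline: preferred side from the preference sign,
    trial linkage, then the permutation slope test."""
    sign = codings.contra_sign(spikes.recorded_side)
    # preference > 0 means contra-preferring
    preferred = next(
        tok for tok, s in sign.items()
        if s == (1.0 if preference > 0 else -1.0)
    )
    x, y = link_trials(spikes, trials, preferred, epoch)
    res = slope_test(x, y, n_perm=n_perm, seed=seed, fit=fit)
    res.unit_id = spikes.unit_id
    return res


def population_slopes(
    results: list[SlopeResult],
    mouse_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Fractions of positive/negative/ns slopes overall and per mouse,
    with a chi-square comparing positive vs negative counts."""
    if not results:
        return pd.DataFrame(
            columns=["mouse_id", "n_units", "frac_positive", "frac_negative",
                     "frac_ns", "chi2", "p_value"]
        )
    if mouse_ids is None:
        mouse_ids = ["all"] * len(results)
    df = pd.DataFrame(
        {
            "mouse_id": mouse_ids,
            "sign_class": [r.sign_class for r in results],
        }
    )
    groups = [("all", df)] + [
        (m, g) for m, g in df.groupby("mouse_id") if len(set(mouse_ids)) > 1
    ]
    rows = []
    for label, g in groups:
        n = len(g)
        n_pos = int((g["sign_class"] == "positive").sum())
        n_neg = int((g["sign_class"] == "negative").sum())
        row = {
            "mouse_id": label,
            "n_units": n,
            "frac_positive": n_pos / n,
            "frac_negative": n_neg / n,
            "frac_ns": (n - n_pos - n_neg) / n,
            "chi2": np.nan,
            "p_value": np.nan,
        }
        if n_pos + n_neg > 0:
            chi2, p = stats.chisquare([n_pos, n_neg])
            row["chi2"], row["p_value"] = float(chi2), float(p)
        rows.append(row)
    return pd.DataFrame(rows)
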