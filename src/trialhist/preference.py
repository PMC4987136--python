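"""ROC-based preference index, permutation significance, and PSTHs.

Preference is 2*(ROC_area - 0.5) in [-1, 1], where ROC_area is the
probability that a random rate from the positively-oriented group exceeds
one from the other group (ties count half). For choice groupings the
contralateral side is oriented +1; for outcome, reward is +1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import gaussian_filter1d

from . import codings
from .io import SpikeTrain

MIN_TRIALS_PER_GROUP = 4
MIN_RATE_SPIKES_PER_S = 2.0


@dataclass(frozen=True)
class EpochSpec:
    """A per-trial time window anchored to two named events."""

    name: str
    start_event: str
    start_offset_s: float
    end_event: str
    end_offset_s: float


#: odor-port entry to 100 ms after odor valve open
PRE_STIMULUS = EpochSpec("pre_stimulus", "odor_port_entry", 0.0, "valve_open", 0.100)
OUTBOUND_MOVEMENT = EpochSpec(
    "outbound_movement", "odor_port_exit", 0.0, "reward_port_entry", 0.0
)


@dataclass
class PreferenceResult:
    unit_id: str
    variable: str  # choice | outcome
    lag: int
    preference: float
    p_value: float | None
    included: bool
    n_per_group: tuple[int, int]
    mean_rates: tuple[float, float]


def epoch_rate(
    spikes: SpikeTrain, trials: pd.DataFrame, epoch: EpochSpec
) -> np.ndarray:
    """Per-trial firing rate (spikes/s) in a half-open [start, end) epoch.

    Trials whose anchor events are missing yield NaN (with a warning).
    """
    start = trials[epoch.start_event].to_numpy(dtype=float) + epoch.start_offset_s
    end = trials[epoch.end_event].to_numpy(dtype=float) + epoch.end_offset_s
    rates = np.full(len(trials), np.nan)
    ok = np.isfinite(start) & np.isfinite(end) & (end > start)
    if (~ok).any():
        warnings.warn(
            f"{int((~ok).sum())} trial(s) lack a resolvable '{epoch.name}' epoch",
            stacklevel=2,
        )
    counts = np.searchsorted(spikes.spike_times, end[ok], side="left") - \
        np.searchsorted(spikes.spike_times, start[ok], side="left")
    rates[ok] = counts / (end[ok] - start[ok])
    return rates


def _u_stat(pos: np.ndarray, neg: np.ndarray) -> float:
    """Mann-Whitney U of ``pos`` over ``neg`` (midranks; exact in halves)."""
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([pos, neg])
    ranks = stats.rankdata(combined)  # midranks
    r_pos = ranks[: pos.size].sum()
    return float(r_pos - pos.size * (pos.size + 1) / 2.0)


def roc_area(pos: np.ndarray, neg: np.ndarray) -> float:
    """P(random draw from ``pos`` > draw from ``neg``), ties counted half."""
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    return _u_stat(pos, neg) / (pos.size * neg.size)


def roc_preference(rates_pos: np.ndarray, rates_neg: np.ndarray) -> float:
    """Preference index 2*(ROC_area - 0.5) of the +1-oriented group.

    Computed as (2U - n_pos*n_neg) / (n_pos*n_neg) so that swapping the
    groups negates the result exactly (2U and the pair count are exact
    in floating point).
    """
    pos = np.asarray(rates_pos, dtype=float)
    neg = np.asarray(rates_neg, dtype=float)
    n_pairs = pos.size * neg.size
    u = _u_stat(pos, neg)
    return float((2.0 * u - n_pairs) / n_pairs)


def meets_inclusion(rates_pos: np.ndarray, rates_neg: np.ndarray) -> bool:
    """At least 4 trials per group and >= 2 spikes/s mean rate in one group."""
    if len(rates_pos) < MIN_TRIALS_PER_GROUP or len(rates_neg) < MIN_TRIALS_PER_GROUP:
        return False
    return (
        np.mean(rates_pos) >= MIN_RATE_SPIKES_PER_S
        or np.mean(rates_neg) >= MIN_RATE_SPIKES_PER_S
    )


def preference_permutation(
    rates_pos: np.ndarray,
    rates_neg: np.ndarray,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
    alternative: str = "two-sided",
) -> float:
    """Monte-Carlo permutation p-value for the preference index.

    Group labels are reshuffled ``n_perm`` times; the two-sided p is the
    add-one-corrected fraction of |permuted preference| >= |observed|.
    ``alternative='greater'`` gives the one-sided tail on the signed value.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pos = np.asarray(rates_pos, dtype=float)
    neg = np.asarray(rates_neg, dtype=float)
    observed = roc_preference(pos, neg)
    combined = np.concatenate([pos, neg])
    n_pos = pos.size

    # vectorized: rank once per permutation via argsort of shuffled matrix
    perms = np.tile(combined, (n_perm, 1))
    perms = rng.permuted(perms, axis=1)
    ranks = stats.rankdata(perms, axis=1)
    u = ranks[:, :n_pos].sum(axis=1) - n_pos * (n_pos + 1) / 2.0
    pref = 2.0 * (u / (n_pos * neg.size) - 0.5)
    if alternative == "two-sided":
        k = int(np.sum(np.abs(pref) >= abs(observed) - 1e-12))
    elif alternative == "greater":
        k = int(np.sum(pref >= observed - 1e-12))
    else:
        raise ValueError("alternative must be 'two-sided' or 'greater'")
    return (k + 1) / (n_perm + 1)


def group_rates(
    spikes: SpikeTrain,
    trials: pd.DataFrame,
    variable: str,
    lag: int,
    epoch: EpochSpec = PRE_STIMULUS,
) -> tuple[np.ndarray, np.ndarray]:
    """(positive-group rates, negative-group rates) for a variable x lag.

    Choice groups are contra (+) vs ipsi (-) by the unit's recorded side;
    outcome groups are rewarded (+) vs unrewarded (-).
    """
    rates = epoch_rate(spikes, trials, epoch)
    choice, rewarded = codings.lagged_choice_outcome(trials, lag)
    has_rate = np.isfinite(rates)
    if variable == "choice":
        sign = codings.contra_sign(spikes.recorded_side)
        x = np.array([sign[c] for c in choice])
        pos = has_rate & (x > 0)
        neg = has_rate & (x < 0)
    elif variable == "outcome":
        pos = has_rate & (rewarded == 1.0)
        neg = has_rate & (rewarded == 0.0)
    else:
        raise ValueError("variable must be 'choice' or 'outcome'")
    return rates[pos], rates[neg]


def compute_preference(
    spikes: SpikeTrain,
    trials: pd.DataFrame,
    variable: str,
    lag: int,
    epoch: EpochSpec = PRE_STIMULUS,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
    alternative: str = "two-sided",
) -> PreferenceResult:
    pos, neg = group_rates(spikes, trials, variable, lag, epoch)
    if not meets_inclusion(pos, neg):
        return PreferenceResult(
            unit_id=spikes.unit_id, variable=variable, lag=lag,
            preference=np.nan, p_value=None, included=False,
            n_per_group=(len(pos), len(neg)),
            mean_rates=(
                float(np.mean(pos)) if len(pos) else np.nan,
                float(np.mean(neg)) if len(neg) else np.nan,
            ),
        )
    pref = roc_preference(pos, neg)
    p = preference_permutation(pos, neg, n_perm=n_perm, seed=seed,
                               alternative=alternative)
    return PreferenceResult(
        unit_id=spikes.unit_id, variable=variable, lag=lag,
        preference=pref, p_value=p, included=True,
        n_per_group=(len(pos), len(neg)),
        mean_rates=(float(np.mean(pos)), float(np.mean(neg))),
    )


def results_table(results: list[PreferenceResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "unit_id": [r.unit_id for r in results],
            "variable": [r.variable for r in results],
            "lag": [r.lag for r in results],
            "preference": [r.preference for r in results],
            "p_value": [np.nan if r.p_value is None else r.p_value for r in results],
            "included": [r.included for r in results],
            "n_pos": [r.n_per_group[0] for r in results],
            "n_neg": [r.n_per_group[1] for r in results],
        }
    )


def population_preference(
    results: list[PreferenceResult], alpha: float = 0.05
) -> dict:
    """Population summary: significant fractions, sign test, lag contrasts.

    Returns per-(variable, lag) significant fractions by sign with a
    chi-square on the positive-vs-negative significant counts, a
    Kruskal-Wallis test across lags on |preference| (per variable, when
    >= 2 lags present) with pairwise Mann-Whitney post-hocs, and the
    Pearson correlation between lag-0 and lag-1 preferences.
    """
    included = [r for r in results if r.included]
    if not included:
        warnings.warn("no included units; empty population summary")
        return {"groups": {}, "kruskal": {}, "lag_correlation": {}}

    summary: dict = {"groups": {}, "kruskal": {}, "lag_correlation": {}}
    keys = sorted({(r.variable, r.lag) for r in included})
    for var, lag in keys:
        grp = [r for r in included if r.variable == var and r.lag == lag]
        sig = [r for r in grp if r.p_value is not None and r.p_value < alpha]
        n_pos = sum(1 for r in sig if r.preference > 0)
        n_neg = sum(1 for r in sig if r.preference < 0)
        entry = {
            "n_included": len(grp),
            "frac_significant": len(sig) / len(grp),
            "frac_positive": n_pos / len(grp),
            "frac_negative": n_neg / len(grp),
        }
        if n_pos + n_neg > 0:
            chi2, p = stats.chisquare([n_pos, n_neg])
            entry["sign_chi2"] = float(chi2)
            entry["sign_p"] = float(p)
        summary["groups"][(var, lag)] = entry

    for var in sorted({r.variable for r in included}):
        by_lag = {
            lag: np.abs([r.preference for r in included
                         if r.variable == var and r.lag == lag])
            for lag in sorted({r.lag for r in included if r.variable == var})
        }
        if len(by_lag) >= 2 and all(len(v) >= 2 for v in by_lag.values()):
            h, p = stats.kruskal(*by_lag.values())
            posthoc = {}
            lags = list(by_lag)
            for i, a in enumerate(lags):
                for b in lags[i + 1:]:
                    _, pp = stats.mannwhitneyu(by_lag[a], by_lag[b])
                    posthoc[(a, b)] = float(pp)
            summary["kruskal"][var] = {"H": float(h), "p": float(p),
                                       "posthoc": posthoc}

    for var in sorted({r.variable for r in included}):
        p0 = {r.unit_id: r.preference for r in included
              if r.variable == var and r.lag == 0}
        p1 = {r.unit_id: r.preference for r in included
              if r.variable == var and r.lag == 1}
        common = sorted(set(p0) & set(p1))
        if len(common) >= 3:
            x = np.array([p0[u] for u in common])
            yv = np.array([p1[u] for u in common])
            r, p = stats.pearsonr(x, yv)
            summary["lag_correlation"][var] = {"r": float(r), "p": float(p),
                                               "n": len(common)}
    return summary


def _return_epoch_rates(
    spikes: SpikeTrain, trials: pd.DataFrame
) -> np.ndarray:
    """Rates from reward-port exit to the next trial's odor-port entry."""
    rp_exit = trials["reward_port_exit"].to_numpy(dtype=float)
    entry = trials["odor_port_entry"].to_numpy(dtype=float)
    session = trials["session_id"].to_numpy()
    start = rp_exit
    end = np.full(len(trials), np.nan)
    if len(trials) > 1:
        same = session[1:] == session[:-1]
        end[:-1] = np.where(same, entry[1:], np.nan)
    rates = np.full(len(trials), np.nan)
    ok = np.isfinite(start) & np.isfinite(end) & (end > start)
    counts = np.searchsorted(spikes.spike_times, end[ok], side="left") - \
        np.searchsorted(spikes.spike_times, start[ok], side="left")
    rates[ok] = counts / (end[ok] - start[ok])
    return rates


def movement_direction_check(
    trains: list[SpikeTrain],
    trials: pd.DataFrame,
    n_perm: int = 1000,
    seed: int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Classify units as port-preserving vs direction-preserving.

    Choice preference is computed separately during the outbound movement
    (odor-port exit to reward-port entry) and the return movement
    (reward-port exit to next odor-port entry); matching preference signs
    mark a port-preserving unit, inverted signs a direction-preserving one.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for train in trains:
        out_rates = epoch_rate(train, trials, OUTBOUND_MOVEMENT)
        ret_rates = _return_epoch_rates(train, trials)
        choice, _ = codings.lagged_choice_outcome(trials, 0)
        sign = codings.contra_sign(train.recorded_side)
        x = np.array([sign[c] for c in choice])
        prefs = []
        ok = True
        for rates in (out_rates, ret_rates):
            has = np.isfinite(rates)
            pos, neg = rates[has & (x > 0)], rates[has & (x < 0)]
            if not meets_inclusion(pos, neg):
                ok = False
                break
            prefs.append(roc_preference(pos, neg))
        if not ok:
            continue
        outbound, ret = prefs
        if outbound == 0.0 or ret == 0.0:
            cls = "indeterminate"
        elif np.sign(outbound) == np.sign(ret):
            cls = "port_preserving"
        else:
            cls = "direction_preserving"
        rows.append({"unit_id": train.unit_id, "outbound_preference": outbound,
                     "return_preference": ret, "classification": cls})
    table = pd.DataFrame(rows)
    summary: dict = {"n_units": len(table)}
    if len(table):
        n_port = int((table["classification"] == "port_preserving").sum())
        n_dir = int((table["classification"] == "direction_preserving").sum())
        summary["frac_port_preserving"] = n_port / len(table)
        summary["frac_direction_preserving"] = n_dir / len(table)
        if n_port + n_dir > 0:
            chi2, p = stats.chisquare([n_port, n_dir])
            summary["chi2"] = float(chi2)
            summary["p_value"] = float(p)
    return table, summary


def compute_psth(
    spikes: SpikeTrain,
    trials: pd.DataFrame,
    align_event: str,
    group_by: str | None = None,
    group_lag: int = 0,
    window: tuple[float, float] = (-0.5, 1.0),
    bin_s: float = 0.001,
    smoothing_sigma_s: float = 0.015,
) -> dict[str, dict[str, np.ndarray]]:
    """Trial-averaged, Gaussian-smoothed firing rate around an event.

    Returns a mapping group-label -> {'time', 'mean', 'sem'}; when
    ``group_by`` is None a single group 'all' is returned. Groups with no
    trials are omitted.
    """
    anchors = trials[align_event].to_numpy(dtype=float)
    ok = np.isfinite(anchors)
    edges = np.arange(window[0], window[1] + bin_s / 2, bin_s)
    times = (edges[:-1] + edges[1:]) / 2.0
    n_bins = len(times)

    if group_by is None:
        labels = np.array(["all"] * len(trials), dtype=object)
    elif group_by == "choice":
        labels, _ = codings.lagged_choice_outcome(trials, group_lag)
    elif group_by == "outcome":
        _, rew = codings.lagged_choice_outcome(trials, group_lag)
        labels = np.where(rew == 1.0, "rewarded",
                          np.where(rew == 0.0, "unrewarded", "none"))
    else:
        raise ValueError("group_by must be None, 'choice' or 'outcome'")

    out = {}
    for label in pd.unique(labels[ok]):
        if label == "none":
            continue
        sel = np.flatnonzero(ok & (labels == label))
        if sel.size == 0:
            continue
        per_trial = np.empty((sel.size, n_bins))
        for i, t in enumerate(sel):
            rel = spikes.spike_times - anchors[t]
            counts, _ = np.histogram(rel, bins=edges)
            per_trial[i] = counts / bin_s
        if smoothing_sigma_s > 0:
            per_trial = gaussian_filter1d(
                per_trial, sigma=smoothing_sigma_s / bin_s, axis=1
            )
        out[str(label)] = {
            "time": times,
            "mean": per_trial.mean(axis=0),
            "sem": per_trial.std(axis=0, ddof=1) / np.sqrt(sel.size)
            if sel.size > 1 else np.zeros(n_bins),
        }
    return out
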