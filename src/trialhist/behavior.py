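"""History-dependent logistic choice models and inactivation analyses.

The response is P(left choice). The linear predictor always contains a
bias and two clamped odor-strength terms; the extended models add lagged
choice/outcome regressors, the muscimol model a binary session regressor,
and the reduced model a single 1-back choice term.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from . import codings

MODEL_TAGS = ("simple", "extended1", "extended2", "muscimol", "reduced_choice1")

IRLS_TOL = 1e-8
IRLS_MAX_ITER = 100
#: |coefficient| beyond which a fit is treated as separated
SEPARATION_BOUND = 15.0


class SeparationWarning(UserWarning):
    pass


@dataclass
class ChoiceDesign:
    """Per-trial regressor matrix and response for one logistic model."""

    X: pd.DataFrame  # included trials only; first column is the bias
    y: np.ndarray  # 1 = left choice
    included_mask: np.ndarray  # over the original trial table
    model_tag: str
    trial_rows: np.ndarray  # original row index of each design row
    session_ids: np.ndarray = field(default=None)


@dataclass
class LogisticFit:
    coefficients: dict[str, float]
    covariance: np.ndarray
    ci95: dict[str, tuple[float, float]]
    log_likelihood: float
    n_trials_used: int
    model_tag: str
    converged: bool = True
    separation: bool = False

    def __getitem__(self, name: str) -> float:
        return self.coefficients[name]


def _model_lags(model_tag: str, max_lag: int | None) -> int:
    if model_tag == "simple":
        return 0
    if model_tag == "extended1":
        return 1
    if model_tag == "extended2":
        return 2
    if model_tag in ("muscimol", "reduced_choice1"):
        return 0
    raise ValueError(f"unknown model_tag {model_tag!r}; expected one of {MODEL_TAGS}")


def build_design(
    trials: pd.DataFrame, model_tag: str, max_lag: int | None = None
) -> ChoiceDesign:
    """Construct the regressor matrix for ``model_tag`` from a trial table.

    Trials are excluded when no reward port was entered within 1.5 s of
    odor-port exit (or no choice was made); lagged regressors never cross
    session boundaries and code excluded/late-restart predecessors as 0.
    """
    if model_tag not in MODEL_TAGS:
        raise ValueError(f"unknown model_tag {model_tag!r}; expected one of {MODEL_TAGS}")
    for col in ("odor_port_entry",):
        per_session = trials.groupby("session_id", sort=False)[col]
        if not per_session.apply(lambda s: s.is_monotonic_increasing).all():
            raise ValueError("trials must be time-sorted within each session")

    cols: dict[str, np.ndarray] = {"bias": np.ones(len(trials))}
    cols.update(codings.odor_columns(trials))
    if model_tag == "muscimol":
        cond = trials["condition"].to_numpy()
        cols["muscimol"] = (cond == "muscimol").astype(float)
    n_lags = _model_lags(model_tag, max_lag)
    if max_lag is not None:
        n_lags = max_lag
    for lag in range(1, n_lags + 1):
        cols.update(codings.behavioral_lag_columns(trials, lag))
    if model_tag == "reduced_choice1":
        lag_cols = codings.behavioral_lag_columns(trials, 1)
        cols["choice_1"] = lag_cols["choice_1"]

    included = codings.inclusion_mask(trials)
    X = pd.DataFrame(cols).loc[included].reset_index(drop=True)
    y = (trials.loc[included, "choice"].to_numpy() == codings.CHOICE_LEFT).astype(float)
    return ChoiceDesign(
        X=X,
        y=y,
        included_mask=included,
        model_tag=model_tag,
        trial_rows=np.flatnonzero(included),
        session_ids=trials.loc[included, "session_id"].to_numpy(),
    )


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, rmat = np.linalg.qr(X)
        diag = np.abs(np.diag(rmat))
        bad = [names[i] for i in np.flatnonzero(diag < 1e-10 * diag.max())]
        raise ValueError(f"design matrix is singular; collinear columns: {bad or names}")


def _irls(
    X: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float, bool, bool]:
    n, p = X.shape
    beta = np.zeros(p)
    converged = False
    xtwx = np.eye(p)
    for _ in range(IRLS_MAX_ITER):
        eta = X @ beta
        mu = expit(eta)
        w = np.maximum(mu * (1.0 - mu), 1e-12)
        xtwx = (X * w[:, None]).T @ X
        grad = X.T @ (y - mu)
        try:
            step = np.linalg.solve(xtwx, grad)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.max(np.abs(step)) < IRLS_TOL:
            converged = True
            break
    eta = X @ beta
    mu = np.clip(expit(eta), 1e-12, 1.0 - 1e-12)
    ll = float(np.sum(y * np.log(mu) + (1.0 - y) * np.log(1.0 - mu)))
    separation = bool(np.max(np.abs(beta)) > SEPARATION_BOUND) or (
        len(np.unique(y)) < 2
    )
    w = np.maximum(mu * (1.0 - mu), 1e-12)
    xtwx = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(xtwx)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
    return beta, cov, ll, converged, separation


def fit_choice_model(design: ChoiceDesign) -> LogisticFit:
    """Maximum-likelihood logistic fit with Wald 95% confidence intervals."""
    names = list(design.X.columns)
    X = design.X.to_numpy(dtype=float)
    y = np.asarray(design.y, dtype=float)
    if len(y) == 0:
        raise ValueError("no included trials to fit")
    _check_rank(X, names)
    if len(np.unique(y)) < 2:
        warnings.warn(
            "all responses identical; estimates are separated", SeparationWarning
        )
    beta, cov, ll, converged, separation = _irls(X, y)
    if separation and len(np.unique(y)) == 2:
        warnings.warn(
            "possible perfect separation; coefficients diverged", SeparationWarning
        )
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    z = stats.norm.ppf(0.975)
    ci = {nm: (b - z * s, b + z * s) for nm, b, s in zip(names, beta, se)}
    return LogisticFit(
        coefficients=dict(zip(names, beta)),
        covariance=cov,
        ci95=ci,
        log_likelihood=ll,
        n_trials_used=len(y),
        model_tag=design.model_tag,
        converged=converged,
        separation=separation,
    )


def predict_proba(fit: LogisticFit, X: pd.DataFrame) -> np.ndarray:
    beta = np.array([fit.coefficients[c] for c in X.columns])
    return expit(X.to_numpy(dtype=float) @ beta)


_PAIRS = {
    "simple_vs_ext1": ("simple", "extended1"),
    "ext1_vs_ext2": ("extended1", "extended2"),
}


def compare_models_cv(
    trials: pd.DataFrame,
    pair: str = "simple_vs_ext1",
    n_repeats: int = 50,
    seed: int | None = None,
    stratify: bool = True,
    deterministic: bool = False,
) -> tuple[pd.DataFrame, float]:
    """Cross-validated predictive-accuracy comparison for one mouse.

    Per repeat and session: a random half of that session's included
    trials is held out; both models are fitted on all remaining trials of
    the mouse; simulated choices are drawn on the held-out trials from
    each model's fitted probabilities; accuracy is the percentage of
    held-out trials whose simulated choice matches the actual choice.

    Returns a per-session table (session_id, mean_improvement in
    percentage points) and the one-tailed paired t-test p-value across
    sessions for improvement > 0.
    """
    if pair not in _PAIRS:
        raise ValueError(f"pair must be one of {sorted(_PAIRS)}")
    tag_a, tag_b = _PAIRS[pair]
    rng = np.random.default_rng(seed)
    design_a = build_design(trials, tag_a)
    design_b = build_design(trials, tag_b)
    assert np.array_equal(design_a.trial_rows, design_b.trial_rows)
    sessions = pd.unique(design_a.session_ids)
    y = design_a.y
    odor = trials.loc[design_a.trial_rows, "odor_left_fraction"].to_numpy()

    rows = []
    for sid in sessions:
        in_session = np.flatnonzero(design_a.session_ids == sid)
        improvements = []
        for _ in range(n_repeats):
            test_idx = _split_half(in_session, odor[in_session], rng, stratify)
            if test_idx.size == 0:
                warnings.warn(f"session {sid}: empty test split; resplitting")
                test_idx = _split_half(in_session, odor[in_session], rng, False)
            train_mask = np.ones(len(y), dtype=bool)
            train_mask[test_idx] = False
            accs = []
            for design in (design_a, design_b):
                sub = ChoiceDesign(
                    X=design.X.loc[train_mask].reset_index(drop=True),
                    y=design.y[train_mask],
                    included_mask=design.included_mask,
                    model_tag=design.model_tag,
                    trial_rows=design.trial_rows[train_mask],
                )
                fit = fit_choice_model(sub)
                p = predict_proba(fit, design.X.iloc[test_idx])
                if deterministic:
                    sim = (p > 0.5).astype(float)
                else:
                    sim = (rng.random(p.size) < p).astype(float)
                accs.append(100.0 * np.mean(sim == y[test_idx]))
            improvements.append(accs[1] - accs[0])
        rows.append({"session_id": sid, "mean_improvement": float(np.mean(improvements))})
    table = pd.DataFrame(rows)
    if len(table) >= 2:
        _, p_value = stats.ttest_1samp(
            table["mean_improvement"], 0.0, alternative="greater"
        )
    else:
        p_value = np.nan
    return table, float(p_value)


def _split_half(
    idx: np.ndarray, strata: np.ndarray, rng: np.random.Generator, stratify: bool
) -> np.ndarray:
    if not stratify:
        k = len(idx) // 2
        return rng.choice(idx, size=k, replace=False)
    picks = []
    for s in np.unique(strata):
        pool = idx[strata == s]
        k = len(pool) // 2
        if k:
            picks.append(rng.choice(pool, size=k, replace=False))
    return np.sort(np.concatenate(picks)) if picks else np.empty(0, dtype=int)


def fit_inactivation(trials: pd.DataFrame) -> LogisticFit:
    """Muscimol-model fit on a pooled saline/muscimol/saline session set."""
    cond = trials["condition"].to_numpy()
    if "baseline" in cond or not {"saline", "muscimol"} <= set(cond):
        raise ValueError(
            "inactivation fit requires saline and muscimol condition labels"
        )
    sessions = trials.groupby("session_id")["condition"].first()
    if (sessions == "muscimol").sum() != 1 or (sessions == "saline").sum() != 2:
        raise ValueError("expected one muscimol and two saline sessions")
    return fit_choice_model(build_design(trials, "muscimol"))


def fit_reduced_choice1(trials: pd.DataFrame, condition: str) -> LogisticFit:
    """Reduced 1-back model (bias, odors, choice_1) on one condition only."""
    if condition not in ("saline", "muscimol"):
        raise ValueError("condition must be 'saline' or 'muscimol'")
    subset = trials.loc[trials["condition"] == condition].reset_index(drop=True)
    if subset.empty:
        raise ValueError(f"no trials with condition {condition!r}")
    return fit_choice_model(build_design(subset, "reduced_choice1"))


def compare_choice1_conditions(
    session_sets: list[pd.DataFrame],
) -> dict[str, float | list[float]]:
    """One-tailed Mann-Whitney test: beta_choice1 lower under muscimol.

    Each element of ``session_sets`` is a pooled saline/muscimol/saline
    trial table; the reduced model is fitted per condition per set.
    """
    if len(session_sets) < 2:
        raise ValueError("need >= 2 session sets for the across-set comparison")
    mus, sal = [], []
    for t in session_sets:
        mus.append(fit_reduced_choice1(t, "muscimol").coefficients["choice_1"])
        sal.append(fit_reduced_choice1(t, "saline").coefficients["choice_1"])
    u, p = stats.mannwhitneyu(mus, sal, alternative="less")
    return {"beta_choice1_muscimol": mus, "beta_choice1_saline": sal,
            "U": float(u), "p_value": float(p)}


def movement_metrics(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-trial latency, movement duration and return duration (seconds)."""
    go = trials["go"].to_numpy(dtype=float)
    exit_t = trials["odor_port_exit"].to_numpy(dtype=float)
    rp_entry = trials["reward_port_entry"].to_numpy(dtype=float)
    rp_exit = trials["reward_port_exit"].to_numpy(dtype=float)
    entry = trials["odor_port_entry"].to_numpy(dtype=float)
    session = trials["session_id"].to_numpy()

    latency = exit_t - go
    movement = rp_entry - exit_t
    ret = np.full(len(trials), np.nan)
    if len(trials) > 1:
        same = session[1:] == session[:-1]
        ret[:-1] = np.where(same, entry[1:] - rp_exit[:-1], np.nan)
    for name, vals in (("latency", latency), ("movement", movement), ("return", ret)):
        finite = vals[np.isfinite(vals)]
        if finite.size and finite.min() < 0:
            raise ValueError(f"negative {name} duration: corrupt event times")
    prev_choice, _ = codings.lagged_choice_outcome(trials, 1)
    return pd.DataFrame(
        {
            "session_id": session,
            "mouse_id": trials["mouse_id"].to_numpy(),
            "condition": trials["condition"].to_numpy(),
            "prev_choice": prev_choice,
            "latency_s": latency,
            "movement_duration_s": movement,
            "return_duration_s": ret,
        }
    )


def movement_comparisons(
    metrics: pd.DataFrame, by: str = "condition"
) -> pd.DataFrame:
    """Two-tailed unpaired t-tests on each duration metric.

    ``by='condition'`` contrasts muscimol vs saline (pooled);
    ``by='prev_choice'`` contrasts previous-left vs previous-right,
    separately per mouse.
    """
    measures = ["latency_s", "movement_duration_s", "return_duration_s"]
    rows = []
    if by == "condition":
        a = metrics[metrics["condition"] == "muscimol"]
        b = metrics[metrics["condition"] == "saline"]
        for m in measures:
            x, yv = a[m].dropna(), b[m].dropna()
            t, p = stats.ttest_ind(x, yv)
            rows.append({"mouse_id": "all", "measure": m, "t": float(t),
                         "p_value": float(p),
                         "mean_muscimol": float(x.mean()),
                         "mean_saline": float(yv.mean())})
    elif by == "prev_choice":
        for mouse, g in metrics.groupby("mouse_id"):
            a = g[g["prev_choice"] == codings.CHOICE_LEFT]
            b = g[g["prev_choice"] == codings.CHOICE_RIGHT]
            for m in measures:
                x, yv = a[m].dropna(), b[m].dropna()
                if len(x) < 2 or len(yv) < 2:
                    continue
                t, p = stats.ttest_ind(x, yv)
                rows.append({"mouse_id": mouse, "measure": m, "t": float(t),
                             "p_value": float(p)})
    else:
        raise ValueError("by must be 'condition' or 'prev_choice'")
    return pd.DataFrame(rows)


_CONDITIONS = {
    "none": None,
    "prev_left_rew": (codings.CHOICE_LEFT, 1.0),
    "prev_left_unrew": (codings.CHOICE_LEFT, 0.0),
    "prev_right_rew": (codings.CHOICE_RIGHT, 1.0),
    "prev_right_unrew": (codings.CHOICE_RIGHT, 0.0),
}


def psychometric_conditional(
    trials: pd.DataFrame, condition_on: str = "none"
) -> tuple[pd.DataFrame, LogisticFit]:
    """Per-mixture left-choice fraction (± s.e.) plus a Simple-model fit.

    Optionally conditions on the previous trial's choice and outcome.
    """
    if condition_on not in _CONDITIONS:
        raise ValueError(f"condition_on must be one of {sorted(_CONDITIONS)}")
    subset = trials.reset_index(drop=True)
    if _CONDITIONS[condition_on] is not None:
        want_choice, want_rew = _CONDITIONS[condition_on]
        prev_choice, prev_rew = codings.lagged_choice_outcome(subset, 1)
        keep = (prev_choice == want_choice) & (prev_rew == want_rew)
        subset = subset.loc[keep].reset_index(drop=True)
        if subset.empty:
            warnings.warn(f"no trials for condition {condition_on!r}")
            return pd.DataFrame(
                columns=["odor_left_fraction", "frac_left", "se", "n"]
            ), None
    included = codings.inclusion_mask(subset)
    sub = subset.loc[included]
    rows = []
    for frac, g in sub.groupby("odor_left_fraction"):
        n = len(g)
        p_left = float((g["choice"] == codings.CHOICE_LEFT).mean())
        rows.append({
            "odor_left_fraction": float(frac),
            "frac_left": p_left,
            "se": float(np.sqrt(p_left * (1 - p_left) / n)) if n else np.nan,
            "n": n,
        })
    curve = pd.DataFrame(rows).sort_values("odor_left_fraction", ignore_index=True)
    fit = fit_choice_model(build_design(subset, "simple"))
    return curve, fit
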