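"""Synthetic sessions with known ground truth.

Generates task-event streams, history-dependent choices and outcomes,
inhomogeneous-Poisson spike trains with event-locked modulations, and
saline/muscimol session sets, so that every analysis stage can be tested
against generator truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import codings
from .io import SpikeTrain, TRIAL_COLUMNS

DEFAULT_ODOR_SET = (0.95, 0.80, 0.60, 0.50, 0.40, 0.20, 0.05)

#: delays are truncated-normal with a hard floor (s)
DELAY_FLOOR_S = 0.010


@dataclass(frozen=True)
class TaskConfig:
    """Timing and session-size parameters of the simulated task."""

    odor_set: tuple[float, ...] = DEFAULT_ODOR_SET
    n_trials_mean: int = 451
    n_trials_sd: int = 115
    valve_delay_mean_s: float = 0.144
    valve_delay_sd_s: float = 0.064
    go_delay_mean_s: float = 0.434
    go_delay_sd_s: float = 0.068
    reward_delay_mean_s: float = 0.041
    reward_delay_sd_s: float = 0.032
    reaction_mean_s: float = 0.200
    reaction_sd_s: float = 0.050
    movement_duration_mean_s: float = 0.350
    movement_duration_sd_s: float = 0.100
    drink_duration_mean_s: float = 1.000
    drink_duration_sd_s: float = 0.200
    inter_trial_mean_s: float = 0.500
    inter_trial_sd_s: float = 0.200
    no_choice_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if any(not (0.0 <= f <= 1.0) for f in self.odor_set):
            raise ValueError("odor fractions must lie in [0, 1]")
        for name in (
            "valve_delay_mean_s",
            "go_delay_mean_s",
            "reward_delay_mean_s",
            "reaction_mean_s",
            "movement_duration_mean_s",
            "drink_duration_mean_s",
            "inter_trial_mean_s",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 <= self.no_choice_rate < 1.0):
            raise ValueError("no_choice_rate must lie in [0, 1)")


@dataclass(frozen=True)
class BehaviorParams:
    """Generating coefficients of the history-dependent choice model.

    Lag lists are ordered 1-back first; all three must share a length.
    """

    beta0: float = 0.0
    beta_odor_L: float = 3.0
    beta_odor_R: float = 3.0
    beta_choice: tuple[float, ...] = (0.5,)
    beta_outcome_L: tuple[float, ...] = (0.3,)
    beta_outcome_R: tuple[float, ...] = (-0.3,)
    beta_muscimol: float = 0.0
    lapse_rate: float = 0.0

    def __post_init__(self) -> None:
        if not (len(self.beta_choice) == len(self.beta_outcome_L)
                == len(self.beta_outcome_R)):
            raise ValueError("lag coefficient lists must share a length")
        if not (0.0 <= self.lapse_rate < 0.5):
            raise ValueError("lapse_rate must lie in [0, 0.5)")


@dataclass(frozen=True)
class Modulation:
    """One additive, event-locked firing-rate modulation."""

    regressor: str  # prev_choice | prev_outcome | cur_choice | cur_outcome
    amplitude: float  # spikes/s, multiplies the -1/0/+1 coding
    align_event: str  # column of the trial table
    window: tuple[float, float]  # (start_s, end_s) relative to align_event

    def __post_init__(self) -> None:
        valid = {"prev_choice", "prev_outcome", "cur_choice", "cur_outcome"}
        if self.regressor not in valid:
            raise ValueError(f"unknown regressor {self.regressor!r}")
        if self.window[1] <= self.window[0]:
            raise ValueError("modulation window must have positive length")


@dataclass(frozen=True)
class NeuronParams:
    unit_id: str = "u0"
    baseline_rate: float = 10.0
    modulation_terms: tuple[Modulation, ...] = ()
    recorded_side: str = "left"
    noise_model: str = "poisson"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_rate < 0:
            raise ValueError("baseline_rate must be >= 0")
        if self.noise_model != "poisson":
            raise ValueError("only the 'poisson' noise model is supported")


@dataclass
class SimulatedSession:
    trials: pd.DataFrame
    spikes: list[SpikeTrain]
    behavior_params: BehaviorParams
    neuron_params: list[NeuronParams]


def _trunc_normal(
    rng: np.random.Generator, mean: float, sd: float, size: int
) -> np.ndarray:
    draws = rng.normal(mean, sd, size)
    return np.maximum(draws, DELAY_FLOOR_S)


def _as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def simulate_trial_events(
    cfg: TaskConfig,
    n_trials: int,
    rng: np.random.Generator | int | None = None,
    session_id: str = "s0",
    mouse_id: str = "m0",
    condition: str = "baseline",
) -> pd.DataFrame:
    """Event times and odor fractions for ``n_trials`` trials (no choices yet)."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = _as_rng(cfg.seed if rng is None else rng)
    valve = _trunc_normal(rng, cfg.valve_delay_mean_s, cfg.valve_delay_sd_s, n_trials)
    go = _trunc_normal(rng, cfg.go_delay_mean_s, cfg.go_delay_sd_s, n_trials)
    react = _trunc_normal(rng, cfg.reaction_mean_s, cfg.reaction_sd_s, n_trials)
    move = _trunc_normal(
        rng, cfg.movement_duration_mean_s, cfg.movement_duration_sd_s, n_trials
    )
    drink = _trunc_normal(
        rng, cfg.drink_duration_mean_s, cfg.drink_duration_sd_s, n_trials
    )
    iti = _trunc_normal(rng, cfg.inter_trial_mean_s, cfg.inter_trial_sd_s, n_trials)
    odor = rng.choice(np.asarray(cfg.odor_set, dtype=float), size=n_trials)

    trial_span = valve + go + react + move + drink
    starts = np.concatenate([[iti[0]], iti[1:]]).cumsum() + np.concatenate(
        [[0.0], trial_span[:-1]]
    ).cumsum()
    entry = starts
    valve_open = entry + valve
    go_t = valve_open + go
    exit_t = go_t + react
    reward_entry = exit_t + move
    reward_exit = reward_entry + drink
    return pd.DataFrame(
        {
            "session_id": session_id,
            "mouse_id": mouse_id,
            "trial_index": np.arange(n_trials),
            "odor_port_entry": entry,
            "valve_open": valve_open,
            "go": go_t,
            "odor_port_exit": exit_t,
            "reward_port_entry": reward_entry,
            "reward_port_exit": reward_exit,
            "odor_left_fraction": odor,
            "choice": "none",
            "rewarded": np.nan,
            "condition": condition,
        }
    )[TRIAL_COLUMNS]


def _outcome_for(choice: str, f_left: float, u: float) -> float:
    """Reward rule: dominant-odor side pays; 50/50 pays each port with p=0.5."""
    if choice == codings.CHOICE_NONE:
        return np.nan
    if not np.isfinite(f_left):
        raise ValueError("odor_left_fraction missing")
    if f_left == 0.5:
        return 1.0 if u < 0.5 else 0.0
    dominant = codings.CHOICE_LEFT if f_left > 0.5 else codings.CHOICE_RIGHT
    return 1.0 if choice == dominant else 0.0


def simulate_choices(
    trials: pd.DataFrame,
    params: BehaviorParams,
    rng: np.random.Generator | int | None = None,
    no_choice_rate: float = 0.02,
    extra_eta: np.ndarray | None = None,
) -> pd.DataFrame:
    """Sequentially draw choices (and outcomes) from the extended logistic model.

    Outcomes are drawn alongside choices because lagged outcome regressors
    feed back into subsequent trials. History regressors follow the same
    validity rules the analyses use (within session; no-choice coding for
    excluded predecessors and late restarts).
    """
    out = trials.copy().reset_index(drop=True)
    n = len(out)
    rng = _as_rng(rng)
    f_left = out["odor_left_fraction"].to_numpy(dtype=float)
    x_l = np.maximum(0.0, (f_left - 0.5) / 0.5)
    x_r = np.maximum(0.0, (0.5 - f_left) / 0.5)
    x_mus = (out["condition"].to_numpy() == "muscimol").astype(float)
    if extra_eta is None:
        extra_eta = np.zeros(n)

    entry = out["odor_port_entry"].to_numpy(dtype=float)
    exit_t = out["odor_port_exit"].to_numpy(dtype=float)
    reward_entry = out["reward_port_entry"].to_numpy(dtype=float)
    reward_exit = out["reward_port_exit"].to_numpy(dtype=float)
    session = out["session_id"].to_numpy()
    move_ok = (reward_entry - exit_t) <= codings.REENTRY_LIMIT_S
    restart_ok = np.ones(n, dtype=bool)
    if n > 1:
        same = session[1:] == session[:-1]
        gap = entry[1:] - reward_exit[:-1]
        restart_ok[:-1] = ~same | (gap <= codings.REENTRY_LIMIT_S)

    n_lags = len(params.beta_choice)
    bc = params.beta_choice
    bol = params.beta_outcome_L
    bor = params.beta_outcome_R

    choices = np.empty(n, dtype=object)
    rewards = np.full(n, np.nan)
    # history codings of already-simulated trials (0 when invalid)
    xc = np.zeros(n)
    xol = np.zeros(n)
    xor_ = np.zeros(n)
    valid = np.zeros(n, dtype=bool)

    for t in range(n):
        eta = (
            params.beta0
            + params.beta_odor_L * x_l[t]
            + params.beta_odor_R * x_r[t]
            + params.beta_muscimol * x_mus[t]
            + extra_eta[t]
        )
        for lag in range(1, n_lags + 1):
            j = t - lag
            if j >= 0 and session[j] == session[t] and valid[j]:
                eta += bc[lag - 1] * xc[j] + bol[lag - 1] * xol[j] + bor[lag - 1] * xor_[j]
        if rng.random() < no_choice_rate:
            choice = codings.CHOICE_NONE
        else:
            p = 1.0 / (1.0 + np.exp(-eta))
            if params.lapse_rate and rng.random() < params.lapse_rate:
                left = rng.random() < 0.5
            else:
                left = rng.random() < p
            choice = codings.CHOICE_LEFT if left else codings.CHOICE_RIGHT
        choices[t] = choice
        if choice != codings.CHOICE_NONE:
            rewards[t] = _outcome_for(choice, f_left[t], rng.random())
            is_left = choice == codings.CHOICE_LEFT
            xc[t] = 1.0 if is_left else -1.0
            signed = 2.0 * rewards[t] - 1.0
            xol[t] = signed if is_left else 0.0
            xor_[t] = 0.0 if is_left else signed
            valid[t] = move_ok[t] and restart_ok[t]

    out["choice"] = choices
    out["rewarded"] = rewards
    none = choices == codings.CHOICE_NONE
    out.loc[none, ["reward_port_entry", "reward_port_exit"]] = np.nan
    return out


def assign_outcomes(trials: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Assign rewards given choices (standalone; choices must be present)."""
    out = trials.copy().reset_index(drop=True)
    rng = np.random.default_rng(seed)
    rewards = np.full(len(out), np.nan)
    for i, (choice, f) in enumerate(
        zip(out["choice"], out["odor_left_fraction"].to_numpy(dtype=float))
    ):
        rewards[i] = _outcome_for(choice, f, rng.random())
    out["rewarded"] = rewards
    return out


_REGRESSOR_LAG = {
    "prev_choice": 1,
    "prev_outcome": 1,
    "cur_choice": 0,
    "cur_outcome": 0,
}


def _modulation_signs(
    trials: pd.DataFrame, term: Modulation, recorded_side: str
) -> np.ndarray:
    lag = _REGRESSOR_LAG[term.regressor]
    x_choice, x_outcome = codings.neural_lag_columns(trials, lag, recorded_side)
    return x_choice if term.regressor.endswith("choice") else x_outcome


def simulate_spike_train(
    trials: pd.DataFrame,
    neuron: NeuronParams,
    rng: np.random.Generator | int | None = None,
) -> SpikeTrain:
    """Inhomogeneous-Poisson spikes: baseline plus event-locked modulations."""
    rng = _as_rng(neuron.seed if rng is None else rng)
    t_end = float(np.nanmax(trials[
        ["reward_port_exit", "reward_port_entry", "odor_port_exit"]
    ].to_numpy())) + 1.0

    # sweep events: (time, rate delta)
    deltas: list[tuple[float, float]] = [(0.0, neuron.baseline_rate),
                                         (t_end, -neuron.baseline_rate)]
    for term in neuron.modulation_terms:
        if term.align_event not in trials.columns:
            raise ValueError(f"unknown align event {term.align_event!r}")
        signs = _modulation_signs(trials, term, neuron.recorded_side)
        anchors = trials[term.align_event].to_numpy(dtype=float)
        for anchor, sign in zip(anchors, signs):
            if sign == 0.0 or not np.isfinite(anchor):
                continue
            lo = anchor + term.window[0]
            hi = anchor + term.window[1]
            if lo < 0.0 or hi > t_end:
                warnings.warn(
                    f"unit {neuron.unit_id}: modulation window clipped to "
                    "session bounds",
                    stacklevel=2,
                )
                lo, hi = max(lo, 0.0), min(hi, t_end)
            if hi > lo:
                deltas.append((lo, term.amplitude * sign))
                deltas.append((hi, -term.amplitude * sign))

    times = np.array([d[0] for d in deltas])
    amps = np.array([d[1] for d in deltas])
    order = np.argsort(times, kind="stable")
    times, amps = times[order], amps[order]
    edges = np.unique(times)
    # rate on [edges[i], edges[i+1]) = cumulative delta up to edges[i]
    cum = np.cumsum(
        np.add.reduceat(amps, np.searchsorted(times, edges, side="left"))
    )
    seg_lo, seg_hi = edges[:-1], edges[1:]
    rate = np.maximum(cum[:-1], 0.0)

    spikes: list[np.ndarray] = []
    counts = rng.poisson(rate * (seg_hi - seg_lo))
    for lo, hi, k in zip(seg_lo, seg_hi, counts):
        if k:
            spikes.append(rng.uniform(lo, hi, k))
    spike_times = np.sort(np.concatenate(spikes)) if spikes else np.empty(0)
    return SpikeTrain(
        unit_id=neuron.unit_id,
        mouse_id=str(trials["mouse_id"].iloc[0]),
        session_id=str(trials["session_id"].iloc[0]),
        recorded_side=neuron.recorded_side,
        spike_times=spike_times,
    )


def simulate_session(
    cfg: TaskConfig,
    params: BehaviorParams,
    neurons: list[NeuronParams] = (),
    seed: int = 0,
    session_id: str = "s0",
    mouse_id: str = "m0",
    condition: str = "baseline",
    n_trials: int | None = None,
    extra_eta: np.ndarray | None = None,
) -> SimulatedSession:
    """One full session: events, choices, outcomes, and spike trains."""
    rng = np.random.default_rng(seed)
    if n_trials is None:
        n_trials = max(20, int(round(rng.normal(cfg.n_trials_mean, cfg.n_trials_sd))))
    trials = simulate_trial_events(
        cfg, n_trials, rng, session_id=session_id, mouse_id=mouse_id,
        condition=condition,
    )
    trials = simulate_choices(
        trials, params, rng, no_choice_rate=cfg.no_choice_rate,
        extra_eta=extra_eta,
    )
    spikes = [simulate_spike_train(trials, nrn, rng) for nrn in neurons]
    return SimulatedSession(trials, spikes, params, list(neurons))


def simulate_mouse(
    cfg: TaskConfig,
    params: BehaviorParams,
    n_sessions: int = 12,
    seed: int = 0,
    mouse_id: str = "m0",
) -> pd.DataFrame:
    """Concatenated trial tables for one mouse across sessions."""
    seeds = np.random.SeedSequence(seed).spawn(n_sessions)
    tables = []
    for i, s in enumerate(seeds):
        sess = simulate_session(
            cfg, params, seed=s, session_id=f"{mouse_id}_s{i}", mouse_id=mouse_id
        )
        tables.append(sess.trials)
    return pd.concat(tables, ignore_index=True)


def simulate_inactivation_set(
    cfg: TaskConfig,
    params: BehaviorParams,
    delta_bias: float,
    choice1_scale: float,
    seed: int = 0,
    set_id: str = "set0",
    mouse_id: str = "m0",
) -> pd.DataFrame:
    """Saline-pre, muscimol, saline-post sessions as one concatenated table.

    The muscimol session's generator shifts the bias by ``delta_bias``
    and scales the 1-back choice coefficient by ``choice1_scale``.
    """
    if not (0.0 <= choice1_scale <= 1.0):
        raise ValueError("choice1_scale must lie in [0, 1]")
    mus_choice = (params.beta_choice[0] * choice1_scale,) + params.beta_choice[1:]
    mus_params = replace(
        params, beta0=params.beta0 + delta_bias, beta_choice=mus_choice
    )
    rng = np.random.default_rng(seed)
    tables = []
    for tag, p, cond in (
        ("pre", params, "saline"),
        ("mus", mus_params, "muscimol"),
        ("post", params, "saline"),
    ):
        n = max(20, int(round(rng.normal(cfg.n_trials_mean, cfg.n_trials_sd))))
        t = simulate_trial_events(
            cfg, n, rng, session_id=f"{set_id}_{tag}", mouse_id=mouse_id,
            condition=cond,
        )
        tables.append(simulate_choices(t, p, rng, no_choice_rate=cfg.no_choice_rate))
    return pd.concat(tables, ignore_index=True)


def simulate_linked_session(
    cfg: TaskConfig,
    params: BehaviorParams,
    n_units: int = 10,
    coupling: float = 1.0,
    rate_gain: float = 8.0,
    baseline_rate: float = 10.0,
    seed: int = 0,
    session_id: str = "s0",
    mouse_id: str = "m0",
    n_trials: int | None = None,
) -> SimulatedSession:
    """Session whose units share a per-trial latent with the choice process.

    Each unit's pre-stimulus rate is ``baseline + rate_gain * z_t`` and the
    same latent ``z_t`` adds ``coupling * z_t`` to the contralateral choice
    log-odds, producing a positive rate-to-preferred-choice slope. All
    units also carry a previous-choice modulation so they pass the
    selectivity screen.
    """
    rng = np.random.default_rng(seed)
    if n_trials is None:
        n_trials = max(20, int(round(rng.normal(cfg.n_trials_mean, cfg.n_trials_sd))))
    trials = simulate_trial_events(
        cfg, n_trials, rng, session_id=session_id, mouse_id=mouse_id
    )
    z = rng.normal(0.0, 1.0, n_trials)
    # contra (= right for a left implant) log-odds gain: eta is log-odds of LEFT
    extra = -coupling * z
    trials = simulate_choices(
        trials, params, rng, no_choice_rate=cfg.no_choice_rate, extra_eta=extra
    )

    entry = trials["odor_port_entry"].to_numpy(dtype=float)
    valve = trials["valve_open"].to_numpy(dtype=float)
    neurons = []
    spikes = []
    for u in range(n_units):
        nrn = NeuronParams(
            unit_id=f"{session_id}_u{u}",
            baseline_rate=baseline_rate,
            modulation_terms=(
                Modulation("prev_choice", 4.0, "odor_port_entry", (-0.05, 0.30)),
            ),
            recorded_side="left",
        )
        train = simulate_spike_train(trials, nrn, rng)
        # add latent-driven spikes in the pre-stimulus epoch
        extra_spikes = []
        for t in range(n_trials):
            lo, hi = entry[t], valve[t] + 0.100
            lam = max(0.0, rate_gain * z[t]) * (hi - lo)
            k = rng.poisson(lam)
            if k:
                extra_spikes.append(rng.uniform(lo, hi, k))
        if extra_spikes:
            merged = np.sort(
                np.concatenate([train.spike_times, *extra_spikes])
            )
            train = SpikeTrain(
                train.unit_id, train.mouse_id, train.session_id,
                train.recorded_side, merged,
            )
        neurons.append(nrn)
        spikes.append(train)
    return SimulatedSession(trials, spikes, params, neurons)
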