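"""Trial inclusion rules and regressor codings shared across analyses.

A trial enters a choice model only if a reward port was reached within
1.5 s of odor-port exit. When a trial serves as the *predecessor* for a
lagged regressor it additionally counts as "no choice" if the next trial
was not initiated within 1.5 s of reward-port exit.

Two coding frames are used:

* behavioral (left/right): left = +1, right = -1, no choice = 0;
  outcome split into separate left- and right-side terms.
* neural (ipsi/contra): contra = +1, ipsi = -1, derived from the
  recorded hemisphere; outcome rewarded = +1, unrewarded = -1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: maximum allowed delay (s) between odor-port exit and reward-port entry
REENTRY_LIMIT_S = 1.5

CHOICE_LEFT = "L"
CHOICE_RIGHT = "R"
CHOICE_NONE = "none"


def inclusion_mask(trials: pd.DataFrame) -> np.ndarray:
    """Boolean mask of trials usable as model responses.

    A trial is included when a choice was made and the reward port was
    entered within ``REENTRY_LIMIT_S`` of odor-port exit.
    """
    choice = trials["choice"].to_numpy()
    made = (choice == CHOICE_LEFT) | (choice == CHOICE_RIGHT)
    exit_t = trials["odor_port_exit"].to_numpy(dtype=float)
    entry_t = trials["reward_port_entry"].to_numpy(dtype=float)
    delay = entry_t - exit_t
    timely = np.isfinite(delay) & (delay <= REENTRY_LIMIT_S)
    return made & timely


def history_valid_mask(trials: pd.DataFrame) -> np.ndarray:
    """Mask of trials that count as real choices when referenced as history.

    Requires the trial itself to be included *and* the next trial in the
    same session (if any) to have been initiated within
    ``REENTRY_LIMIT_S`` of this trial's reward-port exit.
    """
    included = inclusion_mask(trials)
    reward_exit = trials["reward_port_exit"].to_numpy(dtype=float)
    next_entry = np.full(len(trials), np.nan)
    entry = trials["odor_port_entry"].to_numpy(dtype=float)
    session = trials["session_id"].to_numpy()
    if len(trials) > 1:
        same_session = session[1:] == session[:-1]
        next_entry[:-1] = np.where(same_session, entry[1:], np.nan)
    gap = next_entry - reward_exit
    # last trial of a session has no successor; the initiation rule is moot
    has_next = np.isfinite(next_entry)
    timely_restart = ~has_next | (np.isfinite(gap) & (gap <= REENTRY_LIMIT_S))
    return included & timely_restart


def effective_history_choice(trials: pd.DataFrame) -> np.ndarray:
    """Per-trial choice token with history-invalid trials mapped to 'none'."""
    valid = history_valid_mask(trials)
    choice = trials["choice"].to_numpy(dtype=object).copy()
    choice[~valid] = CHOICE_NONE
    return choice


def _lag_reference(trials: pd.DataFrame, lag: int) -> np.ndarray:
    """Integer index of the trial ``lag`` back within the same session, or -1."""
    n = len(trials)
    idx = np.arange(n) - lag
    session = trials["session_id"].to_numpy()
    ok = idx >= 0
    ref = np.where(ok, idx, 0)
    same = ok & (session[ref] == session)
    return np.where(same, idx, -1)


def lagged_choice_outcome(
    trials: pd.DataFrame, lag: int
) -> tuple[np.ndarray, np.ndarray]:
    """(choice token, rewarded) of the trial ``lag`` back, within-session.

    Out-of-session or history-invalid references yield ('none', nan).
    For ``lag == 0`` the current trial's own choice/outcome are returned,
    with non-included trials mapped to 'none'.
    """
    if lag == 0:
        valid = inclusion_mask(trials)
        choice = trials["choice"].to_numpy(dtype=object).copy()
        rewarded = trials["rewarded"].to_numpy(dtype=float).copy()
        choice[~valid] = CHOICE_NONE
        rewarded[~valid] = np.nan
        return choice, rewarded
    eff_choice = effective_history_choice(trials)
    rewarded = trials["rewarded"].to_numpy(dtype=float)
    ref = _lag_reference(trials, lag)
    out_choice = np.full(len(trials), CHOICE_NONE, dtype=object)
    out_rew = np.full(len(trials), np.nan)
    has = ref >= 0
    out_choice[has] = eff_choice[ref[has]]
    out_rew[has] = rewarded[ref[has]]
    none = out_choice == CHOICE_NONE
    out_rew[none] = np.nan
    return out_choice, out_rew


def behavioral_lag_columns(
    trials: pd.DataFrame, lag: int
) -> dict[str, np.ndarray]:
    """Left/right-frame lagged regressors x_choice, x_outcome_L, x_outcome_R."""
    choice, rewarded = lagged_choice_outcome(trials, lag)
    x_choice = np.where(choice == CHOICE_LEFT, 1.0,
                        np.where(choice == CHOICE_RIGHT, -1.0, 0.0))
    rew = np.nan_to_num(rewarded, nan=0.0)
    signed = 2.0 * rew - 1.0  # +1 rewarded, -1 unrewarded
    x_out_l = np.where((choice == CHOICE_LEFT) & np.isfinite(rewarded), signed, 0.0)
    x_out_r = np.where((choice == CHOICE_RIGHT) & np.isfinite(rewarded), signed, 0.0)
    return {
        f"choice_{lag}": x_choice,
        f"outcome_L_{lag}": x_out_l,
        f"outcome_R_{lag}": x_out_r,
    }


def odor_columns(trials: pd.DataFrame) -> dict[str, np.ndarray]:
    """Odor-strength regressors, clamped at 0 for the non-dominant side."""
    f_left = trials["odor_left_fraction"].to_numpy(dtype=float)
    if np.any(~np.isfinite(f_left)):
        raise ValueError("odor_left_fraction contains missing values")
    x_l = np.maximum(0.0, (f_left - 0.5) / 0.5)
    x_r = np.maximum(0.0, ((1.0 - f_left) - 0.5) / 0.5)
    return {"odor_L": x_l, "odor_R": x_r}


def contra_sign(recorded_side: str) -> dict[str, float]:
    """Map choice token -> neural-frame sign (contra = +1, ipsi = -1)."""
    if recorded_side == "left":
        return {CHOICE_LEFT: -1.0, CHOICE_RIGHT: 1.0, CHOICE_NONE: 0.0}
    if recorded_side == "right":
        return {CHOICE_LEFT: 1.0, CHOICE_RIGHT: -1.0, CHOICE_NONE: 0.0}
    raise ValueError(f"recorded_side must be 'left' or 'right', got {recorded_side!r}")


def neural_lag_columns(
    trials: pd.DataFrame, lag: int, recorded_side: str
) -> tuple[np.ndarray, np.ndarray]:
    """Ipsi/contra-frame (x_choice, x_outcome) for the trial ``lag`` back."""
    choice, rewarded = lagged_choice_outcome(trials, lag)
    sign = contra_sign(recorded_side)
    x_choice = np.array([sign[c] for c in choice])
    x_outcome = np.where(
        (choice != CHOICE_NONE) & np.isfinite(rewarded),
        2.0 * np.nan_to_num(rewarded) - 1.0,
        0.0,
    )
    return x_choice, x_outcome
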