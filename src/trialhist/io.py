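"""Delimited-text readers/writers for trial tables and spike trains.

All interchange is CSV with a header row; times are seconds from session
start in double precision. Trial tables carry one row per trial; spike
files carry one row per spike plus a companion unit-metadata file so
that silent units survive a round trip.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

TRIAL_COLUMNS = [
    "session_id",
    "mouse_id",
    "trial_index",
    "odor_port_entry",
    "valve_open",
    "go",
    "odor_port_exit",
    "reward_port_entry",
    "reward_port_exit",
    "odor_left_fraction",
    "choice",
    "rewarded",
    "condition",
]

TIME_COLUMNS = [
    "odor_port_entry",
    "valve_open",
    "go",
    "odor_port_exit",
    "reward_port_entry",
    "reward_port_exit",
]

CHOICE_TOKENS = {"L", "R", "none"}
CONDITION_TOKENS = {"saline", "muscimol", "baseline"}


class TrialTableError(ValueError):
    """Raised when a trial table fails validation."""


@dataclass
class SpikeTrain:
    """Spike times for one unit, in seconds from session start."""

    unit_id: str
    mouse_id: str
    session_id: str
    recorded_side: str
    spike_times: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.spike_times.size and self.spike_times.min() < 0:
            raise ValueError(f"unit {self.unit_id}: negative spike time")
        if self.recorded_side not in ("left", "right"):
            raise ValueError(
                f"unit {self.unit_id}: recorded_side must be 'left' or 'right'"
            )
        self.spike_times = np.sort(self.spike_times)


def validate_trials(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize a trial table; returns a canonical copy."""
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise TrialTableError(f"missing required columns: {missing}")
    out = df[TRIAL_COLUMNS].copy().reset_index(drop=True)
    for col in TIME_COLUMNS + ["odor_left_fraction", "rewarded"]:
        out[col] = pd.to_numeric(out[col], errors="coerce").astype(float)
    out["choice"] = out["choice"].astype(str)
    out["condition"] = out["condition"].astype(str)
    out["trial_index"] = out["trial_index"].astype(int)

    for row, val in out["choice"].items():
        if val not in CHOICE_TOKENS:
            raise TrialTableError(
                f"row {row}, column 'choice': {val!r} is not one of "
                f"{sorted(CHOICE_TOKENS)}"
            )
    for row, val in out["condition"].items():
        if val not in CONDITION_TOKENS:
            raise TrialTableError(
                f"row {row}, column 'condition': {val!r} is not one of "
                f"{sorted(CONDITION_TOKENS)}"
            )
    bad_frac = ~out["odor_left_fraction"].between(0.0, 1.0)
    if bad_frac.any():
        row = int(np.flatnonzero(bad_frac)[0])
        raise TrialTableError(
            f"row {row}, column 'odor_left_fraction': value outside [0, 1]"
        )
    none_rows = out["choice"] == "none"
    if (out.loc[none_rows, "rewarded"].notna()).any():
        row = int(out.index[none_rows & out["rewarded"].notna()][0])
        raise TrialTableError(
            f"row {row}: rewarded must be empty/none when choice is 'none'"
        )
    times = out[TIME_COLUMNS].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        diffs = np.diff(times, axis=1)
    bad = np.nan_to_num(diffs, nan=1.0) <= 0
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise TrialTableError(
            f"row {int(r)}: event times not strictly increasing at "
            f"column '{TIME_COLUMNS[c + 1]}'"
        )
    return out


def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    out = trials.copy()
    out["rewarded"] = out["rewarded"].map(
        lambda v: "none" if pd.isna(v) else str(int(v))
    )
    out.to_csv(path, index=False, float_format="%.17g")


def read_trials(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"session_id": str, "mouse_id": str,
                                  "condition": str, "choice": str})
    if "rewarded" in df.columns:
        df["rewarded"] = df["rewarded"].replace("none", np.nan)
    return validate_trials(df)


def write_spikes(
    trains: list[SpikeTrain], spikes_path: str | Path, units_path: str | Path
) -> None:
    units = pd.DataFrame(
        {
            "unit_id": [t.unit_id for t in trains],
            "mouse_id": [t.mouse_id for t in trains],
            "session_id": [t.session_id for t in trains],
            "recorded_side": [t.recorded_side for t in trains],
        }
    )
    units.to_csv(units_path, index=False)
    rows = [
        pd.DataFrame({"unit_id": t.unit_id, "spike_time_s": t.spike_times})
        for t in trains
        if t.spike_times.size
    ]
    spikes = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame({"unit_id": pd.Series(dtype=str),
                           "spike_time_s": pd.Series(dtype=float)})
    )
    spikes.to_csv(spikes_path, index=False, float_format="%.17g")


def read_spikes(
    spikes_path: str | Path, units_path: str | Path
) -> list[SpikeTrain]:
    """Load spike trains; units listed in metadata but silent get empty trains."""
    units = pd.read_csv(units_path, dtype=str)
    for col in ("unit_id", "mouse_id", "session_id", "recorded_side"):
        if col not in units.columns:
            raise ValueError(f"units file missing column '{col}'")
    spikes = pd.read_csv(spikes_path, dtype={"unit_id": str})
    if not {"unit_id", "spike_time_s"} <= set(spikes.columns):
        raise ValueError("spikes file must have columns unit_id, spike_time_s")
    if len(spikes) and (spikes["spike_time_s"] < 0).any():
        raise ValueError("negative spike time in spikes file")
    grouped = {k: g["spike_time_s"].to_numpy() for k, g in spikes.groupby("unit_id")}
    trains = []
    for _, row in units.iterrows():
        times = grouped.get(row["unit_id"], np.empty(0))
        trains.append(
            SpikeTrain(
                unit_id=row["unit_id"],
                mouse_id=row["mouse_id"],
                session_id=row["session_id"],
                recorded_side=row["recorded_side"],
                spike_times=times,
            )
        )
    return trains
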