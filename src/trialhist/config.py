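"""Run configuration and the end-to-end pipeline.

Configuration is a YAML mapping with a mandatory top-level seed; unknown
keys are rejected so typos fail loudly. The pipeline runs
simulate -> behavior -> preference -> sliding -> link -> inactivation and
writes delimited-text tables plus a JSON run log.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, behavior, choicelink, preference, sliding, synthetic
from .io import write_spikes, write_trials

_SCHEMA: dict[str, set[str]] = {
    "": {"seed", "output_dir", "verbosity", "simulate", "behavior",
         "preference", "sliding", "link", "inactivation"},
    "simulate": {"n_mice", "n_sessions", "n_units_per_session", "n_trials",
                 "beta0", "beta_odor_L", "beta_odor_R", "beta_choice",
                 "beta_outcome_L", "beta_outcome_R", "lapse_rate",
                 "modulation_amplitude", "baseline_rate"},
    "behavior": {"n_repeats", "pair"},
    "preference": {"n_perm", "lags", "variables"},
    "sliding": {"align_event", "window", "bin_width_s", "step_s"},
    "link": {"n_perm", "fit"},
    "inactivation": {"n_sets", "delta_bias", "choice1_scale"},
}


class ConfigError(ValueError):
    pass


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return validate_config(cfg)


def validate_config(cfg: dict) -> dict:
    if not isinstance(cfg, dict):
        raise ConfigError("configuration must be a mapping")
    unknown = set(cfg) - _SCHEMA[""]
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    if "seed" not in cfg:
        raise ConfigError("configuration must set an explicit 'seed'")
    for section, allowed in _SCHEMA.items():
        if not section or section not in cfg:
            continue
        sub = cfg[section]
        if not isinstance(sub, dict):
            raise ConfigError(f"section '{section}' must be a mapping")
        bad = set(sub) - allowed
        if bad:
            raise ConfigError(f"unknown keys in '{section}': {sorted(bad)}")
    return cfg


def _sim_cohort(cfg: dict, seed_seq: np.random.SeedSequence):
    sim = cfg.get("simulate", {})
    n_mice = sim.get("n_mice", 1)
    n_sessions = sim.get("n_sessions", 2)
    n_units = sim.get("n_units_per_session", 4)
    n_trials = sim.get("n_trials", 250)
    params = synthetic.BehaviorParams(
        beta0=sim.get("beta0", 0.0),
        beta_odor_L=sim.get("beta_odor_L", 3.0),
        beta_odor_R=sim.get("beta_odor_R", 3.0),
        beta_choice=tuple(sim.get("beta_choice", [0.7])),
        beta_outcome_L=tuple(sim.get("beta_outcome_L", [0.3])),
        beta_outcome_R=tuple(sim.get("beta_outcome_R", [-0.3])),
        lapse_rate=sim.get("lapse_rate", 0.0),
    )
    task = synthetic.TaskConfig()
    amp = sim.get("modulation_amplitude", 5.0)
    base = sim.get("baseline_rate", 10.0)
    trials_tables, trains, neuron_meta = [], [], []
    child = seed_seq.spawn(n_mice * n_sessions)
    k = 0
    for m in range(n_mice):
        for s in range(n_sessions):
            mouse_id = f"m{m}"
            session_id = f"m{m}_s{s}"
            neurons = [
                synthetic.NeuronParams(
                    unit_id=f"{session_id}_u{u}",
                    baseline_rate=base,
                    modulation_terms=(
                        synthetic.Modulation(
                            "prev_choice", amp, "odor_port_entry", (-0.05, 0.30)
                        ),
                    ),
                )
                for u in range(n_units)
            ]
            sess = synthetic.simulate_session(
                task, params, neurons, seed=child[k], session_id=session_id,
                mouse_id=mouse_id, n_trials=n_trials,
            )
            k += 1
            trials_tables.append(sess.trials)
            trains.extend(sess.spikes)
            neuron_meta.extend(sess.neuron_params)
    return pd.concat(trials_tables, ignore_index=True), trains, params


def run_pipeline(cfg: dict, output_dir: str | Path) -> dict:
    """Execute all configured stages; returns the run log dictionary."""
    cfg = validate_config(cfg)
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    root_seq = np.random.SeedSequence(cfg["seed"])
    stage_seq = {name: s for name, s in zip(
        ("simulate", "behavior", "preference", "sliding", "link", "inactivation"),
        root_seq.spawn(6),
    )}
    log: dict = {
        "package_version": __version__,
        "python": platform.python_version(),
        "seed": cfg["seed"],
        "config": cfg,
        "stages": [],
    }

    def _stage(name):
        log["stages"].append(name)

    try:
        _stage("simulate")
        trials, trains, gen_params = _sim_cohort(cfg, stage_seq["simulate"])
        write_trials(trials, out / "trials.csv")
        write_spikes(trains, out / "spikes.csv", out / "units.csv")

        _stage("behavior")
        beh = cfg.get("behavior", {})
        fits = []
        for mouse, g in trials.groupby("mouse_id"):
            g = g.reset_index(drop=True)
            fit = behavior.fit_choice_model(behavior.build_design(g, "extended1"))
            for nm, v in fit.coefficients.items():
                lo, hi = fit.ci95[nm]
                fits.append({"mouse_id": mouse, "coefficient": nm,
                             "estimate": v, "ci_low": lo, "ci_high": hi})
        pd.DataFrame(fits).to_csv(out / "behavior_fits.csv", index=False)
        cv_rows = []
        rng_seed = int(stage_seq["behavior"].generate_state(1)[0])
        for mouse, g in trials.groupby("mouse_id"):
            table, p = behavior.compare_models_cv(
                g.reset_index(drop=True), beh.get("pair", "simple_vs_ext1"),
                n_repeats=beh.get("n_repeats", 10), seed=rng_seed,
            )
            table["mouse_id"] = mouse
            table["p_value"] = p
            cv_rows.append(table)
        pd.concat(cv_rows, ignore_index=True).to_csv(
            out / "cv_comparison.csv", index=False
        )

        _stage("preference")
        pref_cfg = cfg.get("preference", {})
        n_perm = pref_cfg.get("n_perm", 200)
        rng = np.random.default_rng(stage_seq["preference"])
        results = []
        for train in trains:
            sess = trials[trials["session_id"] == train.session_id].reset_index(
                drop=True
            )
            for variable in pref_cfg.get("variables", ["choice", "outcome"]):
                for lag in pref_cfg.get("lags", [0, 1, 2]):
                    results.append(
                        preference.compute_preference(
                            train, sess, variable, lag, n_perm=n_perm, seed=rng
                        )
                    )
        pref_table = preference.results_table(results)
        pref_table.to_csv(out / "preference.csv", index=False)

        _stage("sliding")
        sl_cfg = cfg.get("sliding", {})
        selected = pref_table[
            (pref_table["variable"] == "choice")
            & (pref_table["lag"] == 1)
            & pref_table["included"]
            & (pref_table["p_value"] < 0.05)
        ]["unit_id"].tolist()
        fits_sl = []
        for train in trains:
            if train.unit_id not in selected:
                continue
            sess = trials[trials["session_id"] == train.session_id].reset_index(
                drop=True
            )
            mat = sliding.bin_rates(
                train, sess, sl_cfg.get("align_event", "valve_open"),
                window=tuple(sl_cfg.get("window", (-0.5, 1.0))),
                bin_width_s=sl_cfg.get("bin_width_s", sliding.BIN_WIDTH_S),
                step_s=sl_cfg.get("step_s", sliding.STEP_S),
            )
            reg = sliding.code_regressors(sess, train.recorded_side)
            fits_sl.append(sliding.fit_sliding(mat, reg))
        if fits_sl:
            pd.concat(
                [sliding.fit_table(f) for f in fits_sl], ignore_index=True
            ).to_csv(out / "sliding_fits.csv", index=False)
            pop = sliding.population_timecourse(fits_sl)
            rows = []
            for nm in sliding.COEF_NAMES:
                rows.append(pd.DataFrame({
                    "bin_center_s": pop["bin_centers"],
                    "coefficient": nm,
                    "mean": pop[nm]["mean"],
                    "sem": pop[nm]["sem"],
                    "frac_significant": pop[nm]["frac_significant"],
                }))
            pd.concat(rows, ignore_index=True).to_csv(
                out / "sliding_population.csv", index=False
            )

        _stage("link")
        link_cfg = cfg.get("link", {})
        rng_link = np.random.default_rng(stage_seq["link"])
        slope_rows = []
        pref_lookup = {
            r.unit_id: r for r in results
            if r.variable == "choice" and r.lag == 1 and r.included
        }
        for train in trains:
            r = pref_lookup.get(train.unit_id)
            if r is None or r.p_value is None or r.p_value >= 0.05:
                continue
            sess = trials[trials["session_id"] == train.session_id].reset_index(
                drop=True
            )
            res = choicelink.unit_slope(
                train, sess, r.preference,
                n_perm=link_cfg.get("n_perm", 200), seed=rng_link,
                fit=link_cfg.get("fit", "line"),
            )
            slope_rows.append({"unit_id": res.unit_id, "slope": res.slope,
                               "p_value": res.p_value,
                               "sign_class": res.sign_class,
                               "n_trials": res.n_trials})
        pd.DataFrame(slope_rows).to_csv(out / "link_slopes.csv", index=False)

        _stage("inactivation")
        inact = cfg.get("inactivation", {})
        n_sets = inact.get("n_sets", 2)
        child = stage_seq["inactivation"].spawn(n_sets)
        task = synthetic.TaskConfig()
        rows = []
        sets = []
        for i in range(n_sets):
            t = synthetic.simulate_inactivation_set(
                task,
                synthetic.BehaviorParams(beta_choice=(0.7,)),
                delta_bias=inact.get("delta_bias", 0.8),
                choice1_scale=inact.get("choice1_scale", 0.5),
                seed=child[i],
                set_id=f"set{i}",
            )
            sets.append(t)
            fit = behavior.fit_inactivation(t)
            lo, hi = fit.ci95["muscimol"]
            rows.append({"set_id": f"set{i}",
                         "beta_muscimol": fit.coefficients["muscimol"],
                         "ci_low": lo, "ci_high": hi})
        pd.DataFrame(rows).to_csv(out / "inactivation.csv", index=False)
        if n_sets >= 2:
            comp = behavior.compare_choice1_conditions(sets)
            pd.DataFrame({
                "set_id": [f"set{i}" for i in range(n_sets)],
                "beta_choice1_muscimol": comp["beta_choice1_muscimol"],
                "beta_choice1_saline": comp["beta_choice1_saline"],
                "mannwhitney_p": comp["p_value"],
            }).to_csv(out / "inactivation_choice1.csv", index=False)
    except Exception as err:  # noqa: BLE001 - re-raise with stage context
        raise RuntimeError(
            f"pipeline failed during stage '{log['stages'][-1]}': {err}"
        ) from err

    with open(out / "runlog.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True, default=str)
    return log
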