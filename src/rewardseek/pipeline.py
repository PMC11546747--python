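"""Config-driven pipeline runner with provenance manifests.

A pipeline config (dict or YAML) names an output directory, a master seed
and an ordered list of stages with per-stage parameters.  Every run writes
a ``manifest.json`` tying outputs to the config hash, per-stage seeds and
package version, so identical configs reproduce identical results.

Available stages: ``simulate_pr``, ``gonogo_plan``, ``photometry``,
``spikes``, ``tca``, ``demand``, ``bias``, ``endophenotype``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import bayes, demand, endophenotype, schedules, spikes, synth, tca
from . import photometry as phot
from .io import load_config, write_json

log = logging.getLogger("rewardseek")


def _stage_seed(master_seed: int, stage: str, index: int) -> int:
    h = hashlib.sha256(f"{master_seed}:{index}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()


def run_config(config: dict | str, out_dir: str | None = None) -> dict:
    """Execute the configured stages in order; returns the run manifest.

    ``config`` is a dict or a path to a YAML file with keys ``seed``,
    ``out_dir`` and ``stages`` (list of ``{name: ..., params: {...}}``).
    Stage outputs are written under ``out_dir``; intermediate objects flow
    between stages in memory (a spikes stage feeds the tca stage, etc.).
    """
    if isinstance(config, (str, Path)):
        config = load_config(config)
    for key in ("seed", "stages"):
        if key not in config:
            raise ValueError(f"config missing required field {key!r}")
    out = Path(out_dir or config.get("out_dir", "rewardseek_out"))
    out.mkdir(parents=True, exist_ok=True)
    known = {
        "simulate_pr", "gonogo_plan", "photometry", "spikes",
        "tca", "demand", "bias", "endophenotype",
    }
    manifest = {
        "config_hash": _config_hash(config),
        "version": __version__,
        "seed": config["seed"],
        "stages": [],
        "started": _time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    state: dict = {}
    for i, stage in enumerate(config["stages"]):
        name = stage.get("name")
        if name not in known:
            raise ValueError(f"unknown stage name {name!r} (field stages[{i}].name)")
        params = dict(stage.get("params", {}))
        seed = _stage_seed(config["seed"], name, i)
        log.info("stage %d: %s (seed %d)", i, name, seed)
        outputs = _STAGES[name](params, seed, state, out)
        manifest["stages"].append({"name": name, "seed": seed, "outputs": outputs})
    manifest["finished"] = _time.strftime("%Y-%m-%dT%H:%M:%S")
    write_json(manifest, out / "manifest.json")
    return manifest


# -- stage implementations --------------------------------------------------


def _run_simulate_pr(params, seed, state, out):
    agent = schedules.AgentParams(
        press_rate=params.get("press_rate", 0.5),
        persistence_limit=params.get("persistence_limit", float("inf")),
    )
    sched = schedules.ScheduleSpec.for_task(params.get("task", "food_PR"))
    events = schedules.simulate_pr_session(agent, sched, seed)
    events.to_csv(out / "events.csv")
    state["events"] = events
    return ["events.csv"]


def _run_gonogo(params, seed, state, out):
    plan = schedules.gonogo_session_plan(params.get("phase", 1), seed)
    write_json(
        {"trial_types": list(plan.trial_types), "block_sizes": list(plan.block_sizes),
         "cue_duration_nogo": plan.cue_duration_nogo},
        out / "gonogo_plan.json",
    )
    return ["gonogo_plan.json"]


def _run_photometry(params, seed, state, out):
    events = state.get("events")
    duration = events.duration + 20.0 if events else params.get("duration", 600.0)
    spec = synth.PhotometryGenSpec(duration=duration, seed=seed, **params.get("gen", {}))
    rec = synth.gen_photometry_session(spec, events)
    dff = phot.detrend_isosbestic(rec)
    cues = events.times_of("cue_on") if events else rec.ground_truth["transient_times"]
    psth = phot.event_psth(dff, rec.fs, cues)
    ws = phot.WindowSpec()
    metrics = {
        "cue": phot.window_metrics(psth, ws.cue),
        "reward": phot.window_metrics(psth, ws.reward),
    }
    transients = phot.detect_transients(100.0 * dff, rec.fs,
                                        params.get("min_prominence", 1.0))
    rec.to_hdf5(out / "photometry.h5")
    pd.DataFrame(psth.z).to_csv(out / "photometry_psth.csv", index=False)
    transients.to_csv(out / "transients.csv", index=False)
    write_json(metrics, out / "photometry_metrics.json")
    state["psth"] = psth
    return ["photometry.h5", "photometry_psth.csv", "transients.csv", "photometry_metrics.json"]


def _run_spikes(params, seed, state, out):
    events = state.get("events") or synth.pr_like_events(params.get("n_trials", 30))
    spec = synth.SpikeGenSpec(seed=seed, **params.get("gen", {}))
    session = synth.gen_spike_session(spec, events)
    psths, feats, model = spikes.discover_encoding_patterns(session, events, seed=seed)
    pd.DataFrame(
        {
            "unit_id": model.unit_ids,
            "cluster": model.assignments,
            "semantic_label": [model.label_of(i) for i in range(len(model.unit_ids))],
        }
    ).to_csv(out / "clusters.csv", index=False)
    pd.DataFrame([f.as_array() for f in feats],
                 columns=["n_transients", "t_first", "mean_cue", "mean_reward"]).to_csv(
        out / "features.csv", index=False
    )
    state["session"] = session
    state["psths"] = psths
    state["cluster_model"] = model
    return ["clusters.csv", "features.csv"]


def _run_tca(params, seed, state, out):
    spec = synth.TensorGenSpec(seed=seed, **params.get("gen", {}))
    tensor, truth = synth.gen_trial_tensor(spec)
    sel = tca.select_rank(
        tensor,
        candidates=params.get("candidates", list(range(1, 9))),
        runs_per_candidate=params.get("runs_per_candidate", 10),
        seed=seed,
    )
    r = sel.selected_r or spec.r_true
    model = tca.cp_als(tensor, r, n_restarts=params.get("n_restarts", 3), seed=seed)
    for mode, M in (("units", model.W), ("trials", model.B), ("time", model.A)):
        pd.DataFrame(M).to_csv(out / f"tca_factors_{mode}.csv", index=False)
    write_json(
        {"selected_r": sel.selected_r, "similarity": sel.similarity,
         "rel_errors": sel.rel_errors},
        out / "tca_selection.json",
    )
    state["tca_model"] = model
    state["tensor"] = tensor
    return ["tca_factors_units.csv", "tca_factors_trials.csv", "tca_factors_time.csv",
            "tca_selection.json"]


def _run_demand(params, seed, state, out):
    n_subjects = params.get("n_subjects", 8)
    rows = []
    ss = np.random.SeedSequence(seed)
    for sid, child in enumerate(ss.spawn(n_subjects)):
        spec = synth.DemandGenSpec(seed=int(child.generate_state(1)[0] % 2**31),
                                   **params.get("gen", {}))
        df = synth.gen_demand_observations(spec)
        df["subject_id"] = sid
        rows.append(df)
    table = pd.concat(rows, ignore_index=True)
    fits = demand.fit_demand_table(table)
    fits.to_csv(out / "demand_fits.csv", index=False)
    state["demand_fits"] = fits
    return ["demand_fits.csv"]


def _run_bias(params, seed, state, out):
    model = state.get("cluster_model")
    if model is not None and "y" not in params:
        enc = model.assignments >= 0
        labels = np.array([model.label_of(i) for i in range(len(model.unit_ids))])
        y = np.array([l.startswith("cue") for l in labels], dtype=int)[enc]
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 2, enc.sum())  # placeholder group labels for the demo
    else:
        y = np.asarray(params["y"], dtype=int)
        x = np.asarray(params["x"], dtype=int)
    summary = bayes.fit_bayes_logistic(y, x)
    write_json(
        {"beta_mean": summary.beta_mean, "ci_low": summary.beta_ci[0],
         "ci_high": summary.beta_ci[1], "bf10": summary.bf10, "bf01": summary.bf01,
         "evidence_label": summary.evidence_label, "n_per_cell": summary.n_per_cell},
        out / "bias.json",
    )
    return ["bias.json"]


def _run_endophenotype(params, seed, state, out):
    fits = state.get("demand_fits")
    if fits is None:
        raise ValueError("endophenotype stage requires a preceding demand stage")
    rng = np.random.default_rng(seed)
    mat = fits.set_index("subject_id")[["Q0", "alpha", "EV", "Pmax"]].copy()
    mat["PR_rewards"] = rng.poisson(10, len(mat)) + 1.0 + mat["Pmax"].to_numpy() * 0.01
    res = endophenotype.pca_endophenotype(mat)
    res.loadings.to_csv(out / "endophenotype_loadings.csv")
    res.scores.to_csv(out / "endophenotype_scores.csv")
    write_json({"variance_explained": res.variance_explained}, out / "endophenotype.json")
    return ["endophenotype_loadings.csv", "endophenotype_scores.csv", "endophenotype.json"]


_STAGES = {
    "simulate_pr": _run_simulate_pr,
    "gonogo_plan": _run_gonogo,
    "photometry": _run_photometry,
    "spikes": _run_spikes,
    "tca": _run_tca,
    "demand": _run_demand,
    "bias": _run_bias,
    "endophenotype": _run_endophenotype,
}
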