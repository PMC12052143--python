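"""Session bundle format, pipeline runner and provenance.

A session bundle is a directory of plain delimited text tables plus a JSON
manifest: trials.csv, position.csv, events.csv, spikes.csv, units.csv, an
optional raw float32 LFP file with its metadata in the manifest.  Time is
in seconds, positions in cm, rates in Hz.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior, cellclass, decoder, goal_coding, goal_decoder, lfp
from . import ratemaps as rm_mod
from .core import MazeGeometry, NeuronSpec, Session, SessionConfig, TrialRecord
from .synth import generate_session

__all__ = ["write_session", "read_session", "run_pipeline", "load_config"]

SCHEMA_VERSION = 1
REQUIRED_TABLES = ("trials.csv", "position.csv", "events.csv", "spikes.csv")


def _config_hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str)
                          .encode()).hexdigest()[:16]


def write_session(session: Session, path: str | Path) -> Path:
    """Write a session bundle (CSV tables + JSON manifest) to a directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    rows = []
    for tr in session.trials:
        row = {"trial": tr.index, "sample_goal": tr.sample_goal,
               "choice_goal": tr.choice_goal, "correct": tr.correct,
               "light_on": tr.light_on}
        for ph, (lo, hi) in tr.phase_bounds.items():
            row[f"{ph}_start"], row[f"{ph}_end"] = lo, hi
        rows.append(row)
    pd.DataFrame(rows).to_csv(path / "trials.csv", index=False)

    pd.DataFrame({"t_s": session.pos_t, "d_cm": session.pos_d,
                  "arm": session.pos_arm}).to_csv(path / "position.csv",
                                                  index=False)
    ev = [{"t_s": on, "t_end_s": off, "kind": "light", "phase": ph}
          for on, off, ph in session.light_events]
    pd.DataFrame(ev, columns=["t_s", "t_end_s", "kind", "phase"]).to_csv(
        path / "events.csv", index=False)

    spk = [(u, t) for u in session.units for t in session.spikes[u]]
    pd.DataFrame(spk, columns=["unit_id", "t_s"]).to_csv(
        path / "spikes.csv", index=False)

    wf_rows = []
    for u in session.units:
        wf = session.waveforms.get(u)
        wf_rows.append({"unit_id": u,
                        "waveform": "" if wf is None else
                        ";".join(f"{v:.6f}" for v in wf)})
    pd.DataFrame(wf_rows, columns=["unit_id", "waveform"]).to_csv(
        path / "units.csv", index=False)

    manifest = {
        "schema_version": SCHEMA_VERSION,
        "seed": session.config.seed,
        "geometry": asdict(session.geometry),
        "config": {k: v for k, v in asdict(session.config).items()},
        "config_hash": _config_hash(asdict(session.config)),
        "waveform_fs": session.waveform_fs,
        "lfp": None,
    }
    if session.lfp is not None:
        np.asarray(session.lfp, "<f4").tofile(path / "lfp.f32")
        manifest["lfp"] = {"file": "lfp.f32", "dtype": "<f4", "t0": 0.0,
                           "rate_hz": session.config.lfp_rate,
                           "n_samples": int(len(session.lfp))}
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                   default=str))
    return path


def read_session(path: str | Path) -> Session:
    """Read a session bundle back into a :class:`Session`.

    Validates the schema and the referential integrity of the tables
    (every event refers to an existing trial; phase intervals are ordered).
    """
    path = Path(path)
    for name in REQUIRED_TABLES + ("manifest.json",):
        if not (path / name).exists():
            raise FileNotFoundError(f"session bundle missing {name}")
    manifest = json.loads((path / "manifest.json").read_text())
    geometry = MazeGeometry(**manifest["geometry"])
    cfg_dict = dict(manifest["config"])
    if isinstance(cfg_dict.get("goal_dwell_range"), list):
        cfg_dict["goal_dwell_range"] = tuple(cfg_dict["goal_dwell_range"])
    config = SessionConfig(**cfg_dict)

    trials_df = pd.read_csv(path / "trials.csv")
    for col in ("trial", "sample_goal", "choice_goal", "light_on"):
        if col not in trials_df.columns:
            raise ValueError(f"trials.csv missing column {col!r}")
    trials = []
    for _, r in trials_df.iterrows():
        bounds = {}
        for ph in ("sample", "delay", "choice"):
            if f"{ph}_start" in r and np.isfinite(r[f"{ph}_start"]):
                bounds[ph] = (float(r[f"{ph}_start"]), float(r[f"{ph}_end"]))
        trials.append(TrialRecord(int(r.trial), str(r.sample_goal),
                                  str(r.choice_goal), bool(r.light_on), bounds))
    trial_ids = {tr.index for tr in trials}

    pos = pd.read_csv(path / "position.csv")
    spk = pd.read_csv(path / "spikes.csv")
    spikes = {str(u): np.sort(g["t_s"].to_numpy(float))
              for u, g in spk.groupby("unit_id")}

    events = pd.read_csv(path / "events.csv")
    light_events = []
    duration = float(pos["t_s"].iloc[-1]) if len(pos) else 0.0
    for _, r in events.iterrows():
        if r["kind"] == "light":
            light_events.append((float(r.t_s), float(r.t_end_s), str(r.phase)))
        if "trial" in events.columns and np.isfinite(r.get("trial", np.nan)):
            if int(r["trial"]) not in trial_ids:
                raise ValueError(f"event references unknown trial {int(r['trial'])}")
        if float(r.t_s) > duration + 1.0:
            raise ValueError("event time beyond the position clock")

    waveforms, wf_fs = {}, float(manifest.get("waveform_fs", 32000.0))
    units_path = path / "units.csv"
    if units_path.exists():
        for _, r in pd.read_csv(units_path).iterrows():
            if isinstance(r.get("waveform"), str) and r["waveform"]:
                waveforms[str(r.unit_id)] = np.array(
                    [float(v) for v in r["waveform"].split(";")])

    lfp_trace = None
    if manifest.get("lfp"):
        meta = manifest["lfp"]
        lfp_trace = np.fromfile(path / meta["file"], dtype=meta["dtype"]).astype(float)
        if len(lfp_trace) != meta["n_samples"]:
            raise ValueError("LFP sample count disagrees with manifest")

    session = Session(geometry=geometry, config=config, trials=trials,
                      pos_t=pos["t_s"].to_numpy(float),
                      pos_d=pos["d_cm"].to_numpy(float),
                      pos_arm=pos["arm"].to_numpy(str),
                      spikes=spikes, light_events=light_events, lfp=lfp_trace,
                      waveforms=waveforms, waveform_fs=wf_fs)
    session.validate()
    return session


def load_config(path: str | Path) -> dict:
    """Read a pipeline configuration from a YAML/key-value text file."""
    with open(path) as fh:
        return yaml.safe_load(fh)


KNOWN_STAGES = ("simulate", "behavior", "ratemaps", "decode-position",
                "goal-index", "decode-goal", "phase-locking", "classify-cells")


def run_pipeline(config: dict, out_dir: str | Path,
                 seed: int | None = None) -> Path:
    """Run the requested analysis stages in dependency order.

    ``config`` holds a ``session`` section (generator parameters or a bundle
    path) and a ``stages`` list.  Every output table lands in ``out_dir``
    with a provenance record (config hash, seed, stage timings, exclusions).
    Reruns with the same config are byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = list(config.get("stages", KNOWN_STAGES))
    for st in stages:
        if st not in KNOWN_STAGES:
            raise ValueError(f"unknown stage {st!r}")
    if seed is None:
        seed = int(config.get("seed", 0))
    timings, exclusions = {}, []

    t0 = time.perf_counter()
    sess_cfg = dict(config.get("session", {}))
    if "path" in sess_cfg:
        session = read_session(sess_cfg["path"])
    else:
        neurons = _neurons_from_config(sess_cfg.pop("neurons", 20), seed)
        sc = SessionConfig(seed=seed, **{k: v for k, v in sess_cfg.items()})
        session = generate_session(sc, neurons=neurons)
        if "simulate" in stages:
            write_session(session, out / "session")
    timings["simulate"] = time.perf_counter() - t0

    track = behavior.track_from_session(session)
    segments = behavior.segment_trajectories(session, track)

    if "behavior" in stages:
        t0 = time.perf_counter()
        behavior.segments_table(segments).to_csv(out / "segments.csv", index=False)
        perf = behavior.score_performance(session.trials)
        pd.DataFrame([
            {"condition": c, **v} for c, v in perf.by_condition.items()
        ]).assign(difference_score=perf.difference_score).to_csv(
            out / "performance.csv", index=False)
        timings["behavior"] = time.perf_counter() - t0

    if "ratemaps" in stages:
        t0 = time.perf_counter()
        rows, tables = [], []
        for phase in ("sample", "choice"):
            for cond, flag in (("off", False), ("on", True)):
                segs = rm_mod.select_segments(segments, phase=phase,
                                              light_on=flag)
                if not segs:
                    continue
                for u in session.units:
                    rmap = rm_mod.linearized_rate_map(session.spikes[u], segs,
                                                      track)
                    res = rm_mod.spatial_modulation_test(rmap)
                    try:
                        si = rm_mod.spatial_information(rmap)
                    except ValueError:
                        si = np.nan
                        exclusions.append({"stage": "ratemaps", "unit": u,
                                           "rule": "silent cell: SI undefined"})
                    rows.append({"unit": u, "phase": phase, "condition": cond,
                                 "F": res.F, "p": res.p,
                                 "significant": res.significant,
                                 "spatial_information": si})
                    tables.append(rmap.to_table(u, f"{phase}_{cond}"))
        pd.DataFrame(rows).to_csv(out / "spatial_stats.csv", index=False)
        pd.concat(tables).to_csv(out / "ratemaps.csv", index=False)
        timings["ratemaps"] = time.perf_counter() - t0

    if "decode-position" in stages:
        t0 = time.perf_counter()
        rows = []
        for phase in ("sample", "choice"):
            for cond, flag in (("off", False), ("on", True)):
                res = decoder.cross_validated_decoding(session, track,
                                                       segments, phase, flag)
                if res.status != "ok":
                    exclusions.append({"stage": "decode-position",
                                       "unit": f"{phase}/{cond}",
                                       "rule": res.detail.get("reason", "")})
                rows.append({"phase": phase, "condition": cond,
                             "status": res.status,
                             "mean_error_cm": res.mean_error_cm,
                             "percent_correct": res.percent_correct,
                             "n_windows": res.n_windows})
        pd.DataFrame(rows).to_csv(out / "decoding.csv", index=False)
        timings["decode-position"] = time.perf_counter() - t0

    if "goal-index" in stages:
        t0 = time.perf_counter()
        sel_rows, idx_tables = [], []
        for u in session.units:
            summaries = {c: goal_coding.goal_summary_bins(
                session.spikes[u], segments, track, "sample", flag)
                for c, flag in (("off", False), ("on", True))}
            sel = goal_coding.goal_selectivity_test(summaries)
            sel_rows.append({"unit": u, "significant": sel.significant,
                             "preferred": sel.preferred,
                             "p_off": sel.p_by_condition.get("off"),
                             "p_on": sel.p_by_condition.get("on")})
            if sel.significant and sel.preferred:
                for c, flag in (("off", False), ("on", True)):
                    prof = goal_coding.goal_arm_rates(session.spikes[u],
                                                      segments, track,
                                                      "sample", flag)
                    gip = goal_coding.goal_index_profile(prof, sel.preferred)
                    idx_tables.append(gip.to_table(u, c))
        pd.DataFrame(sel_rows).to_csv(out / "goal_selectivity.csv", index=False)
        if idx_tables:
            pd.concat(idx_tables).to_csv(out / "goal_index.csv", index=False)
        timings["goal-index"] = time.perf_counter() - t0

    if "decode-goal" in stages:
        t0 = time.perf_counter()
        tables = []
        for cond, flag in (("off", False), ("on", True)):
            gv = goal_decoder.build_goal_vectors(session, track, segments,
                                                 "sample", flag)
            res = goal_decoder.decode_goal_by_position(
                gv, n_pairs=min(goal_decoder.N_PAIRS["sample"],
                                config.get("goal_pairs", 10)),
                n_repeats=config.get("goal_repeats", 20),
                rng=np.random.default_rng(seed + 1))
            if res.status != "ok":
                exclusions.append({"stage": "decode-goal", "unit": cond,
                                   "rule": res.detail.get("reason", "")})
            else:
                tables.append(res.to_table("sample", cond))
        if tables:
            pd.concat(tables).to_csv(out / "goal_decoding.csv", index=False)
        timings["decode-goal"] = time.perf_counter() - t0

    if "phase-locking" in stages and session.lfp is not None:
        t0 = time.perf_counter()
        phase = lfp.instantaneous_theta_phase(session.lfp,
                                              session.config.lfp_rate)
        epochs = [(s.t_start, s.t_end) for s in rm_mod.select_segments(
            segments, phase="sample", kinds=("outbound",))]
        rows = []
        for u in session.units:
            pl = lfp.phase_locking(session.spikes[u], phase, epochs,
                                   fs=session.config.lfp_rate)
            if pl.status == "excluded":
                exclusions.append({"stage": "phase-locking", "unit": u,
                                   "rule": "< 30 spikes in condition"})
            rows.append(pl.to_row(u))
        pd.DataFrame(rows).to_csv(out / "phase_locking.csv", index=False)
        timings["phase-locking"] = time.perf_counter() - t0

    if "classify-cells" in stages and session.waveforms:
        t0 = time.perf_counter()
        feats = [cellclass.waveform_features(session.waveforms[u],
                                             session.waveform_fs, u)
                 for u in session.units]
        classes = cellclass.classify_cells(feats, seed=0)
        cellclass.cell_class_table(feats, classes).to_csv(
            out / "cells.csv", index=False)
        timings["classify-cells"] = time.perf_counter() - t0

    provenance = {
        "schema_version": SCHEMA_VERSION,
        "seed": seed,
        "config_hash": _config_hash(config),
        "stages": stages,
        "timings_s": {k: round(v, 4) for k, v in timings.items()},
        "exclusions": exclusions,
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    return out


def _neurons_from_config(spec, seed: int) -> list[NeuronSpec]:
    """Default roster: spatially tuned cells with a few goal-selective and
    theta-locked units, mirroring the statistical structure the analyses
    assume."""
    from .core import LightEffect, gaussian_field

    if isinstance(spec, list):
        return [NeuronSpec(**s) for s in spec]
    n = int(spec)
    rng = np.random.default_rng(seed + 104729)
    neurons = []
    for i in range(n):
        center = rng.uniform(0, 80)
        neurons.append(NeuronSpec(
            baseline_rate=rng.uniform(0.5, 2.0),
            tuning=gaussian_field(center, rng.uniform(6, 12),
                                  rng.uniform(5, 15)),
            goal_gain=2.0 if i % 5 == 0 else 1.0,
            preferred_goal="L" if i % 2 else "R",
            light=LightEffect(-1, 0.5, latency_ms=20.0) if i % 3 == 0
            else LightEffect(),
            theta_kappa=1.0 if i % 4 == 0 else 0.0,
            cell_type="int" if i % 6 == 0 else "pyr",
        ))
    return neurons
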