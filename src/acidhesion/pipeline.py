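"""Reproducible multi-stage runs driven by a single YAML/JSON config.

A run config is a mapping::

    out_dir: runs/demo
    seed: 1
    stages:
      - stage: simulate_curves
        params: {n_curves: 20}
      - stage: afm
        params: {reference_condition: pH7.4}
      ...

Every stage writes its outputs under ``out_dir`` and the run finishes
with a ``provenance.json`` recording the config, its hash, the seed and
the package version; re-running the same config reproduces every output
byte-for-byte (all randomness flows from the config seed).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io, synthetic_data
from .force_spectroscopy import (
    GateThresholds,
    analyze_curve,
    binding_frequency,
    events_to_frame,
    relative_binding_frequency,
    summarize_condition,
)
from .migration import cell_speed, filter_and_average, fit_prw, msd_nonoverlapping
from .morphodynamics import detect_protrusions, shape_metrics
from .trajectory_metrics import opening_distance_series, replicate_histogram

__all__ = ["run_pipeline", "config_hash"]


def config_hash(config: dict) -> str:
    """SHA-256 of the canonical JSON form of a config."""
    canon = json.dumps(config, sort_keys=True, separators=(",", ":"), default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _stage_simulate_curves(out: Path, seed: int, params: dict) -> dict:
    cfg = synthetic_data.CurveSimConfig(seed=seed, **params.get("config", {}))
    curves, truth = synthetic_data.simulate_force_curves(
        cfg,
        cell_id=params.get("cell_id", "cell0"),
        condition=params.get("condition", ""),
    )
    io.write_curves(curves, out / "curves.csv", out / "curves_meta.csv")
    truth.to_csv(out / "curves_truth.csv", index=False)
    return {"n_curves": len(curves), "n_events": len(truth)}


def _stage_afm(out: Path, seed: int, params: dict) -> dict:
    curves = io.read_curves(out / "curves.csv", out / "curves_meta.csv")
    gate = GateThresholds(
        f_r_min=params.get("f_r_min", 50.0), f_prime_min=params.get("f_prime_min", 2000.0)
    )
    events = []
    for c in curves:
        events.extend(analyze_curve(c, gate=gate))
    ev = events_to_frame(events)
    ev.to_csv(out / "events.csv", index=False)
    summaries = binding_frequency(ev[ev["quantifiable"]])
    ref = params.get("reference_condition")
    if ref is not None:
        summaries = relative_binding_frequency(summaries, ref)
    per_cell = pd.DataFrame(
        {
            "cell_id": [s.cell_id for s in summaries],
            "condition": [s.condition for s in summaries],
            "n_events_total": [s.n_events_total for s in summaries],
            "n_events_specific": [s.n_events_specific for s in summaries],
            "f_b": [s.f_b for s in summaries],
            "f_b_rel": [s.f_b_rel for s in summaries],
        }
    )
    per_cell.to_csv(out / "binding_per_cell.csv", index=False)
    cond = summarize_condition(summaries, events=ev)
    cond.to_json(out / "binding_per_condition.json", orient="records", indent=1)
    return {"n_events": len(ev)}


def _stage_simulate_tracks(out: Path, seed: int, params: dict) -> dict:
    cfg = synthetic_data.TrackSimConfig(seed=seed, **params.get("config", {}))
    tracks = synthetic_data.simulate_prw_tracks(cfg, condition=params.get("condition", ""))
    io.write_tracks(tracks, out / "tracks.csv")
    return {"n_tracks": len(tracks)}


def _stage_migrate(out: Path, seed: int, params: dict) -> dict:
    dt = params.get("dt", 5.0)
    tracks = io.read_tracks(out / "tracks.csv", dt=dt)
    rows = []
    for t in tracks:
        msd = msd_nonoverlapping(t)
        fit = fit_prw(msd)
        rows.append(
            {
                "cell_id": t.cell_id,
                "condition": t.condition,
                "speed_um_per_min": cell_speed(msd),
                "S_fit": fit.S,
                "P_fit": fit.P,
                "r_squared": fit.r_squared,
                "converged": fit.converged,
            }
        )
    per_cell = pd.DataFrame(rows)
    per_cell.to_csv(out / "prw_per_cell.csv", index=False)
    summary = filter_and_average(
        per_cell, r2_min=params.get("r2_min", 0.5), min_cells=params.get("min_cells", 40)
    )
    summary.to_json(out / "migration_summary.json", orient="records", indent=1)
    return {"n_cells": len(per_cell)}


def _stage_shapes(out: Path, seed: int, params: dict) -> dict:
    specs = params.get(
        "shapes",
        [
            {"kind": "circle_ngon", "params": {"radius": 10.0, "n_vertices": 256}},
            {"kind": "rectangle", "params": {"width": 2.0, "height": 4.0}},
            {"kind": "star", "params": {"n_arms": 5, "r_outer": 10.0, "r_inner": 4.0}},
        ],
    )
    rows = []
    for i, spec in enumerate(specs):
        verts, a_true, p_true = synthetic_data.simulate_shapes(spec["kind"], spec["params"])
        m = shape_metrics(outline=verts, cell_id=f"shape{i}")
        rows.append(
            {
                "cell_id": m.cell_id,
                "kind": spec["kind"],
                "area_um2": m.area,
                "perimeter_um": m.perimeter,
                "circularity": m.circularity,
                "area_true_um2": a_true,
                "perimeter_true_um": p_true,
            }
        )
    pd.DataFrame(rows).to_csv(out / "shape_metrics.csv", index=False)
    return {"n_shapes": len(rows)}


def _stage_kymo(out: Path, seed: int, params: dict) -> dict:
    cfg = synthetic_data.KymoSimConfig(
        seed=seed,
        **params.get(
            "config",
            {"n_frames": 120, "events": [(10, 2.0, 10, 5), (60, 1.5, 8, 4)], "noise_sd": 0.3},
        ),
    )
    trace, truth = synthetic_data.simulate_kymograph(cfg)
    truth.to_csv(out / "kymo_truth.csv", index=False)
    events = detect_protrusions(trace)
    pd.DataFrame(
        {
            "start_frame": [e.start_frame for e in events],
            "ramp_end_frame": [e.ramp_end_frame for e in events],
            "plateau_frames": [e.plateau_frames for e in events],
            "height_px": [e.height_px for e in events],
            "velocity_um_per_min": [e.velocity_um_per_min for e in events],
            "lifetime_s": [e.lifetime_s for e in events],
        }
    ).to_csv(out / "protrusions.csv", index=False)
    return {"n_events": len(events)}


def _stage_traj(out: Path, seed: int, params: dict) -> dict:
    cfg = synthetic_data.FrameSimConfig(seed=seed, **params.get("config", {}))
    framesets, truth = synthetic_data.simulate_headpiece_frames(cfg)
    truth.to_csv(out / "frames_truth.csv", index=False)
    for fs in framesets:
        io.write_frames_pdb(fs, out / f"frames_{fs.replicate_id}.pdb")
    series = [opening_distance_series(fs) for fs in framesets]
    per_frame = pd.concat(
        [
            pd.DataFrame(
                {"replicate_id": s.replicate_id, "frame": np.arange(s.values.size), "d_nm": s.values}
            )
            for s in series
        ],
        ignore_index=True,
    )
    per_frame.to_csv(out / "opening_distance.csv", index=False)
    hist = replicate_histogram(series, bin_width=params.get("bin_width", 0.05))
    pd.DataFrame(
        {
            "bin_left_nm": hist.bin_edges[:-1],
            "bin_right_nm": hist.bin_edges[1:],
            "mean_frequency": hist.mean,
            "sem": hist.sem,
        }
    ).to_csv(out / "opening_histogram.csv", index=False)
    return {"n_replicates": len(framesets)}


_STAGES = {
    "simulate_curves": _stage_simulate_curves,
    "afm": _stage_afm,
    "simulate_tracks": _stage_simulate_tracks,
    "migrate": _stage_migrate,
    "shapes": _stage_shapes,
    "kymo": _stage_kymo,
    "traj": _stage_traj,
}

_ALLOWED_KEYS = {"out_dir", "seed", "stages"}


def run_pipeline(config: dict) -> Path:
    """Execute the configured stages in order; returns the run directory.

    The whole config is validated before any stage runs (unknown top-level
    keys and unknown stage names are rejected).  A failing stage stops the
    run, leaving earlier outputs intact and marked in ``provenance.json``.
    """
    unknown = set(config) - _ALLOWED_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "out_dir" not in config or "stages" not in config:
        raise ValueError("config requires 'out_dir' and 'stages'")
    for entry in config["stages"]:
        extra = set(entry) - {"stage", "params"}
        if extra:
            raise ValueError(f"unknown stage keys: {sorted(extra)}")
        if entry.get("stage") not in _STAGES:
            raise ValueError(f"unknown stage {entry.get('stage')!r}")

    out = Path(config["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    chash = config_hash(config)
    provenance = {
        "config": config,
        "config_hash": chash,
        "seed": seed,
        "package_version": __version__,
        "stages": [],
    }
    try:
        for entry in config["stages"]:
            name = entry["stage"]
            info = _STAGES[name](out, seed, entry.get("params", {}))
            provenance["stages"].append({"stage": name, "status": "ok", **info})
    except Exception as exc:
        provenance["stages"].append({"stage": name, "status": "failed", "error": str(exc)})
        with open(out / "provenance.json", "w") as fh:
            json.dump(provenance, fh, indent=1, default=str)
        raise
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=1, default=str)
    return out
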