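"""End-to-end pipeline: simulate -> preprocess -> detect -> fit -> average ->
quantify -> compare, driven by one seeded configuration.

The configuration is a nested dict (YAML/JSON on disk) with optional blocks
``instrument``, ``mechanics``, ``drift``, ``detection``, ``fitting``,
``ensemble``, ``comparison`` and top-level ``seed``, ``out_dir``, ``forces``,
``molecules``, ``duration_s``, ``attachment_rate``, ``scheme`` and ``pi_mM``.
Every run writes a manifest recording the seed, the config hash, and the
artifacts of each stage, so a run is reproducible from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import yaml

from . import dsc, dwell
from .compare import compare_orderings
from .detect import DetectionConfig, detect_events, select_threshold
from .ensemble import build_ensemble, fit_stroke_rate, quantify_stroke
from .io import InstrumentConfig, SchemaError, write_events, write_trace, write_truth
from .kinetics import preset_scheme
from .simulate import DriftModel, MechanicsConfig, apply_drift_and_pauses, simulate_trace

log = logging.getLogger("uffclamp")

STAGES = ["simulate", "preprocess", "detect", "fitdur", "ensemble", "quantify", "compare"]

_DEFAULTS = {
    "seed": 1,
    "out_dir": "uffc_run",
    "scheme": "stroke_first",
    "pi_mM": 0.0,
    "forces": [3.0],
    "molecules": 2,
    "duration_s": 30.0,
    "attachment_rate": 2.0,
    "min_duration_s": 0.015,
    "apply_dsc": True,
    "run_compare": False,
}


class ConfigError(ValueError):
    pass


def load_config(path: str | Path) -> dict:
    with open(path) as f:
        cfg = yaml.safe_load(f)
    if not isinstance(cfg, dict):
        raise SchemaError(f"{path}: pipeline config must be a mapping")
    return cfg


def _merged(config: dict) -> dict:
    cfg = dict(_DEFAULTS)
    cfg.update(config or {})
    if "forces" not in cfg or not cfg["forces"]:
        raise ConfigError("config missing required field 'forces' (list of pN values)")
    return cfg


def _hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _file_hash(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def run_pipeline(config: dict, write_traces: bool = False) -> dict:
    """Execute the full pipeline; returns (and writes) the run manifest.

    Idempotent for a fixed seed: re-running with the same config produces
    identical artifact hashes.  On stage failure, raises after recording the
    completed stages in the manifest on disk.
    """
    cfg = _merged(config)
    seed = int(cfg["seed"])
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    instrument_cfg = cfg.get("instrument", {})
    mechanics = MechanicsConfig(**cfg.get("mechanics", {}))
    drift = DriftModel(**cfg.get("drift", {}))
    det_cfg = DetectionConfig(**cfg.get("detection", {}))

    manifest: dict = {
        "seed": seed,
        "config_hash": _hash(cfg),
        "config": cfg,
        "stages": {},
        "outputs": {},
    }
    manifest_path = out / "manifest.json"

    def _finish_stage(name, t0, **info):
        manifest["stages"][name] = {"wall_s": round(time.perf_counter() - t0, 3), **info}
        log.info("stage %s done in %.1fs %s", name, time.perf_counter() - t0, info)
        with open(manifest_path, "w") as f:
            json.dump(manifest, f, indent=1, default=str)

    try:
        # --- simulate -----------------------------------------------------
        t0 = time.perf_counter()
        traces, truths = {}, {}
        for force in cfg["forces"]:
            inst = InstrumentConfig(**{**instrument_cfg, "applied_force": float(force)})
            scheme = preset_scheme(cfg["scheme"], pi_mM=float(cfg["pi_mM"]))
            for m in range(int(cfg["molecules"])):
                tid = f"f{force:g}_mol{m}"
                tr, tru = simulate_trace(
                    scheme,
                    inst,
                    mechanics,
                    float(cfg["duration_s"]),
                    float(cfg["attachment_rate"]),
                    rng_seed=int(rng.integers(2**31)),
                    molecule_id=f"mol{m}",
                    trace_id=tid,
                )
                tr, tru = apply_drift_and_pauses(tr, drift, int(rng.integers(2**31)), truth=tru)
                traces[tid] = tr
                truths[tid] = tru
                if write_traces:
                    write_trace(tr, out / f"{tid}.h5")
                    write_truth(tru, out / f"{tid}_truth.tsv")
        _finish_stage("simulate", t0, n_traces=len(traces))

        # --- preprocess (DSC) ---------------------------------------------
        t0 = time.perf_counter()
        if cfg["apply_dsc"]:
            traces = {tid: dsc.correct_forces(tr, dsc.estimate_baseline(tr)) for tid, tr in traces.items()}
        _finish_stage("preprocess", t0, applied=bool(cfg["apply_dsc"]))

        # --- detect --------------------------------------------------------
        t0 = time.perf_counter()
        events_by_force = {}
        thresholds = {}
        for force in cfg["forces"]:
            if det_cfg.threshold_fraction is None and det_cfg.threshold_nm_per_s is None:
                inst = InstrumentConfig(**{**instrument_cfg, "applied_force": float(force)})
                free_tr, _ = simulate_trace(
                    preset_scheme(cfg["scheme"]),
                    inst,
                    mechanics,
                    max(20.0, float(cfg["duration_s"])),
                    0.0,
                    rng_seed=int(rng.integers(2**31)),
                )
                expected = max(10.0, cfg["attachment_rate"] * cfg["duration_s"])
                theta = select_threshold(free_tr, det_cfg, expected, force=force)
            else:
                theta = det_cfg.threshold_fraction
            thresholds[force] = theta
            fcfg = dataclasses.replace(det_cfg, threshold_fraction=theta)
            parts = [
                detect_events(traces[tid], fcfg, force=float(force))
                for tid in traces
                if tid.startswith(f"f{force:g}_")
            ]
            import pandas as pd

            events = pd.concat(parts, ignore_index=True) if parts else parts
            events_by_force[force] = events
            write_events(events, out / f"events_f{force:g}.tsv")
        manifest["outputs"]["events"] = {
            f"{force:g}": str(out / f"events_f{force:g}.tsv") for force in cfg["forces"]
        }
        _finish_stage(
            "detect",
            t0,
            thresholds={f"{k:g}": v for k, v in thresholds.items()},
            n_events={f"{k:g}": len(v) for k, v in events_by_force.items()},
        )

        # --- fitdur --------------------------------------------------------
        t0 = time.perf_counter()
        fits = {}
        for force, events in events_by_force.items():
            deadtime = det_cfg.deadtime_for(force)
            sample = dwell.dwell_sample_from_events(events, deadtime, force_pN=force)
            try:
                fit = dwell.select_model(sample, rng_seed=seed)
                fits[f"{force:g}"] = {
                    "n_components": fit.n_components,
                    "rates_s^-1": fit.rates.tolist(),
                    "amplitudes_observed": fit.amplitudes_observed.tolist(),
                    "amplitudes_corrected": fit.amplitudes_corrected.tolist(),
                    "log_likelihood": fit.log_likelihood,
                    "llr_pvalues": fit.llr_pvalues,
                    "n_events": fit.n_events,
                    "n_molecules": fit.n_molecules,
                }
            except dwell.FitError as e:
                fits[f"{force:g}"] = {"error": str(e)}
        with open(out / "dwell_fits.json", "w") as f:
            json.dump({"seed": seed, "fits": fits}, f, indent=1)
        manifest["outputs"]["dwell_fits"] = str(out / "dwell_fits.json")
        _finish_stage("fitdur", t0, forces=list(fits))

        # --- ensemble ------------------------------------------------------
        t0 = time.perf_counter()
        averages = {}
        for force, events in events_by_force.items():
            hind = events[events.direction == "hindering"]
            if not len(hind):
                continue
            try:
                averages[force] = build_ensemble(
                    hind, traces, min_duration_s=float(cfg["min_duration_s"]), force_pN=force
                )
            except Exception as e:  # noqa: BLE001 - recorded, not fatal
                log.warning("ensemble at %g pN failed: %s", force, e)
        _finish_stage("ensemble", t0, forces=[f"{k:g}" for k in averages])

        # --- quantify ------------------------------------------------------
        t0 = time.perf_counter()
        quants = {}
        for force, avg in averages.items():
            q = quantify_stroke(avg)
            try:
                k, ci = fit_stroke_rate(avg, q)
            except Exception:  # noqa: BLE001
                k, ci = None, None
            quants[f"{force:g}"] = {
                "t_init_s": q.t_init_s,
                "initial_displacement_nm": q.initial_displacement_nm,
                "dip_amplitude_nm": q.dip_amplitude_nm,
                "dip_time_s": q.dip_time_s,
                "total_displacement_nm": q.total_displacement_nm,
                "k_stroke_s^-1": k,
                "k_stroke_ci95": ci,
                "n_events": avg.n_events,
            }
        with open(out / "stroke_quant.json", "w") as f:
            json.dump({"seed": seed, "quantifications": quants}, f, indent=1)
        manifest["outputs"]["stroke_quant"] = str(out / "stroke_quant.json")
        _finish_stage("quantify", t0, forces=list(quants))

        # --- compare -------------------------------------------------------
        t0 = time.perf_counter()
        if cfg["run_compare"]:
            cmp_cfg = cfg.get("comparison", {})
            report = compare_orderings(
                forces=cmp_cfg.get("forces", cfg["forces"]),
                pi_levels=tuple(cmp_cfg.get("pi_levels", (0.0, 10.0))),
                schemes=tuple(cmp_cfg.get("schemes", ("stroke_first", "pi_first"))),
                seed=seed,
                n=int(cmp_cfg.get("n", 3000)),
                cutoff_s=float(cmp_cfg.get("cutoff_s", 0.025)),
            )
            report.table.to_json(out / "comparison.json", orient="records", indent=1)
            manifest["outputs"]["comparison"] = str(out / "comparison.json")
            _finish_stage("compare", t0, flags=report.flags)
        else:
            _finish_stage("compare", t0, skipped=True)
    except Exception as e:
        completed = list(manifest["stages"])
        raise RuntimeError(
            f"pipeline failed at stage {STAGES[len(completed)] if len(completed) < len(STAGES) else '?'}; "
            f"completed: {completed}; outputs: {manifest['outputs']}"
        ) from e

    for key, val in list(manifest["outputs"].items()):
        if isinstance(val, str) and Path(val).exists():
            manifest["outputs"][key] = {"path": val, "sha256_16": _file_hash(Path(val))}
    with open(manifest_path, "w") as f:
        json.dump(manifest, f, indent=1, default=str)
    return manifest
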