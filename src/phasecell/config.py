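"""Run configuration files and the run orchestrator.

A run is described by a single YAML mapping (documented in the README):

.. code-block:: yaml

    scenario: ptm3          # one of phasecell.scenarios.SCENARIOS
    params:                 # optional overrides of the model constants
      epsilon: 0.0
      f0: 0.0
    scenario_args:          # optional generator arguments (widths, seeds…)
      t_end: 250
    sample_every: 1.0       # metrics cadence, time units
    snapshot_every: 50      # optional field-snapshot cadence
    seed: 0                 # recorded; scenarios are deterministic anyway

``execute`` builds the scenario, integrates it, and writes the artifact
set: ``metrics.csv``, ``manifest.json``, ``snapshots.h5`` (if requested),
``substrate.h5`` and a final ``checkpoint.h5``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from . import io as pio
from .dynamics import run_simulation
from .scenarios import build_scenario

__all__ = ["load_config", "execute", "resume"]

_DEFAULTS = {
    "scenario": None,
    "params": {},
    "scenario_args": {},
    "sample_every": 1.0,
    "snapshot_every": None,
    "seed": 0,
}


def load_config(path) -> dict:
    """Read and normalize a YAML run config."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    unknown = set(raw) - set(_DEFAULTS)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = dict(_DEFAULTS)
    cfg.update(raw)
    if not cfg["scenario"]:
        raise ValueError("config must name a scenario")
    return cfg


def execute(cfg: dict, outdir, progress: bool = False):
    """Run a configured simulation and write its artifacts.

    Returns the trajectory.  Deterministic given the config (the model
    has no stochastic terms; substrate generators are seeded through
    ``scenario_args``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    args = dict(cfg.get("scenario_args") or {})
    args.update(cfg.get("params") or {})
    substrate, state, params, run_kw, info = build_scenario(
        cfg["scenario"], **args)
    run_kw = dict(run_kw)
    traj = None
    try:
        traj = run_simulation(
            state, substrate, params,
            sample_every=cfg["sample_every"],
            snapshot_every=cfg["snapshot_every"],
            progress=progress,
            **run_kw,
        )
        termination = traj.termination
        steady = traj.steady_state_time
    except Exception as err:
        pio.write_manifest(outdir / "manifest.json", params, cfg,
                           dict(substrate.meta), f"aborted: {err}",
                           extra={"scenario_info": info})
        raise
    pio.write_metrics_csv(outdir / "metrics.csv", traj)
    pio.save_substrate(outdir / "substrate.h5", substrate)
    pio.save_checkpoint(outdir / "checkpoint.h5", traj.final_state,
                        pio.config_hash(cfg))
    if traj.snapshots:
        grid = state.grid
        snap_fields = {}
        for t, (rho, p) in traj.snapshots.items():
            key = f"{t:012.4f}"
            snap_fields[f"rho_{key}"] = rho
            snap_fields[f"p_{key}"] = p
        pio.save_fields(outdir / "snapshots.h5", grid, **snap_fields)
    pio.write_manifest(
        outdir / "manifest.json", params, cfg, dict(substrate.meta),
        termination, steady,
        extra={"scenario_info": info,
               "final_displacement": float(traj.r[-1]) if len(traj.r) else 0.0},
    )
    return traj


def resume(checkpoint_path, cfg: dict, outdir, progress: bool = False):
    """Continue a checkpointed run to the configured end time.

    The continuation is step-identical to an uninterrupted run: the
    active-region refresh schedule is keyed to absolute step count.
    """
    state, _ = pio.load_checkpoint(checkpoint_path)
    args = dict(cfg.get("scenario_args") or {})
    args.update(cfg.get("params") or {})
    substrate, _, params, run_kw, info = build_scenario(cfg["scenario"], **args)
    traj = run_simulation(
        state, substrate, params,
        sample_every=cfg["sample_every"],
        snapshot_every=cfg["snapshot_every"],
        progress=progress,
        **dict(run_kw),
    )
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pio.write_metrics_csv(outdir / "metrics.csv", traj)
    pio.write_manifest(outdir / "manifest.json", params, cfg,
                       dict(substrate.meta), traj.termination,
                       traj.steady_state_time,
                       extra={"scenario_info": info, "resumed": True})
    return traj
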