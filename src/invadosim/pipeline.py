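"""End-to-end recipes and run manifests.

A recipe is an ordered list of named stages (``generate-data``,
``fit-frap``, ``simulate``, ``sweep-timp2``, ``intervene``,
``spatial``) with per-stage configuration; :func:`run_pipeline`
validates the whole recipe before any stage runs (fail-fast), executes
the stages, writes their artifacts into an output directory and
records a manifest (config hash, package version, seeds, per-stage
artifacts, wall time) so every artifact is traceable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any, Callable, Mapping

import numpy as np
import pandas as pd

from . import __version__
from . import frap, intervention, network, spatial, synthetic, turnover, wellmixed  # noqa: F401 (stages)

__all__ = ["run_pipeline", "load_recipe", "RECIPES"]

log = logging.getLogger("invadosim")

_STAGES: dict[str, Callable[[dict, Path, dict], dict]] = {}


def _stage(name: str):
    def deco(fn):
        _STAGES[name] = fn
        return fn

    return deco


def _config_hash(recipe: Mapping[str, Any]) -> str:
    blob = json.dumps(recipe, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _require(cfg: Mapping[str, Any], stage: str, keys: list[str]) -> None:
    missing = [k for k in keys if k not in cfg]
    if missing:
        raise KeyError(f"stage {stage!r}: missing config keys {missing}")


@_stage("generate-data")
def _generate_data(cfg: dict, out: Path, ctx: dict) -> dict:
    traces = synthetic.generate_dataset(
        n_replicates=int(cfg.get("n", 20)),
        conditions=cfg.get("conditions", ["control", "bafilomycin"]),
        noise=synthetic.NoiseSpec(
            sd=float(cfg.get("noise_sd", 2.0)), seed=int(cfg.get("seed", ctx["seed"]))
        ),
    )
    path = out / "traces.csv"
    synthetic.write_traces_csv(traces, path)
    ctx["traces"] = traces
    return {"traces_csv": str(path), "n_traces": len(traces)}


@_stage("fit-frap")
def _fit_frap(cfg: dict, out: Path, ctx: dict) -> dict:
    traces = ctx.get("traces")
    if traces is None:
        _require(cfg, "fit-frap", ["traces_csv"])
        traces = synthetic.read_traces_csv(cfg["traces_csv"])
    fits = []
    summary = {}
    for cond in sorted({t.condition for t in traces}):
        group = [t for t in traces if t.condition == cond]
        mean = synthetic.mean_trace(group)
        n = cfg.get("components", "auto")
        n = frap.select_model(mean) if n == "auto" else int(n)
        fit = frap.fit_exponential_mixture(mean, n)
        fits.append(fit)
        summary[cond.value] = fit.to_record()
    path = out / "fits.json"
    frap.fits_to_json(fits, path)
    ctx["fits"] = {c: f for c, f in zip(sorted({t.condition for t in traces}), fits)}
    return {"fits_json": str(path), **summary}


def _network_from_cfg(cfg: dict) -> network.ReactionNetwork:
    rates = (
        network.RateTable.from_yaml(cfg["rates_yaml"])
        if "rates_yaml" in cfg
        else network.default_rate_table()
    )
    return network.build_network(max_m14=int(cfg.get("max_m14", 2)), rates=rates)


def _simconfig_from_cfg(cfg: dict) -> wellmixed.SimConfig:
    keys = (
        "timp2_initial_nM",
        "m2_initial_uM",
        "fn_initial_uM",
        "t_end_s",
        "dt_s",
        "output_every_s",
        "turnover_factor",
        "conc_factor",
    )
    return wellmixed.SimConfig(**{k: cfg[k] for k in keys if k in cfg})


@_stage("simulate")
def _simulate(cfg: dict, out: Path, ctx: dict) -> dict:
    net = _network_from_cfg(cfg)
    sim_cfg = _simconfig_from_cfg(cfg)
    res = wellmixed.integrate(net, sim_cfg)
    res.to_frame().to_csv(out / "trajectory.csv", index=False)
    tau = wellmixed.tau_half(res)
    summary = {
        "tau_half_s": tau if np.isfinite(tau) else None,
        "final_ecm_remaining": float(res.ecm_remaining[-1]),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return {"trajectory_csv": str(out / "trajectory.csv"), **summary}


@_stage("sweep-timp2")
def _sweep(cfg: dict, out: Path, ctx: dict) -> dict:
    _require(cfg, "sweep-timp2", ["concs_nM"])
    net = _network_from_cfg(cfg)
    df = wellmixed.timp2_sweep(
        net, cfg["concs_nM"], t_end_s=float(cfg.get("t_end_s", 700.0))
    )
    df.to_csv(out / "timp2_sweep.csv", index=False)
    return {"sweep_csv": str(out / "timp2_sweep.csv"), "argmax_nM": df.attrs["argmax_nM"]}


@_stage("intervene")
def _intervene(cfg: dict, out: Path, ctx: dict) -> dict:
    net = _network_from_cfg(cfg)
    outcomes = intervention.efficacy_curve(
        net,
        _simconfig_from_cfg(cfg),
        modes=cfg.get("modes", intervention.MODES),
        factors=cfg.get("factors", (1.0, 2.0, 5.0, 10.0, 20.0)),
        method=cfg.get("method", "reference"),
    )
    df = intervention.outcomes_to_frame(outcomes)
    df.to_csv(out / "efficacy.csv", index=False)
    return {"efficacy_csv": str(out / "efficacy.csv"), "n_runs": len(outcomes)}


@_stage("spatial")
def _spatial(cfg: dict, out: Path, ctx: dict) -> dict:
    net = _network_from_cfg(cfg)
    spec = spatial.GridSpec(
        shape=tuple(cfg.get("shape", (4, 4, 4))),
        voxel_size_um=float(cfg.get("voxel_size_um", 1.0)),
        patch_shape=tuple(cfg["patch_shape"]) if cfg.get("patch_shape") else None,
        ecm_layers=int(cfg.get("ecm_layers", 1)),
    )
    grid = spatial.build_grid(spec, net)
    sim_cfg = _simconfig_from_cfg(cfg)
    if sim_cfg.dt_s >= grid.max_stable_dt():
        sim_cfg = wellmixed.SimConfig(
            **{**sim_cfg.__dict__, "dt_s": 0.5 * grid.max_stable_dt()}
        )
    res = spatial.run_spatiotemporal(grid, net, sim_cfg)
    pd.DataFrame(
        {"time_s": res.times, "ecm_remaining": res.ecm_remaining}
    ).to_csv(out / "spatial_ecm.csv", index=False)
    tau = spatial.spatial_tau_half(res)
    return {
        "spatial_csv": str(out / "spatial_ecm.csv"),
        "tau_half_s": tau if np.isfinite(tau) else None,
    }


#: built-in recipes reproducing the headline analyses
RECIPES: dict[str, list[dict]] = {
    "frap": [
        {"stage": "generate-data", "n": 20, "noise_sd": 2.0},
        {"stage": "fit-frap", "components": "auto"},
    ],
    "degradation": [
        {"stage": "simulate", "t_end_s": 700.0},
        {"stage": "intervene", "factors": [1.0, 2.0, 5.0, 10.0], "t_end_s": 700.0},
    ],
}


def load_recipe(source) -> list[dict]:
    """A recipe is a YAML/JSON list of stage dicts or a built-in name."""
    if isinstance(source, str) and source in RECIPES:
        return [dict(s) for s in RECIPES[source]]
    import yaml

    with open(source, "r", encoding="utf-8") as fh:
        recipe = yaml.safe_load(fh)
    if not isinstance(recipe, list):
        raise ValueError("recipe must be a list of stage mappings")
    return recipe


def run_pipeline(recipe: list[dict], out_dir, seed: int = 42) -> dict:
    """Execute a recipe; returns (and writes) the run manifest.

    Validation is fail-fast: unknown stages or missing required keys
    abort before any stage executes.
    """
    out = Path(out_dir)
    # validate everything first
    for i, stage_cfg in enumerate(recipe):
        if "stage" not in stage_cfg:
            raise KeyError(f"recipe item {i} lacks a 'stage' key")
        name = stage_cfg["stage"]
        if name not in _STAGES:
            raise KeyError(f"unknown stage {name!r}; known: {sorted(_STAGES)}")
    out.mkdir(parents=True, exist_ok=True)

    manifest: dict[str, Any] = {
        "version": __version__,
        "config_hash": _config_hash({"recipe": recipe, "seed": seed}),
        "seed": seed,
        "stages": [],
    }
    ctx: dict[str, Any] = {"seed": seed}
    for i, stage_cfg in enumerate(recipe):
        name = stage_cfg["stage"]
        stage_dir = out / f"{i:02d}_{name}"
        stage_dir.mkdir(exist_ok=True)
        cfg = {k: v for k, v in stage_cfg.items() if k != "stage"}
        t0 = time.perf_counter()
        log.info("stage %s: start", name)
        artifacts = _STAGES[name](cfg, stage_dir, ctx)
        elapsed = time.perf_counter() - t0
        log.info("stage %s: done in %.2fs", name, elapsed)
        manifest["stages"].append(
            {"stage": name, "config": cfg, "artifacts": artifacts, "wall_time_s": round(elapsed, 3)}
        )
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str)
    )
    # summary omits wall times: deterministic recipes give byte-identical output
    summary = {
        "version": manifest["version"],
        "config_hash": manifest["config_hash"],
        "seed": seed,
        "stages": [
            {"stage": s["stage"], "artifacts": s["artifacts"]} for s in manifest["stages"]
        ],
    }
    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=str)
    )
    return manifest
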