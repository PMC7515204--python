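"""Configuration, pipeline driver, serialization and test-fixture generation.

A run is described by a YAML document (model overrides, stage list, seeds,
output directory).  ``run_pipeline`` executes the requested stages in order,
writes CSV/JSON outputs plus a machine-readable manifest, and is bit-for-bit
reproducible for a fixed config and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .model_core import (
    PRX3_RANGE_UM,
    RateParameters,
    default_initial_state,
    default_parameters,
    network_document,
)
from .simulate import find_steady_state, fractions
from . import experiments as ex
from . import western as ws

__all__ = ["RunConfig", "ConfigError", "load_config", "run_pipeline",
           "generate_fixtures"]

log = logging.getLogger("mitoh2o2")

_STAGES = ("basal", "basal_sweep", "mc_basal", "perturb", "threshold",
           "sensitivity", "mc_efflux", "western")

_TOP_KEYS = {"seed", "output_dir", "model", "stages", "tolerances"}
_MODEL_KEYS = {"prx3_total", "parameters", "efflux_mode", "efflux_eps",
               "init_policy"}
_STAGE_KEYS = {
    "basal": set(),
    "basal_sweep": {"grid", "n_points"},
    "mc_basal": {"n", "range", "method"},
    "perturb": {"kdaao_grid", "t_end"},
    "threshold": {"lo", "hi", "iterations"},
    "sensitivity": {"outputs", "delta", "t_eval"},
    "mc_efflux": {"kdaao_range", "kefflux_range", "n", "times"},
    "western": {"times_min", "n_reps", "band_sigma", "loading_sigma"},
}


class ConfigError(ValueError):
    """A configuration document violated the schema."""


@dataclass
class RunConfig:
    """Validated run description."""

    seed: int = 0
    output_dir: str = "results/run"
    prx3_total: float = 62.0
    init_policy: str = "zeros"
    params: RateParameters = field(default_factory=default_parameters)
    stages: list[dict] = field(default_factory=lambda: [{"name": "basal"}])
    raw: dict = field(default_factory=dict)


def _validate_keys(mapping: dict, allowed: set, where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {where}; "
                          f"allowed: {sorted(allowed)}")


def load_config(path: str | Path | None = None, text: str | None = None) -> RunConfig:
    """Parse and validate a YAML run configuration; an empty document means
    pure defaults."""
    if text is None:
        text = Path(path).read_text() if path is not None else ""
    doc = yaml.safe_load(text) or {}
    if not isinstance(doc, dict):
        raise ConfigError("configuration must be a mapping")
    _validate_keys(doc, _TOP_KEYS, "top level")

    model = doc.get("model") or {}
    _validate_keys(model, _MODEL_KEYS, "model")
    params = default_parameters()
    overrides = dict(model.get("parameters") or {})
    if "efflux_mode" in model:
        overrides["efflux_mode"] = model["efflux_mode"]
    if "efflux_eps" in model:
        overrides["efflux_eps"] = model["efflux_eps"]
    try:
        params = params.with_values(**overrides)
    except KeyError as exc:
        raise ConfigError(f"unknown rate parameter: {exc}") from exc

    stages = doc.get("stages") or [{"name": "basal"}]
    norm_stages = []
    for st in stages:
        if isinstance(st, str):
            st = {"name": st}
        name = st.get("name")
        if name not in _STAGES:
            raise ConfigError(f"unknown stage {name!r}; valid stages: {_STAGES}")
        _validate_keys({k: v for k, v in st.items() if k != "name"},
                       _STAGE_KEYS[name], f"stage {name!r}")
        norm_stages.append(dict(st))

    return RunConfig(
        seed=int(doc.get("seed", 0)),
        output_dir=str(doc.get("output_dir", "results/run")),
        prx3_total=float(model.get("prx3_total", 62.0)),
        init_policy=str(model.get("init_policy", "zeros")),
        params=params,
        stages=norm_stages,
        raw=doc,
    )


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, default=float))


def run_pipeline(config: RunConfig, output_dir: str | Path | None = None) -> dict:
    """Execute the configured stages; returns the manifest."""
    outdir = Path(output_dir or config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": config.raw,
        "config_sha256": hashlib.sha256(
            json.dumps(config.raw, sort_keys=True).encode()).hexdigest(),
        "stages": [],
        "outputs": [],
    }
    p = config.params
    y0 = default_initial_state(config.prx3_total, policy=config.init_policy)

    def emit(name: str, df_or_obj, kind: str) -> None:
        path = outdir / name
        if kind == "csv":
            df_or_obj.to_csv(path, index=False, float_format="%.12g")
        else:
            _write_json(path, df_or_obj)
        manifest["outputs"].append(name)

    for st in config.stages:
        name = st["name"]
        log.info("running stage %s", name)
        try:
            if name == "basal":
                ss = find_steady_state(y0, p)
                doc = json.loads(ss.to_json())
                doc["fractions"] = fractions(ss.state).as_dict()
                emit("basal_steady_state.json", doc, "json")
            elif name == "basal_sweep":
                res = ex.basal_prx3_sweep(grid=st.get("grid"), params=p,
                                          n_points=int(st.get("n_points", 10)))
                emit("basal_prx3_sweep.csv", res.table, "csv")
            elif name == "mc_basal":
                df = ex.monte_carlo_basal(
                    n=int(st.get("n", 10_000)),
                    prx3_range=tuple(st.get("range", PRX3_RANGE_UM)),
                    seed=config.seed, params=p,
                    method=st.get("method", "integrate"))
                emit("mc_basal_samples.csv", df, "csv")
                summary = {
                    "n": len(df),
                    "h2o2_nM_percentiles": {
                        str(q): float(np.percentile(df["h2o2_nM"], q))
                        for q in (2.5, 25, 50, 75, 97.5)},
                    "h2o2_nM_min": float(df["h2o2_nM"].min()),
                    "h2o2_nM_max": float(df["h2o2_nM"].max()),
                }
                emit("mc_basal_summary.json", summary, "json")
            elif name == "perturb":
                res = ex.perturbation_sweep(
                    kdaao_grid=st.get("kdaao_grid", ex.TABLE_GRID_KDAAO),
                    prx3_total=config.prx3_total,
                    t_end=float(st.get("t_end", 3600.0)),
                    params=p, keep_trajectories=False)
                emit("perturbation_sweep.csv", res.table, "csv")
            elif name == "threshold":
                kd = ex.collapse_threshold(
                    lo=float(st.get("lo", 0.0)), hi=float(st.get("hi", 100.0)),
                    prx3_total=config.prx3_total,
                    iterations=int(st.get("iterations", 12)), params=p)
                emit("collapse_threshold.json",
                     {"kdaao_star_uM_per_s": kd}, "json")
            elif name == "sensitivity":
                df = ex.sensitivity_analysis(
                    outputs=tuple(st.get("outputs",
                                         ("H2O2", "Prx3-SH", "Prx3-SS", "Prx3-SOOH"))),
                    delta=float(st.get("delta", 0.10)),
                    t_eval=float(st.get("t_eval", 5.0)),
                    prx3_total=config.prx3_total, params=p)
                emit("sensitivity.csv", df, "csv")
            elif name == "mc_efflux":
                df = ex.efflux_monte_carlo(
                    kdaao_range=tuple(st.get("kdaao_range", (50.0, 100.0))),
                    kefflux_range=tuple(st.get("kefflux_range", (50.0, 100.0))),
                    n=int(st.get("n", 10_000)), seed=config.seed,
                    times=st.get("times"), prx3_total=config.prx3_total,
                    params=p)
                emit("mc_efflux_percentiles.csv", df, "csv")
            elif name == "western":
                noise = ws.NoiseModel(
                    band_sigma=float(st.get("band_sigma", 0.15)),
                    loading_sigma=float(st.get("loading_sigma", 0.20)),
                    seed=config.seed)
                obs = ws.simulate_westerns(
                    times_min=tuple(st.get("times_min", (15.0, 30.0, 60.0))),
                    n_reps=int(st.get("n_reps", 3)), noise=noise,
                    prx3_total=config.prx3_total, params=p)
                fr = ws.densitometry_fractions(obs)
                emit("western_observations.csv", fr, "csv")
                statsdoc = [ws.anova_tukey(fr, t)
                            for t in sorted(fr["time_min"].unique())]
                emit("western_statistics.json", statsdoc, "json")
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        manifest["stages"].append(name)

    _write_json(outdir / "model_network.json", network_document(p))
    manifest["outputs"].append("model_network.json")
    _write_json(outdir / "manifest.json", manifest)
    return manifest


def generate_fixtures(seed: int = 0, output_dir: str | Path = "fixtures") -> list[Path]:
    """Write miniature deterministic inputs for the test suite: a tiny basal
    Monte Carlo sample and a 3-dose synthetic Western set."""
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    mc = ex.monte_carlo_basal(n=5, seed=seed, method="refine")
    path = outdir / "mc_basal_tiny.csv"
    mc.to_csv(path, index=False, float_format="%.12g")
    written.append(path)

    dose_map = ws.default_dose_map(doses=(0.0, 5.0, 25.0))
    obs = ws.simulate_westerns(dose_map=dose_map, times_min=(15.0,),
                               n_reps=3, noise=ws.NoiseModel(seed=seed))
    path = outdir / "western_tiny.csv"
    obs.to_csv(path, index=False, float_format="%.12g")
    written.append(path)
    return written
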