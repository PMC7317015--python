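"""Run configuration, validation and the end-to-end pipeline.

A single YAML file configures a full run: input paths (or a synthetic
simulation), marker filtering, the model list, the cross-validation
scenario and all seeds.  Unknown keys are rejected so typos fail fast.
All randomness flows from one master seed recorded in the manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibration import MCMCConfig
from .envcoef import K_ALPHA, K_BETA
from .envs import ECMatrix, env_covariance, standardize_ec
from .evaluate import SCENARIOS, run_scenario
from .gei import METData, MODEL_NAMES
from .markers import (MarkerMatrix, compute_kinship, filter_markers, impute_missing,
                      ld_prune, read_csv_matrix, read_plink_raw, read_vcf)
from .phenology import CGMConfig, WeatherSeries
from .simulate import SimConfig, simulate

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "load_config", "run_pipeline"]


@dataclass
class FilterConfig:
    maf_min: float = 0.05
    max_het: float = 0.05
    max_missing: float = 0.05
    ld_window: int = 100
    ld_step: int = 5
    ld_r2: float = 0.8
    prune: bool = True


@dataclass
class InputConfig:
    genotypes: str | None = None
    genotype_format: str = "csv"      # csv | vcf | raw
    pheno: str | None = None
    weather: str | None = None
    env_meta: str | None = None
    ec: str | None = None


@dataclass
class RunConfig:
    """Validated top-level configuration (defaults reproduce the study
    settings: 6 folds, 10 repeats, stepwise penalties 3.7/8, LD pruning
    100/5/0.8, 5% marker filters)."""

    scenario: str = "CVrandom"
    models: tuple[str, ...] = ("EG", "EG_GxW", "EG_HD", "EG_GxW_HD")
    n_folds: int = 6
    n_repeats: int | None = None
    seed: int = 0
    k_alpha: float = K_ALPHA
    k_beta: float = K_BETA
    out_dir: str = "results"
    simulate: dict | None = None      # SimConfig overrides; None → real inputs
    inputs: InputConfig = field(default_factory=InputConfig)
    filters: FilterConfig = field(default_factory=FilterConfig)
    mcmc: dict = field(default_factory=dict)
    cgm: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}, got {self.scenario!r}")
        bad = [m for m in self.models if m not in MODEL_NAMES]
        if bad:
            raise ValueError(f"unknown models {bad}; valid: {MODEL_NAMES}")
        self.mcmc_config = MCMCConfig(**{**self.mcmc, "rng_seed": self.seed})
        self.cgm_config = CGMConfig(**self.cgm)


def _build(cls, data: dict, path: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown configuration keys at {path}: {sorted(unknown)}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if dataclasses.is_dataclass(f.type) if isinstance(f.type, type) else False:
            v = _build(f.type, v, f"{path}.{f.name}")
        kwargs[f.name] = v
    return cls(**kwargs)


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration; an empty file yields
    all defaults, unknown keys raise."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError("configuration must be a mapping")
    if "models" in data:
        data["models"] = tuple(data["models"])
    if "inputs" in data:
        data["inputs"] = _build(InputConfig, data["inputs"], "inputs")
    if "filters" in data:
        data["filters"] = _build(FilterConfig, data["filters"], "filters")
    return _build(RunConfig, data, "<root>")


_READERS = {"csv": read_csv_matrix, "vcf": read_vcf, "raw": read_plink_raw}


def load_weather(weather_path, env_meta_path=None) -> dict[str, WeatherSeries]:
    df = pd.read_csv(weather_path)
    meta = None
    if env_meta_path:
        meta = pd.read_csv(env_meta_path).set_index("env_id")
    out = {}
    for env, sub in df.groupby("env_id"):
        lat = float(meta.loc[env, "latitude"]) if meta is not None else None
        sow = (pd.to_datetime(meta.loc[env, "sowing_date"]).date()
               if meta is not None else None)
        out[str(env)] = WeatherSeries.from_frame(str(env), sub, sowing_date=sow,
                                                 latitude=lat)
    return out


def prepare_kinship(markers: MarkerMatrix, filters: FilterConfig):
    """Standard marker pipeline: filter → LD prune → impute → kinship."""
    m = filter_markers(markers, filters.maf_min, filters.max_het, filters.max_missing)
    if filters.prune and m.positions is not None:
        m = ld_prune(m, filters.ld_window, filters.ld_step, filters.ld_r2)
    m = impute_missing(m)
    return m, compute_kinship(m)


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(cfg: RunConfig):
    """Execute the full pipeline and write results plus a manifest.

    Stages: data (load or simulate) → kinship → environment covariance →
    cross-validation scenario.  Any stage error aborts with the stage
    name attached.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"version": __version__, "seed": cfg.seed,
                "scenario": cfg.scenario, "models": list(cfg.models),
                "config": dataclasses.asdict(cfg), "inputs": {}}

    stage = "data"
    try:
        if cfg.simulate is not None:
            sim = simulate(SimConfig(**cfg.simulate), seed=cfg.seed)
            markers, met, weathers = sim.markers, sim.met, sim.weathers
            omega = sim.omega
        else:
            inp = cfg.inputs
            for name in ("genotypes", "pheno", "weather", "ec"):
                p = getattr(inp, name)
                if p is None:
                    raise ValueError(f"inputs.{name} is required when not simulating")
                if not Path(p).exists():
                    raise FileNotFoundError(f"inputs.{name}: {p} does not exist")
                manifest["inputs"][name] = _sha256(p)
            markers = _READERS[inp.genotype_format](inp.genotypes)
            met = METData.from_csv(inp.pheno)
            stage = "phenology"
            weathers = load_weather(inp.weather, inp.env_meta)
            omega = standardize_ec(pd.read_csv(inp.ec, index_col=0))

        stage = "kinship"
        _, K = prepare_kinship(markers, cfg.filters)
        stage = "environment covariance"
        W = env_covariance(omega)
        stage = "cross-validation"
        result = run_scenario(
            met, cfg.scenario, list(cfg.models), K, W=W, omega=omega,
            weathers=weathers, mcmc_cfg=cfg.mcmc_config, cgm_cfg=cfg.cgm_config,
            seed=cfg.seed, n_folds=cfg.n_folds, n_repeats=cfg.n_repeats,
            markers=markers)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    result.gy.to_csv(out / "gy_predictive_ability.csv", index=False)
    result.hd.to_csv(out / "hd_metrics.csv", index=False)
    summary = result.summary()
    summary.to_csv(out / "summary.csv")
    manifest["notices"] = result.notices
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return result
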