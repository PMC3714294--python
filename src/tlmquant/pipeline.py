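"""Run configuration and the end-to-end pipeline.

One YAML config drives a full run: (optionally) simulate a ground-truthed
series, segment every phase image, measure and normalize fluorescence, fit
or load the noise-baseline model, compute corrected heterogeneity, and
render plots.  Outputs land in a fresh run directory; inputs of earlier
stages are never mutated.  A run log records package version, parameters
and seed, and a rerun with the same config reproduces the CSV outputs
byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .heterogeneity import (
    NoiseModel, compute_frame_stats, correct_heterogeneity, fit_noise_baseline,
    heterogeneity_table, summarize_timepoints,
)
from .image_io import load_timeseries
from .quantification import quantify_timeseries
from .segmentation import Kernel, SegmentationConfig
from .synthetic import ScenarioParams, generate_timeseries
from .visualization import ColorScheme, build_heatmap, render_barchart, render_heatmap

__all__ = ["RunConfig", "ConfigError", "StageError", "validate_config", "run_pipeline"]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid run configuration; ``errors`` lists every problem found."""

    def __init__(self, errors: list[str]):
        super().__init__("; ".join(errors))
        self.errors = errors


class StageError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Typed, defaulted configuration of one pipeline run."""

    outdir: Path
    seed: int = 0
    log_level: str = "INFO"
    simulate: dict[str, Any] | None = None  # scenario/duration_h/interval_h/...
    manifest: Path | None = None
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    method: str = "direct"  # 'direct' | 'inverted' (the mask-arithmetic path)
    normalization: str = "subtract"  # 'subtract' | 'ratio'
    model: Path | None = None  # existing noise model; fitted from run if None
    heatmap: bool = True
    n_bins: int = 64
    colors: Path | None = None
    bar_times: list[float] = field(default_factory=list)


_TOP_KEYS = {
    "outdir", "seed", "log_level", "simulate", "manifest",
    "segmentation", "quantification", "model", "plot",
}
_SEG_KEYS = {
    "rolling_ball_radius", "light_background", "kernel", "normalize_kernel",
    "threshold_method", "fixed_threshold", "polarity", "min_area", "max_area",
    "connectivity", "exclude_edges",
}
_SIM_KEYS = {
    "scenario", "duration_h", "interval_h", "n_seed_cells", "field_shape", "seed",
}
_PLOT_KEYS = {"heatmap", "n_bins", "colors", "bar_times"}


def validate_config(path: str | Path) -> RunConfig:
    """Parse + validate a YAML run config, reporting *all* errors at once."""
    path = Path(path)
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    except (OSError, yaml.YAMLError) as exc:
        raise ConfigError([f"cannot read config {path}: {exc}"])
    if not isinstance(raw, dict):
        raise ConfigError([f"config root must be a mapping, got {type(raw).__name__}"])

    errors: list[str] = []
    for key in raw:
        if key not in _TOP_KEYS:
            errors.append(f"unknown config key {key!r}; allowed: {sorted(_TOP_KEYS)}")

    if "outdir" not in raw:
        errors.append("missing required key 'outdir'")
    cfg = RunConfig(outdir=Path(raw.get("outdir", ".")))
    cfg.seed = _expect_int(raw, "seed", cfg.seed, errors, minimum=0)
    cfg.log_level = str(raw.get("log_level", cfg.log_level)).upper()
    if cfg.log_level not in ("DEBUG", "INFO", "WARNING", "ERROR"):
        errors.append(f"log_level {cfg.log_level!r} not one of DEBUG/INFO/WARNING/ERROR")

    sim = raw.get("simulate")
    if sim is not None:
        if not isinstance(sim, dict):
            errors.append("'simulate' must be a mapping")
        else:
            for key in sim:
                if key not in _SIM_KEYS:
                    errors.append(f"unknown simulate key {key!r}")
            if sim.get("scenario", "homogeneous") not in ("homogeneous", "noisy", "bistable"):
                errors.append(
                    f"simulate.scenario {sim.get('scenario')!r}; "
                    "allowed: homogeneous, noisy, bistable"
                )
            cfg.simulate = sim
    if raw.get("manifest") is not None:
        cfg.manifest = Path(raw["manifest"])
        if not cfg.manifest.exists():
            errors.append(f"manifest path not resolvable: {cfg.manifest}")
    if cfg.simulate is None and cfg.manifest is None:
        errors.append("either 'simulate' or 'manifest' must be given")

    seg = raw.get("segmentation", {}) or {}
    if not isinstance(seg, dict):
        errors.append("'segmentation' must be a mapping")
        seg = {}
    for key in seg:
        if key not in _SEG_KEYS:
            errors.append(f"unknown segmentation key {key!r}; allowed: {sorted(_SEG_KEYS)}")
    seg_kwargs: dict[str, Any] = {
        k: seg[k] for k in seg
        if k in _SEG_KEYS and k not in ("kernel", "normalize_kernel")
    }
    if "rolling_ball_radius" in seg_kwargs:
        seg_kwargs["rolling_ball_radius"] = _expect_int(
            seg, "rolling_ball_radius", 50, errors, minimum=1,
            prefix="segmentation.",
        )
    if seg.get("kernel") is not None:
        try:
            seg_kwargs["kernel"] = Kernel(
                values=np.asarray(seg["kernel"], dtype=float),
                normalize=bool(seg.get("normalize_kernel", False)),
            )
        except (ValueError, TypeError) as exc:
            errors.append(f"segmentation.kernel: {exc}")
    try:
        cfg.segmentation = SegmentationConfig(**seg_kwargs)
    except (ValueError, TypeError) as exc:
        errors.append(f"segmentation: {exc}")

    quant = raw.get("quantification", {}) or {}
    if not isinstance(quant, dict):
        errors.append("'quantification' must be a mapping")
        quant = {}
    cfg.method = quant.get("method", cfg.method)
    if cfg.method not in ("direct", "inverted"):
        errors.append(f"quantification.method {cfg.method!r}; allowed: direct, inverted")
    cfg.normalization = quant.get("normalization", cfg.normalization)
    if cfg.normalization not in ("subtract", "ratio"):
        errors.append(
            f"quantification.normalization {cfg.normalization!r}; allowed: subtract, ratio"
        )

    if raw.get("model") is not None:
        cfg.model = Path(raw["model"])
        if not cfg.model.exists():
            errors.append(f"model path not resolvable: {cfg.model}")

    plot = raw.get("plot", {}) or {}
    if not isinstance(plot, dict):
        errors.append("'plot' must be a mapping")
        plot = {}
    for key in plot:
        if key not in _PLOT_KEYS:
            errors.append(f"unknown plot key {key!r}; allowed: {sorted(_PLOT_KEYS)}")
    cfg.heatmap = bool(plot.get("heatmap", cfg.heatmap))
    cfg.n_bins = _expect_int(plot, "n_bins", cfg.n_bins, errors, minimum=2, prefix="plot.")
    if plot.get("colors") is not None:
        cfg.colors = Path(plot["colors"])
        if not cfg.colors.exists():
            errors.append(f"plot.colors path not resolvable: {cfg.colors}")
    bar_times = plot.get("bar_times", [])
    if not isinstance(bar_times, (list, tuple)):
        errors.append("plot.bar_times must be a list of hours")
    else:
        cfg.bar_times = [float(t) for t in bar_times]

    if errors:
        raise ConfigError(errors)
    return cfg


def _expect_int(
    mapping: dict, key: str, default: int, errors: list[str],
    minimum: int | None = None, prefix: str = "",
) -> int:
    value = mapping.get(key, default)
    if not isinstance(value, int) or isinstance(value, bool):
        errors.append(f"{prefix}{key} must be an integer, got {value!r}")
        return default
    if minimum is not None and value < minimum:
        errors.append(f"{prefix}{key} must be >= {minimum}, got {value}")
        return default
    return value


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            logger.info("stage %s", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 — named-stage abort contract
                raise StageError(name, exc) from exc
        return inner
    return wrap


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the configured stages in order; returns artifact paths.

    Artifacts per run directory: ``data/`` (if simulating), then
    ``measurements.csv``, ``frame_stats.csv``, ``model.json``,
    ``heterogeneity.csv`` and the requested plots.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    artifacts: dict[str, Path] = {}
    _write_runlog(outdir, config)

    if config.simulate is not None:
        manifest = _stage("simulate")(_simulate)(config, outdir)
        artifacts["data"] = manifest.parent
    else:
        manifest = config.manifest

    series = _stage("load")(load_timeseries)(manifest)

    measurements = _stage("quantify")(quantify_timeseries)(
        series, config.segmentation,
        method=config.method, norm_mode=config.normalization,
    )
    measurements.to_csv(outdir / "measurements.csv", index=False)
    artifacts["measurements"] = outdir / "measurements.csv"

    stats = _stage("frame-stats")(compute_frame_stats)(measurements)
    pd.DataFrame([dataclasses.asdict(s) for s in stats]).to_csv(
        outdir / "frame_stats.csv", index=False
    )
    artifacts["frame_stats"] = outdir / "frame_stats.csv"

    if config.model is not None:
        model = _stage("fit-baseline")(NoiseModel.load)(config.model)
    else:
        model = _stage("fit-baseline")(fit_noise_baseline)(stats)
    artifacts["model"] = model.save(outdir / "model.json")

    records = _stage("heterogeneity")(correct_heterogeneity)(stats, model)
    heterogeneity_table(records).to_csv(outdir / "heterogeneity.csv", index=False)
    artifacts["heterogeneity"] = outdir / "heterogeneity.csv"

    if config.heatmap:
        scheme = ColorScheme.from_csv(config.colors) if config.colors else None
        grid = _stage("plot")(build_heatmap)(measurements, n_bins=config.n_bins)
        artifacts["heatmap"] = _stage("plot")(render_heatmap)(
            grid, scheme, outdir / "heatmap.pdf"
        )
    if config.bar_times:
        summary = _stage("plot")(summarize_timepoints)(stats, config.bar_times)
        artifacts["bars"] = _stage("plot")(render_barchart)(
            summary, outdir / "bars.pdf"
        )
    logger.info("run complete: %s", ", ".join(str(p) for p in artifacts.values()))
    return artifacts


def _simulate(config: RunConfig, outdir: Path) -> Path:
    sim = dict(config.simulate or {})
    scenario = sim.pop("scenario", "homogeneous")
    duration = float(sim.pop("duration_h", 6.0))
    interval = float(sim.pop("interval_h", 1.0))
    sim.setdefault("seed", config.seed)
    if "field_shape" in sim:
        sim["field_shape"] = tuple(sim["field_shape"])
    params = ScenarioParams.preset(scenario, **sim)
    return generate_timeseries(params, duration, interval, outdir / "data")


def _write_runlog(outdir: Path, config: RunConfig) -> None:
    entry = dataclasses.asdict(config)
    entry["segmentation"]["kernel"] = config.segmentation.kernel.values.tolist()
    entry["version"] = __version__
    with open(outdir / "run.json", "w") as fh:
        json.dump(entry, fh, indent=1, default=str)
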