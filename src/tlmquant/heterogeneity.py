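"""Population statistics and noise-baseline correction.

The expression heterogeneity of a population at one time point is the
standard deviation of the per-cell normalized fluorescence in that frame.
Even a perfectly homogeneous reporter shows a nonzero SD from shot noise,
segmentation error and illumination drift, and this measurement floor grows
with the mean brightness.  A control strain whose reporter is driven by a
tunable inducible promoter (hence homogeneous by construction) is therefore
imaged at several induction levels; the per-frame SD is regressed on the
per-frame mean, and the fitted line predicts the noise floor at any mean
intensity.  Subtracting the prediction from an observed SD isolates the
biological heterogeneity.

The fitted line is a separate artifact (JSON) so one control experiment can
correct any number of test series.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = [
    "FrameStats",
    "NoiseModel",
    "HeterogeneityRecord",
    "frame_stats",
    "compute_frame_stats",
    "fit_noise_baseline",
    "correct_heterogeneity",
    "pool_stats",
    "summarize_timepoints",
    "count_modes",
    "heterogeneity_table",
]

logger = logging.getLogger(__name__)

HETEROGENEITY_COLUMNS = [
    "frame_index", "time_h", "n_cells", "mean_fluor",
    "raw_sd", "predicted_sd", "corrected",
]


@dataclass(frozen=True)
class FrameStats:
    """n, mean and sample SD of normalized cell fluorescence in one frame."""

    frame_index: int
    time_h: float
    n_cells: int
    mean_fluor: float
    sd_fluor: float

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("a frame needs at least one cell")
        if self.sd_fluor < 0:
            raise ValueError("sd_fluor must be >= 0")
        if self.n_cells == 1 and self.sd_fluor != 0:
            raise ValueError("sd_fluor must be 0 for a single cell")


@dataclass(frozen=True)
class NoiseModel:
    """SD-on-mean regression line fitted to a homogeneous control."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise ValueError("noise model needs >= 3 points")
        if not 0 <= self.r_squared <= 1:
            raise ValueError("r_squared must lie in [0, 1]")

    def predict(self, mean_fluor: float | np.ndarray) -> float | np.ndarray:
        return self.slope * mean_fluor + self.intercept

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "NoiseModel":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass(frozen=True)
class HeterogeneityRecord:
    """Observed, predicted and corrected SD for one frame."""

    frame_index: int
    time_h: float
    n_cells: int
    mean_fluor: float
    raw_sd: float
    predicted_sd: float
    corrected: float


def frame_stats(
    values: Sequence[float] | np.ndarray, *, frame_index: int = 0, time_h: float = 0.0
) -> FrameStats:
    """Mean and sample SD (n−1 denominator; 0 when n = 1) of one frame."""
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if values.size == 0:
        raise ValueError("frame has no valid measurements")
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return FrameStats(
        frame_index=frame_index,
        time_h=time_h,
        n_cells=int(values.size),
        mean_fluor=float(values.mean()),
        sd_fluor=sd,
    )


def compute_frame_stats(
    measurements: pd.DataFrame, value_column: str = "mean_normalized"
) -> list[FrameStats]:
    """Per-frame stats from a measurement table (frames with no valid
    measurement are skipped with a warning, never reported as zero rows)."""
    out: list[FrameStats] = []
    for (idx, t), group in measurements.groupby(["frame_index", "time_h"], sort=True):
        vals = group[value_column].to_numpy(dtype=float)
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            logger.warning("frame %s (t=%.3g h): no valid measurements, skipped", idx, t)
            continue
        out.append(frame_stats(vals, frame_index=int(idx), time_h=float(t)))
    return out


def fit_noise_baseline(
    points: Iterable[tuple[float, float]] | Sequence[FrameStats],
) -> NoiseModel:
    """Ordinary least squares of per-frame SD on per-frame mean.

    ``points`` is a list of (mean, sd) pairs or of :class:`FrameStats`.
    Unweighted: every frame counts once regardless of its cell count.
    """
    pts = [
        (p.mean_fluor, p.sd_fluor) if isinstance(p, FrameStats) else (p[0], p[1])
        for p in points
    ]
    if len(pts) < 3:
        raise ValueError("noise baseline fit needs >= 3 points")
    x = np.array([p[0] for p in pts], dtype=float)
    y = np.array([p[1] for p in pts], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: all mean intensities identical")
    fit = sstats.linregress(x, y)
    return NoiseModel(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        n_points=len(pts),
    )


def correct_heterogeneity(
    stats: Sequence[FrameStats], model: NoiseModel
) -> list[HeterogeneityRecord]:
    """Subtract the predicted noise floor from each frame's observed SD.

    ``corrected = raw_sd − (slope·mean + intercept)``; negative values are
    preserved — clamping them would hide model misfit.
    """
    return [
        HeterogeneityRecord(
            frame_index=s.frame_index,
            time_h=s.time_h,
            n_cells=s.n_cells,
            mean_fluor=s.mean_fluor,
            raw_sd=s.sd_fluor,
            predicted_sd=float(model.predict(s.mean_fluor)),
            corrected=s.sd_fluor - float(model.predict(s.mean_fluor)),
        )
        for s in stats
    ]


def heterogeneity_table(records: Sequence[HeterogeneityRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records], columns=HETEROGENEITY_COLUMNS)


def pool_stats(stats: Sequence[FrameStats]) -> tuple[int, float, float]:
    """Exact (n, mean, sample SD) of the concatenation of several frames,
    computed from the per-frame summaries alone."""
    if not stats:
        raise ValueError("nothing to pool")
    n = sum(s.n_cells for s in stats)
    grand = sum(s.n_cells * s.mean_fluor for s in stats) / n
    if n == 1:
        return n, grand, 0.0
    ss = sum(
        (s.n_cells - 1) * s.sd_fluor**2 + s.n_cells * (s.mean_fluor - grand) ** 2
        for s in stats
    )
    return n, grand, math.sqrt(ss / (n - 1))


def summarize_timepoints(
    stats: Sequence[FrameStats],
    times: Sequence[float],
    *,
    condition: str = "",
    window: float | None = None,
    tolerance: float | None = None,
) -> pd.DataFrame:
    """Combined mean/SD at selected hours, for bar charts with error bars.

    Each requested time selects the nearest frame (earlier frame on an
    exact tie); with ``window`` set, all frames within ±window are pooled
    (combined statistics equal those of the concatenated raw values).
    ``tolerance`` bounds the request-to-frame distance; a requested time
    beyond the series span is an error.
    """
    if not stats:
        raise ValueError("no frame statistics to summarize")
    stats = sorted(stats, key=lambda s: (s.time_h, s.frame_index))
    t_all = np.array([s.time_h for s in stats])
    rows = []
    for req in times:
        if req < t_all.min() or req > t_all.max():
            raise ValueError(
                f"requested time {req} h outside series span "
                f"[{t_all.min()}, {t_all.max()}] h"
            )
        if window is not None:
            chosen = [s for s in stats if abs(s.time_h - req) <= window]
        else:
            # stable argmin keeps the earlier frame on an exact distance tie
            chosen = [stats[int(np.argmin(np.abs(t_all - req)))]]
        dist = min(abs(s.time_h - req) for s in chosen)
        if tolerance is not None and dist > tolerance:
            raise ValueError(f"no frame within {tolerance} h of requested {req} h")
        n, mean, sd = pool_stats(chosen)
        rows.append((condition, req, chosen[0].time_h, n, mean, sd))
    return pd.DataFrame(
        rows,
        columns=["condition", "time_requested", "time_h", "n_cells", "mean_fluor", "sd_fluor"],
    )


def count_modes(
    values: Sequence[float] | np.ndarray,
    n_bins: int = 16,
    smooth_width: int = 3,
    min_height: float = 0.1,
) -> int:
    """Descriptive count of local maxima in the smoothed intensity histogram.

    An exploratory aid for telling bistable from merely noisy populations,
    not a formal bimodality test.  Peaks below ``min_height`` of the
    tallest peak are ignored (histogram sampling noise).
    """
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if values.size == 0:
        raise ValueError("no values")
    if np.ptp(values) == 0:
        return 1
    hist, _ = np.histogram(values, bins=n_bins)
    kernel = np.ones(smooth_width) / smooth_width
    smooth = np.convolve(hist.astype(float), kernel, mode="same")
    padded = np.concatenate([[-np.inf], smooth, [-np.inf]])
    # strict-left / loose-right comparison counts plateaus once
    peaks = (padded[1:-1] > padded[:-2]) & (padded[1:-1] >= padded[2:])
    peaks &= smooth >= min_height * smooth.max()
    runs = 0
    prev = False
    for p in peaks:
        if p and not prev:
            runs += 1
        prev = p
    return runs
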