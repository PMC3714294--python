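"""Time-resolved intensity heatmaps and summary bar charts.

The heatmap shows, for every frame (x, hours), the histogram of per-cell
normalized fluorescence (y, AU); color encodes the number of cells in each
(time, intensity) bin.  A homogeneous population draws a single tight band,
a noisy one a broad smear, and a bistable one two separated bands.  The
color scale comes from a small CSV of (count upper bound, color) pairs so
schemes can be swapped without touching code.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import matplotlib
matplotlib.use("Agg")  # headless, deterministic
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.colors import to_rgb

__all__ = ["ColorScheme", "HeatmapGrid", "build_heatmap", "render_heatmap", "render_barchart"]


@dataclass(frozen=True)
class ColorScheme:
    """Ordered (count upper bound → color) steps; counts beyond the last
    bound saturate to the last color."""

    bounds: tuple[float, ...]
    colors: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.bounds) != len(self.colors):
            raise ValueError("bounds and colors must have equal length")
        if len(self.bounds) < 2:
            raise ValueError("a color scheme needs at least 2 entries")
        if any(b2 <= b1 for b1, b2 in zip(self.bounds, self.bounds[1:])):
            raise ValueError("bounds must be strictly increasing")

    @classmethod
    def from_csv(cls, path: str | Path) -> "ColorScheme":
        """Read a two-column (upper_bound, color) CSV; header row optional."""
        bounds, colors = [], []
        with open(path, newline="") as fh:
            for row in csv.reader(fh):
                if not row or not row[0].strip():
                    continue
                try:
                    bound = float(row[0])
                except ValueError:
                    continue  # header line
                if len(row) < 2 or not row[1].strip():
                    raise ValueError(f"{path}: row {row!r} lacks a color")
                bounds.append(bound)
                colors.append(row[1].strip())
        return cls(bounds=tuple(bounds), colors=tuple(colors))

    @classmethod
    def default(cls) -> "ColorScheme":
        """White → yellow → red → black with doubling count steps."""
        return cls(
            bounds=(0, 1, 2, 4, 8, 16, 32, 64),
            colors=("#ffffff", "#fff7bc", "#fee391", "#fec44f",
                    "#fe9929", "#ec7014", "#cc4c02", "#662506"),
        )

    def color_for(self, count: float) -> str:
        """Color of the first bound ≥ count; the last color past the top."""
        idx = int(np.searchsorted(self.bounds, count, side="left"))
        return self.colors[min(idx, len(self.colors) - 1)]

    def rgb_image(self, counts: np.ndarray) -> np.ndarray:
        """Map a count grid to an (h, w, 3) float RGB image."""
        lut = np.array([to_rgb(c) for c in self.colors])
        idx = np.searchsorted(self.bounds, counts, side="left")
        return lut[np.minimum(idx, len(self.colors) - 1)]


@dataclass(frozen=True)
class HeatmapGrid:
    """Cells per (time, intensity) bin: counts[i, j] at intensity bin i
    (edges ``intensity_edges``) and frame time ``time_bins[j]``."""

    time_bins: np.ndarray  # (n_frames,) hours
    intensity_edges: np.ndarray  # (n_bins + 1,) AU
    counts: np.ndarray  # (n_bins, n_frames)

    def __post_init__(self) -> None:
        if self.counts.shape != (len(self.intensity_edges) - 1, len(self.time_bins)):
            raise ValueError("counts shape inconsistent with bin axes")
        if (self.counts < 0).any():
            raise ValueError("counts must be >= 0")


def build_heatmap(
    measurements: pd.DataFrame,
    n_bins: int = 64,
    value_range: tuple[float, float] | None = None,
    value_column: str = "mean_normalized",
) -> HeatmapGrid:
    """Histogram per-cell normalized intensity per frame into fixed bins.

    One column per frame; global bins over ``value_range`` (default: the
    observed range).  Values outside the range are clipped into the edge
    bins so every measured cell is counted exactly once (column sums equal
    per-frame cell counts).
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    df = measurements.dropna(subset=[value_column])
    if df.empty:
        raise ValueError("no measurements to bin")
    values = df[value_column].to_numpy(dtype=float)
    if value_range is None:
        lo, hi = float(values.min()), float(values.max())
        if lo == hi:
            hi = lo + 1.0
    else:
        lo, hi = map(float, value_range)
        if hi <= lo:
            raise ValueError("empty value_range")
    edges = np.linspace(lo, hi, n_bins + 1)
    frames = sorted(df["time_h"].unique())
    counts = np.zeros((n_bins, len(frames)), dtype=int)
    for j, t in enumerate(frames):
        v = np.clip(df.loc[df["time_h"] == t, value_column].to_numpy(dtype=float), lo, hi)
        counts[:, j], _ = np.histogram(v, bins=edges)
    return HeatmapGrid(
        time_bins=np.asarray(frames, dtype=float),
        intensity_edges=edges,
        counts=counts,
    )


def _save(fig, dest: str | Path) -> Path:
    dest = Path(dest)
    meta = {"CreationDate": None} if dest.suffix.lower() == ".pdf" else None
    fig.savefig(dest, metadata=meta)
    plt.close(fig)
    return dest


def render_heatmap(
    grid: HeatmapGrid,
    scheme: ColorScheme | None = None,
    dest: str | Path = "heatmap.pdf",
    *,
    title: str = "",
) -> Path:
    """Render the grid to PDF/PNG: time (h) on x, intensity (AU) on y,
    color = cells per bin.  Deterministic for fixed inputs (PDF metadata
    dates are stripped)."""
    if scheme is None:
        scheme = ColorScheme.default()
    rgb = scheme.rgb_image(grid.counts)
    fig, ax = plt.subplots(figsize=(7, 4))
    dt = (grid.time_bins[-1] - grid.time_bins[0]) / max(1, len(grid.time_bins) - 1)
    extent = (
        float(grid.time_bins[0] - dt / 2), float(grid.time_bins[-1] + dt / 2),
        float(grid.intensity_edges[0]), float(grid.intensity_edges[-1]),
    )
    ax.imshow(rgb, origin="lower", aspect="auto", extent=extent, interpolation="nearest")
    ax.set_xlabel("time (h)")
    ax.set_ylabel("normalized fluorescence (AU)")
    if title:
        ax.set_title(title)
    return _save(fig, dest)


def render_barchart(
    summary: pd.DataFrame,
    dest: str | Path = "heterogeneity_bars.pdf",
    *,
    title: str = "",
    ax=None,
) -> Path | None:
    """Grouped bar chart of combined mean fluorescence with SD error bars.

    One bar per (condition, time) row of a summary table; bars are grouped
    by condition on x and colored by time point, so multiple measurements
    are compared at matched times.  The error bar is the combined SD — the
    heterogeneity readout (it cannot distinguish merely noisy from bistable
    expression; the heatmap can).
    """
    if summary.empty:
        raise ValueError("empty summary table")
    times = sorted(summary["time_requested"].unique())
    conditions = list(dict.fromkeys(summary["condition"]))
    cmap = plt.get_cmap("tab10")
    width = 0.8 / len(times)
    if ax is not None:
        fig = None
    else:
        fig, ax = plt.subplots(figsize=(2.5 + 1.2 * len(conditions), 4))
    for k, t in enumerate(times):
        sub = summary[summary["time_requested"] == t].set_index("condition")
        xs, ys, errs = [], [], []
        for i, cond in enumerate(conditions):
            if cond not in sub.index:
                continue
            xs.append(i + (k - (len(times) - 1) / 2) * width)
            row = sub.loc[cond]
            ys.append(float(row["mean_fluor"]))
            errs.append(float(row["sd_fluor"]))
        ax.bar(xs, ys, width=width, color=cmap(k % 10), label=f"t = {t:g} h",
               yerr=errs, capsize=3)
    ax.set_xticks(range(len(conditions)))
    ax.set_xticklabels([c or "series" for c in conditions])
    ax.set_ylabel("normalized fluorescence (AU)")
    ax.legend(frameon=False)
    if title:
        ax.set_title(title)
    if fig is None:
        return None  # drew on a caller-supplied axes
    return _save(fig, dest)
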