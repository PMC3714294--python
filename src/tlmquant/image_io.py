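"""Reading and writing 8-bit image time series and measurement tables.

The pipeline operates on pairs of spatially registered 8-bit grayscale
images per time point: a phase-contrast image (used for segmentation) and a
fluorescence image (used for quantification).  Images are exchanged as
single-plane grayscale TIFFs; tabular results as plain CSV with a header
row, comma separator and ``.`` decimal point.

Time points can be loaded either from a directory of TIFF pairs sharing a
stem with channel suffixes (``t000_ph.tif`` / ``t000_gfp.tif``) or from a
JSON manifest that lists the file pair and acquisition time of every frame.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "Frame",
    "TimeSeries",
    "MEASUREMENT_COLUMNS",
    "load_image",
    "load_timeseries",
    "write_manifest",
    "write_measurements",
    "read_measurements",
    "validate_measurements",
]

#: Column contract for per-particle measurement tables.
MEASUREMENT_COLUMNS = ["frame_index", "time_h", "particle_id", "area_px", "mean_intensity"]


class ImageFormatError(ValueError):
    """Raised for inputs that violate the 8-bit single-plane contract."""


@dataclass(frozen=True)
class Frame:
    """One time point: registered phase-contrast + fluorescence image pair.

    Both channels are 2-D ``uint8`` arrays of identical shape with
    intensities in [0, 255]; ``time_h`` is the acquisition time in hours and
    ``index`` the ordinal position in the series.
    """

    phase: np.ndarray
    fluor: np.ndarray
    time_h: float
    index: int

    def __post_init__(self) -> None:
        for name, img in (("phase", self.phase), ("fluor", self.fluor)):
            if img.ndim != 2:
                raise ImageFormatError(f"{name} image must be 2-D, got {img.ndim}-D")
            if img.dtype != np.uint8:
                raise ImageFormatError(
                    f"expected 8-bit {name} image, got dtype {img.dtype}"
                )
        if self.phase.shape != self.fluor.shape:
            raise ImageFormatError(
                f"phase/fluorescence shape mismatch at frame {self.index}: "
                f"{self.phase.shape} vs {self.fluor.shape}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.phase.shape


@dataclass(frozen=True)
class TimeSeries:
    """Ordered frames plus the fluorescence channel labels (≥ 1)."""

    frames: tuple[Frame, ...]
    channel_names: tuple[str, ...] = ("gfp",)

    def __post_init__(self) -> None:
        if not self.channel_names:
            raise ValueError("at least one fluorescence channel name required")
        if self.frames:
            shape = self.frames[0].shape
            for f in self.frames:
                if f.shape != shape:
                    raise ImageFormatError(
                        f"frame {f.index} shape {f.shape} differs from {shape}"
                    )
            times = [f.time_h for f in self.frames]
            if any(b <= a for a, b in zip(times, times[1:])):
                raise ValueError("frame times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)


def load_image(path: str | Path) -> np.ndarray:
    """Load one single-plane 8-bit grayscale TIFF, bit-exact.

    Non-8-bit or multi-plane inputs are rejected (no silent rescaling).
    """
    arr = tifffile.imread(str(path))
    if arr.ndim != 2:
        raise ImageFormatError(f"{path}: expected a single 2-D plane, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        raise ImageFormatError(f"{path}: expected 8-bit image, got dtype {arr.dtype}")
    return arr


def load_timeseries(
    source: str | Path,
    *,
    phase_suffix: str = "_ph",
    fluor_suffix: str = "_gfp",
    interval_h: float = 1.0,
    start_h: float = 0.0,
    channel_name: str = "gfp",
) -> TimeSeries:
    """Load a time series from a JSON manifest or a directory of TIFF pairs.

    Directory layout: for every time point a phase and a fluorescence TIFF
    share a stem and differ by the channel suffix (``t000_ph.tif`` /
    ``t000_gfp.tif``).  Stems are ordered lexicographically and times are
    assigned as ``start_h + index * interval_h``.  A manifest JSON instead
    lists frames explicitly with acquisition times::

        {"channel_names": ["gfp"],
         "frames": [{"phase": "t000_ph.tif", "fluor": "t000_gfp.tif",
                     "time_h": 0.0}, ...]}

    Relative manifest paths resolve against the manifest's directory.
    Missing channels and shape mismatches are hard errors naming the time
    point.
    """
    source = Path(source)
    if source.is_file():
        return _load_from_manifest(source)
    if not source.is_dir():
        raise FileNotFoundError(f"no such file or directory: {source}")

    tiffs = sorted(p for p in source.iterdir() if p.suffix.lower() in (".tif", ".tiff"))
    phase_files = {p.name[: -len(p.suffix)].removesuffix(phase_suffix): p
                   for p in tiffs if p.stem.endswith(phase_suffix)}
    fluor_files = {p.name[: -len(p.suffix)].removesuffix(fluor_suffix): p
                   for p in tiffs if p.stem.endswith(fluor_suffix)}
    stems = sorted(set(phase_files) | set(fluor_files))
    if not stems:
        raise FileNotFoundError(
            f"{source}: no TIFF pairs with suffixes {phase_suffix!r}/{fluor_suffix!r}"
        )
    frames = []
    for i, stem in enumerate(stems):
        if stem not in phase_files:
            raise FileNotFoundError(f"time point {stem!r}: missing phase channel")
        if stem not in fluor_files:
            raise FileNotFoundError(f"time point {stem!r}: missing fluorescence channel")
        frames.append(
            Frame(
                phase=load_image(phase_files[stem]),
                fluor=load_image(fluor_files[stem]),
                time_h=start_h + i * interval_h,
                index=i,
            )
        )
    return TimeSeries(frames=tuple(frames), channel_names=(channel_name,))


def _load_from_manifest(path: Path) -> TimeSeries:
    with open(path) as fh:
        spec = json.load(fh)
    base = path.parent
    frames = []
    for i, entry in enumerate(spec["frames"]):
        for key in ("phase", "fluor"):
            if key not in entry:
                raise KeyError(f"manifest frame {i}: missing {key!r} channel")
        frames.append(
            Frame(
                phase=load_image(base / entry["phase"]),
                fluor=load_image(base / entry["fluor"]),
                time_h=float(entry.get("time_h", i)),
                index=i,
            )
        )
    channels = tuple(spec.get("channel_names", ["gfp"]))
    return TimeSeries(frames=tuple(frames), channel_names=channels)


def write_manifest(
    dest: str | Path,
    entries: Sequence[dict],
    channel_names: Sequence[str] = ("gfp",),
) -> Path:
    """Write a manifest JSON; ``entries`` carry phase/fluor paths and time_h."""
    dest = Path(dest)
    with open(dest, "w") as fh:
        json.dump({"channel_names": list(channel_names), "frames": list(entries)}, fh, indent=1)
    return dest


def validate_measurements(table: pd.DataFrame) -> pd.DataFrame:
    """Enforce the measurement-table contract; returns the table unchanged.

    Requires the :data:`MEASUREMENT_COLUMNS` (extra columns allowed),
    areas ≥ 1 px, raw means within [0, 255] (NaN allowed for measurements
    flagged invalid upstream) and particle ids unique within each frame.
    """
    missing = [c for c in MEASUREMENT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"measurement table missing columns: {missing}")
    if len(table):
        if (table["area_px"] < 1).any():
            raise ValueError("area_px must be >= 1")
        vals = table["mean_intensity"].dropna()
        if ((vals < 0) | (vals > 255)).any():
            raise ValueError("mean_intensity must lie in [0, 255]")
        dup = table.duplicated(subset=["frame_index", "particle_id"])
        if dup.any():
            raise ValueError("particle_id must be unique within a frame")
    return table


def write_measurements(table: pd.DataFrame, dest: str | Path) -> Path:
    """Write a measurement table as CSV (header row, one row per particle).

    Round-trips losslessly through :func:`read_measurements`.
    """
    validate_measurements(table)
    dest = Path(dest)
    table.to_csv(dest, index=False)
    return dest


def read_measurements(path: str | Path) -> pd.DataFrame:
    """Read a measurement CSV written by :func:`write_measurements`."""
    table = pd.read_csv(path)
    return validate_measurements(table)
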