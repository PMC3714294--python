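"""Ground-truthed synthetic phase/fluorescence time series.

Replaces the microscope for testing and calibration: rod-shaped cells
(rectangles with semicircular caps) grow exponentially in length, divide at
a jittered division length, and express a fluorescent reporter under one of
three scenarios —

* ``homogeneous``: one Normal intensity mode (an inducible-promoter
  control, induced at the start of imaging);
* ``noisy``: a single heavy-tailed lognormal mode (noisy promoter);
* ``bistable``: a two-component Normal mixture (ON/OFF subpopulations);
  daughters inherit their mother's mode.

Rendering emulates phase contrast (dark rods with a bright halo rim on a
bright field) and epifluorescence (dim background plus a uniform cell
interior at the cell's true intensity, 1 AU = 1 grey level by default),
with additive Gaussian read noise, and emits the exact per-pixel label
mask plus a truth table.  Everything is reproducible from a seed.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import tifffile

from .heterogeneity import FrameStats, frame_stats
from .image_io import write_manifest

__all__ = [
    "SyntheticCell",
    "ScenarioParams",
    "RenderParams",
    "simulate_population",
    "render_frame",
    "generate_timeseries",
    "match_to_truth",
    "simulate_noise_calibration",
    "TRUTH_COLUMNS",
]

TRUTH_COLUMNS = [
    "frame_index", "time_h", "cell_id", "mode", "true_intensity",
    "length_px", "center_row", "center_col",
]


@dataclass(frozen=True)
class SyntheticCell:
    """Ground-truth rod: geometry plus true reporter intensity (AU)."""

    id: int
    center: tuple[float, float]  # (row, col)
    orientation: float  # radians
    length: float  # px, tip to tip
    width: float  # px
    true_intensity: float  # AU
    mode: int = 0
    lineage_parent: int | None = None
    birth_time: float = 0.0
    birth_length: float = 0.0
    division_length: float = math.inf


@dataclass(frozen=True)
class ScenarioParams:
    """Study conditions for one simulated experiment.

    ``mode_means``/``mode_sds`` give the intensity distribution per
    expression mode (one mode for homogeneous/noisy, low+high for
    bistable); ``mixture_fraction`` is the probability a founder lineage is
    in the high mode.  Growth is exponential in cell length with the given
    doubling time; cells divide at ``division_length`` (5 % jitter) into
    two daughters.  Induction coincides with the start of imaging.
    """

    scenario: Literal["homogeneous", "noisy", "bistable"] = "homogeneous"
    mode_means: tuple[float, ...] = (60.0,)
    mode_sds: tuple[float, ...] = (6.0,)
    mixture_fraction: float = 0.4
    doubling_time_h: float = 1.0
    division_length: float = 30.0
    init_length: float = 15.0
    width: float = 5.0
    n_seed_cells: int = 10
    field_shape: tuple[int, int] = (512, 512)
    min_separation: float = 4.0
    division_jitter: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in ("homogeneous", "noisy", "bistable"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        n_modes = 2 if self.scenario == "bistable" else 1
        if len(self.mode_means) < n_modes or len(self.mode_sds) < n_modes:
            raise ValueError(f"{self.scenario} scenario needs {n_modes} mode(s)")
        if self.scenario == "bistable" and not 0 < self.mixture_fraction < 1:
            raise ValueError("mixture_fraction must lie in (0, 1)")
        if not (self.division_length >= self.init_length >= self.width >= 3):
            raise ValueError("need division_length >= init_length >= width >= 3 px")
        if self.doubling_time_h <= 0:
            raise ValueError("doubling_time_h must be positive")
        if self.n_seed_cells < 1:
            raise ValueError("need at least one seed cell")

    @classmethod
    def preset(cls, scenario: str, seed: int = 0, **overrides) -> "ScenarioParams":
        """Default study conditions for the three scenarios (AU)."""
        base = {
            "homogeneous": dict(mode_means=(60.0,), mode_sds=(6.0,)),
            "noisy": dict(mode_means=(60.0,), mode_sds=(40.0,)),
            "bistable": dict(mode_means=(10.0, 120.0), mode_sds=(3.0, 12.0),
                             mixture_fraction=0.4),
        }[scenario]
        base.update(overrides)
        return cls(scenario=scenario, seed=seed, **base)


@dataclass(frozen=True)
class RenderParams:
    """Optics emulation: grey levels, halo rim, read noise, AU scaling."""

    phase_background: float = 180.0
    phase_cell: float = 60.0
    phase_halo: float = 210.0
    halo_rim_px: float = 1.5
    phase_noise_sd: float = 3.0
    fluor_background: float = 8.0
    fluor_noise_sd: float = 2.0
    au_per_grey: float = 1.0  # intensity-to-8-bit scale: AU per grey level


def _draw_intensity(params: ScenarioParams, mode: int, rng: np.random.Generator) -> float:
    if params.scenario == "noisy":
        m, s = params.mode_means[0], params.mode_sds[0]
        # lognormal moment-matched to the requested mean and SD
        sigma2 = math.log1p((s / m) ** 2)
        mu = math.log(m) - sigma2 / 2
        return float(rng.lognormal(mu, math.sqrt(sigma2)))
    m, s = params.mode_means[mode], params.mode_sds[mode]
    return float(max(0.0, rng.normal(m, s)))


def _draw_mode(params: ScenarioParams, rng: np.random.Generator) -> int:
    if params.scenario == "bistable":
        return int(rng.random() < params.mixture_fraction)
    return 0


def _segment_points(center, theta, half, n: int = 9) -> np.ndarray:
    """Points sampled along a rod's center segment, shape (n, 2)."""
    ts = np.linspace(-1.0, 1.0, n)
    ur, uc = math.cos(theta), math.sin(theta)
    return np.stack([center[0] + ts * half * ur, center[1] + ts * half * uc], axis=1)


def _place_seed_cells(params: ScenarioParams, rng: np.random.Generator) -> list[SyntheticCell]:
    h, w = params.field_shape
    cells: list[SyntheticCell] = []
    placed_pts = np.empty((0, 2))  # sampled axis points of accepted cells
    max_tries = 200 * params.n_seed_cells + 20000
    tries = 0
    while len(cells) < params.n_seed_cells:
        if tries > max_tries:
            raise ValueError(
                f"field {params.field_shape} too small to place "
                f"{params.n_seed_cells} non-touching cells"
            )
        tries += 1
        # log-uniform lengths = stationary age distribution of exponential
        # growth, so founder divisions spread evenly over the first doubling
        u = rng.uniform(0.0, 1.0)
        length = float(
            params.init_length * (params.division_length / params.init_length) ** u
        )
        margin = length / 2 + params.width
        if 2 * margin >= min(h, w):
            raise ValueError("field too small for the configured cell size")
        center = (float(rng.uniform(margin, h - margin)),
                  float(rng.uniform(margin, w - margin)))
        theta = float(rng.uniform(0, math.pi))
        # capsule-distance rejection keeps seed cells non-touching
        half = max(0.0, length / 2 - params.width / 2)
        pts = _segment_points(center, theta, half)
        if len(placed_pts):
            d2 = ((pts[:, None, :] - placed_pts[None, :, :]) ** 2).sum(-1)
            if d2.min() <= (params.width + params.min_separation) ** 2:
                continue
        placed_pts = np.vstack([placed_pts, pts])
        mode = _draw_mode(params, rng)
        cells.append(
            SyntheticCell(
                id=len(cells) + 1,
                center=center,
                orientation=theta,
                length=length,
                width=params.width,
                true_intensity=_draw_intensity(params, mode, rng),
                mode=mode,
                lineage_parent=None,
                birth_time=0.0,
                birth_length=length,
                # floor keeps a fresh cell from dividing instantly at t = 0
                division_length=max(
                    float(params.division_length
                          * (1 + params.division_jitter * rng.standard_normal())),
                    1.02 * length,
                ),
            )
        )
    return cells


def _division_time(cell: SyntheticCell, rate: float) -> float:
    if cell.birth_length >= cell.division_length:
        return cell.birth_time
    return cell.birth_time + math.log(cell.division_length / cell.birth_length) / rate


def simulate_population(params: ScenarioParams, t: float) -> list[SyntheticCell]:
    """Population state at time ``t`` hours after the start.

    Deterministic replay: for a fixed seed the simulation up to any ``t``
    is a prefix of the simulation up to any later time, so snapshots taken
    at increasing times share one consistent lineage.
    """
    if t < 0:
        raise ValueError("time must be >= 0")
    rng = np.random.default_rng(params.seed)
    rate = math.log(2) / params.doubling_time_h
    cells = _place_seed_cells(params, rng)
    next_id = len(cells) + 1
    # min-heap of (division_time, cell_id); ids break ties deterministically
    heap = [(_division_time(c, rate), c.id) for c in cells]
    heapq.heapify(heap)
    alive = {c.id: c for c in cells}
    while heap and heap[0][0] <= t:
        t_div, cid = heapq.heappop(heap)
        mother = alive.pop(cid)
        length_d = mother.division_length
        u = (math.cos(mother.orientation), math.sin(mother.orientation))
        eps = params.division_jitter * rng.standard_normal()
        for k, sign in ((0, -1.0), (1, 1.0)):
            frac = 0.5 + (eps if k == 0 else -eps)
            birth_len = max(params.width, length_d * frac)
            offset = length_d / 4 * sign
            center = (mother.center[0] + offset * u[0], mother.center[1] + offset * u[1])
            theta = mother.orientation + 0.05 * rng.standard_normal()
            daughter = SyntheticCell(
                id=next_id,
                center=center,
                orientation=theta,
                length=birth_len,
                width=params.width,
                true_intensity=_draw_intensity(params, mother.mode, rng),
                mode=mother.mode,
                lineage_parent=mother.id,
                birth_time=t_div,
                birth_length=birth_len,
                division_length=float(
                    params.division_length * (1 + params.division_jitter * rng.standard_normal())
                ),
            )
            alive[next_id] = daughter
            heapq.heappush(heap, (_division_time(daughter, rate), next_id))
            next_id += 1
    # advance lengths to t
    out = []
    for cid in sorted(alive):
        c = alive[cid]
        length = min(c.birth_length * math.exp(rate * (t - c.birth_time)), c.division_length)
        out.append(replace(c, length=length))
    return out


def _paint_rod(
    shape: tuple[int, int], cell: SyntheticCell, rim_px: float
):
    """Boolean interior and rim footprints of one rod, clipped to the field.

    Returns (row-slice, col-slice, (interior, rim)) or None off-field.
    """
    h, w = shape
    half = cell.length / 2 + rim_px + 2
    r0 = max(0, int(math.floor(cell.center[0] - half)))
    r1 = min(h, int(math.ceil(cell.center[0] + half)) + 1)
    c0 = max(0, int(math.floor(cell.center[1] - half)))
    c1 = min(w, int(math.ceil(cell.center[1] + half)) + 1)
    if r0 >= r1 or c0 >= c1:
        return None
    rr, cc = np.mgrid[r0:r1, c0:c1]
    # distance from pixel centers to the rod's center segment
    seg_half = max(0.0, cell.length / 2 - cell.width / 2)
    ur, uc = math.cos(cell.orientation), math.sin(cell.orientation)
    dr, dc = rr - cell.center[0], cc - cell.center[1]
    proj = np.clip(dr * ur + dc * uc, -seg_half, seg_half)
    dist = np.hypot(dr - proj * ur, dc - proj * uc)
    interior = dist <= cell.width / 2
    rim = (dist > cell.width / 2) & (dist <= cell.width / 2 + rim_px)
    return slice(r0, r1), slice(c0, c1), (interior, rim)


def render_frame(
    cells: Sequence[SyntheticCell],
    field_shape: tuple[int, int] = (512, 512),
    optics: RenderParams | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render (phase, fluor, label_mask) for one field of cells.

    Phase: bright background, dark rod interiors, brighter halo rim.
    Fluorescence: dim background plus uniform interior at the cell's true
    intensity scaled to grey levels.  Gaussian read noise is added to both
    channels and values are clamped to [0, 255]; the uint16 label mask is
    exact (later ids overwrite on overlap).  Off-field cells are clipped.
    """
    if optics is None:
        optics = RenderParams()
    if min(field_shape) < 16:
        raise ValueError(f"field {field_shape} too small")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    shape = tuple(field_shape)
    phase = np.full(shape, optics.phase_background, dtype=float)
    fluor = np.full(shape, optics.fluor_background, dtype=float)
    labels = np.zeros(shape, dtype=np.uint16)
    ordered = sorted(cells, key=lambda c: c.id)
    footprints = []
    for cell in ordered:
        painted = _paint_rod(shape, cell, optics.halo_rim_px)
        if painted is not None:
            footprints.append((cell, painted))
    # rims first, interiors second: the halo exists only outside any cell,
    # so touching cells are never severed by a neighbour's rim
    for _, (rs, cs, (_, rim)) in footprints:
        phase[rs, cs][rim] = optics.phase_halo
    for cell, (rs, cs, (interior, _)) in footprints:
        phase[rs, cs][interior] = optics.phase_cell
        fluor[rs, cs][interior] = (
            optics.fluor_background + cell.true_intensity / optics.au_per_grey
        )
        labels[rs, cs][interior] = cell.id
    if optics.phase_noise_sd > 0:
        phase += rng.normal(0, optics.phase_noise_sd, shape)
    if optics.fluor_noise_sd > 0:
        fluor += rng.normal(0, optics.fluor_noise_sd, shape)
    phase = np.clip(np.round(phase), 0, 255).astype(np.uint8)
    fluor = np.clip(np.round(fluor), 0, 255).astype(np.uint8)
    return phase, fluor, labels


def render_population_frame(
    params: ScenarioParams,
    t: float,
    optics: RenderParams | None = None,
    frame_seed: int | None = None,
) -> tuple[list[SyntheticCell], np.ndarray, np.ndarray, np.ndarray]:
    """Simulate the population at ``t`` and render it in params.field_shape."""
    cells = simulate_population(params, t)
    seed = frame_seed if frame_seed is not None else params.seed
    phase, fluor, labels = render_frame(cells, params.field_shape, optics, seed)
    return cells, phase, fluor, labels


def generate_timeseries(
    params: ScenarioParams,
    duration_h: float,
    interval_h: float,
    outdir: str | Path,
    optics: RenderParams | None = None,
) -> Path:
    """Write a full synthetic series to ``outdir``; returns the manifest path.

    Frames at 0, interval, …, duration hours (inclusive).  Per frame:
    ``tNNN_ph.tif`` / ``tNNN_gfp.tif`` (uint8) and ``tNNN_labels.tif``
    (uint16 ground truth); plus ``truth.csv`` (per frame and cell: id,
    mode, true intensity, geometry) and ``manifest.json``.  Byte-identical
    for a fixed seed.
    """
    if duration_h < interval_h:
        raise ValueError("duration must be >= interval")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    n_frames = int(math.floor(duration_h / interval_h + 1e-9)) + 1
    entries, truth_rows = [], []
    for i in range(n_frames):
        t = i * interval_h
        # independent render stream per frame, derived from the master seed
        cells, phase, fluor, labels = render_population_frame(
            params, t, optics, frame_seed=(params.seed * 1009 + i) % (2**31 - 1)
        )
        names = {c: f"t{i:03d}_{c}.tif" for c in ("ph", "gfp", "labels")}
        tifffile.imwrite(outdir / names["ph"], phase)
        tifffile.imwrite(outdir / names["gfp"], fluor)
        tifffile.imwrite(outdir / names["labels"], labels)
        entries.append({"phase": names["ph"], "fluor": names["gfp"],
                        "labels": names["labels"], "time_h": t})
        for c in cells:
            truth_rows.append(
                (i, t, c.id, c.mode, c.true_intensity, c.length, c.center[0], c.center[1])
            )
    pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS).to_csv(outdir / "truth.csv", index=False)
    return write_manifest(outdir / "manifest.json", entries)


def match_to_truth(
    labels: np.ndarray, particles, threshold: float = 0.5
) -> tuple[int, int, int]:
    """Greedy Jaccard matching of segmented particles to truth labels.

    Returns (number of true cells, number matched by a particle with
    Jaccard overlap > threshold, number of spurious particles).
    """
    labels = np.asarray(labels)
    ids, areas = np.unique(labels[labels > 0], return_counts=True)
    truth_areas = dict(zip(ids.tolist(), areas.tolist()))
    matched: set[int] = set()
    spurious = 0
    for p in particles:
        lv = labels[p.rows_cols()]
        best_j, best_id = 0.0, 0
        for cid in np.unique(lv[lv > 0]):
            inter = int((lv == cid).sum())
            j = inter / (p.area_px + truth_areas[int(cid)] - inter)
            if j > best_j:
                best_j, best_id = j, int(cid)
        if best_j > threshold:
            matched.add(best_id)
        else:
            spurious += 1
    return len(truth_areas), len(matched), spurious


def simulate_noise_calibration(
    mean_levels: Sequence[float] = (20.0, 40.0, 80.0, 160.0),
    slope: float = 0.1,
    intercept: float = 2.0,
    n_frames_per_level: int = 134,
    cells_per_frame: int = 50,
    seed: int | np.random.Generator = 0,
    start_index: int = 0,
) -> list[FrameStats]:
    """Per-frame (mean, SD) points from homogeneous control populations.

    Emulates the induction-series calibration: one homogeneous population
    per induction level, per-cell normalized intensities Normal with SD
    following the line ``sd = slope·mean + intercept``; each frame yields
    one (sample mean, sample SD) point.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    idx = start_index
    for m in mean_levels:
        for j in range(n_frames_per_level):
            values = rng.normal(m, slope * m + intercept, size=cells_per_frame)
            out.append(frame_stats(values, frame_index=idx, time_h=float(j)))
            idx += 1
    return out
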