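"""Fluence-map reconstruction on an isocenter-plane grid.

The log-file QA channel compares *fluence*, not dose: each static segment
contributes its meterset to every grid pixel whose center lies inside the
open aperture (leaf-pair interval intersected with the diaphragm rectangle).
The model is an idealized aperture-MU product -- no transmission, penumbra or
output factors -- which is the granularity at which a delivery log can be
checked against the plan.

Pixel openness is evaluated at pixel centers on an isotropic grid (default
1.0 mm pitch, adequate at millimetre-class tolerances; configurable for
convergence studies).  Leaf rows are half-open intervals [low, high) along y
so every pixel belongs to exactly one leaf pair.

Delivered fluence is reconstructed by first collapsing the log's beam-on
samples into stationary :class:`DeliveredSegment` intervals (leaf motion
below a tolerance between consecutive samples), then rasterizing each
segment's mean positions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .logfile import DeliveryLog
from .rtplan import BeamPlan, MachineGeometry, PlanSegment

__all__ = [
    "FluenceGrid",
    "FluenceMap",
    "DeliveredSegment",
    "FluenceError",
    "auto_grid",
    "rasterize_aperture",
    "plan_fluence",
    "delivered_fluence",
    "extract_segments",
    "extract_segments_detailed",
    "write_fluence",
    "read_fluence",
]

FLUENCE_FORMAT = "#logqa-fluence v1"


class FluenceError(ValueError):
    """Fluence reconstruction failed (empty delivery, bad grid, ...)."""


@dataclass(frozen=True)
class FluenceGrid:
    """Isotropic isocenter-plane grid; (origin_x, origin_y) is the center of
    pixel (0, 0); row j, column i sits at origin + (i, j) * spacing."""

    origin_x_mm: float
    origin_y_mm: float
    spacing_mm: float
    nx: int
    ny: int

    def __post_init__(self) -> None:
        if self.spacing_mm <= 0:
            raise FluenceError("grid spacing must be > 0")
        if self.nx < 1 or self.ny < 1:
            raise FluenceError("grid dimensions must be >= 1")

    @property
    def xs(self) -> np.ndarray:
        return self.origin_x_mm + np.arange(self.nx) * self.spacing_mm

    @property
    def ys(self) -> np.ndarray:
        return self.origin_y_mm + np.arange(self.ny) * self.spacing_mm

    @property
    def x_extent(self) -> tuple[float, float]:
        h = self.spacing_mm / 2.0
        return self.origin_x_mm - h, self.origin_x_mm + (self.nx - 1) * self.spacing_mm + h

    @property
    def y_extent(self) -> tuple[float, float]:
        h = self.spacing_mm / 2.0
        return self.origin_y_mm - h, self.origin_y_mm + (self.ny - 1) * self.spacing_mm + h


@dataclass
class FluenceMap:
    """MU-weighted open-aperture accumulation on a :class:`FluenceGrid`."""

    grid: FluenceGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.ny, self.grid.nx):
            raise FluenceError(
                f"values shape {self.values.shape} does not match grid "
                f"({self.grid.ny}, {self.grid.nx})"
            )
        if np.any(self.values < 0):
            raise FluenceError("fluence values must be non-negative")

    @property
    def integral_mu_mm2(self) -> float:
        """Sum of pixel values times pixel area (MU * mm^2)."""
        return float(self.values.sum() * self.grid.spacing_mm ** 2)

    def __add__(self, other: "FluenceMap") -> "FluenceMap":
        if other.grid != self.grid:
            raise FluenceError("cannot add fluence maps on different grids")
        return FluenceMap(self.grid, self.values + other.values)


@dataclass
class DeliveredSegment:
    """One stationary beam-on interval recovered from a delivery log.

    Positions are per-leaf/per-jaw means over the interval's beam-on
    samples; the gantry mean is circular (angles live on [0, 360)).
    """

    index: int
    mu: float
    n_samples: int
    gantry_deg: float
    collimator_deg: float
    leaf_a_mm: np.ndarray
    leaf_b_mm: np.ndarray
    diaphragm_x1_mm: float
    diaphragm_x2_mm: float
    diaphragm_y1_mm: float
    diaphragm_y2_mm: float


# ---------------------------------------------------------------------------
# Segment extraction
# ---------------------------------------------------------------------------


def extract_segments_detailed(
    log: DeliveryLog,
    stationarity_tol_mm: float = 0.3,
    min_segment_mu: float = 0.1,
) -> tuple[list[DeliveredSegment], int]:
    """Collapse a log into stationary segments; also return the number of
    sub-threshold (MU < ``min_segment_mu``) intervals that were discarded.

    Beam-on samples are grouped into runs split wherever any leaf moves by
    ``stationarity_tol_mm`` or more between consecutive samples (or the beam
    toggles).  Adjacent runs (no beam-off sample between them) whose per-leaf
    mean positions agree within twice that tolerance are re-merged: jitter
    spikes can exceed the per-sample motion threshold without the aperture
    actually changing, and two noisy estimates of the same static aperture
    can sit up to two single-sample excursions apart.  Genuine step-and-shoot
    segments are always separated by beam-off travel samples, so they are
    never candidates for merging.  Segment MU is the cumulative-MU difference
    from the record preceding the run to the run's last record, so no monitor
    units are lost to sampling.
    """
    on_idx = np.nonzero(log.beam_on)[0]
    if on_idx.size == 0:
        raise FluenceError("empty delivery: no beam-on samples")

    motion = np.zeros(log.n_records)
    if log.n_records > 1:
        da = np.abs(np.diff(log.leaf_a_mm, axis=0)).max(axis=1)
        db = np.abs(np.diff(log.leaf_b_mm, axis=0)).max(axis=1)
        motion[1:] = np.maximum(da, db)

    runs: list[list[int]] = []
    for pos, i in enumerate(on_idx):
        new_run = (
            pos == 0
            or on_idx[pos - 1] != i - 1          # beam-off gap
            or motion[i] >= stationarity_tol_mm  # sustained-motion boundary
        )
        if new_run:
            runs.append([i])
        else:
            runs[-1].append(i)

    # merge adjacent runs (no intervening samples) with matching mean apertures
    merge_tol = 2.0 * stationarity_tol_mm
    merged: list[list[int]] = []
    for run in runs:
        if merged and run[0] == merged[-1][-1] + 1:
            prev = merged[-1]
            da = np.abs(log.leaf_a_mm[prev].mean(axis=0) - log.leaf_a_mm[run].mean(axis=0))
            db = np.abs(log.leaf_b_mm[prev].mean(axis=0) - log.leaf_b_mm[run].mean(axis=0))
            if max(da.max(), db.max()) < merge_tol:
                prev.extend(run)
                continue
        merged.append(run)

    # means are bit-exact when all samples agree (the zero-noise case must
    # reproduce the logged positions, not a rounded resummation of them)
    def _mean_cols(arr2d: np.ndarray) -> np.ndarray:
        if np.array_equiv(arr2d, arr2d[0]):
            return arr2d[0].copy()
        return arr2d.mean(axis=0)

    def _mean_scalar(arr1d: np.ndarray) -> float:
        if np.ptp(arr1d) == 0:
            return float(arr1d[0])
        return float(arr1d.mean())

    def _mean_angle(arr1d: np.ndarray) -> float:
        if np.ptp(arr1d) == 0:
            return float(arr1d[0]) % 360.0
        ang = np.deg2rad(arr1d)
        return math.degrees(math.atan2(np.sin(ang).mean(), np.cos(ang).mean())) % 360.0

    segments: list[DeliveredSegment] = []
    n_discarded = 0
    for run in merged:
        idx = np.asarray(run)
        start, end = int(idx[0]), int(idx[-1])
        mu_before = float(log.mu_cum[start - 1]) if start > 0 else 0.0
        mu = float(log.mu_cum[end]) - mu_before
        if mu < min_segment_mu:
            n_discarded += 1
            continue
        segments.append(
            DeliveredSegment(
                index=len(segments),
                mu=mu,
                n_samples=len(idx),
                gantry_deg=_mean_angle(log.gantry_deg[idx]),
                collimator_deg=_mean_scalar(log.collimator_deg[idx]),
                leaf_a_mm=_mean_cols(log.leaf_a_mm[idx]),
                leaf_b_mm=_mean_cols(log.leaf_b_mm[idx]),
                diaphragm_x1_mm=_mean_scalar(log.dia_x1_mm[idx]),
                diaphragm_x2_mm=_mean_scalar(log.dia_x2_mm[idx]),
                diaphragm_y1_mm=_mean_scalar(log.dia_y1_mm[idx]),
                diaphragm_y2_mm=_mean_scalar(log.dia_y2_mm[idx]),
            )
        )
    return segments, n_discarded


def extract_segments(
    log: DeliveryLog,
    stationarity_tol_mm: float = 0.3,
    min_segment_mu: float = 0.1,
) -> list[DeliveredSegment]:
    """Stationary beam-on segments of a delivery log (see the detailed variant)."""
    segments, _ = extract_segments_detailed(log, stationarity_tol_mm, min_segment_mu)
    return segments


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------


def _effective_bounds(
    a: np.ndarray, b: np.ndarray,
    x1: float, x2: float, y1: float, y2: float,
    geometry: MachineGeometry,
) -> tuple[float, float, float, float] | None:
    """Bounding box of the jaw-clipped open aperture, or None if fully closed."""
    xmin = math.inf
    xmax = -math.inf
    ymin = math.inf
    ymax = -math.inf
    for i in range(geometry.n_leaf_pairs):
        low, high = geometry.pair_y_interval(i)
        if high <= y1 or low >= y2:
            continue
        lo, hi = max(float(a[i]), x1), min(float(b[i]), x2)
        if hi <= lo:
            continue
        xmin, xmax = min(xmin, lo), max(xmax, hi)
        ymin, ymax = min(ymin, max(low, y1)), max(ymax, min(high, y2))
    if xmin > xmax:
        return None
    return xmin, xmax, ymin, ymax


def auto_grid(plan: BeamPlan, spacing_mm: float = 1.0, margin_mm: float = 10.0) -> FluenceGrid:
    """Grid covering every jaw-clipped open aperture of ``plan`` plus a margin.

    The origin snaps to the spacing lattice offset by half a pixel, so
    integer-coordinate field edges fall on pixel boundaries.
    """
    boxes = [
        _effective_bounds(s.leaf_a_mm, s.leaf_b_mm, s.diaphragm_x1_mm,
                          s.diaphragm_x2_mm, s.diaphragm_y1_mm, s.diaphragm_y2_mm,
                          plan.geometry)
        for s in plan.segments
    ]
    boxes = [bx for bx in boxes if bx is not None]
    if not boxes:
        raise FluenceError("plan has no open aperture; cannot size a grid")
    xmin = min(bx[0] for bx in boxes) - margin_mm
    xmax = max(bx[1] for bx in boxes) + margin_mm
    ymin = min(bx[2] for bx in boxes) - margin_mm
    ymax = max(bx[3] for bx in boxes) + margin_mm
    x0 = math.floor(xmin / spacing_mm) * spacing_mm
    y0 = math.floor(ymin / spacing_mm) * spacing_mm
    nx = math.ceil((xmax - x0) / spacing_mm)
    ny = math.ceil((ymax - y0) / spacing_mm)
    return FluenceGrid(
        origin_x_mm=x0 + spacing_mm / 2.0,
        origin_y_mm=y0 + spacing_mm / 2.0,
        spacing_mm=spacing_mm, nx=nx, ny=ny,
    )


def rasterize_aperture(
    leaf_a_mm: np.ndarray,
    leaf_b_mm: np.ndarray,
    diaphragms: tuple[float, float, float, float],
    mu: float,
    geometry: MachineGeometry,
    grid: FluenceGrid,
) -> FluenceMap:
    """Rasterize one segment: pixel value = mu where the pixel center lies
    inside its leaf pair's [a, b] interval AND the diaphragm rectangle.

    Raises if the jaw-clipped open aperture extends beyond the grid (grid
    auto-sizing is the caller's job); jaw-shielded leaf positions -- e.g.
    closed pairs parked beyond the diaphragm edge -- need no grid coverage
    and contribute no pixels.
    """
    x1, x2, y1, y2 = diaphragms
    a = np.asarray(leaf_a_mm, dtype=float)
    b = np.asarray(leaf_b_mm, dtype=float)
    bounds = _effective_bounds(a, b, x1, x2, y1, y2, geometry)
    values = np.zeros((grid.ny, grid.nx))
    if bounds is None or mu == 0:
        return FluenceMap(grid, values)
    gx, gy = grid.x_extent, grid.y_extent
    if bounds[0] < gx[0] or bounds[1] > gx[1] or bounds[2] < gy[0] or bounds[3] > gy[1]:
        raise FluenceError(
            f"grid extent x{gx} y{gy} does not cover the open aperture "
            f"x({bounds[0]}, {bounds[1]}) y({bounds[2]}, {bounds[3]})"
        )
    xs = grid.xs
    half_span = geometry.bank_span_mm / 2.0
    for j, y in enumerate(grid.ys):
        if not (y1 <= y <= y2):
            continue
        pair = math.floor((y + half_span) / geometry.leaf_width_mm)
        if not 0 <= pair < geometry.n_leaf_pairs:
            continue
        lo, hi = max(a[pair], x1), min(b[pair], x2)
        if hi <= lo:
            continue
        values[j, (xs >= lo) & (xs <= hi)] = mu
    return FluenceMap(grid, values)


def plan_fluence(plan: BeamPlan, grid: FluenceGrid | None = None) -> FluenceMap:
    """Planned fluence: sum of per-segment aperture rasterizations."""
    grid = grid or auto_grid(plan)
    total = FluenceMap(grid, np.zeros((grid.ny, grid.nx)))
    for seg in plan.segments:
        total = total + rasterize_aperture(
            seg.leaf_a_mm, seg.leaf_b_mm,
            (seg.diaphragm_x1_mm, seg.diaphragm_x2_mm,
             seg.diaphragm_y1_mm, seg.diaphragm_y2_mm),
            seg.mu, plan.geometry, grid,
        )
    return total


def delivered_fluence(
    log: DeliveryLog,
    grid: FluenceGrid,
    stationarity_tol_mm: float = 0.3,
    min_segment_mu: float = 0.1,
) -> FluenceMap:
    """Delivered fluence reconstructed from a log's stationary segments."""
    segments = extract_segments(log, stationarity_tol_mm, min_segment_mu)
    total = FluenceMap(grid, np.zeros((grid.ny, grid.nx)))
    for seg in segments:
        total = total + rasterize_aperture(
            seg.leaf_a_mm, seg.leaf_b_mm,
            (seg.diaphragm_x1_mm, seg.diaphragm_x2_mm,
             seg.diaphragm_y1_mm, seg.diaphragm_y2_mm),
            seg.mu, log.geometry, grid,
        )
    return total


def segment_open_area_mm2(
    leaf_a_mm: np.ndarray,
    leaf_b_mm: np.ndarray,
    diaphragms: tuple[float, float, float, float],
    geometry: MachineGeometry,
    grid: FluenceGrid,
) -> float:
    """Open area of one aperture under the pixel-center rule (pixel count
    times pixel area), the same discretization the rasterizer uses."""
    fm = rasterize_aperture(leaf_a_mm, leaf_b_mm, diaphragms, 1.0, geometry, grid)
    return float((fm.values > 0).sum()) * grid.spacing_mm ** 2


# ---------------------------------------------------------------------------
# Plain-text fluence format
# ---------------------------------------------------------------------------


def write_fluence(fmap: FluenceMap, path: str | Path) -> None:
    """Export a fluence map as plain text (3 header lines + row-major values)."""
    g = fmap.grid
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(FLUENCE_FORMAT + "\n")
        fh.write(f"nx={g.nx} ny={g.ny}\n")
        fh.write(
            f"spacing_mm={g.spacing_mm!r} origin_x_mm={g.origin_x_mm!r} "
            f"origin_y_mm={g.origin_y_mm!r}\n"
        )
        for row in fmap.values:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_fluence(path: str | Path) -> FluenceMap:
    """Import a fluence map from the plain-text format."""
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].strip() != FLUENCE_FORMAT:
        raise FluenceError(f"not a fluence file (expected {FLUENCE_FORMAT!r} header)")
    try:
        dims = dict(kv.split("=") for kv in lines[1].split())
        geom = dict(kv.split("=") for kv in lines[2].split())
        grid = FluenceGrid(
            origin_x_mm=float(geom["origin_x_mm"]),
            origin_y_mm=float(geom["origin_y_mm"]),
            spacing_mm=float(geom["spacing_mm"]),
            nx=int(dims["nx"]), ny=int(dims["ny"]),
        )
    except (KeyError, ValueError) as exc:
        raise FluenceError(f"malformed fluence header: {exc}") from exc
    values = np.array([[float(v) for v in ln.split()] for ln in lines[3:3 + grid.ny]])
    return FluenceMap(grid, values)
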