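"""Quadrat sampling of local diffusion coefficients.

The analysed field is partitioned into a checkerboard of square quadrats
(typically 1-4 um^2). Trajectory-window segments are assigned to the quadrat
containing their centroid; each quadrat with enough data contributes one
local D_lat value obtained by averaging its segments' MSD curves lag-by-lag
and fitting the initial slope of the averaged curve. Quadrats with too few
contributing trajectory segments are excluded from statistics (and shown
black/masked on maps).

A quadrat-level statistic enables spatial statistics: per the central limit
theorem the per-quadrat mean D_lat values of a homogeneous membrane are
normally distributed even though individual window estimates are gamma-like,
so departures from normality signal spatial heterogeneity.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from skimage.draw import line as _draw_line
from skimage.morphology import dilation as _dilation, footprint_rectangle

from .msd import DEFAULT_N_FIT_LAGS, MSDCurve, SegmentEstimate, fit_dlat

__all__ = [
    "QuadratGrid",
    "QuadratResult",
    "MobilityMap",
    "Classification",
    "assign_segments",
    "quadrat_dlat",
    "analyze_quadrats",
    "classify_quadrats",
    "render_dlat_map",
    "quadrat_raster",
]

logger = logging.getLogger(__name__)

DEFAULT_MIN_TRAJECTORIES = 5


@dataclass(frozen=True)
class QuadratGrid:
    """Checkerboard of square sample cells.

    Cells use half-open intervals: cell (row, col) covers
    [origin_x + col*s, origin_x + (col+1)*s) x [origin_y + row*s, ...).
    """

    origin: tuple[float, float]
    cell_side: float
    n_cols: int
    n_rows: int

    def __post_init__(self) -> None:
        if self.cell_side <= 0:
            raise ValueError("cell_side must be positive")
        if self.n_cols < 1 or self.n_rows < 1:
            raise ValueError("grid must have at least one cell")

    @classmethod
    def from_bounds(cls, x_min: float, y_min: float, x_max: float,
                    y_max: float, cell_side: float) -> "QuadratGrid":
        """Grid anchored at (x_min, y_min) covering the bounding box."""
        n_cols = max(1, int(np.ceil((x_max - x_min) / cell_side - 1e-9)))
        n_rows = max(1, int(np.ceil((y_max - y_min) / cell_side - 1e-9)))
        return cls((x_min, y_min), cell_side, n_cols, n_rows)

    @property
    def n_cells(self) -> int:
        return self.n_cols * self.n_rows

    def cell_of(self, x: float, y: float) -> Optional[tuple[int, int]]:
        """Cell containing (x, y), or None if outside the grid (overflow)."""
        col = int(np.floor((x - self.origin[0]) / self.cell_side))
        row = int(np.floor((y - self.origin[1]) / self.cell_side))
        if 0 <= col < self.n_cols and 0 <= row < self.n_rows:
            return row, col
        return None

    def cell_bounds(self, row: int, col: int) -> tuple[float, float, float, float]:
        x0 = self.origin[0] + col * self.cell_side
        y0 = self.origin[1] + row * self.cell_side
        return x0, y0, x0 + self.cell_side, y0 + self.cell_side

    def cells_overlapping(self, region: tuple[float, float, float, float]
                          ) -> list[tuple[int, int]]:
        """Cells whose open interior intersects the rectangle `region`.

        A cell straddling a region boundary belongs to every region it
        overlaps, so adjacent regions can share a boundary column/row of
        cells.
        """
        rx0, ry0, rx1, ry1 = region
        out = []
        for row in range(self.n_rows):
            for col in range(self.n_cols):
                x0, y0, x1, y1 = self.cell_bounds(row, col)
                if x0 < rx1 and x1 > rx0 and y0 < ry1 and y1 > ry0:
                    out.append((row, col))
        return out


@dataclass
class QuadratResult:
    """Aggregate result for one grid cell."""

    cell: tuple[int, int]                  # (row, col)
    n_segments: int
    n_trajectories: int                    # distinct parent tracks
    status: str                            # "included" | "excluded_too_few"
    curve: Optional[MSDCurve] = None       # per-lag mean of segment curves
    D_lat: Optional[float] = None          # um^2/s, only when included
    intercept: Optional[float] = None

    @property
    def included(self) -> bool:
        return self.status == "included"


@dataclass
class MobilityMap:
    """Raster of locally averaged D_lat values at display resolution.

    Pixels never touched by a (dilated) trajectory segment are masked, not
    zero-filled; ``values`` is a masked array in um^2/s.
    """

    values: np.ma.MaskedArray
    pixel_size: float

    @property
    def mask(self) -> np.ndarray:
        """True where a pixel is covered by at least one segment."""
        return ~np.ma.getmaskarray(self.values)


@dataclass
class Classification:
    """Fast/intermediate/slow labels for included quadrats.

    Thresholds are mean +/- k*SD of the included quadrat D_lat values, where
    the mean is the mean of the quadrat means.
    """

    labels: dict[tuple[int, int], str]
    mean: float
    sd: float
    k_sd: float = 1.5


# ---------------------------------------------------------------------------


def assign_segments(
    segments: Sequence[SegmentEstimate], grid: QuadratGrid
) -> tuple[dict[tuple[int, int], list[SegmentEstimate]], list[SegmentEstimate]]:
    """Assign each segment to the single cell containing its centroid.

    Returns (per-cell segment lists, overflow list of segments whose centroid
    lies outside the grid). Cells use half-open intervals, so a centroid on
    an interior boundary goes to the higher-index cell.
    """
    cells: dict[tuple[int, int], list[SegmentEstimate]] = {}
    overflow: list[SegmentEstimate] = []
    for seg in segments:
        key = grid.cell_of(seg.centroid[0], seg.centroid[1])
        if key is None:
            overflow.append(seg)
        else:
            cells.setdefault(key, []).append(seg)
    if overflow:
        logger.info("assign_segments: %d segments fell outside the grid",
                    len(overflow))
    return cells, overflow


def quadrat_dlat(
    cell_segments: Sequence[SegmentEstimate],
    cell: tuple[int, int] = (0, 0),
    min_trajectories: int = DEFAULT_MIN_TRAJECTORIES,
    n_fit_lags: int = DEFAULT_N_FIT_LAGS,
    count: str = "segments",
    weighting: str = "unweighted",
) -> QuadratResult:
    """Local D_lat for one quadrat from its trajectory segments.

    The segments' MSD curves are averaged lag-by-lag (default: unweighted
    mean across segments; ``weighting="pairs"`` weights each segment's value
    by its pair count) and the initial slope of the averaged curve gives
    D_lat. A quadrat is excluded when it holds fewer than ``min_trajectories``
    units, where a unit is a trajectory segment of >= 10 points
    (``count="segments"``, the default) or a distinct parent trajectory
    (``count="tracks"``).
    """
    n_seg = len(cell_segments)
    n_par = len({s.track_id for s in cell_segments})
    n_units = n_seg if count == "segments" else n_par
    if count not in ("segments", "tracks"):
        raise ValueError("count must be 'segments' or 'tracks'")
    if n_units < min_trajectories:
        return QuadratResult(cell, n_seg, n_par, "excluded_too_few")
    lags = cell_segments[0].curve.lags
    curves = np.array([s.curve.msd for s in cell_segments])
    pairs = np.array([s.curve.n_pairs for s in cell_segments])
    if weighting == "unweighted":
        mean_msd = curves.mean(axis=0)
    elif weighting == "pairs":
        mean_msd = (curves * pairs).sum(axis=0) / pairs.sum(axis=0)
    else:
        raise ValueError("weighting must be 'unweighted' or 'pairs'")
    avg = MSDCurve(lags, mean_msd, pairs.sum(axis=0))
    fit = fit_dlat(avg, n_fit_lags)
    return QuadratResult(cell, n_seg, n_par, "included", avg,
                         fit.D_lat, fit.intercept)


def analyze_quadrats(
    segments: Sequence[SegmentEstimate],
    grid: QuadratGrid,
    min_trajectories: int = DEFAULT_MIN_TRAJECTORIES,
    n_fit_lags: int = DEFAULT_N_FIT_LAGS,
    count: str = "segments",
    weighting: str = "unweighted",
) -> list[QuadratResult]:
    """Full quadrat analysis: assign, aggregate and fit every occupied cell."""
    cells, _overflow = assign_segments(segments, grid)
    return [
        quadrat_dlat(cells[key], key, min_trajectories, n_fit_lags, count,
                     weighting)
        for key in sorted(cells)
    ]


def classify_quadrats(results: Iterable[QuadratResult],
                      k_sd: float = 1.5) -> Classification:
    """Label included quadrats fast / intermediate / slow.

    fast: D_lat > mean + k*SD; slow: D_lat < mean - k*SD; otherwise
    intermediate. The mean is the mean of the included quadrat means and SD
    their sample standard deviation.
    """
    included = [r for r in results if r.included]
    if len(included) < 2:
        raise ValueError("need at least 2 included quadrats to classify")
    values = np.array([r.D_lat for r in included])
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    labels = {}
    for r in included:
        if r.D_lat > mean + k_sd * sd:
            labels[r.cell] = "fast"
        elif r.D_lat < mean - k_sd * sd:
            labels[r.cell] = "slow"
        else:
            labels[r.cell] = "intermediate"
    return Classification(labels, mean, sd, k_sd)


# ---------------------------------------------------------------------------
# rendering


def render_dlat_map(
    segments: Sequence[SegmentEstimate],
    pixel_size: float,
    shape: Optional[tuple[int, int]] = None,
    dilation: int = 5,
) -> MobilityMap:
    """Paint every segment's (dilated) path with its D_lat value.

    Each segment's polyline is rasterised, dilated to ``dilation`` pixels
    width, and painted with the segment's D_lat; where segments overlap the
    pixel holds the mean of all contributing values. For display the caller
    may clip negative values at zero; the stored values are not clipped.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    if not segments:
        raise ValueError("no segments to render")
    if shape is None:
        all_pts = np.concatenate([s.points for s in segments])
        ny = int(np.ceil(all_pts[:, 1].max() / pixel_size)) + dilation
        nx = int(np.ceil(all_pts[:, 0].max() / pixel_size)) + dilation
        shape = (ny, nx)
    total = np.zeros(shape)
    count = np.zeros(shape, dtype=int)
    # dilation to an odd width w: square footprint of w x w applied once
    half = dilation // 2
    footprint = footprint_rectangle((2 * half + 1, 2 * half + 1))
    for seg in segments:
        mask = np.zeros(shape, dtype=bool)
        ij = np.floor(seg.points[:, ::-1] / pixel_size).astype(int)  # (row, col)
        ij = np.clip(ij, 0, np.array(shape) - 1)
        for a, b in zip(ij[:-1], ij[1:]):
            rr, cc = _draw_line(a[0], a[1], b[0], b[1])
            mask[rr, cc] = True
        if half:
            mask = _dilation(mask, footprint)
        total[mask] += seg.D_lat
        count[mask] += 1
    values = np.ma.masked_array(
        np.divide(total, count, out=np.zeros(shape), where=count > 0),
        mask=count == 0)
    return MobilityMap(values, pixel_size)


def quadrat_raster(results: Iterable[QuadratResult],
                   grid: QuadratGrid) -> np.ma.MaskedArray:
    """One value per grid cell; excluded / empty cells are masked."""
    raster = np.ma.masked_all((grid.n_rows, grid.n_cols))
    for r in results:
        if r.included:
            raster[r.cell] = r.D_lat
    return raster
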