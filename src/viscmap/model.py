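"""Model/Results interface tying the pipeline together.

`QuadratMobilityModel` is constructed from observed trajectories (simulated
or tracked) plus the analysis parameters; `fit()` segments the trajectories
into 10-frame windows, runs the quadrat aggregation and the statistical
layer, and returns a `QuadratMobilityResults` carrying the per-quadrat
estimates, the global summary (mean of quadrat means, SD, KS normality) and
plotting/reporting helpers — in the spirit of the statsmodels fit/results
split.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import msd as _msd
from . import quadrat as _quadrat
from . import stats as _stats
from .tracks import Trajectory

__all__ = ["QuadratMobilityModel", "QuadratMobilityResults"]

Rect = tuple[float, float, float, float]


class QuadratMobilityModel:
    """Quadrat-sampled membrane mobility analysis of a set of trajectories.

    Parameters
    ----------
    trajectories : sequence of Trajectory
        Observed tracks in um; tracks shorter than ``min_track_length``
        frames are ignored.
    frame_interval : float
        Time between frames (s).
    cell_side : float
        Quadrat side (um); 1 or 2 um are typical.
    window : int
        Segment window length in frames.
    n_fit_lags : int
        Number of initial MSD lags used in every slope fit.
    min_trajectories : int
        Minimum data units for a quadrat to be included.
    count : str
        What the inclusion rule counts: "segments" (trajectory segments of
        >= ``window`` points; default) or "tracks" (distinct parents).
    min_track_length : int
        Minimum track length in frames (tracks below are dropped).
    grid : QuadratGrid, optional
        Explicit grid; by default anchored at the trajectories' bounding box
        lower-left corner.
    regions : mapping name -> (x0, y0, x1, y1), optional
        Named rectangular regions for grouped reports and pairwise tests;
        a cell belongs to every region its rectangle overlaps.
    alpha, ks_variant :
        Passed to the statistical layer.
    """

    def __init__(
        self,
        trajectories: Sequence[Trajectory],
        frame_interval: float,
        cell_side: float = 2.0,
        window: int = _msd.DEFAULT_WINDOW,
        n_fit_lags: int = _msd.DEFAULT_N_FIT_LAGS,
        min_trajectories: int = _quadrat.DEFAULT_MIN_TRAJECTORIES,
        count: str = "segments",
        min_track_length: int = 10,
        grid: Optional[_quadrat.QuadratGrid] = None,
        regions: Optional[Mapping[str, Rect]] = None,
        alpha: float = _stats.DEFAULT_ALPHA,
        ks_variant: str = "fitted",
    ):
        if frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        self.trajectories = [t for t in trajectories
                             if len(t) >= min_track_length]
        if not self.trajectories:
            raise ValueError("no trajectories of sufficient length")
        self.frame_interval = frame_interval
        self.cell_side = cell_side
        self.window = window
        self.n_fit_lags = n_fit_lags
        self.min_trajectories = min_trajectories
        self.count = count
        self.min_track_length = min_track_length
        self.grid = grid
        self.regions = dict(regions) if regions else {}
        self.alpha = alpha
        self.ks_variant = ks_variant

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, frame_interval: float,
                       **kwargs) -> "QuadratMobilityModel":
        """Build from a table with columns track_id, frame, x_um, y_um."""
        trajs = []
        for tid, g in df.sort_values(["track_id", "frame"]).groupby("track_id"):
            trajs.append(Trajectory(int(tid), g["frame"].to_numpy(),
                                    g[["x_um", "y_um"]].to_numpy(),
                                    source="detected"))
        return cls(trajs, frame_interval, **kwargs)

    def fit(self) -> "QuadratMobilityResults":
        segments = _msd.segment_trajectories(
            self.trajectories, self.frame_interval, self.window,
            self.n_fit_lags)
        if not segments:
            raise ValueError("no complete segment windows")
        grid = self.grid
        if grid is None:
            cents = np.array([s.centroid for s in segments])
            grid = _quadrat.QuadratGrid.from_bounds(
                cents[:, 0].min(), cents[:, 1].min(),
                cents[:, 0].max(), cents[:, 1].max(), self.cell_side)
        results = _quadrat.analyze_quadrats(
            segments, grid, self.min_trajectories, self.n_fit_lags,
            self.count)
        group_cells = {name: grid.cells_overlapping(rect)
                       for name, rect in self.regions.items()} or None
        report = _stats.summarize(results, group_cells=group_cells,
                                  alpha=self.alpha, ks_variant=self.ks_variant)
        return QuadratMobilityResults(self, grid, segments, results, report)


@dataclass
class QuadratMobilityResults:
    """Fitted quadrat mobility analysis."""

    model: QuadratMobilityModel
    grid: _quadrat.QuadratGrid
    segments: list[_msd.SegmentEstimate]
    quadrats: list[_quadrat.QuadratResult]
    report: _stats.HeterogeneityReport

    # -- scalar accessors ---------------------------------------------------
    @property
    def dlat_values(self) -> np.ndarray:
        """Included quadrats' local D_lat values (um^2/s)."""
        return self.report.values

    @property
    def mean_dlat(self) -> float:
        """Mean of the quadrat means (um^2/s)."""
        return self.report.mean

    @property
    def sd_dlat(self) -> float:
        return self.report.sd

    @property
    def n_included(self) -> int:
        return self.report.n

    @property
    def ks(self):
        return self.report.ks

    def classify(self, k_sd: float = 1.5) -> _quadrat.Classification:
        return _quadrat.classify_quadrats(self.quadrats, k_sd)

    def region_values(self, name: str) -> np.ndarray:
        return self.report.groups[name].values

    # -- tabular / plotting -------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Per-quadrat table."""
        rows = []
        for r in self.quadrats:
            x0, y0, x1, y1 = self.grid.cell_bounds(*r.cell)
            rows.append({
                "row": r.cell[0], "col": r.cell[1],
                "x_center_um": (x0 + x1) / 2, "y_center_um": (y0 + y1) / 2,
                "n_segments": r.n_segments,
                "n_trajectories": r.n_trajectories,
                "status": r.status,
                "D_lat_um2_s": r.D_lat,
                "intercept_um2": r.intercept,
            })
        return pd.DataFrame(rows)

    def quadrat_raster(self) -> np.ma.MaskedArray:
        return _quadrat.quadrat_raster(self.quadrats, self.grid)

    def mobility_map(self, pixel_size: float = 0.1,
                     dilation: int = 5) -> _quadrat.MobilityMap:
        return _quadrat.render_dlat_map(self.segments, pixel_size,
                                        dilation=dilation)

    def plot_map(self, ax=None, pixel_size: float = 0.1, clip_zero: bool = True):
        """Pseudo-colour heat map of locally averaged D_lat along tracks."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        m = self.mobility_map(pixel_size)
        vals = m.values
        if clip_zero:
            vals = np.ma.clip(vals, 0, None)
        im = ax.imshow(vals, origin="lower", cmap="inferno",
                       extent=(0, vals.shape[1] * pixel_size,
                               0, vals.shape[0] * pixel_size))
        ax.set_xlabel("x (μm)")
        ax.set_ylabel("y (μm)")
        plt.colorbar(im, ax=ax, label="$D_{lat}$ (μm$^2$ s$^{-1}$)")
        return ax

    def plot_quadrats(self, ax=None):
        """Heat map of the quadrat-sampled D_lat values (excluded cells masked)."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        raster = self.quadrat_raster()
        x0, y0 = self.grid.origin
        s = self.grid.cell_side
        cmap = plt.get_cmap("inferno").copy()
        cmap.set_bad("black")
        im = ax.imshow(raster, origin="lower", cmap=cmap,
                       extent=(x0, x0 + self.grid.n_cols * s,
                               y0, y0 + self.grid.n_rows * s))
        ax.set_xlabel("x (μm)")
        ax.set_ylabel("y (μm)")
        plt.colorbar(im, ax=ax, label="quadrat $D_{lat}$ (μm$^2$ s$^{-1}$)")
        return ax

    def plot_hist(self, ax=None, bins: int = 25):
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        ax.hist(self.dlat_values, bins=bins, color="0.4", edgecolor="white")
        ax.axvline(self.mean_dlat, color="crimson", label="mean of quadrat means")
        ax.set_xlabel("quadrat $D_{lat}$ (μm$^2$ s$^{-1}$)")
        ax.set_ylabel("quadrats")
        ax.legend()
        return ax

    # -- reporting ----------------------------------------------------------
    def summary(self) -> str:
        """Human-readable summary table."""
        buf = io.StringIO()
        w = buf.write
        w("Quadrat mobility analysis\n")
        w("=" * 60 + "\n")
        w(f"trajectories (>= {self.model.min_track_length} frames): "
          f"{len(self.model.trajectories)}\n")
        w(f"segments ({self.model.window}-frame windows): {len(self.segments)}\n")
        w(f"grid: {self.grid.n_rows} x {self.grid.n_cols} cells of "
          f"{self.grid.cell_side} um; inclusion: >= "
          f"{self.model.min_trajectories} {self.model.count}\n")
        w("-" * 60 + "\n")
        w(f"{'group':<16}{'mean':>8}{'SD':>8}{'n':>6}{'KS D':>8}"
          f"{'p':>10}  verdict\n")

        def row(name, rep):
            ks = rep.ks
            w(f"{name:<16}{rep.mean:>8.3f}{rep.sd:>8.3f}{rep.n:>6d}"
              + (f"{ks.D:>8.3f}{ks.pvalue:>10.3g}  {ks.verdict}\n"
                 if ks else f"{'--':>8}{'--':>10}  (n too small)\n"))

        row("all quadrats", self.report)
        for name, rep in self.report.groups.items():
            row(name, rep)
        for c in self.report.comparisons:
            dftxt = f", df={c.df:.1f}" if c.df is not None else ""
            w(f"{c.group_a} vs {c.group_b}: {c.test} stat={c.statistic:.3f}"
              f"{dftxt}, p={c.pvalue:.3g}\n")
        w("units: D_lat in um^2/s\n")
        return buf.getvalue()

    def to_dict(self) -> dict:
        d = self.report.to_dict()
        d["n_segments"] = len(self.segments)
        d["n_trajectories"] = len(self.model.trajectories)
        d["cell_side_um"] = self.grid.cell_side
        return d
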