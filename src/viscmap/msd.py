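"""Mean-squared displacement analysis and local diffusion estimation.

The local lateral diffusion coefficient D_lat of a 2D Brownian walker is
estimated from the initial slope of its MSD vs dT plot: MSD(dT) = 4 D dT for
free 2D diffusion, plus a constant offset of 4 sigma_loc^2 contributed by
localization error. The slope is obtained by ordinary least squares over the
first few lags with a free intercept, so the noise floor is absorbed by the
intercept rather than biasing D_lat; fitted values may be negative on slow,
noisy segments and are deliberately retained (clipping would bias averages
upward).

Trajectories are chopped into sequential non-overlapping windows (default 10
frames, ~0.4 s at 33 fps); each window yields one local D_lat estimate tied
to the window's centroid. The distribution of these per-window estimates is
strongly right-skewed (approximately gamma, because each rests on very few
displacements), which is why downstream quadrat statistics average many
windows per unit area.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy import optimize

from .tracks import Trajectory

__all__ = [
    "MSDCurve",
    "SegmentEstimate",
    "BleachFit",
    "DlatFit",
    "compute_msd",
    "fit_dlat",
    "segment_windows",
    "segment_trajectories",
    "estimate_bleach_rate",
    "pooled_msd",
]

DEFAULT_WINDOW = 10
DEFAULT_N_FIT_LAGS = 4


@dataclass(frozen=True)
class MSDCurve:
    """Mean squared displacement vs time lag.

    lags: time lags dT in seconds (strictly increasing);
    msd: mean squared 2D displacement per lag (um^2), averaged over all
    overlapping point pairs at that lag; n_pairs: pairs per lag.
    """

    lags: np.ndarray
    msd: np.ndarray
    n_pairs: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "lags", np.asarray(self.lags, float))
        object.__setattr__(self, "msd", np.asarray(self.msd, float))
        object.__setattr__(self, "n_pairs", np.asarray(self.n_pairs, int))
        if not (self.lags.shape == self.msd.shape == self.n_pairs.shape):
            raise ValueError("lags, msd and n_pairs must have equal shape")
        if self.lags.size and np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        if np.any(self.n_pairs < 1):
            raise ValueError("every reported lag needs at least one pair")

    def __len__(self) -> int:
        return int(self.lags.size)


class DlatFit(NamedTuple):
    D_lat: float      # um^2/s, slope/4
    intercept: float  # um^2


@dataclass
class SegmentEstimate:
    """Local D_lat estimate from one trajectory window."""

    track_id: int
    start_frame: int
    centroid: np.ndarray      # (x, y) mean of the window's points, um
    D_lat: float
    intercept: float
    curve: MSDCurve
    points: np.ndarray        # (window, 2) observed positions, um


@dataclass(frozen=True)
class BleachFit:
    """Exponential photobleaching fit."""

    rate: float        # 1/s
    amplitude: float   # initial count (counts fit) or sample size (lifetimes)
    r_squared: float   # goodness of fit (1.0 for the ML lifetime estimator)
    method: str        # "counts" or "lifetimes"


# ---------------------------------------------------------------------------


def _as_points(points) -> tuple[np.ndarray, np.ndarray]:
    """Accept a Trajectory or an (n, >=3) array of (frame, x, y) rows."""
    if isinstance(points, Trajectory):
        return points.frames, points.xy
    arr = np.asarray(points, float)
    if arr.ndim != 2 or arr.shape[1] < 3:
        raise ValueError("expected a Trajectory or (n, 3) rows of (frame, x, y)")
    return arr[:, 0].astype(np.int64), arr[:, 1:3]


def compute_msd(points, frame_interval: float,
                max_lag: Optional[int] = None) -> MSDCurve:
    """MSD over all possible time intervals, using every overlapping pair.

    For each lag n = 1..max_lag (default: track length - 1),
    msd(n) = mean_i [ (x_{i+n}-x_i)^2 + (y_{i+n}-y_i)^2 ].
    Tracks must have consecutive frame numbers.
    """
    frames, xy = _as_points(points)
    n = len(frames)
    if n < 2:
        raise ValueError("need at least 2 points")
    if np.any(np.diff(frames) != 1):
        raise ValueError("frames must be consecutive (gap-free) for MSD")
    if max_lag is None:
        max_lag = n - 1
    max_lag = min(max_lag, n - 1)
    lags = np.arange(1, max_lag + 1)
    msd = np.empty(max_lag)
    n_pairs = np.empty(max_lag, dtype=int)
    for k in lags:
        d = xy[k:] - xy[:-k]
        msd[k - 1] = np.mean((d ** 2).sum(axis=1))
        n_pairs[k - 1] = n - k
    return MSDCurve(lags * frame_interval, msd, n_pairs)


def _slope_hat(lags: np.ndarray) -> np.ndarray:
    """(2, k) matrix mapping msd values to (slope, intercept) by OLS."""
    A = np.column_stack([lags, np.ones_like(lags)])
    return np.linalg.pinv(A)


def fit_dlat(curve: MSDCurve, n_fit_lags: int = DEFAULT_N_FIT_LAGS) -> DlatFit:
    """Initial slope of the MSD vs dT plot; D_lat = slope / 4 (2D diffusion).

    Ordinary least squares through the first ``n_fit_lags`` points with a
    free intercept (the intercept absorbs the 4 sigma^2 localization noise
    floor).
    """
    if n_fit_lags < 2:
        raise ValueError("n_fit_lags must be >= 2")
    if len(curve) < n_fit_lags:
        raise ValueError(f"curve has {len(curve)} lags, need {n_fit_lags}")
    x = curve.lags[:n_fit_lags]
    if np.ptp(x) == 0:
        raise ValueError("degenerate lags")
    slope, intercept = _slope_hat(x) @ curve.msd[:n_fit_lags]
    return DlatFit(slope / 4.0, intercept)


# ---------------------------------------------------------------------------
# windowed segmentation


def _window_msd_batch(windows: np.ndarray) -> np.ndarray:
    """All-pairs MSD curves for a batch of equal-length windows.

    windows: (N, w, 2) -> (N, w-1) msd values for lags 1..w-1.
    """
    n, w, _ = windows.shape
    out = np.empty((n, w - 1))
    for k in range(1, w):
        d = windows[:, k:, :] - windows[:, :-k, :]
        out[:, k - 1] = (d ** 2).sum(axis=2).mean(axis=1)
    return out


def segment_windows(
    traj: Trajectory,
    frame_interval: float,
    window: int = DEFAULT_WINDOW,
    n_fit_lags: int = DEFAULT_N_FIT_LAGS,
) -> list[SegmentEstimate]:
    """Chop a trajectory into sequential non-overlapping windows.

    Each full window of ``window`` points yields a local MSD curve (lags
    1..window-1), a D_lat estimate (initial-slope fit) and a centroid; the
    trailing remainder shorter than ``window`` is dropped. Trajectories
    shorter than one window yield an empty list.
    """
    return segment_trajectories([traj], frame_interval, window, n_fit_lags)


def segment_trajectories(
    trajectories: Sequence[Trajectory],
    frame_interval: float,
    window: int = DEFAULT_WINDOW,
    n_fit_lags: int = DEFAULT_N_FIT_LAGS,
) -> list[SegmentEstimate]:
    """Windowed local D_lat estimates for many trajectories (vectorised)."""
    if window < n_fit_lags + 1:
        raise ValueError("window must allow at least n_fit_lags lags")
    blocks = []
    meta = []
    for traj in trajectories:
        n_win = len(traj) // window
        if n_win == 0:
            continue
        pts = traj.xy[: n_win * window].reshape(n_win, window, 2)
        blocks.append(pts)
        for w in range(n_win):
            meta.append((traj.track_id, int(traj.frames[w * window])))
    if not blocks:
        return []
    windows = np.concatenate(blocks, axis=0)
    msd = _window_msd_batch(windows)                      # (N, window-1)
    lags = np.arange(1, window) * frame_interval
    params = msd[:, :n_fit_lags] @ _slope_hat(lags[:n_fit_lags]).T  # (N, 2)
    centroids = windows.mean(axis=1)
    n_pairs = window - np.arange(1, window)
    out = []
    for i, (tid, start) in enumerate(meta):
        curve = MSDCurve(lags, msd[i], n_pairs)
        out.append(SegmentEstimate(tid, start, centroids[i],
                                   params[i, 0] / 4.0, params[i, 1],
                                   curve, windows[i]))
    return out


def pooled_msd(trajectories: Sequence[Trajectory], frame_interval: float,
               max_lag: int) -> MSDCurve:
    """Pair-count-weighted MSD pooled over whole trajectories."""
    sums = np.zeros(max_lag)
    counts = np.zeros(max_lag, dtype=int)
    for traj in trajectories:
        if len(traj) < 2:
            continue
        for k in range(1, min(max_lag, len(traj) - 1) + 1):
            d = traj.xy[k:] - traj.xy[:-k]
            sums[k - 1] += (d ** 2).sum()
            counts[k - 1] += len(traj) - k
    keep = counts > 0
    lags = np.arange(1, max_lag + 1)[keep] * frame_interval
    return MSDCurve(lags, sums[keep] / counts[keep], counts[keep])


# ---------------------------------------------------------------------------
# photobleaching


def estimate_bleach_rate(
    counts: Optional[np.ndarray] = None,
    times: Optional[np.ndarray] = None,
    lifetimes: Optional[np.ndarray] = None,
    frame_interval: Optional[float] = None,
) -> BleachFit:
    """Photobleaching rate from visible-molecule counts or track lifetimes.

    Two estimators are exposed:

    * counts mode — nonlinear least squares of A * exp(-k t) to the number of
      visible molecules per frame (pass ``counts`` and either ``times`` or
      ``frame_interval``); needs >= 10 time points.
    * lifetimes mode — maximum-likelihood exponential fit to per-track
      lifetimes in seconds (k = 1 / mean); needs >= 50 lifetimes.
    """
    if (counts is None) == (lifetimes is None):
        raise ValueError("pass exactly one of counts= or lifetimes=")
    if counts is not None:
        counts = np.asarray(counts, float)
        if counts.size < 10:
            raise ValueError("need >= 10 time points")
        if np.all(counts == 0):
            raise ValueError("cannot fit all-zero counts")
        if times is None:
            if frame_interval is None:
                raise ValueError("counts mode needs times= or frame_interval=")
            times = np.arange(counts.size) * frame_interval
        times = np.asarray(times, float)
        if np.ptp(counts) == 0:
            return BleachFit(0.0, float(counts[0]), 1.0, "counts")
        k0 = 1.0 / max(times[-1] - times[0], 1e-12)
        popt, _ = optimize.curve_fit(
            lambda t, a, k: a * np.exp(-k * t), times, counts,
            p0=(counts[0] if counts[0] > 0 else counts.max(), k0),
            bounds=([0, 0], [np.inf, np.inf]), maxfev=10000)
        fit = popt[0] * np.exp(-popt[1] * times)
        ss_res = float(np.sum((counts - fit) ** 2))
        ss_tot = float(np.sum((counts - counts.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        return BleachFit(float(popt[1]), float(popt[0]), r2, "counts")
    lifetimes = np.asarray(lifetimes, float)
    if lifetimes.size < 50:
        raise ValueError("need >= 50 lifetimes")
    if np.any(lifetimes <= 0):
        raise ValueError("lifetimes must be positive")
    return BleachFit(float(1.0 / lifetimes.mean()), float(lifetimes.size),
                     1.0, "lifetimes")
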