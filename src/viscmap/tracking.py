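"""Single-fluorophore detection and trajectory linking.

Spots are detected per frame as local maxima above an adaptive background
threshold and refined to sub-pixel precision by least-squares 2D Gaussian
fitting in a small window. Detections are linked frame-to-frame by greedy
nearest-neighbour assignment under a maximum-displacement gate (default
0.7 um/frame). Linking is deliberately conservative: whenever an assignment
is ambiguous — two active tracks competing for one detection (spots merged)
or a track torn between two detections — every involved track is terminated
and fresh tracks start once detections become unambiguous again. No gap
closing is performed; a missed detection ends the track. Tracks shorter than
a minimum length (default 10 frames) are excluded from analysis output.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage, optimize
from skimage.registration import phase_cross_correlation

from .simulate import VideoStack
from .tracks import Trajectory

__all__ = [
    "SpotDetection",
    "LinkConfig",
    "LinkResult",
    "detect_spots",
    "detect_stack",
    "link_tracks",
    "correct_drift",
    "remove_immobile",
    "intensity_projections",
]

logger = logging.getLogger(__name__)


@dataclass
class SpotDetection:
    """One sub-pixel localisation (coordinates in um)."""

    frame: int
    x: float
    y: float
    amplitude: float
    sigma: float           # fitted PSF sigma, um
    background: float      # fitted local background, counts
    residual: float        # rms fit residual, counts
    saturated: bool = False


@dataclass(frozen=True)
class LinkConfig:
    """Detection and linking parameters."""

    max_link_distance: float = 0.7    # um per frame
    min_track_length: int = 10        # frames
    threshold_k: float = 4.0          # detection threshold, background SDs
    smooth_sigma: float = 1.0         # matched-filter Gaussian sigma, pixels
    fit_window: int = 7               # odd, pixels
    sigma_bounds: tuple[float, float] = (0.06, 0.35)  # plausible PSF sigma, um

    def __post_init__(self) -> None:
        if self.max_link_distance <= 0:
            raise ValueError("max_link_distance must be positive")
        if self.min_track_length < 2:
            raise ValueError("min_track_length must be >= 2")
        if self.fit_window % 2 == 0 or self.fit_window < 3:
            raise ValueError("fit_window must be odd and >= 3")


@dataclass
class LinkResult:
    """Output of the linker: analysis tracks, raw (unfiltered) tracks and
    termination statistics."""

    trajectories: list[Trajectory]
    raw_trajectories: list[Trajectory]
    stats: dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# detection


def _gauss2d(params, xx, yy):
    a, x0, y0, s, b = params
    return a * np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2) / (2 * s ** 2)) + b


def detect_spots(
    frame: np.ndarray,
    pixel_size: float,
    config: Optional[LinkConfig] = None,
    frame_index: int = 0,
    saturation_level: Optional[float] = None,
) -> list[SpotDetection]:
    """Detect fluorophores in one frame with sub-pixel precision.

    The frame is first matched-filtered (Gaussian smoothing at roughly the
    PSF scale) to suppress single-pixel shot-noise spikes; candidate local
    maxima of the smoothed image exceeding background + k * background SD
    (robust estimates: median and MAD of the smoothed image) are then
    refined by least-squares 2D Gaussian fits to the raw pixels in a
    ``fit_window`` x ``fit_window`` region. Fits that diverge, wander out of
    the window or land outside plausible PSF width bounds are discarded.
    Saturated candidates are flagged, not dropped.
    """
    if config is None:
        config = LinkConfig()
    img = np.asarray(frame, float)
    if img.size == 0:
        raise ValueError("empty frame")
    smooth = ndimage.gaussian_filter(img, config.smooth_sigma)
    bg_median = np.median(smooth)
    bg_sd = 1.4826 * np.median(np.abs(smooth - bg_median))
    if bg_sd == 0:
        bg_sd = smooth.std() or 1.0
    threshold = bg_median + config.threshold_k * bg_sd
    half = config.fit_window // 2
    maxima = (ndimage.maximum_filter(smooth, size=2 * half - 1) == smooth) \
        & (smooth > threshold)
    maxima[:half, :] = maxima[-half:, :] = False
    maxima[:, :half] = maxima[:, -half:] = False
    if saturation_level is None:
        saturation_level = np.inf
    out: list[SpotDetection] = []
    yy, xx = np.mgrid[-half:half + 1, -half:half + 1].astype(float)
    for i, j in zip(*np.nonzero(maxima)):
        patch = img[i - half:i + half + 1, j - half:j + half + 1]
        b0 = patch.min()
        a0 = patch[half, half] - b0
        if a0 <= 0:
            continue
        try:
            res = optimize.least_squares(
                lambda p: (_gauss2d(p, xx, yy) - patch).ravel(),
                x0=(a0, 0.0, 0.0, 0.13 / pixel_size, b0),
                bounds=([0, -half, -half, 0.2, -np.inf],
                        [np.inf, half, half, 2.0 * half, np.inf]),
                max_nfev=200)
        except Exception:  # fit diverged
            continue
        if not res.success:
            continue
        a, dx, dy, s_px, b = res.x
        sigma_um = s_px * pixel_size
        if not (config.sigma_bounds[0] <= sigma_um <= config.sigma_bounds[1]):
            continue
        if abs(dx) > half - 0.5 or abs(dy) > half - 0.5:
            continue
        x_um = (j + dx + 0.5) * pixel_size
        y_um = (i + dy + 0.5) * pixel_size
        rms = float(np.sqrt(np.mean(res.fun ** 2)))
        out.append(SpotDetection(frame_index, x_um, y_um, float(a),
                                 float(sigma_um), float(b), rms,
                                 saturated=bool(patch.max() >= saturation_level)))
    return out


def detect_stack(video: VideoStack, config: Optional[LinkConfig] = None,
                 drift: Optional[np.ndarray] = None) -> list[list[SpotDetection]]:
    """Detect spots in every frame; optional per-frame drift (um) is
    subtracted from the detection coordinates."""
    if config is None:
        config = LinkConfig()
    sat = 2 ** 16 - 1 if video.frames.dtype == np.uint16 else None
    out = []
    for f in range(video.n_frames):
        dets = detect_spots(video.frames[f], video.pixel_size, config,
                            frame_index=f, saturation_level=sat)
        if drift is not None:
            for d in dets:
                d.x -= drift[f, 0]
                d.y -= drift[f, 1]
        out.append(dets)
    return out


# ---------------------------------------------------------------------------
# linking


class _Active:
    __slots__ = ("track_id", "detections")

    def __init__(self, track_id: int, det: SpotDetection):
        self.track_id = track_id
        self.detections = [det]

    @property
    def last(self) -> SpotDetection:
        return self.detections[-1]


def link_tracks(
    detections_by_frame: Sequence[Sequence[SpotDetection]],
    config: Optional[LinkConfig] = None,
) -> LinkResult:
    """Greedy nearest-neighbour linking with ambiguity truncation.

    Per frame, candidate (track, detection) pairs within the gate are
    processed in order of increasing distance; a pair links only if the
    track's candidate set and the detection's candidate set are both
    singletons (mutually unambiguous). Any track or detection involved in a
    conflict terminates/does not seed, mirroring the behaviour of spots
    merging during a frame; a fresh track starts at the next unambiguous
    detection. Tracks shorter than ``min_track_length`` are dropped from
    ``trajectories`` but retained in ``raw_trajectories``.
    """
    if config is None:
        config = LinkConfig()
    gate = config.max_link_distance
    active: list[_Active] = []
    finished: list[_Active] = []
    stats = {"terminated_no_candidate": 0, "terminated_conflict": 0,
             "detections_discarded_conflict": 0, "terminated_end": 0}
    next_id = 0
    for frame_dets in detections_by_frame:
        dets = list(frame_dets)
        if not active:
            for d in dets:
                active.append(_Active(next_id, d))
                next_id += 1
            continue
        # candidate sets within the gate
        t_cand: list[list[int]] = [[] for _ in active]
        d_cand: list[list[int]] = [[] for _ in dets]
        for ti, tr in enumerate(active):
            for di, d in enumerate(dets):
                dist = np.hypot(tr.last.x - d.x, tr.last.y - d.y)
                if dist <= gate:
                    t_cand[ti].append(di)
                    d_cand[di].append(ti)
        survivors: list[_Active] = []
        used_det: set[int] = set()
        for ti, tr in enumerate(active):
            cands = t_cand[ti]
            if not cands:
                stats["terminated_no_candidate"] += 1
                finished.append(tr)
            elif len(cands) == 1 and len(d_cand[cands[0]]) == 1:
                di = cands[0]
                tr.detections.append(dets[di])
                used_det.add(di)
                survivors.append(tr)
            else:
                stats["terminated_conflict"] += 1
                finished.append(tr)
        active = survivors
        for di, d in enumerate(dets):
            if di in used_det:
                continue
            if len(d_cand[di]) >= 2 or (len(d_cand[di]) == 1
                                        and len(t_cand[d_cand[di][0]]) > 1):
                # detection was part of a conflict (merge/split); do not seed
                stats["detections_discarded_conflict"] += 1
                continue
            active.append(_Active(next_id, d))
            next_id += 1
    stats["terminated_end"] = len(active)
    finished.extend(active)

    raw, kept = [], []
    for tr in finished:
        frames = np.array([d.frame for d in tr.detections])
        xy = np.array([[d.x, d.y] for d in tr.detections])
        traj = Trajectory(tr.track_id, frames, xy, source="detected")
        if traj.max_step() > gate + 1e-9:
            raise AssertionError("linker produced a step beyond the gate")
        raw.append(traj)
        if len(traj) >= config.min_track_length:
            kept.append(traj)
    logger.info("link_tracks: %d raw tracks, %d kept; %s", len(raw),
                len(kept), stats)
    return LinkResult(kept, raw, stats)


# ---------------------------------------------------------------------------
# drift, filtering, projections


def correct_drift(video: VideoStack, n_reference_frames: int = 10,
                  upsample: int = 20) -> np.ndarray:
    """Per-frame (dx, dy) drift offsets in um by cross-correlation.

    Each frame is registered against the average of the first
    ``n_reference_frames`` frames; the correlation peak is refined to
    sub-pixel precision. Subtract the returned offsets from detection
    coordinates to undo the drift. Warns when the correlation peak is weak
    (featureless frames).
    """
    if video.n_frames < 2:
        raise ValueError("need at least 2 frames")
    ref = video.frames[:n_reference_frames].mean(axis=0)
    offsets = np.zeros((video.n_frames, 2))
    weak = 0
    for f in range(video.n_frames):
        shift, error, _ = phase_cross_correlation(
            ref, video.frames[f].astype(float), upsample_factor=upsample,
            normalization=None)
        # skimage returns (row, col) displacement of frame relative to ref
        offsets[f] = (-shift[1] * video.pixel_size, -shift[0] * video.pixel_size)
        if error > 0.99:
            weak += 1
    if weak:
        warnings.warn(f"weak correlation peak in {weak} frames; "
                      "drift estimates may be unreliable", RuntimeWarning,
                      stacklevel=2)
    return offsets


def remove_immobile(
    trajectories: Sequence[Trajectory],
    radius_threshold: float = 0.066,
    min_duration: int = 50,
) -> tuple[list[Trajectory], list[Trajectory]]:
    """Split off long-lived stuck objects.

    A track is removed when its rms spread about its mean position stays
    below ``radius_threshold`` (default 2x the 2D localization noise floor of
    2 * sigma_loc = 33 nm) over its entire record AND it lasts at least
    ``min_duration`` frames. Returns (kept, removed).
    """
    kept, removed = [], []
    for traj in trajectories:
        if len(traj) >= min_duration and traj.spread_rms() < radius_threshold:
            removed.append(traj)
        else:
            kept.append(traj)
    return kept, removed


def intensity_projections(video: VideoStack) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel mean and standard-deviation projections.

    The SD projection uses the population convention (ddof=0). Moving
    fluorophores light up in the SD projection (their pixels blink), which
    reveals structures such as a reticulated ER network; static structure
    cancels out.
    """
    if video.n_frames < 2:
        raise ValueError("need at least 2 frames")
    stack = video.frames.astype(float)
    return stack.mean(axis=0), stack.std(axis=0, ddof=0)
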