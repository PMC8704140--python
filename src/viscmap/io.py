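"""File formats: multi-page TIFF video stacks, trajectory CSV tables, run
configuration and fixture generation.

Trajectory tables are CSV with a commented metadata header::

    # viscmap trajectory table
    # frame_interval_s = 0.0303
    # field_width_um = 30.0
    track_id,frame,time_s,x_um,y_um
    0,0,0.0,1.234,5.678

Coordinates are stored in micrometres (never pixels) so downstream stages do
not depend on the camera geometry; the time column is derived from the frame
index and the header's frame interval.
"""
from __future__ import annotations

import ast
import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .simulate import CameraModel, SimConfig, VideoStack
from .tracking import LinkConfig
from .tracks import Trajectory

__all__ = [
    "TrackTableError",
    "read_video",
    "write_video",
    "read_tracks",
    "write_tracks",
    "RunConfig",
    "load_config",
    "make_fixtures",
]


class TrackTableError(ValueError):
    """Raised when a trajectory table violates its invariants."""


# ---------------------------------------------------------------------------
# video


def write_video(path, video: VideoStack) -> None:
    """Write a video stack as a multi-page grayscale TIFF.

    Pixel size and frame interval are stored as JSON in the TIFF description
    tag so the stack round-trips without an external config.
    """
    meta = {"pixel_size_um": video.pixel_size,
            "frame_interval_s": video.frame_interval,
            "n_frames": int(video.n_frames)}
    tifffile.imwrite(path, video.frames, photometric="minisblack",
                     description=json.dumps(meta))


def read_video(path, pixel_size: Optional[float] = None,
               frame_interval: Optional[float] = None) -> VideoStack:
    """Read an 8- or 16-bit grayscale multi-page TIFF.

    Metadata (pixel size, frame interval) is taken from the TIFF description
    written by :func:`write_video`; for third-party files pass
    ``pixel_size``/``frame_interval`` explicitly.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tf:
            pages = tf.pages
            frames = []
            for i in range(len(pages)):
                try:
                    frames.append(pages[i].asarray())
                except Exception as exc:
                    raise IOError(
                        f"{path.name}: failed reading frame {i} "
                        f"({len(frames)} frames read; file truncated or "
                        f"corrupt): {exc}") from exc
            desc = pages[0].description if len(pages) else ""
    except tifffile.TiffFileError as exc:
        raise IOError(f"{path.name}: not a readable TIFF: {exc}") from exc
    if not frames:
        raise IOError(f"{path.name}: no frames")
    stack = np.stack(frames)
    if stack.ndim != 3:
        raise IOError(f"{path.name}: expected grayscale pages, got shape "
                      f"{stack.shape} (RGB/multichannel is unsupported)")
    if stack.dtype == np.uint8:
        stack = stack.astype(np.uint16)  # promote without value change
    elif stack.dtype not in (np.uint16, np.dtype(">u2")):
        raise IOError(f"{path.name}: unsupported dtype {stack.dtype}; "
                      "expected 8- or 16-bit grayscale")
    meta = {}
    try:
        meta = json.loads(desc) if desc else {}
    except json.JSONDecodeError:
        meta = {}
    declared = meta.get("n_frames")
    if declared is not None and len(frames) < int(declared):
        raise IOError(
            f"{path.name}: truncated stack: only {len(frames)} of "
            f"{declared} declared frames could be read")
    pixel_size = pixel_size or meta.get("pixel_size_um")
    frame_interval = frame_interval or meta.get("frame_interval_s")
    if pixel_size is None or frame_interval is None:
        raise IOError(f"{path.name}: pixel size / frame interval not found in "
                      "TIFF metadata; pass them explicitly")
    return VideoStack(stack, float(pixel_size), float(frame_interval))


# ---------------------------------------------------------------------------
# trajectory tables


def write_tracks(path, trajectories: Sequence[Trajectory],
                 frame_interval: float,
                 metadata: Optional[dict] = None) -> None:
    """Write trajectories as a CSV table with a commented metadata header."""
    rows = []
    for t in trajectories:
        for f, (x, y) in zip(t.frames, t.xy):
            rows.append((t.track_id, int(f), float(f) * frame_interval,
                         float(x), float(y)))
    df = pd.DataFrame(rows, columns=["track_id", "frame", "time_s",
                                     "x_um", "y_um"])
    header = ["# viscmap trajectory table",
              f"# frame_interval_s = {frame_interval!r}"]
    for k, v in (metadata or {}).items():
        header.append(f"# {k} = {v!r}")
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        df.to_csv(fh, index=False)  # default float repr round-trips exactly


def read_tracks(path) -> tuple[list[Trajectory], dict]:
    """Read a trajectory CSV table; validates and returns (tracks, metadata).

    Raises :class:`TrackTableError` naming the offending row / track on
    duplicate (track_id, frame) pairs, frame gaps inside a track, or
    non-finite coordinates.
    """
    path = Path(path)
    meta: dict = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                k, _, v = body.partition("=")
                try:
                    meta[k.strip()] = ast.literal_eval(v.strip())
                except (ValueError, SyntaxError):
                    meta[k.strip()] = v.strip()
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    required = {"track_id", "frame", "x_um", "y_um"}
    if not required.issubset(df.columns):
        raise TrackTableError(
            f"{path.name}: missing columns {sorted(required - set(df.columns))}")
    dup = df.duplicated(subset=["track_id", "frame"])
    if dup.any():
        row = df[dup].iloc[0]
        raise TrackTableError(
            f"{path.name}: duplicate (track_id, frame) = "
            f"({int(row.track_id)}, {int(row.frame)}) at csv row "
            f"{int(dup.idxmax()) + 2}")
    if not np.all(np.isfinite(df[["x_um", "y_um"]].to_numpy())):
        bad = df.index[~np.isfinite(df[["x_um", "y_um"]]).all(axis=1)][0]
        raise TrackTableError(f"{path.name}: non-finite coordinate at csv row "
                              f"{int(bad) + 2}")
    trajectories = []
    for tid, g in df.sort_values(["track_id", "frame"]).groupby("track_id"):
        frames = g["frame"].to_numpy()
        if len(frames) > 1 and np.any(np.diff(frames) != 1):
            raise TrackTableError(
                f"{path.name}: frame gap inside track_id {int(tid)}")
        trajectories.append(Trajectory(int(tid), frames,
                                       g[["x_um", "y_um"]].to_numpy(),
                                       source="detected"))
    return trajectories, meta


# ---------------------------------------------------------------------------
# run configuration


@dataclass(frozen=True)
class SegmentationOptions:
    window: int = 10
    n_fit_lags: int = 4


@dataclass(frozen=True)
class QuadratOptions:
    cell_side: float = 2.0
    min_trajectories: int = 5
    count: str = "segments"


@dataclass(frozen=True)
class StatsOptions:
    alpha: float = 0.05
    ks_variant: str = "fitted"


@dataclass(frozen=True)
class RunConfig:
    """Validated nested configuration for the command-line pipeline."""

    sim: SimConfig = field(default_factory=SimConfig)
    camera: CameraModel = field(default_factory=CameraModel)
    tracking: LinkConfig = field(default_factory=LinkConfig)
    segmentation: SegmentationOptions = field(default_factory=SegmentationOptions)
    quadrat: QuadratOptions = field(default_factory=QuadratOptions)
    stats: StatsOptions = field(default_factory=StatsOptions)
    seed: int = 0
    scenario: str = "homogeneous"   # homogeneous | two_region
    output_dir: str = "viscmap_out"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_SECTIONS = {"sim": SimConfig, "camera": CameraModel, "tracking": LinkConfig,
             "segmentation": SegmentationOptions, "quadrat": QuadratOptions,
             "stats": StatsOptions}
_SCALARS = {"seed", "scenario", "output_dir"}


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    unknown = set(raw) - set(_SECTIONS) - _SCALARS
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        section = raw.get(name, {})
        if not isinstance(section, dict):
            raise ValueError(f"{path}: section '{name}' must be a mapping")
        valid = {f.name for f in dataclasses.fields(cls)}
        bad = set(section) - valid
        if bad:
            raise ValueError(
                f"{path}: unknown keys {sorted(bad)} in section '{name}'")
        # convert lists from yaml to tuples where the dataclass expects them
        clean = {k: tuple(v) if isinstance(v, list) else v
                 for k, v in section.items()}
        kwargs[name] = cls(**clean)
    for key in _SCALARS:
        if key in raw:
            kwargs[key] = raw[key]
    cfg = RunConfig(**kwargs)
    if cfg.scenario not in ("homogeneous", "two_region"):
        raise ValueError(f"{path}: scenario must be 'homogeneous' or "
                         f"'two_region', got {cfg.scenario!r}")
    return cfg


# ---------------------------------------------------------------------------
# fixtures


def make_fixtures(seed: int, outdir) -> dict[str, Path]:
    """Generate the small bundled test inputs (all seed-deterministic).

    * ``toy_track.csv`` — a 5-point hand-checkable track.
    * ``static_spot.tif`` — one immobile rendered fluorophore (noise floor).
    * ``two_spot_overlap.tif`` — two spots crossing paths (overlap
      truncation: tracks terminate at the merge, restart after separation).
    * ``mini_homogeneous.csv`` / ``mini_two_region.csv`` — the canonical
      scenarios at reduced field size (12 x 12 um, 400 frames).
    """
    from . import simulate as sim

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    dt = sim.DEFAULT_FRAME_INTERVAL

    toy = Trajectory(0, np.arange(5),
                     np.array([[0.0, 0.0], [0.1, 0.0], [0.1, 0.1],
                               [0.2, 0.1], [0.2, 0.2]]))
    paths["toy_track"] = outdir / "toy_track.csv"
    write_tracks(paths["toy_track"], [toy], dt)

    cam = sim.default_camera()
    cfg = sim.SimConfig(field_width=3.0, field_height=3.0, n_frames=40,
                        D_free=0.0, bleach_rate=0.0, initial_density=0.0,
                        rng_seed=seed)
    static = sim.GroundTruthTrack(0, 0, np.tile([1.5, 1.5], (40, 1)))
    video = sim.render_video([static], cam, cfg,
                             rng=np.random.default_rng(seed))
    paths["static_spot"] = outdir / "static_spot.tif"
    write_video(paths["static_spot"], video)

    # two bright spots crossing paths: they merge into one unresolved
    # detection mid-video and separate again, exercising the
    # overlap-truncation rule of the linker
    cfg2 = sim.SimConfig(field_width=4.0, field_height=4.0, n_frames=60,
                         D_free=0.0, bleach_rate=0.0, initial_density=0.0,
                         rng_seed=seed)
    bright = sim.CameraModel(photons_per_frame=1500)
    t = np.arange(60)
    a = sim.GroundTruthTrack(0, 0, np.column_stack(
        [0.8 + 2.0 * t / 59.0, np.full(60, 2.0)]))
    b = sim.GroundTruthTrack(1, 0, np.column_stack(
        [3.2 - 2.0 * t / 59.0, np.full(60, 2.0)]))
    video2 = sim.render_video([a, b], bright, cfg2,
                              rng=np.random.default_rng(seed + 1))
    paths["two_spot_overlap"] = outdir / "two_spot_overlap.tif"
    write_video(paths["two_spot_overlap"], video2)

    mini = dict(field_width=12.0, field_height=12.0, n_frames=400)
    for name, factory in (("mini_homogeneous", sim.homogeneous_scenario),
                          ("mini_two_region", sim.two_region_scenario)):
        scen = factory(seed=seed, **mini)
        trajs = scen.observe()
        paths[name] = outdir / f"{name}.csv"
        write_tracks(paths[name], trajs, scen.config.frame_interval,
                     metadata={"field_width_um": scen.config.field_width,
                               "field_height_um": scen.config.field_height,
                               "scenario": name})
    return paths
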