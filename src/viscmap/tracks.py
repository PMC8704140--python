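"""Trajectory container shared by the simulator, the tracker and the analysis layer.

Coordinates are continuous positions in micrometres with the origin at the
lower-left corner of the imaged field; pixel (i, j) of a raster has its centre
at ((j + 0.5) * pixel_size, (i + 0.5) * pixel_size).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Trajectory"]


@dataclass
class Trajectory:
    """One observed single-molecule track.

    Parameters
    ----------
    track_id : int
        Identifier; for simulated data this is the ground-truth molecule id.
    frames : ndarray of int, shape (n,)
        Frame indices, consecutive (gap of exactly 1). Tracks are split at
        every interruption, so gaps are never closed.
    xy : ndarray, shape (n, 2)
        Positions in micrometres.
    source : str
        ``"simulated"`` or ``"detected"``.
    """

    track_id: int
    frames: np.ndarray
    xy: np.ndarray
    source: str = "simulated"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.xy = np.asarray(self.xy, dtype=float)
        if self.frames.ndim != 1 or self.xy.shape != (self.frames.size, 2):
            raise ValueError("frames must be (n,) and xy (n, 2)")
        if self.frames.size == 0:
            raise ValueError("empty trajectory")
        if self.frames.size > 1 and np.any(np.diff(self.frames) != 1):
            raise ValueError(
                f"track {self.track_id}: frames must be consecutive"
            )
        if not np.all(np.isfinite(self.xy)):
            raise ValueError(f"track {self.track_id}: non-finite coordinates")

    def __len__(self) -> int:
        return int(self.frames.size)

    @property
    def start_frame(self) -> int:
        return int(self.frames[0])

    @property
    def end_frame(self) -> int:
        return int(self.frames[-1])

    def max_step(self) -> float:
        """Largest frame-to-frame displacement (um)."""
        if len(self) < 2:
            return 0.0
        return float(np.max(np.linalg.norm(np.diff(self.xy, axis=0), axis=1)))

    def spread_rms(self) -> float:
        """RMS radial spread about the track's mean position (um)."""
        d = self.xy - self.xy.mean(axis=0)
        return float(np.sqrt(np.mean((d ** 2).sum(axis=1))))
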