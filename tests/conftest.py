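import numpy as np
import pytest

from viscmap import simulate as sim
from viscmap.tracks import Trajectory


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def static_spot_video():
    """400 frames of one immobile rendered fluorophore (noise-floor probe)."""
    cam = sim.default_camera()
    cfg = sim.SimConfig(field_width=3.0, field_height=3.0, n_frames=400,
                        D_free=0.0, bleach_rate=0.0, initial_density=0.0,
                        rng_seed=0)
    track = sim.GroundTruthTrack(0, 0, np.tile([1.53, 1.47], (400, 1)))
    video = sim.render_video([track], cam, cfg,
                             rng=np.random.default_rng(0))
    return video, np.array([1.53, 1.47])


def brownian_trajectory(rng, n_points, D, dt, start=(0.0, 0.0),
                        track_id=0, loc_sigma=0.0):
    """Unbounded free-diffusion track (test helper, no reflection)."""
    steps = rng.normal(0.0, np.sqrt(2 * D * dt), (n_points - 1, 2))
    xy = np.vstack([start, start + np.cumsum(steps, axis=0)])
    if loc_sigma > 0:
        xy = xy + rng.normal(0.0, loc_sigma, xy.shape)
    return Trajectory(track_id, np.arange(n_points), xy)
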