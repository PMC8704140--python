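"""Monte Carlo simulator: raft placement, diffusion statistics, bleaching,
observation noise and determinism."""
import numpy as np
import pytest
import scipy.stats as sps

from viscmap import simulate as sim


class TestPlaceRafts:
    def test_zero_count_gives_empty_layout(self, rng):
        layout = sim.place_rafts((0, 0, 10, 10), 0.3, 0, rng)
        assert len(layout) == 0

    def test_hundred_rafts_pairwise_disjoint_and_inside(self, rng):
        layout = sim.place_rafts((0, 0, 15, 30), 0.3, 100, rng)
        assert len(layout) == 100
        assert layout.overlap_pairs() == []
        r = layout.rafts
        assert np.all(r[:, 0] >= 0) and np.all(r[:, 0] + r[:, 2] <= 15)
        assert np.all(r[:, 1] >= 0) and np.all(r[:, 1] + r[:, 2] <= 30)

    def test_raft_spanning_region_width(self, rng):
        layout = sim.place_rafts((0, 0, 1.0, 5.0), 1.0, 1, rng)
        assert len(layout) == 1
        assert layout.rafts[0, 2] == 1.0

    def test_too_dense_precondition(self, rng):
        with pytest.raises(ValueError, match="70%"):
            sim.place_rafts((0, 0, 1, 1), 0.3, 9, rng)

    def test_bounded_attempts_error(self, rng):
        with pytest.raises(RuntimeError, match="attempts"):
            sim.place_rafts((0, 0, 2, 2), 0.45, 13, rng, max_attempts=30)


class TestSimulateTracks:
    def test_frozen_dynamics(self):
        cfg = sim.SimConfig(field_width=5, field_height=5, n_frames=50,
                            D_free=0.0, bleach_rate=0.0, initial_density=1.0,
                            rng_seed=1)
        tracks = sim.simulate_tracks(cfg)
        assert tracks
        for t in tracks:
            assert t.n_frames == 50
            assert np.all(t.positions == t.positions[0])

    def test_exponential_survival_at_5s(self):
        # bleach 0.2/s, no influx: ~ e^-1 of molecules still visible at t=5 s
        cfg = sim.SimConfig(field_width=60, field_height=60, n_frames=200,
                            frame_interval=0.05, D_free=0.1, bleach_rate=0.2,
                            initial_density=1.0, rng_seed=2)
        tracks = sim.simulate_tracks(cfg)
        n0 = len(tracks)
        frame_5s = int(5.0 / cfg.frame_interval)
        alive = sum(t.bleach_frame >= frame_5s for t in tracks)
        p = np.exp(-1.0)
        se = np.sqrt(p * (1 - p) / n0)
        assert abs(alive / n0 - p) < 4 * se

    def test_single_frame_msd_matches_4_D_dt(self):
        cfg = sim.SimConfig(field_width=200, field_height=200, n_frames=60,
                            D_free=0.2, bleach_rate=0.0, initial_density=0.05,
                            rng_seed=3)
        tracks = sim.simulate_tracks(cfg)
        sq = np.concatenate([
            ((t.positions[1:] - t.positions[:-1]) ** 2).sum(axis=1)
            for t in tracks])
        expected = 4 * 0.2 * cfg.frame_interval
        se = sq.std() / np.sqrt(sq.size)
        assert sq.size > 1e5
        assert abs(sq.mean() - expected) < 3 * se

    def test_per_axis_step_variance(self):
        cfg = sim.SimConfig(field_width=300, field_height=300, n_frames=40,
                            D_free=0.3, bleach_rate=0.0, initial_density=0.05,
                            rng_seed=4)
        tracks = sim.simulate_tracks(cfg)
        steps = np.concatenate([np.diff(t.positions, axis=0) for t in tracks])
        assert steps.shape[0] * 2 >= 1e5
        var = 2 * 0.3 * cfg.frame_interval
        for ax in (0, 1):
            v = steps[:, ax].var()
            se = var * np.sqrt(2 / steps.shape[0])
            assert abs(v - var) < 3 * se

    def test_confined_molecules_never_leave_their_raft(self):
        scen = sim.two_region_scenario(seed=5, field_width=10, field_height=10,
                                       n_frames=300)
        assert scen.layout is not None and len(scen.layout)
        for t in scen.ground_truth:
            if t.raft_id is None:
                continue
            rx, ry, side = scen.layout.rafts[t.raft_id]
            assert np.all(t.positions[:, 0] >= rx - 1e-12)
            assert np.all(t.positions[:, 0] <= rx + side + 1e-12)
            assert np.all(t.positions[:, 1] >= ry - 1e-12)
            assert np.all(t.positions[:, 1] <= ry + side + 1e-12)

    def test_free_molecules_respect_field_boundaries(self):
        cfg = sim.SimConfig(field_width=2, field_height=2, n_frames=400,
                            D_free=0.5, bleach_rate=0.0, initial_density=5.0,
                            rng_seed=6)
        for t in sim.simulate_tracks(cfg):
            assert np.all(t.positions >= 0) and np.all(t.positions <= 2)

    def test_lifetimes_are_exponential(self):
        # long video so end-truncation is negligible
        cfg = sim.SimConfig(field_width=50, field_height=50, n_frames=4000,
                            D_free=0.0, bleach_rate=0.2, initial_density=0.8,
                            rng_seed=7)
        tracks = sim.simulate_tracks(cfg)
        assert len(tracks) >= 1e3
        lifetimes = np.array([t.n_frames for t in tracks]) * cfg.frame_interval
        res = sps.kstest(lifetimes, "expon", args=(0, 1 / 0.2))
        assert res.pvalue > 0.01

    def test_influx_adds_molecules_over_time(self):
        cfg = sim.SimConfig(field_width=10, field_height=10, n_frames=100,
                            bleach_rate=0.2, initial_density=0.5,
                            influx_rate=sim.balanced_influx_rate(
                                sim.SimConfig(initial_density=0.5)),
                            rng_seed=8)
        tracks = sim.simulate_tracks(cfg)
        assert any(t.birth_frame > 0 for t in tracks)

    def test_same_seed_bit_identical(self):
        a = sim.two_region_scenario(seed=9, field_width=8, field_height=8,
                                    n_frames=100)
        b = sim.two_region_scenario(seed=9, field_width=8, field_height=8,
                                    n_frames=100)
        assert len(a.ground_truth) == len(b.ground_truth)
        for ta, tb in zip(a.ground_truth, b.ground_truth):
            assert ta.birth_frame == tb.birth_frame
            assert np.array_equal(ta.positions, tb.positions)


class TestObserveTracks:
    def test_zero_noise_is_identity(self, rng):
        cfg = sim.SimConfig(field_width=5, field_height=5, n_frames=30,
                            initial_density=1.0, rng_seed=10)
        tracks = sim.simulate_tracks(cfg)
        trajs = sim.observe_tracks(tracks, 0.0, rng)
        for gt, tr in zip(tracks, trajs):
            assert np.array_equal(tr.xy, gt.positions)
            assert tr.start_frame == gt.birth_frame

    def test_static_track_noise_floor(self, rng):
        # sigma = 16.5 nm/coordinate -> apparent MSD 4 sigma^2 ~ 1.1e-3 um^2
        # at every lag, and 2D frame-to-frame rms deviation 2 sigma ~ 33 nm
        sigma = 0.0165
        n = 20000
        gt = [sim.GroundTruthTrack(0, 0, np.tile([1.0, 1.0], (n, 1)))]
        (traj,) = sim.observe_tracks(gt, sigma, rng)
        from viscmap.msd import compute_msd
        curve = compute_msd(traj, 1 / 33, max_lag=5)
        expected = 4 * sigma ** 2
        for lag_idx in range(5):
            # var of squared-noise mean: each term ~ sum of 4 squared normals
            se = expected * np.sqrt(2.0) / np.sqrt(curve.n_pairs[lag_idx])
            assert abs(curve.msd[lag_idx] - expected) < 4 * se
        step_rms = np.sqrt(np.mean(
            ((traj.xy[1:] - traj.xy[:-1]) ** 2).sum(axis=1)))
        assert abs(step_rms - 2 * sigma) < 0.002  # ~33 nm

    def test_negative_sigma_rejected(self, rng):
        with pytest.raises(ValueError):
            sim.observe_tracks([], -0.1, rng)


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        dict(frame_interval=0.0), dict(n_frames=1), dict(D_free=-1),
        dict(bleach_rate=-0.1), dict(field_width=0), dict(substeps=0),
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            sim.SimConfig(**kwargs)

    def test_balanced_influx(self):
        cfg = sim.SimConfig(initial_density=0.8, bleach_rate=0.2)
        assert sim.balanced_influx_rate(cfg) == pytest.approx(0.16)


def test_motion_blur_mode_reduces_apparent_msd():
    # full-exposure averaging of k substeps lowers the single-lag MSD by
    # about a factor (1 - 1/(3k))... relative to instantaneous sampling
    dt = 1 / 33
    base = sim.SimConfig(field_width=100, field_height=100, n_frames=40,
                         D_free=0.3, bleach_rate=0.0, initial_density=0.05,
                         rng_seed=11)
    blur = sim.SimConfig(field_width=100, field_height=100, n_frames=40,
                         D_free=0.3, bleach_rate=0.0, initial_density=0.05,
                         substeps=8, rng_seed=11)
    def msd1(cfg):
        tracks = sim.simulate_tracks(cfg)
        sq = np.concatenate([
            ((t.positions[1:] - t.positions[:-1]) ** 2).sum(axis=1)
            for t in tracks])
        return sq.mean()
    m_inst, m_blur = msd1(base), msd1(blur)
    assert m_blur < m_inst
    # theoretical blurred MSD at lag 1: 4 D dt (1 - 1/(3k)) + corrections;
    # just require the reduction to be in the right ballpark (<= ~1/3)
    assert m_blur > 0.6 * m_inst
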