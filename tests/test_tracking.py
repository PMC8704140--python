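"""Spot detection, trajectory linking, drift correction, immobile filtering
and projections."""
import numpy as np
import pytest

from viscmap import simulate as sim
from viscmap import tracking as trk
from viscmap.simulate import VideoStack
from viscmap.tracking import LinkConfig, SpotDetection

from conftest import brownian_trajectory

DT = 1 / 33


def det(frame, x, y):
    return SpotDetection(frame, x, y, 100.0, 0.13, 0.0, 1.0)


class TestDetectSpots:
    def test_blank_frames_at_5_sigma_nearly_clean(self):
        cfg = sim.SimConfig(field_width=5, field_height=5, n_frames=100,
                            D_free=0, bleach_rate=0, initial_density=0,
                            rng_seed=3)
        video = sim.render_video([], sim.default_camera(), cfg,
                                 rng=np.random.default_rng(3))
        dets = trk.detect_stack(video, LinkConfig(threshold_k=5.0))
        assert sum(len(f) for f in dets) < 10  # < 1 false positive / 10 frames

    def test_noise_free_symmetric_spot_is_exact(self):
        # Gaussian exactly centred on a pixel centre, no noise: the fit must
        # return that centre to numerical tolerance
        px = 0.1
        yy, xx = np.mgrid[0:41, 0:41].astype(float)
        img = 50 + 800 * np.exp(-((xx - 20) ** 2 + (yy - 20) ** 2)
                                / (2 * 1.3 ** 2))
        (d,) = trk.detect_spots(img, px)
        assert d.x == pytest.approx((20 + 0.5) * px, abs=1e-6)
        assert d.y == pytest.approx((20 + 0.5) * px, abs=1e-6)
        assert d.sigma == pytest.approx(0.13, rel=1e-3)

    def test_high_snr_subpixel_accuracy(self):
        # rendered bright spot at a known off-centre position: mean
        # localization error well under 0.1 pixel
        cam = sim.CameraModel(photons_per_frame=2000)
        cfg = sim.SimConfig(field_width=3, field_height=3, n_frames=50,
                            D_free=0, bleach_rate=0, initial_density=0,
                            rng_seed=4)
        truth = np.array([1.532, 1.478])
        track = sim.GroundTruthTrack(0, 0, np.tile(truth, (50, 1)))
        video = sim.render_video([track], cam, cfg,
                                 rng=np.random.default_rng(4))
        dets = [d for f in trk.detect_stack(video) for d in f
                if np.hypot(d.x - truth[0], d.y - truth[1]) < 0.3]
        err = np.array([[d.x - truth[0], d.y - truth[1]] for d in dets])
        assert len(err) >= 45
        assert np.sqrt((err ** 2).sum(axis=1)).mean() < 0.1 * cam.pixel_size

    def test_empty_frame_rejected(self):
        with pytest.raises(ValueError):
            trk.detect_spots(np.empty((0, 0)), 0.1)


class TestNoiseFloorCalibration:
    def test_static_spot_scatter_matches_noise_floor(self, static_spot_video):
        # default camera: ~16 nm rms per coordinate (33 nm 2D frame-to-frame
        # rms, apparent MSD ~ 1e-3 um^2)
        video, truth = static_spot_video
        dets = [d for f in trk.detect_stack(video) for d in f
                if np.hypot(d.x - truth[0], d.y - truth[1]) < 0.2]
        pts = np.array([[d.x, d.y] for d in dets])
        assert len(pts) > 350
        for ax in (0, 1):
            assert 0.010 < pts[:, ax].std() < 0.024

    def test_quadrupled_photons_halve_the_scatter(self):
        # in the signal-dominated regime localization error scales ~ 1/sqrt(N)
        def scatter(photons, seed):
            cam = sim.CameraModel(photons_per_frame=photons)
            cfg = sim.SimConfig(field_width=3, field_height=3, n_frames=250,
                                D_free=0, bleach_rate=0, initial_density=0,
                                rng_seed=seed)
            track = sim.GroundTruthTrack(0, 0, np.tile([1.53, 1.47], (250, 1)))
            video = sim.render_video([track], cam, cfg,
                                     rng=np.random.default_rng(seed))
            pts = np.array([[d.x, d.y] for f in trk.detect_stack(video)
                            for d in f
                            if np.hypot(d.x - 1.53, d.y - 1.47) < 0.2])
            return np.sqrt(pts[:, 0].var() + pts[:, 1].var())
        ratio = scatter(1000, 5) / scatter(4000, 6)
        assert ratio == pytest.approx(2.0, rel=0.2)


class TestLinkTracks:
    def test_single_slow_molecule_one_track(self):
        frames = [[det(f, 1.0 + 0.01 * f, 1.0)] for f in range(30)]
        res = trk.link_tracks(frames)
        assert len(res.trajectories) == 1
        assert len(res.trajectories[0]) == 30

    def test_two_close_spots_terminate_on_first_conflict(self):
        # two static detections 0.2 um apart: both tracks see two candidates
        # within the gate -> ambiguity -> termination at the first linking
        # step; no track ever reaches the 10-frame analysis threshold
        frames = [[det(f, 1.0, 1.0), det(f, 1.2, 1.0)] for f in range(30)]
        res = trk.link_tracks(frames)
        assert res.trajectories == []
        assert res.stats["terminated_conflict"] >= 2
        assert all(len(t) <= 2 for t in res.raw_trajectories)

    def test_gap_terminates_track(self):
        frames = [[det(0, 1.0, 1.0)], [], [det(2, 1.0, 1.0)]]
        res = trk.link_tracks(frames)
        assert len(res.raw_trajectories) == 2

    def test_gate_is_never_exceeded(self, rng):
        frames = []
        for f in range(50):
            frames.append([det(f, *rng.uniform(0, 5, 2)) for _ in range(10)])
        res = trk.link_tracks(frames)
        for t in res.raw_trajectories:
            assert t.max_step() <= 0.7 + 1e-9

    def test_each_detection_used_at_most_once(self, rng):
        frames = [[det(f, *rng.uniform(0, 3, 2)) for _ in range(6)]
                  for f in range(40)]
        res = trk.link_tracks(frames)
        for f in range(40):
            pts = []
            for t in res.raw_trajectories:
                idx = np.nonzero(t.frames == f)[0]
                for i in idx:
                    pts.append(tuple(t.xy[i]))
            assert len(pts) == len(set(pts))

    def test_identity_audit_on_simulated_field(self):
        # idealized detections from ground truth at 0.8 /um^2, D = 0.2:
        # fraction of linked points attached to the wrong molecule < 5%
        cfg = sim.SimConfig(field_width=12, field_height=12, n_frames=400,
                            D_free=0.2, bleach_rate=0.2, initial_density=0.8,
                            rng_seed=11)
        tracks = sim.simulate_tracks(cfg)
        rng = np.random.default_rng(11)
        frames = [[] for _ in range(cfg.n_frames)]
        truth = [dict() for _ in range(cfg.n_frames)]
        for t in tracks:
            for k, f in enumerate(range(t.birth_frame, t.bleach_frame + 1)):
                x, y = t.positions[k] + rng.normal(0, 0.0165, 2)
                frames[f].append(det(f, x, y))
                truth[f][(round(x, 9), round(y, 9))] = t.molecule_id
        res = trk.link_tracks(frames)
        total = wrong = 0
        for traj in res.trajectories:
            ids = [truth[f][(round(x, 9), round(y, 9))]
                   for f, (x, y) in zip(traj.frames, traj.xy)]
            majority = max(set(ids), key=ids.count)
            wrong += sum(i != majority for i in ids)
            total += len(ids)
        assert total > 1000
        assert wrong / total < 0.05


class TestDriftAndFilters:
    def test_identical_frames_zero_drift(self, rng):
        frame = rng.uniform(100, 200, (32, 32))
        video = VideoStack(np.stack([frame] * 5), 0.1, DT)
        offsets = trk.correct_drift(video)
        assert np.allclose(offsets, 0.0)

    def test_integer_pixel_shift_recovered_exactly(self, rng):
        frame = rng.uniform(100, 500, (40, 40))
        shifted = np.roll(frame, 2, axis=1)  # +2 px in x
        video = VideoStack(np.stack([frame, shifted]), 0.1, DT)
        offsets = trk.correct_drift(video, n_reference_frames=1)
        assert offsets[1, 0] == pytest.approx(0.2, abs=1e-6)
        assert offsets[1, 1] == pytest.approx(0.0, abs=1e-6)

    def test_linear_drift_on_rendered_video(self):
        # 0.3 px/frame drift injected into a rendered multi-spot video
        cam = sim.CameraModel(photons_per_frame=1500)
        cfg = sim.SimConfig(field_width=8, field_height=8, n_frames=20,
                            D_free=0, bleach_rate=0, initial_density=0,
                            rng_seed=12)
        rng = np.random.default_rng(12)
        spots = rng.uniform(1, 7, (25, 2))
        drift_per_frame = np.array([0.03, 0.0])  # um = 0.3 px
        tracks = [sim.GroundTruthTrack(
            i, 0, s + np.outer(np.arange(20), drift_per_frame))
            for i, s in enumerate(spots)]
        video = sim.render_video(tracks, cam, cfg,
                                 rng=np.random.default_rng(12))
        offsets = trk.correct_drift(video)
        expected = np.outer(np.arange(20), drift_per_frame)
        err = offsets - expected
        err -= err.mean(axis=0)  # reference frame sets the arbitrary origin
        rms_px = np.sqrt((err ** 2).sum(axis=1).mean()) / 0.1
        assert rms_px < 0.5

    def test_remove_immobile(self, rng):
        stuck = brownian_trajectory(rng, 200, 0.0, DT, loc_sigma=0.016,
                                    track_id=0)
        moving = brownian_trajectory(rng, 200, 0.1, DT, loc_sigma=0.016,
                                     track_id=1)
        short_static = brownian_trajectory(rng, 20, 0.0, DT, loc_sigma=0.016,
                                           track_id=2)
        kept, removed = trk.remove_immobile([stuck, moving, short_static])
        assert [t.track_id for t in removed] == [0]
        assert {t.track_id for t in kept} == {1, 2}
        assert trk.remove_immobile([]) == ([], [])


class TestProjections:
    def test_constant_video_zero_sd(self):
        video = VideoStack(np.full((6, 8, 8), 7.0), 0.1, DT)
        mean, sd = trk.intensity_projections(video)
        assert np.all(mean == 7.0)
        assert np.all(sd == 0.0)

    def test_two_frame_closed_form(self):
        video = VideoStack(np.stack([np.zeros((4, 4)), np.full((4, 4), 2.0)]),
                           0.1, DT)
        mean, sd = trk.intensity_projections(video)
        assert np.all(mean == 1.0)
        assert np.all(sd == 1.0)  # population convention (ddof=0)

    def test_moving_spot_stands_out_vs_static(self):
        # a static spot only raises the SD projection by shot noise (~sqrt of
        # its signal) while a pixel visited intermittently by a moving spot
        # gains on/off variance proportional to the signal itself
        cam = sim.CameraModel(photons_per_frame=1000)
        cfg = sim.SimConfig(field_width=4, field_height=4, n_frames=60,
                            D_free=0, bleach_rate=0, initial_density=0,
                            rng_seed=13)
        static = sim.GroundTruthTrack(0, 0, np.tile([2.0, 2.0], (60, 1)))
        path = np.tile([[1.8, 2.0], [2.6, 2.0]], (30, 1))
        moving = sim.GroundTruthTrack(0, 0, path)
        sd_static = trk.intensity_projections(
            sim.render_video([static], cam, cfg,
                             rng=np.random.default_rng(1)))[1]
        sd_moving = trk.intensity_projections(
            sim.render_video([moving], cam, cfg,
                             rng=np.random.default_rng(1)))[1]
        assert sd_moving.max() > 2 * sd_static.max()
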