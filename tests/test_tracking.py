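"""Spot detection, overlap linking, MSD estimation and trajectory filters."""

import numpy as np
import pytest

from latkit.core import ImageStack
from latkit.synthdata import MembraneSimConfig, simulate_membrane_movie
from latkit.tracking import (
    Detection,
    Trajectory,
    detect_assemblies,
    diffusion_coefficient,
    filter_and_extend,
    link_trajectories,
)


def gaussian_spot_frame(size, cx, cy, amp, sigma=1.5, background=0.0):
    yy, xx = np.mgrid[0:size, 0:size]
    return background + amp * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2)
                                     / (2 * sigma**2))


def cell_frame(size=96, cell_value=40.0, baseline=5.0):
    yy, xx = np.mgrid[0:size, 0:size]
    cell = (xx - size / 2) ** 2 + (yy - size / 2) ** 2 <= (0.4 * size) ** 2
    return np.where(cell, cell_value, baseline).astype(float)


class TestDetect:
    def test_uniform_image_no_detections(self):
        stack = ImageStack(np.full((2, 64, 64), 50.0), 0.1, 0.2)
        dets = detect_assemblies(stack)
        assert all(len(d) == 0 for d in dets)

    def test_single_spot_detected_within_one_pixel(self):
        frame = cell_frame()
        frame += gaussian_spot_frame(96, 40.3, 52.7, amp=400.0)  # 10x membrane
        stack = ImageStack(frame[None], 0.1, 0.2)
        dets = detect_assemblies(stack)[0]
        assert len(dets) == 1
        assert abs(dets[0].x - 40.3) < 1.0 and abs(dets[0].y - 52.7) < 1.0

    def test_two_separated_spots_both_detected(self):
        frame = cell_frame()
        frame += gaussian_spot_frame(96, 35, 48, amp=200.0)
        frame += gaussian_spot_frame(96, 55, 48, amp=200.0)
        stack = ImageStack(frame[None], 0.1, 0.2)
        dets = detect_assemblies(stack)[0]
        assert len(dets) == 2

    def test_raising_intensity_ratio_never_adds_detections(self):
        cfg = MembraneSimConfig(
            n_molecules=15, frac_confined=0.0, d_free=0.0, field_size=96,
            n_frames=2, photons_per_molecule=1500.0, membrane_photons=30.0,
            min_separation=0.7, seed=3)
        stack, _ = simulate_membrane_movie(cfg)
        counts = []
        for ratio in (1.5, 2.0, 3.0, 5.0):
            dets = detect_assemblies(stack, intensity_ratio=ratio)
            counts.append(len(dets[0]))
        assert counts == sorted(counts, reverse=True)


def _static_detections(n_frames, x=10.0, y=10.0, start=0):
    return [Detection(frame=start + t, x=x, y=y, mean_intensity=100.0,
                      total_intensity=2800.0) for t in range(n_frames)]


class TestLink:
    def test_stationary_spot_single_trajectory(self):
        dets = [[d] for d in _static_detections(10)]
        trajs = link_trajectories(dets)
        assert len(trajs) == 1 and len(trajs[0]) == 10

    def test_large_jumps_not_linked(self):
        dets = [[Detection(t, 10.0 + 5 * t, 10.0, 1.0, 1.0)] for t in range(5)]
        trajs = link_trajectories(dets)
        assert trajs == []

    def test_no_gap_closing_splits_trajectory(self):
        dets = []
        for t in range(11):
            if t == 5:
                dets.append([])
            else:
                dets.append([Detection(t, 10.0, 10.0, 1.0, 1.0)])
        trajs = link_trajectories(dets)
        assert len(trajs) == 2
        assert [len(t) for t in sorted(trajs, key=lambda t: t.origin_frame)] == [5, 5]

    def test_each_detection_used_once(self):
        rng = np.random.default_rng(0)
        dets = []
        for t in range(20):
            frame = [Detection(t, x, y, 1.0, 1.0)
                     for x, y in rng.uniform(5, 60, (6, 2))]
            dets.append(frame)
        trajs = link_trajectories(dets)
        seen = set()
        for tr in trajs:
            for d in tr.detections:
                key = (d.frame, d.x, d.y)
                assert key not in seen
                seen.add(key)
            frames = tr.frames
            assert np.all(np.diff(frames) == 1)


class TestDiffusion:
    def test_stationary_trajectory_zero_d(self):
        traj = Trajectory(0, _static_detections(30))
        assert diffusion_coefficient(traj, 0.1, 0.2) == 0.0

    def test_too_short_trajectory_excluded(self):
        traj = Trajectory(0, _static_detections(3))
        assert diffusion_coefficient(traj, 0.1, 0.2, max_lag=4) is None

    def test_brownian_tracks_recover_d(self):
        cfg = MembraneSimConfig(n_molecules=100, frac_confined=0.0, d_free=0.1,
                                field_size=256, pixel_size=0.1,
                                frame_interval=0.2, n_frames=300,
                                photons_per_molecule=0.0, seed=11)
        _, gt = simulate_membrane_movie(cfg)
        ests = []
        for m in range(100):
            pos_px = gt.positions_um[:, m, :] / cfg.pixel_size
            dets = [Detection(t, p[0], p[1], 1.0, 1.0)
                    for t, p in enumerate(pos_px)]
            ests.append(diffusion_coefficient(Trajectory(m, dets), 0.1, 0.2))
        assert abs(np.median(ests) - 0.1) / 0.1 < 0.20


class TestFilterAndExtend:
    def _movie(self):
        data = np.tile(cell_frame(64, 40.0, 5.0), (80, 1, 1))
        return ImageStack(data, 0.1, 0.2)

    def _traj(self, origin, length, d=0.01):
        tr = Trajectory(0, _static_detections(length, x=32.0, y=32.0,
                                              start=origin))
        tr.diffusion_coefficient = d
        return tr

    def test_back_extension_limited_by_movie_start(self):
        stack = self._movie()
        kept = filter_and_extend([self._traj(5, 30)], stack)
        assert len(kept) == 1
        assert kept[0].intensity_trace.back_extended_frames == 5

    def test_back_extension_full_twenty_frames(self):
        stack = self._movie()
        kept = filter_and_extend([self._traj(25, 30)], stack)
        assert kept[0].intensity_trace.back_extended_frames == 20
        # pre-frames sample the (flat) membrane at the spot position
        assert np.allclose(kept[0].intensity_trace.values[:20], 40.0)

    def test_short_trajectory_removed(self):
        kept = filter_and_extend([self._traj(5, 29)], self._movie())
        assert kept == []

    def test_frame_zero_trajectory_removed(self):
        kept = filter_and_extend([self._traj(0, 40)], self._movie())
        assert kept == []

    def test_mobile_trajectory_removed(self):
        kept = filter_and_extend([self._traj(5, 40, d=0.08)], self._movie())
        assert kept == []
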