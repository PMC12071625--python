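"""Photobleaching calibration and staircase fitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from latkit.core import ImageStack, IntensityTrace
from latkit.stepfit import (
    CalibrationError,
    FluorophoreCalibration,
    UnfittableTraceError,
    assembly_kinetics,
    best_k_changepoints,
    calibrate,
    fit_steps,
    identify_single_fluorophores,
    segment_changepoints,
)
from latkit.synthdata import AssemblyTraceConfig, simulate_assembly_trace

CAL111 = FluorophoreCalibration(111.0, 0.0, 10)


def bleach_movie(bleach_frames, amp=111.0, noise=0.0, size=64, n_frames=100,
                 seed=0):
    """Sparse immobilized emitters on a grid, each bleaching at its own frame."""
    rng = np.random.default_rng(seed)
    n = len(bleach_frames)
    cols = int(np.ceil(np.sqrt(n)))
    spacing = size // (cols + 1)
    yy, xx = np.mgrid[0:size, 0:size]
    data = np.zeros((n_frames, size, size))
    coords = []
    for i, bf in enumerate(bleach_frames):
        cx = spacing * (1 + i % cols)
        cy = spacing * (1 + i // cols)
        coords.append((cx, cy))
        psf = np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * 1.5**2))
        # disc-mean of this PSF over a 6-px disc ~ amp requires peak scaling
        scale = amp / psf[(xx - cx) ** 2 + (yy - cy) ** 2 <= 9].mean()
        data[:bf] += scale * psf
    if noise > 0:
        data += rng.normal(0, noise, data.shape)
    return ImageStack(data + 5.0, 0.1, 0.2), coords


class TestIdentify:
    def test_single_bleacher_recovered(self):
        stack, _ = bleach_movie([50], noise=1.0)
        traces = identify_single_fluorophores(stack)
        assert len(traces) == 1
        x = traces[0].values
        assert x[:40].mean() > x[60:].mean() + 50

    def test_blinker_rejected(self):
        stack, coords = bleach_movie([100], noise=1.0)
        data = stack.data.copy()
        data[40:70] = 5.0  # off for 30 frames, then back on: not single-step
        stack2 = ImageStack(data, 0.1, 0.2)
        assert identify_single_fluorophores(stack2) == []

    def test_ensemble_mostly_recovered(self):
        rng = np.random.default_rng(3)
        bleach = 10 + rng.geometric(0.02, 20).clip(max=85)
        stack, _ = bleach_movie(list(bleach), amp=111.0, noise=111.0 / 8,
                                n_frames=100, size=96, seed=3)
        traces = identify_single_fluorophores(stack)
        assert len(traces) >= 18


class TestCalibrate:
    def test_single_noiseless_trace(self):
        trace = IntensityTrace(np.r_[np.full(50, 111.0), np.zeros(50)], 0.2)
        cal = calibrate([trace])
        assert cal.mean_intensity == pytest.approx(111.0)
        assert cal.sd_intensity == 0.0

    def test_two_traces_mean_and_sd(self):
        tr1 = IntensityTrace(np.r_[np.full(40, 100.0), np.zeros(40)], 0.2)
        tr2 = IntensityTrace(np.r_[np.full(40, 120.0), np.zeros(40)], 0.2)
        cal = calibrate([tr1, tr2])
        assert cal.mean_intensity == pytest.approx(110.0)
        assert cal.sd_intensity == pytest.approx(np.std([100, 120], ddof=1))

    def test_empty_input_signals_unavailable(self):
        with pytest.raises(CalibrationError):
            calibrate([])

    def test_simulated_ensemble_recovers_generating_mean(self):
        rng = np.random.default_rng(8)
        traces, amps = [], []
        for _ in range(200):
            amp = max(rng.normal(111.0, 40.0), 1.0)
            amps.append(amp)
            bf = int(rng.integers(20, 80))
            x = np.r_[np.full(bf, amp), np.zeros(100 - bf)]
            traces.append(IntensityTrace(x + rng.normal(0, 5.0, 100), 0.2))
        cal = calibrate(traces)
        # estimator recovers the drawn ensemble almost exactly ...
        assert abs(cal.mean_intensity - np.mean(amps)) / np.mean(amps) < 0.02
        # ... and the generating mean to within 5% plus sampling error
        se = 40.0 / np.sqrt(200)
        assert abs(cal.mean_intensity - 111.0) < 0.05 * 111.0 + 3 * se
        assert cal.sd_intensity == pytest.approx(40.0, rel=0.25)


class TestChangepoints:
    def test_optimal_partitioning_finds_exact_steps(self):
        x = np.r_[np.zeros(20), np.full(15, 5.0), np.full(25, 3.0)]
        assert segment_changepoints(x, penalty=1.0) == [20, 35]

    def test_best_k_matches_bruteforce_single_step(self):
        x = np.r_[np.zeros(10), np.ones(7)]
        cps, sse = best_k_changepoints(x, 1)
        assert cps == [10] and sse == pytest.approx(0.0)


class TestFitSteps:
    def test_noiseless_two_steps(self):
        res = fit_steps(IntensityTrace([0, 0, 111, 111, 222, 222], 0.2), CAL111)
        assert res.step_times == [(2, 1), (4, 1)]
        assert list(res.count_trace) == [0, 0, 1, 1, 2, 2]
        assert res.step_size == pytest.approx(111.0)

    def test_missing_step_counted_as_two(self):
        res = fit_steps(IntensityTrace([0, 0, 0, 222, 222, 222], 0.2), CAL111)
        assert res.step_times == [(3, 2)]

    def test_levels_on_lattice(self):
        cfg = AssemblyTraceConfig(arrival_rate=0.2, departure_rate=0.05,
                                  noise_sd=15.0, n_frames=200, seed=5)
        trace, _ = simulate_assembly_trace(cfg)
        res = fit_steps(trace, FluorophoreCalibration(111.0, 40.0, 100))
        k = (res.fitted_levels - res.baseline) / res.step_size
        assert np.allclose(k, np.round(k))
        assert np.all(res.count_trace >= 0)

    def test_idempotent_on_fitted_staircase(self):
        cfg = AssemblyTraceConfig(arrival_rate=0.2, noise_sd=20.0, n_frames=150,
                                  seed=6)
        trace, _ = simulate_assembly_trace(cfg)
        calib = FluorophoreCalibration(111.0, 40.0, 100)
        res = fit_steps(trace, calib)
        again = fit_steps(IntensityTrace(res.fitted_levels, 0.2),
                          FluorophoreCalibration(res.step_size, 0.0, 1))
        assert np.allclose(again.fitted_levels, res.fitted_levels)
        assert again.residual_sse == pytest.approx(0.0, abs=1e-6)

    def test_short_trace_unfittable(self):
        with pytest.raises(UnfittableTraceError):
            fit_steps(IntensityTrace([0, 111, 111], 0.2), CAL111)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.lists(st.integers(min_value=0, max_value=4), min_size=2,
                    max_size=6))
    def test_noiseless_staircases_recovered_exactly(self, counts):
        levels = np.repeat(np.array(counts, dtype=float) * 111.0, 10)
        res = fit_steps(IntensityTrace(levels, 0.2), CAL111)
        assert np.allclose(res.fitted_levels, levels)


class TestKinetics:
    def test_joins_leaves_max(self):
        cfg = AssemblyTraceConfig(arrival_rate=0.4, departure_rate=0.2,
                                  single_intensity_sd=0.0, noise_sd=0.0,
                                  n_frames=120, seed=9)
        trace, gt = simulate_assembly_trace(cfg)
        res = fit_steps(trace, CAL111)
        d = np.diff(gt.staircase)
        assert res.joins == d[d > 0].sum()
        assert res.leaves == -d[d < 0].sum()
        summary = assembly_kinetics([res])
        assert summary["max_count"][0] == gt.staircase.max()

    def test_mean_joins_matches_arrival_rate(self):
        # birth-only ensemble: joins within 2 SE of arrival_rate x duration
        joins, expected = [], None
        for seed in range(60):
            cfg = AssemblyTraceConfig(arrival_rate=0.15, departure_rate=0.0,
                                      noise_sd=20.0, n_frames=250,
                                      brightness_mode="per_trace", seed=seed)
            trace, gt = simulate_assembly_trace(cfg)
            res = fit_steps(trace, FluorophoreCalibration(111.0, 40.0, 100))
            joins.append(res.joins)
            expected = cfg.arrival_rate * cfg.frame_interval * cfg.n_frames
        se = np.std(joins, ddof=1) / np.sqrt(len(joins))
        assert abs(np.mean(joins) - expected) < 2 * se + 0.5

    def test_empty_results_rejected(self):
        with pytest.raises(ValueError):
            assembly_kinetics([])
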