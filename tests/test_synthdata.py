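"""Ground-truth generators: determinism, conservation and calibration."""

import numpy as np
import pytest

from latkit.synthdata import (
    AssemblyTraceConfig,
    MembraneSimConfig,
    PointPatternConfig,
    simulate_assembly_trace,
    simulate_membrane_movie,
    simulate_paired_traces,
    simulate_point_pattern,
)


class TestMembraneMovie:
    def test_zero_diffusion_noise_off_frames_identical(self):
        cfg = MembraneSimConfig(n_molecules=10, frac_confined=0.5, d_free=0.0,
                                d_confined=0.0, field_size=32, n_frames=6,
                                shot_noise=False, read_noise_sd=0.0, seed=1)
        stack, gt = simulate_membrane_movie(cfg)
        assert np.array_equal(stack.data[0], stack.data[-1])
        assert np.all(gt.positions_um[0] == gt.positions_um[-1])

    def test_fixed_seed_bitwise_identical(self):
        cfg = MembraneSimConfig(n_molecules=20, field_size=32, n_frames=8, seed=5)
        a, _ = simulate_membrane_movie(cfg)
        b, _ = simulate_membrane_movie(cfg)
        assert a == b

    def test_free_population_msd_matches_d(self):
        # ensemble MSD slope/4 over lags 1-4 within 10% of the configured D
        cfg = MembraneSimConfig(n_molecules=500, frac_confined=0.0, d_free=0.2,
                                field_size=64, n_frames=40,
                                photons_per_molecule=0.0, seed=2)
        _, gt = simulate_membrane_movie(cfg)
        pos = gt.positions_um
        lags = np.arange(1, 5)
        msd = [np.mean(np.sum((pos[l:] - pos[:-l]) ** 2, axis=-1)) for l in lags]
        slope = np.polyfit(lags * cfg.frame_interval, msd, 1)[0]
        assert abs(slope / 4 - 0.2) / 0.2 < 0.10

    def test_confined_msd_plateaus_below_domain_size(self):
        cfg = MembraneSimConfig(n_molecules=300, frac_confined=1.0, d_free=0.0,
                                d_confined=0.05, domain_diameter=0.4,
                                trap_strength=1.0, field_size=64, n_frames=120,
                                photons_per_molecule=0.0, seed=3)
        _, gt = simulate_membrane_movie(cfg)
        pos = gt.positions_um
        msd_late = np.mean(np.sum((pos[100:] - pos[0]) ** 2, axis=-1))
        assert msd_late < cfg.domain_diameter**2

    def test_bleached_molecules_emit_nothing(self):
        cfg = MembraneSimConfig(n_molecules=5, frac_confined=0.0, d_free=0.0,
                                field_size=32, n_frames=50, bleach_rate=2.0,
                                frame_interval=0.1, shot_noise=False,
                                read_noise_sd=0.0, baseline=0.0, seed=4)
        stack, gt = simulate_membrane_movie(cfg)
        assert np.all(gt.bleach_frame < 50)  # rate 2/s for 5 s: all bleach
        assert stack.data[-1].max() == 0.0

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            MembraneSimConfig(frac_confined=1.5)
        with pytest.raises(ValueError):
            MembraneSimConfig(n_frames=1)

    def test_unresolvable_confinement_warns_not_raises(self, caplog):
        cfg = MembraneSimConfig(n_molecules=2, frac_confined=1.0,
                                d_confined=1.0, domain_diameter=0.05,
                                field_size=32, n_frames=3,
                                photons_per_molecule=0.0, seed=1)
        with caplog.at_level("WARNING", logger="latkit.synthdata"):
            simulate_membrane_movie(cfg)
        assert any("unresolvable" in r.message for r in caplog.records)


class TestAssemblyTrace:
    def test_no_arrivals_flat_noise_only(self):
        cfg = AssemblyTraceConfig(arrival_rate=0.0, noise_sd=5.0, n_frames=50,
                                  seed=1)
        trace, gt = simulate_assembly_trace(cfg)
        assert np.all(gt.staircase == 0)
        assert abs(trace.values.mean()) < 5.0

    def test_noiseless_trace_equals_staircase_times_unit(self):
        cfg = AssemblyTraceConfig(arrival_rate=0.3, departure_rate=0.05,
                                  single_intensity_mean=111.0,
                                  single_intensity_sd=0.0, noise_sd=0.0,
                                  n_frames=100, seed=2)
        trace, gt = simulate_assembly_trace(cfg)
        assert np.allclose(trace.values, 111.0 * gt.staircase)

    def test_step_increments_average_near_111(self):
        # sample mean of per-molecule intensities within 5% of the mCherry mean
        intensities = []
        for seed in range(60):
            cfg = AssemblyTraceConfig(arrival_rate=0.5, n_frames=150, seed=seed)
            _, gt = simulate_assembly_trace(cfg)
            intensities.extend(gt.molecule_intensities)
        assert abs(np.mean(intensities) - 111.0) / 111.0 < 0.05

    def test_departures_shrink_staircase(self):
        cfg = AssemblyTraceConfig(arrival_rate=1.0, departure_rate=0.5,
                                  n_frames=200, seed=3)
        _, gt = simulate_assembly_trace(cfg)
        diffs = np.diff(gt.staircase)
        assert (diffs < 0).any()
        assert gt.staircase.min() >= 0


class TestPointPattern:
    def test_empty_when_densities_zero(self):
        cfg = PointPatternConfig(cluster_density=0.0, background_density=0.0,
                                 seed=1)
        table, _ = simulate_point_pattern(cfg)
        assert len(table) == 0

    def test_full_coloc_shares_channel_a_centers(self):
        cfg = PointPatternConfig(coloc_fraction=1.0, background_density=0.0,
                                 cluster_density=1.0, seed=2)
        _, gt = simulate_point_pattern(cfg)
        centers_a = np.array(gt.extras["centers_a"])
        centers_b = np.array(gt.extras["centers_b"])
        shared = min(len(centers_a), len(centers_b))
        # every shared B center must be one of A's
        for c in centers_b[:shared]:
            assert np.min(np.linalg.norm(centers_a - c, axis=1)) == 0.0

    def test_molecule_count_matches_expectation(self):
        cfg = PointPatternConfig(roi_size=4000, cluster_density=2.0,
                                 molecules_per_cluster_mean=30.0,
                                 background_density=20.0, seed=3)
        _, gt = simulate_point_pattern(cfg)
        area = (cfg.roi_size / 1000) ** 2
        expect = area * (cfg.cluster_density * cfg.molecules_per_cluster_mean
                         + cfg.background_density)
        # compound-Poisson (Neyman-Scott) variance: A*(lc*(m + m^2) + bg)
        var = area * (cfg.cluster_density
                      * (cfg.molecules_per_cluster_mean
                         + cfg.molecules_per_cluster_mean**2)
                      + cfg.background_density)
        n = (gt.molecule_channels == "A").sum()
        assert abs(n - expect) < 3 * np.sqrt(var)

    def test_blinking_conserves_molecules(self):
        cfg = PointPatternConfig(blink_duplication_rate=1.5, seed=4)
        table, gt = simulate_point_pattern(cfg)
        assert len(table) == len(gt.molecule_ids)
        assert len(np.unique(gt.molecule_ids)) == len(gt.molecule_positions_nm)


class TestPairedTraces:
    def test_zero_delay_zero_noise_identical(self):
        t1, t2, _ = simulate_paired_traces(0, 80, 0.0, 1)
        assert np.array_equal(t1.values, t2.values)

    def test_delay_shifts_trace_exactly(self):
        t1, t2, _ = simulate_paired_traces(5, 100, 0.0, 1)
        assert np.allclose(t2.values[5:], t1.values[:-5])

    def test_deterministic(self):
        a = simulate_paired_traces(3, 60, 0.2, 9)
        b = simulate_paired_traces(3, 60, 0.2, 9)
        assert np.array_equal(a[0].values, b[0].values)
        assert np.array_equal(a[1].values, b[1].values)

    def test_delta_too_large_rejected(self):
        with pytest.raises(ValueError):
            simulate_paired_traces(60, 100, 0.0, 1)
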