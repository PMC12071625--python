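"""Ground-truth validation measurements for every analysis stage.

Each function simulates data with :mod:`latkit.synthdata`, runs the
corresponding analysis and measures recovery against the known ground
truth.  They are consumed by the acceptance test suite and by
``scripts/acceptance.py``; all randomness derives from the ``seed``
argument.
"""

from __future__ import annotations

import numpy as np

from latkit import clustering, doc as doc_mod, kics, tccf, tracking
from latkit.core import ImageStack
from latkit.stepfit import FluorophoreCalibration, fit_steps
from latkit.synthdata import (
    AssemblyTraceConfig,
    MembraneSimConfig,
    PointPatternConfig,
    simulate_assembly_trace,
    simulate_membrane_movie,
    simulate_point_pattern,
    simulate_paired_traces,
)


def tracking_recovery(seed: int, n_assemblies: int = 25,
                      n_frames: int = 300) -> dict:
    """Fraction of immobile ground-truth assemblies recovered as single
    full-length trajectories, and their RMS position error (pixels)."""
    cfg = MembraneSimConfig(
        n_molecules=n_assemblies, frac_confined=0.0, d_free=0.0,
        d_confined=0.0, field_size=96, frame_interval=0.2, n_frames=n_frames,
        photons_per_molecule=3000.0, membrane_photons=30.0, baseline=10.0,
        read_noise_sd=2.0, min_separation=0.8, seed=seed)
    stack, gt = simulate_membrane_movie(cfg)
    dets = tracking.detect_assemblies(stack)
    trajs = tracking.link_trajectories(dets)
    true_px = gt.positions_um[0] / cfg.pixel_size  # immobile: frame-0 truth
    recovered = 0
    sq_errors: list[float] = []
    for m in range(n_assemblies):
        best = None
        for tr in trajs:
            pos = tr.positions
            err = np.linalg.norm(pos - true_px[m], axis=1)
            if err.mean() < 2.0 and (best is None or len(tr) > len(best[0])):
                best = (tr, err)
        if best is not None and len(best[0]) == n_frames:
            recovered += 1
            sq_errors.extend(best[1] ** 2)
    rms = float(np.sqrt(np.mean(sq_errors))) if sq_errors else float("inf")
    return {"recovery_percent": 100.0 * recovered / n_assemblies,
            "rms_error_px": rms, "n_trajectories": len(trajs)}


def diffusion_recovery(seed: int, d_true: float = 0.1, n_tracks: int = 100,
                       n_frames: int = 300) -> dict:
    """Median MSD-estimated D over simulated Brownian tracks."""
    cfg = MembraneSimConfig(
        n_molecules=n_tracks, frac_confined=0.0, d_free=d_true,
        field_size=256, pixel_size=0.1, frame_interval=0.2, n_frames=n_frames,
        photons_per_molecule=0.0, seed=seed)
    _, gt = simulate_membrane_movie(cfg)
    ests = []
    for m in range(n_tracks):
        pos_px = gt.positions_um[:, m, :] / cfg.pixel_size
        dets = [tracking.Detection(t, p[0], p[1], 0.0, 0.0)
                for t, p in enumerate(pos_px)]
        ests.append(tracking.diffusion_coefficient(
            tracking.Trajectory(m, dets), cfg.pixel_size, cfg.frame_interval))
    return {"d_true": d_true, "d_median": float(np.median(ests))}


def stepfit_recovery(seed: int, n_traces: int = 100, max_steps: int = 10) -> dict:
    """Exact step-count recovery and fitted step size on synthetic staircases.

    Each trace is an equal-step staircase whose per-trace unit is drawn
    from the mCherry calibration N(111, 40), with additive noise SD 20.
    """
    calib = FluorophoreCalibration(111.0, 40.0, 200)
    exact = 0
    sizes = []
    produced = 0
    trial = 0
    while produced < n_traces:
        cfg = AssemblyTraceConfig(
            arrival_rate=0.1, departure_rate=0.0, noise_sd=20.0, n_frames=300,
            brightness_mode="per_trace", seed=seed * 10_000 + trial)
        trial += 1
        trace, gt = simulate_assembly_trace(cfg)
        d = np.diff(gt.staircase)
        joins_true = int(d[d > 0].sum())
        if joins_true == 0 or joins_true > max_steps:
            continue
        produced += 1
        res = fit_steps(trace, calib)
        sizes.append(res.step_size)
        if res.joins == joins_true and res.leaves == 0:
            exact += 1
    return {"exact_count_percent": 100.0 * exact / n_traces,
            "mean_step_size": float(np.mean(sizes))}


def _kics_analyze(stack: ImageStack, max_tau: int = 20) -> kics.KicsResult:
    cf = kics.compute_kics_cf(stack, max_tau=max_tau, n_k_bins=150,
                              subtract_temporal_mean=False)
    return kics.extract_parameters(kics.fit_decays(cf), stack.frame_interval)


def kics_recovery(seed: int, frac_confined: float = 0.5, d_free: float = 0.2,
                  d_confined: float = 0.01, domain_diameter: float = 0.4,
                  n_frames: int = 3000) -> dict:
    """Two-population kICS parameter recovery with vesicle-immunity check."""
    cfg = MembraneSimConfig(
        n_molecules=200, frac_confined=frac_confined, d_free=d_free,
        d_confined=d_confined, domain_diameter=domain_diameter,
        trap_strength=1.0, field_size=64, frame_interval=0.03,
        n_frames=n_frames, photons_per_molecule=300.0, seed=seed)
    stack, _ = simulate_membrane_movie(cfg)
    res = _kics_analyze(stack)
    # vesicle proxy: spatially uniform, time-varying offset
    rng = np.random.default_rng(seed + 1)
    offset = rng.uniform(0, 30, stack.n_frames)[:, None, None]
    shifted = ImageStack(stack.data + offset, stack.pixel_size,
                         stack.frame_interval)
    res_off = _kics_analyze(shifted)
    true_ratio = (1 - frac_confined) / frac_confined
    return {
        "d_free": res.d_free, "d_free_true": d_free,
        "d_confined": res.d_confined, "d_confined_true": d_confined,
        "amp_ratio": res.amp_ratio_free_over_confined,
        "amp_ratio_true": true_ratio,
        "confinement_length_um": res.confinement_length,
        "d_free_offset_percent_change":
            100.0 * abs(res_off.d_free - res.d_free) / max(res.d_free, 1e-12),
    }


def kics_confinement_sweep(seed: int, domain_diameters=(0.2, 0.4, 0.8),
                           n_frames: int = 3000) -> dict:
    """Extracted confinement length across generating domain diameters."""
    lengths = []
    for i, dom in enumerate(domain_diameters):
        cfg = MembraneSimConfig(
            n_molecules=200, frac_confined=0.5, d_free=0.2, d_confined=0.01,
            domain_diameter=dom, trap_strength=1.0, field_size=64,
            frame_interval=0.03, n_frames=n_frames,
            photons_per_molecule=300.0, seed=seed + 100 * i)
        stack, _ = simulate_membrane_movie(cfg)
        lengths.append(_kics_analyze(stack).confinement_length)
    return {"domain_diameters_um": list(domain_diameters),
            "confinement_lengths_um": lengths,
            "monotone": bool(np.all(np.diff(lengths) > 0))}


def dbscan_oracle_check(seed: int, n_fixtures: int = 50,
                        max_points: int = 2000) -> dict:
    """Agreement of the DBSCAN implementation with an O(n²) oracle."""
    import pandas as pd

    from latkit.synthdata import LOC_COLUMNS

    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_fixtures):
        n_clusters = int(rng.integers(1, 8))
        blobs = [rng.normal(rng.uniform(0, 1500, 2), rng.uniform(5, 30),
                            (int(rng.integers(5, 80)), 2))
                 for _ in range(n_clusters)]
        blobs.append(rng.uniform(0, 1500, (int(rng.integers(50, 400)), 2)))
        pts = np.vstack(blobs)[:max_points]
        mols = pd.DataFrame(
            [(0, x, y, 1.0, 20.0, "A") for x, y in pts], columns=LOC_COLUMNS)
        got = clustering.dbscan(mols).labels
        want = _bruteforce_dbscan(pts)
        agree += int(np.array_equal(got, want))
    return {"n_fixtures": n_fixtures, "n_agreeing": agree,
            "agreement_percent": 100.0 * agree / n_fixtures}


def _bruteforce_dbscan(points, min_neighbors=3, radius=20.0,
                       min_cluster_size=10):
    n = len(points)
    d2 = ((points[:, None, :] - points[None, :, :]) ** 2).sum(-1)
    within = d2 <= radius**2
    core = within.sum(1) - 1 >= min_neighbors
    labels = np.full(n, -1)
    nxt = 0
    for i in range(n):
        if not core[i] or labels[i] >= 0:
            continue
        stack = [i]
        labels[i] = nxt
        while stack:
            j = stack.pop()
            for k in np.where(within[j] & core)[0]:
                if labels[k] < 0:
                    labels[k] = nxt
                    stack.append(k)
        nxt += 1
    for i in range(n):
        if not core[i] and labels[i] < 0:
            nb = np.where(within[i] & core)[0]
            nb = nb[nb != i]
            if len(nb):
                labels[i] = labels[nb.min()]
    out = np.full(n, -1)
    remap: dict[int, int] = {}
    sizes = {c: int((labels == c).sum()) for c in set(labels) if c >= 0}
    for i in range(n):
        c = labels[i]
        if c >= 0 and sizes[c] >= min_cluster_size:
            out[i] = remap.setdefault(c, len(remap))
    return out


def merge_rule_check() -> dict:
    """The three constructed (distance, frame-gap) merging fixtures."""
    import pandas as pd

    from latkit.synthdata import LOC_COLUMNS

    fixtures = [
        ([(5, 0.0, 0.0, 1.0, 20.0, "A"), (30, 0.0, 0.0, 1.0, 20.0, "A")], 1),
        ([(5, 0.0, 0.0, 1.0, 20.0, "A"), (100, 0.0, 0.0, 1.0, 20.0, "A")], 2),
        ([(5, 0.0, 0.0, 1.0, 20.0, "A"), (6, 150.0, 0.0, 1.0, 20.0, "A")], 2),
    ]
    got = [len(clustering.merge_localizations(
        pd.DataFrame(rows, columns=LOC_COLUMNS))) for rows, _ in fixtures]
    want = [w for _, w in fixtures]
    return {"molecule_counts": got, "expected": want,
            "all_correct": got == want}


def doc_calibration(seed: int, n_csr: int = 5000, n_csr_seeds: int = 10,
                    roi: float = 4000.0) -> dict:
    """DoC on identical, independent-CSR and displaced-cluster channels."""
    import pandas as pd

    from latkit.synthdata import LOC_COLUMNS

    bounds = (0.0, 0.0, roi, roi)

    # identical clustered channels -> DoC exactly 1
    cfg = PointPatternConfig(roi_size=roi, cluster_density=2.0,
                             molecules_per_cluster_mean=30.0,
                             background_density=10.0, loc_precision_sd=0.0,
                             seed=seed)
    table, _ = simulate_point_pattern(cfg)
    a = table[table.channel == "A"].reset_index(drop=True)
    sc = doc_mod.doc_scores(a, a.copy(), bounds)
    identical_min = float(np.min(sc.doc[~sc.excluded]))

    # independent CSR channels -> mean ~ 0, few molecules above 0.4
    means, fracs = [], []
    rng = np.random.default_rng(seed + 1)
    for _ in range(n_csr_seeds):
        ch = []
        for chan in ("A", "B"):
            xy = rng.uniform(0, roi, (n_csr, 2))
            ch.append(pd.DataFrame(
                [(0, x, y, 1.0, 20.0, chan) for x, y in xy],
                columns=LOC_COLUMNS))
        sc = doc_mod.doc_scores(ch[0], ch[1], bounds)
        means.append(np.nanmean(sc.doc))
        fracs.append(np.nanmean(sc.doc >= 0.4))
    # displaced clusters -> segregation, median DoC < 0
    cfg = PointPatternConfig(roi_size=roi, cluster_density=2.0,
                             molecules_per_cluster_mean=30.0,
                             background_density=5.0, coloc_fraction=1.0,
                             loc_precision_sd=0.0, seed=seed + 2)
    table, _ = simulate_point_pattern(cfg)
    a = table[table.channel == "A"].reset_index(drop=True)
    b = table[table.channel == "B"].reset_index(drop=True).copy()
    b["x_nm"] = np.mod(b["x_nm"] + 600.0, roi)
    sc = doc_mod.doc_scores(a, b, bounds)
    return {
        "identical_min_doc": identical_min,
        "csr_mean_doc": float(np.mean(means)),
        "csr_percent_above_threshold": 100.0 * float(np.mean(fracs)),
        "displaced_median_doc": float(np.nanmedian(sc.doc)),
    }


def tccf_ordering(seed: int, n_pairs: int = 200, delta: int = 5,
                  noise_fraction: float = 0.2) -> dict:
    """Per-pair sign accuracy of sum ΔCC plus the exact symmetry checks."""
    # identical traces: exactly zero
    t1, t2, _ = simulate_paired_traces(0, 300, 0.0, seed)
    res0 = tccf.compute_tccf(tccf.PairedTrace(t1.values, t2.values), 60, 50)
    # antisymmetry on a noisy pair
    t1, t2, _ = simulate_paired_traces(delta, 300, noise_fraction, seed + 1)
    fwd = tccf.compute_tccf(tccf.PairedTrace(t1.values, t2.values), 60, 50)
    rev = tccf.compute_tccf(tccf.PairedTrace(t2.values, t1.values), 60, 50)
    antisym_err = float(np.max(np.abs(fwd.delta_cc + rev.delta_cc)))

    correct = 0
    sums = []
    for i in range(n_pairs):
        t1, t2, _ = simulate_paired_traces(delta, 300, noise_fraction,
                                           seed * 1000 + i)
        r = tccf.compute_tccf(tccf.PairedTrace(t1.values, t2.values), 60, 50,
                              smooth_frames=15)
        sums.append(r.sum_delta_cc)
        correct += int(r.sum_delta_cc > 0)
    return {
        "identical_sum_delta_cc": res0.sum_delta_cc,
        "antisymmetry_max_error": antisym_err,
        "sign_accuracy_percent": 100.0 * correct / n_pairs,
        "mean_sum_delta_cc": float(np.mean(sums)),
    }


def two_condition_study(seed: int, outdir) -> dict:
    """Activating-vs-resting direction check on the full synthetic pipeline."""
    from latkit.pipeline import RunConfig, run_two_condition_study

    base = RunConfig.from_dict({
        "seed": seed,
        "outdir": str(outdir),
        "membrane": {"n_frames": 1500,
                     "spt": {"n_frames": 120, "min_separation": 0.8}},
        "assembly": {"n_traces": 8},
        "paired": {"n_pairs": 8, "n_frames": 200},
        "kics": {"max_tau": 15, "n_k_bins": 150},
        "tccf": {"max_lag": 60, "n_sum_lags": 50},
    })
    report = run_two_condition_study(base, outdir)
    return report["orderings"] | {
        "activating_pct_in_clusters":
            report["activating"]["cluster"]["percent_in_cluster"],
        "resting_pct_in_clusters":
            report["resting"]["cluster"]["percent_in_cluster"],
        "activating_n_trajectories":
            report["activating"]["track"]["n_trajectories"],
        "resting_n_trajectories":
            report["resting"]["track"]["n_trajectories"],
        "activating_amp_ratio":
            report["activating"]["kics"]["amp_ratio_free_over_confined"],
        "resting_amp_ratio":
            report["resting"]["kics"]["amp_ratio_free_over_confined"],
    }
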