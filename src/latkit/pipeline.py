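"""End-to-end orchestration: configuration, stage execution and reporting.

A :class:`RunConfig` selects stages and carries per-stage parameters;
:func:`run_pipeline` executes them in dependency order
(simulate → track → stepfit | kics | cluster → doc | tccf) and writes a
self-describing run directory (resolved config + seed + summary).
:func:`run_two_condition_study` reproduces the resting-vs-activating
comparison on synthetic data.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from latkit import __version__, clustering, doc as doc_mod, io, kics, synthdata, tccf, tracking
from latkit.stepfit import FluorophoreCalibration, UnfittableTraceError, fit_steps

STAGES = ["simulate", "track", "stepfit", "kics", "cluster", "doc", "tccf"]

_ALLOWED_KEYS = {"stages", "seed", "condition", "outdir", "membrane", "assembly",
                 "point_pattern", "paired", "track", "stepfit", "kics",
                 "cluster", "doc", "tccf"}


class DependencyError(RuntimeError):
    """A stage was requested without its upstream output."""


@dataclass
class RunConfig:
    """Validated pipeline configuration; unknown keys are rejected."""

    stages: list[str] = field(default_factory=lambda: list(STAGES))
    seed: int = 0
    condition: str = "activating"
    outdir: str = "latkit_run"
    membrane: dict[str, Any] = field(default_factory=dict)
    assembly: dict[str, Any] = field(default_factory=dict)
    point_pattern: dict[str, Any] = field(default_factory=dict)
    paired: dict[str, Any] = field(default_factory=dict)
    track: dict[str, Any] = field(default_factory=dict)
    stepfit: dict[str, Any] = field(default_factory=dict)
    kics: dict[str, Any] = field(default_factory=dict)
    cluster: dict[str, Any] = field(default_factory=dict)
    doc: dict[str, Any] = field(default_factory=dict)
    tccf: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stages: {unknown}")
        if self.condition not in ("resting", "activating"):
            raise ValueError("condition must be 'resting' or 'activating'")

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        unknown = set(d) - _ALLOWED_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def _condition_defaults(condition: str) -> dict[str, dict[str, Any]]:
    """Generator parameter shifts that emulate TCR activation.

    Activation increases the number and stability of assemblies, the
    confined fraction of diffusing molecules and the degree of
    clustering; resting cells show the opposite.
    """
    if condition == "activating":
        return {
            "membrane": {"frac_confined": 0.7},
            "assembly_movie": {"n_molecules": 25},
            "point_pattern": {"cluster_density": 3.0,
                              "molecules_per_cluster_mean": 34.0,
                              "background_density": 15.0},
        }
    return {
        "membrane": {"frac_confined": 0.3},
        "assembly_movie": {"n_molecules": 5},
        "point_pattern": {"cluster_density": 1.0,
                          "molecules_per_cluster_mean": 12.0,
                          "background_density": 30.0},
    }


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the requested stages and write a self-describing run directory."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "resolved_config.yaml").write_text(
        yaml.safe_dump({"version": __version__, **config.to_dict()}))

    summary: dict[str, Any] = {"condition": config.condition, "seed": config.seed}
    defaults = _condition_defaults(config.condition)
    stages = set(config.stages)

    movie_path = outdir / "movie.tif"
    spt_movie_path = outdir / "spt_movie.tif"
    traces_path = outdir / "traces.csv"
    locs_path = outdir / "localizations.csv"
    pairs_path = outdir / "pairs.csv"

    if "simulate" in stages:
        # kICS movie: single-molecule two-population diffusion
        membrane_cfg = {k: v for k, v in config.membrane.items() if k != "spt"}
        mcfg = synthdata.MembraneSimConfig(
            seed=config.seed, **{**defaults["membrane"], **membrane_cfg})
        stack, gt = synthdata.simulate_membrane_movie(mcfg)
        io.write_imagestack(stack, movie_path)
        io.write_json(gt.to_json_dict() | {"kind": "membrane"},
                      outdir / "movie_ground_truth.json")

        # SPT movie: bright immobile assemblies on a fluorescent cell
        spt_kwargs = {
            "n_molecules": defaults["assembly_movie"]["n_molecules"],
            "frac_confined": 0.0, "d_free": 0.0, "d_confined": 0.0,
            "field_size": 96, "frame_interval": 0.2, "n_frames": 120,
            "photons_per_molecule": 3000.0, "membrane_photons": 30.0,
            "baseline": 10.0, "read_noise_sd": 2.0,
        }
        spt_kwargs.update(config.membrane.get("spt", {}))
        spt_cfg = synthdata.MembraneSimConfig(seed=config.seed + 1, **spt_kwargs)
        spt_stack, spt_gt = synthdata.simulate_membrane_movie(spt_cfg)
        io.write_imagestack(spt_stack, spt_movie_path)
        io.write_json(spt_gt.to_json_dict() | {"kind": "spt"},
                      outdir / "spt_ground_truth.json")

        # assembly traces
        traces = []
        n_traces = int(config.assembly.get("n_traces", 20))
        acfg_kwargs = {k: v for k, v in config.assembly.items() if k != "n_traces"}
        for i in range(n_traces):
            acfg = synthdata.AssemblyTraceConfig(seed=config.seed * 1000 + i,
                                                 **acfg_kwargs)
            tr, _ = synthdata.simulate_assembly_trace(acfg)
            tr.traj_id = i
            traces.append(tr)
        io.write_traces(traces, traces_path)

        # two-channel point pattern
        pcfg = synthdata.PointPatternConfig(
            seed=config.seed + 2,
            **{**defaults["point_pattern"], **config.point_pattern})
        table, pgt = synthdata.simulate_point_pattern(pcfg)
        io.write_localizations(table, locs_path)
        summary["point_pattern_roi_nm"] = pcfg.roi_size

        # paired traces
        n_pairs = int(config.paired.get("n_pairs", 30))
        delta = int(config.paired.get("delta_frames", 5))
        noise = float(config.paired.get("noise_sd", 0.1))
        pairs = []
        for i in range(n_pairs):
            t1, t2, _ = synthdata.simulate_paired_traces(
                delta, int(config.paired.get("n_frames", 200)), noise,
                seed=config.seed * 500 + i)
            pairs.append((t1.values, t2.values))
        io.write_pairs(pairs, pairs_path)
        summary["simulate"] = {"movie": str(movie_path),
                               "spt_movie": str(spt_movie_path),
                               "n_traces": n_traces, "n_pairs": n_pairs}

    if "track" in stages:
        if not spt_movie_path.exists():
            raise DependencyError("track requires the 'simulate' stage output "
                                  f"{spt_movie_path}")
        spt_stack = io.read_imagestack(spt_movie_path)
        dets = tracking.detect_assemblies(spt_stack, **config.track.get("detect", {}))
        trajs = tracking.link_trajectories(dets, **config.track.get("link", {}))
        for tr in trajs:
            tr.diffusion_coefficient = tracking.diffusion_coefficient(
                tr, spt_stack.pixel_size, spt_stack.frame_interval)
        kept = tracking.filter_and_extend(trajs, spt_stack,
                                          **config.track.get("filter", {}))
        io.write_traces([t.intensity_trace for t in kept],
                        outdir / "tracked_traces.csv")
        summary["track"] = {"n_trajectories": len(trajs),
                            "n_selected": len(kept)}

    if "stepfit" in stages:
        if not traces_path.exists():
            raise DependencyError(f"stepfit requires {traces_path} from 'simulate'")
        calib = FluorophoreCalibration(
            mean_intensity=float(config.stepfit.get("calib_mean", 111.0)),
            sd_intensity=float(config.stepfit.get("calib_sd", 40.0)),
            n_molecules=int(config.stepfit.get("calib_n", 1)))
        results, events = [], []
        for tr in io.read_traces(traces_path):
            try:
                res = fit_steps(tr, calib)
            except UnfittableTraceError:
                continue
            results.append(res)
            events.extend((res.traj_id, f, k) for f, k in res.step_times)
        import pandas as pd
        pd.DataFrame(events, columns=["traj_id", "frame", "delta_molecules"]
                     ).to_csv(outdir / "step_events.csv", index=False)
        summary["stepfit"] = {
            "n_traces_fit": len(results),
            "mean_joins": float(np.mean([r.joins for r in results])) if results else 0.0,
            "mean_step_size": float(np.mean([r.step_size for r in results])) if results else 0.0,
        }

    if "kics" in stages:
        if not movie_path.exists():
            raise DependencyError(f"kics requires {movie_path} from 'simulate'")
        stack = io.read_imagestack(movie_path)
        res = kics.analyze(stack, max_tau=int(config.kics.get("max_tau", 20)),
                           **{k: v for k, v in config.kics.items() if k != "max_tau"})
        summary["kics"] = {
            "d_free": res.d_free, "d_confined": res.d_confined,
            "amp_ratio_free_over_confined": res.amp_ratio_free_over_confined,
            "confinement_length": res.confinement_length,
        }
        io.write_json(summary["kics"], outdir / "kics_result.json")

    molecules_a = molecules_b = clusters = None
    if "cluster" in stages:
        if not locs_path.exists():
            raise DependencyError(f"cluster requires {locs_path} from 'simulate'")
        table = io.read_localizations(locs_path)
        roi_nm = float(summary.get("point_pattern_roi_nm",
                                   config.cluster.get("roi_nm", 4000.0)))
        roi_um2 = (roi_nm / 1000.0) ** 2
        molecules_a = clustering.merge_localizations(table[table.channel == "A"])
        molecules_b = clustering.merge_localizations(table[table.channel == "B"])
        clusters = clustering.dbscan(molecules_a,
                                     **{k: v for k, v in config.cluster.items()
                                        if k != "roi_nm"})
        stats = clustering.cluster_statistics(clusters, roi_um2)
        summary["cluster"] = stats
        io.write_json(stats, outdir / "cluster_stats.json")

    if "doc" in stages:
        if molecules_a is None or molecules_b is None or clusters is None:
            raise DependencyError("doc requires the 'cluster' stage")
        roi_nm = float(summary.get("point_pattern_roi_nm", 4000.0))
        scores = doc_mod.doc_scores(molecules_a, molecules_b,
                                    (0.0, 0.0, roi_nm, roi_nm),
                                    **config.doc.get("scores", {}))
        classification = doc_mod.classify_signaling(
            scores, clusters, (roi_nm / 1000.0) ** 2,
            **config.doc.get("classify", {}))
        n_sig_clusters = int((classification.cluster_class == "signaling").sum())
        summary["doc"] = {
            "n_signaling_clusters": n_sig_clusters,
            "n_clusters": len(classification.cluster_class),
            "n_signaling_molecules": classification.n_signaling_molecules,
            "percent_signaling_outside_clusters":
                classification.percent_signaling_outside_clusters,
            "mean_doc": float(np.nanmean(scores.doc)),
        }
        io.write_json(summary["doc"], outdir / "doc_result.json")

    if "tccf" in stages:
        if not pairs_path.exists():
            raise DependencyError(f"tccf requires {pairs_path} from 'simulate'")
        pairs = io.read_pairs(pairs_path)
        max_lag = int(config.tccf.get("max_lag", 60))
        n_sum = int(config.tccf.get("n_sum_lags", 50))
        results = []
        for t1, t2 in pairs:
            try:
                pair = tccf.PairedTrace(t1, t2)
                results.append(tccf.compute_tccf(pair, max_lag, n_sum))
            except (ValueError, tccf.ZeroVarianceError):
                continue
        if len(results) >= 2:
            agg = tccf.aggregate_ordering(results)
            summary["tccf"] = {
                "mean_sum_delta_cc": agg.mean_sum_delta_cc,
                "ci95": list(agg.ci95), "t": agg.t_statistic, "p": agg.p_value,
                "n_pairs": agg.n_pairs,
            }
            io.write_json(summary["tccf"], outdir / "tccf_result.json")

    io.write_json(summary, outdir / "summary.json")
    return summary


def run_two_condition_study(base: RunConfig, outdir: str | Path) -> dict[str, Any]:
    """Run the pipeline under 'activating' and 'resting' generator settings.

    Returns a report with both summaries and the qualitative orderings
    the analyses are expected to reproduce (more trajectories, lower
    free/confined amplitude ratio and more molecules in clusters upon
    activation).  Group comparisons in the per-stage summaries use
    two-tailed unpaired t-tests where per-entity samples exist; synthetic
    replicates stand in for cells.
    """
    outdir = Path(outdir)
    report: dict[str, Any] = {}
    for condition in ("activating", "resting"):
        cfg = RunConfig.from_dict({**base.to_dict(),
                                   "condition": condition,
                                   "outdir": str(outdir / condition)})
        report[condition] = run_pipeline(cfg)
    act, rest = report["activating"], report["resting"]
    report["orderings"] = {
        "more_trajectories_when_activated":
            act["track"]["n_trajectories"] > rest["track"]["n_trajectories"]
            if "track" in act and "track" in rest else None,
        "lower_free_confined_ratio_when_activated":
            act["kics"]["amp_ratio_free_over_confined"]
            < rest["kics"]["amp_ratio_free_over_confined"]
            if "kics" in act and "kics" in rest else None,
        "higher_percent_in_clusters_when_activated":
            act["cluster"]["percent_in_cluster"]
            > rest["cluster"]["percent_in_cluster"]
            if "cluster" in act and "cluster" in rest else None,
    }
    io.write_json(report, outdir / "two_condition_report.json")
    return report
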