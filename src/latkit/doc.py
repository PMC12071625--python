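"""Degree-of-colocalization (DoC) scoring of two-channel SMLM data.

Around every channel-A molecule the local density of each channel is
evaluated on a ladder of radii (default 10–500 nm in 10-nm steps); the
rank correlation of the two density gradients is the molecule's DoC, in
[−1, 1] (1 colocalized, 0 random, −1 segregated).  Molecules whose local
density falls below the ROI-average density are excluded as DoC
recipients (they still count as neighbours).  Molecules near the ROI
border use the circle∩ROI intersection area for density.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import rankdata
import shapely

from latkit.clustering import ClusterSet, cluster_statistics

_ZERO_RADIUS = 1e-9


@dataclass
class DoCScores:
    """Per-molecule DoC values for channel A (NaN where excluded)."""

    doc: np.ndarray
    local_density: np.ndarray  # molecules/µm² at the largest radius
    excluded: np.ndarray
    radii_nm: np.ndarray


@dataclass
class SignalingClassification:
    """Signaling vs non-signaling cluster classification for one ROI."""

    cluster_class: np.ndarray  # "signaling" / "non-signaling" per cluster
    n_signaling_molecules_per_cluster: np.ndarray
    n_signaling_molecules: int
    percent_signaling_outside_clusters: float
    percent_signaling_inside_clusters: float
    signaling_stats: dict = field(default_factory=dict)
    nonsignaling_stats: dict = field(default_factory=dict)


def _corrected_areas(pts: np.ndarray, radii: np.ndarray,
                     roi_bounds: tuple[float, float, float, float]) -> np.ndarray:
    """circle∩ROI area (nm²) for every molecule × radius.

    Molecules farther than r from every border use πr² directly; the rest
    intersect a buffered point with the ROI box (shapely).
    """
    x0, y0, x1, y1 = roi_bounds
    box = shapely.box(x0, y0, x1, y1)
    dist_border = np.minimum.reduce([pts[:, 0] - x0, x1 - pts[:, 0],
                                     pts[:, 1] - y0, y1 - pts[:, 1]])
    areas = np.pi * radii[None, :] ** 2 * np.ones((len(pts), 1))
    points = shapely.points(pts)
    for j, r in enumerate(radii):
        near = dist_border < r
        if np.any(near):
            circles = shapely.buffer(points[near], r, quad_segs=16)
            areas[near, j] = shapely.area(shapely.intersection(circles, box))
    # a molecule localized (just) outside the ROI can have a vanishing
    # intersection at small radii; clamp so densities stay finite
    return np.maximum(areas, 1.0)


def doc_scores(channel_a: pd.DataFrame, channel_b: pd.DataFrame,
               roi_bounds: tuple[float, float, float, float],
               r_min_nm: float = 10.0, r_max_nm: float = 500.0,
               r_step_nm: float = 10.0, method: str = "spearman") -> DoCScores:
    """Score every channel-A molecule's degree of colocalization with channel B.

    ``roi_bounds`` is (xmin, ymin, xmax, ymax) in nm.  Both channels must
    be non-empty.  Neighbour counts exclude the query molecule itself and
    any zero-distance twin (so identical tables score exactly 1).
    Zero-variance gradients score 0.
    """
    x0, y0, x1, y1 = roi_bounds
    roi_area_nm2 = (x1 - x0) * (y1 - y0)
    if roi_area_nm2 <= 0:
        raise ValueError("ROI area must be > 0")
    if len(channel_a) == 0 or len(channel_b) == 0:
        raise ValueError("both channels must be non-empty")

    pts_a = channel_a[["x_nm", "y_nm"]].to_numpy(dtype=float)
    pts_b = channel_b[["x_nm", "y_nm"]].to_numpy(dtype=float)
    radii = np.arange(r_min_nm, r_max_nm + 0.5 * r_step_nm, r_step_nm)

    tree_a = cKDTree(pts_a)
    tree_b = cKDTree(pts_b)
    counts_a = np.empty((len(pts_a), len(radii)))
    counts_b = np.empty((len(pts_a), len(radii)))
    for j, r in enumerate(radii):
        counts_a[:, j] = tree_a.query_ball_point(pts_a, r, return_length=True)
        counts_b[:, j] = tree_b.query_ball_point(pts_a, r, return_length=True)
    counts_a -= tree_a.query_ball_point(pts_a, _ZERO_RADIUS,
                                        return_length=True)[:, None]
    counts_b -= tree_b.query_ball_point(pts_a, _ZERO_RADIUS,
                                        return_length=True)[:, None]
    counts_a = np.maximum(counts_a, 0)
    counts_b = np.maximum(counts_b, 0)

    areas = _corrected_areas(pts_a, radii, roi_bounds)
    grad_a = counts_a / areas
    grad_b = counts_b / areas

    # exclusion: channel-A local density at r_max below the ROI mean density
    mean_density = len(pts_a) / roi_area_nm2
    local_density = grad_a[:, -1]
    excluded = local_density < mean_density

    if method == "spearman":
        va = rankdata(grad_a, axis=1)
        vb = rankdata(grad_b, axis=1)
    elif method == "pearson":
        va, vb = grad_a, grad_b
    else:
        raise ValueError("method must be 'spearman' or 'pearson'")
    va = va - va.mean(axis=1, keepdims=True)
    vb = vb - vb.mean(axis=1, keepdims=True)
    sa = np.sqrt((va**2).sum(axis=1))
    sb = np.sqrt((vb**2).sum(axis=1))
    denom = sa * sb
    with np.errstate(invalid="ignore", divide="ignore"):
        doc = np.where(denom > 0, (va * vb).sum(axis=1) / denom, 0.0)
    doc = np.clip(doc, -1.0, 1.0)
    doc = np.where(excluded, np.nan, doc)
    return DoCScores(doc=doc, local_density=local_density * 1e6,
                     excluded=excluded, radii_nm=radii)


def classify_signaling(scores: DoCScores, clusters: ClusterSet,
                       roi_area_um2: float, doc_threshold: float = 0.4,
                       min_signaling: int = 10) -> SignalingClassification:
    """Split clusters into signaling / non-signaling by their DoC content.

    A molecule is signaling when its DoC >= ``doc_threshold`` (excluded
    molecules never are); a cluster is signaling when it contains at
    least ``min_signaling`` signaling molecules.  Also reports the
    fraction of signaling molecules outside any cluster and per-class
    cluster statistics.
    """
    if len(scores.doc) != len(clusters.labels):
        raise ValueError("scores and clusters must cover the same molecules")
    signaling_mol = ~scores.excluded & (np.nan_to_num(scores.doc, nan=-2.0)
                                        >= doc_threshold)
    n_clusters = clusters.n_clusters
    n_sig_per = np.array([int(signaling_mol[clusters.members(c)].sum())
                          for c in range(n_clusters)])
    cls = np.where(n_sig_per >= min_signaling, "signaling", "non-signaling")

    n_sig = int(signaling_mol.sum())
    outside = signaling_mol & (clusters.labels < 0)
    pct_out = 100.0 * outside.sum() / n_sig if n_sig else 0.0

    def subset_stats(keep_classes: str) -> dict:
        keep = np.where(cls == keep_classes)[0]
        if len(keep) == 0:
            return {"n_clusters": 0}
        remap = {c: i for i, c in enumerate(keep)}
        labels = np.array([remap.get(lbl, -1) for lbl in clusters.labels])
        sub = ClusterSet(points_nm=clusters.points_nm, labels=labels,
                         min_cluster_size=clusters.min_cluster_size,
                         params=clusters.params)
        return cluster_statistics(sub, roi_area_um2)

    return SignalingClassification(
        cluster_class=cls,
        n_signaling_molecules_per_cluster=n_sig_per,
        n_signaling_molecules=n_sig,
        percent_signaling_outside_clusters=pct_out,
        percent_signaling_inside_clusters=100.0 - pct_out if n_sig else 0.0,
        signaling_stats=subset_stats("signaling"),
        nonsignaling_stats=subset_stats("non-signaling"),
    )


def doc_map(scores: DoCScores, positions_nm: np.ndarray, path: str,
            map_radius_nm: float = 20.0) -> str:
    """Render a pseudo-colored DoC map (PNG) of the scored molecules.

    Each molecule is drawn at its position colored by its DoC value
    normalized to the ROI-average DoC; excluded molecules are grey.
    Returns the written path.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    valid = ~scores.excluded
    mean_doc = float(np.nanmean(scores.doc)) if np.any(valid) else 1.0
    norm = scores.doc / mean_doc if mean_doc not in (0.0,) else scores.doc
    if np.any(~valid):
        ax.scatter(positions_nm[~valid, 0], positions_nm[~valid, 1],
                   s=2, c="lightgrey", label=f"excluded ({int((~valid).sum())})")
    if np.any(valid):
        sc = ax.scatter(positions_nm[valid, 0], positions_nm[valid, 1], s=4,
                        c=norm[valid], cmap="coolwarm",
                        label=f"scored ({int(valid.sum())})")
        fig.colorbar(sc, ax=ax, label="DoC / mean DoC")
    ax.set_xlabel("x (nm)")
    ax.set_ylabel("y (nm)")
    ax.set_aspect("equal")
    ax.legend(loc="upper right", fontsize=7)
    ax.set_title(f"DoC map (r = {map_radius_nm:g} nm), n = {len(scores.doc)}")
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
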