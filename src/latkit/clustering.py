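"""Blink merging, DBSCAN clustering and cluster statistics for SMLM tables.

Localization tables are pandas DataFrames with columns
``frame, x_nm, y_nm, intensity, precision_nm, channel``; molecule tables
additionally carry ``n_merged``, the number of localizations collapsed
into each molecule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from shapely.geometry import MultiPoint

MOLECULE_COLUMNS = ["frame", "x_nm", "y_nm", "intensity", "precision_nm",
                    "channel", "n_merged"]


def merge_localizations(table: pd.DataFrame, radius_nm: float = 100.0,
                        max_gap_frames: int = 50) -> pd.DataFrame:
    """Collapse blinking re-localizations into molecules.

    Localizations are processed in frame order and chained to an existing
    molecule when they fall within ``radius_nm`` of the chain's running
    (precision-weighted) centroid and within ``max_gap_frames`` of the
    chain's last frame.  Each chain becomes one molecule at the weighted
    mean position with summed intensity; ``n_merged`` counts its
    localizations (their sum equals the input row count).
    """
    if len(table) == 0:
        return pd.DataFrame(columns=MOLECULE_COLUMNS)
    df = table.sort_values("frame", kind="stable").reset_index(drop=True)
    cell = max(radius_nm, 1e-9)

    chains: list[dict] = []
    grid: dict[tuple[int, int], list[int]] = {}

    def cell_of(x: float, y: float) -> tuple[int, int]:
        return (int(np.floor(x / cell)), int(np.floor(y / cell)))

    for row in df.itertuples(index=False):
        x, y, f = row.x_nm, row.y_nm, int(row.frame)
        w = 1.0 / max(row.precision_nm, 1e-9) ** 2
        cx, cy = cell_of(x, y)
        best = None
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for ci in grid.get((cx + dx, cy + dy), ()):
                    ch = chains[ci]
                    if ch["channel"] != row.channel:
                        continue
                    if f - ch["last_frame"] > max_gap_frames:
                        continue
                    d = np.hypot(ch["x"] - x, ch["y"] - y)
                    if d <= radius_nm and (best is None or d < best[0]):
                        best = (d, ci)
        if best is None:
            ci = len(chains)
            chains.append({"x": x, "y": y, "wsum": w, "wx": w * x, "wy": w * y,
                           "first_frame": f, "last_frame": f,
                           "intensity": row.intensity, "n": 1,
                           "channel": row.channel, "cell": (cx, cy)})
            grid.setdefault((cx, cy), []).append(ci)
        else:
            ci = best[1]
            ch = chains[ci]
            old_cell = ch["cell"]
            ch["wsum"] += w
            ch["wx"] += w * x
            ch["wy"] += w * y
            ch["x"] = ch["wx"] / ch["wsum"]
            ch["y"] = ch["wy"] / ch["wsum"]
            ch["last_frame"] = f
            ch["intensity"] += row.intensity
            ch["n"] += 1
            new_cell = cell_of(ch["x"], ch["y"])
            if new_cell != old_cell:
                grid[old_cell].remove(ci)
                grid.setdefault(new_cell, []).append(ci)
                ch["cell"] = new_cell

    out = pd.DataFrame({
        "frame": [c["first_frame"] for c in chains],
        "x_nm": [c["x"] for c in chains],
        "y_nm": [c["y"] for c in chains],
        "intensity": [c["intensity"] for c in chains],
        "precision_nm": [1.0 / np.sqrt(c["wsum"]) for c in chains],
        "channel": [c["channel"] for c in chains],
        "n_merged": [c["n"] for c in chains],
    })
    return out


@dataclass
class ClusterSet:
    """DBSCAN result: per-molecule labels (-1 = noise) over point coordinates."""

    points_nm: np.ndarray
    labels: np.ndarray
    min_cluster_size: int
    params: dict = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max() + 1) if len(self.labels) else 0

    def members(self, cluster: int) -> np.ndarray:
        return np.where(self.labels == cluster)[0]


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, a: int) -> int:
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def dbscan(molecules: pd.DataFrame, min_neighbors: int = 3,
           radius_nm: float = 20.0, min_cluster_size: int = 10) -> ClusterSet:
    """DBSCAN with the small-cluster filter used for SMLM cluster maps.

    A molecule is a core point when it has at least ``min_neighbors``
    *other* molecules within ``radius_nm``.  Clusters are connected
    components of core points within ``radius_nm`` of each other; border
    points (non-core with a core neighbour) join the cluster of their
    lowest-index core neighbour, a deterministic variant of the standard
    order-dependent assignment.  Clusters with fewer than
    ``min_cluster_size`` members are demoted to noise, and surviving
    clusters are relabelled 0..k-1 in order of their first member.
    """
    if len(molecules) == 0:
        raise ValueError("need at least one molecule")
    pts = molecules[["x_nm", "y_nm"]].to_numpy(dtype=float)
    n = len(pts)
    tree = cKDTree(pts)
    neighbors = tree.query_ball_point(pts, radius_nm)
    n_other = np.array([len(nb) - 1 for nb in neighbors])
    core = n_other >= min_neighbors

    uf = _UnionFind(n)
    for i in np.where(core)[0]:
        for j in neighbors[i]:
            if j != i and core[j]:
                uf.union(i, int(j))

    labels = np.full(n, -1, dtype=int)
    roots: dict[int, int] = {}
    for i in np.where(core)[0]:
        r = uf.find(int(i))
        labels[i] = roots.setdefault(r, len(roots))
    for i in np.where(~core)[0]:
        core_nb = [j for j in neighbors[i] if j != i and core[j]]
        if core_nb:
            labels[i] = labels[min(core_nb)]

    # small-cluster demotion and dense relabelling
    if labels.max() >= 0:
        sizes = np.bincount(labels[labels >= 0])
        for c in np.where(sizes < min_cluster_size)[0]:
            labels[labels == c] = -1
        remap: dict[int, int] = {}
        new = np.full(n, -1, dtype=int)
        for i in range(n):
            if labels[i] >= 0:
                new[i] = remap.setdefault(labels[i], len(remap))
        labels = new
    return ClusterSet(points_nm=pts, labels=labels,
                      min_cluster_size=min_cluster_size,
                      params={"min_neighbors": min_neighbors,
                              "radius_nm": radius_nm})


def _hull_metrics(points: np.ndarray) -> tuple[float, float, bool]:
    """Convex-hull (area nm², perimeter nm, degenerate flag) of a point set."""
    hull = MultiPoint([tuple(p) for p in points]).convex_hull
    degenerate = hull.area == 0.0
    if degenerate:
        hull = hull.buffer(1.0)  # 1-nm buffer for collinear clusters
    return float(hull.area), float(hull.length), degenerate


def cluster_statistics(clusters: ClusterSet, roi_area_um2: float) -> dict:
    """Per-ROI cluster summary statistics.

    Reports the percentage of molecules in clusters, mean/median convex
    hull area, clusters per µm², molecules per cluster, relative density
    (cluster density over overall density) and hull circularity
    4πA/P².
    """
    if roi_area_um2 <= 0:
        raise ValueError("roi_area_um2 must be > 0")
    n_total = len(clusters.labels)
    in_cluster = clusters.labels >= 0
    n_clusters = clusters.n_clusters
    overall_density = n_total / roi_area_um2 if n_total else 0.0

    areas, dens, circ, sizes, flagged = [], [], [], [], 0
    for c in range(n_clusters):
        pts = clusters.points_nm[clusters.members(c)]
        area_nm2, perim, degenerate = _hull_metrics(pts)
        flagged += degenerate
        area_um2 = area_nm2 / 1e6
        areas.append(area_nm2)
        sizes.append(len(pts))
        dens.append((len(pts) / area_um2) / overall_density
                    if area_um2 > 0 and overall_density > 0 else np.nan)
        circ.append(4 * np.pi * area_nm2 / perim**2 if perim > 0 else np.nan)

    return {
        "n_molecules": int(n_total),
        "n_clusters": int(n_clusters),
        "percent_in_cluster": 100.0 * in_cluster.sum() / n_total if n_total else 0.0,
        "clusters_per_um2": n_clusters / roi_area_um2,
        "mean_cluster_area_nm2": float(np.mean(areas)) if areas else 0.0,
        "median_cluster_area_nm2": float(np.median(areas)) if areas else 0.0,
        "mean_molecules_per_cluster": float(np.mean(sizes)) if sizes else 0.0,
        "mean_relative_density": float(np.nanmean(dens)) if dens else 0.0,
        "mean_circularity": float(np.nanmean(circ)) if circ else 0.0,
        "n_degenerate_hulls": int(flagged),
    }
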