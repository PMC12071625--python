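"""Blink merging, DBSCAN vs brute-force oracle and cluster statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from latkit.clustering import (
    cluster_statistics,
    dbscan,
    merge_localizations,
)
from conftest import make_locs


def brute_force_dbscan(points, min_neighbors=3, radius=20.0,
                       min_cluster_size=10):
    """O(n²) oracle: core graph connected components by BFS over a dense
    distance matrix; border points join their lowest-index core neighbour."""
    n = len(points)
    d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    within = d <= radius
    core = within.sum(1) - 1 >= min_neighbors
    labels = np.full(n, -1)
    next_label = 0
    for i in range(n):
        if not core[i] or labels[i] >= 0:
            continue
        queue = [i]
        labels[i] = next_label
        while queue:
            j = queue.pop()
            for k in np.where(within[j] & core)[0]:
                if labels[k] < 0:
                    labels[k] = next_label
                    queue.append(k)
        next_label += 1
    for i in range(n):
        if core[i] or labels[i] >= 0:
            continue
        nb = np.where(within[i] & core)[0]
        nb = nb[nb != i]
        if len(nb):
            labels[i] = labels[nb.min()]
    # demote small clusters, relabel densely in order of first member
    out = np.full(n, -1)
    remap = {}
    sizes = {c: (labels == c).sum() for c in set(labels) if c >= 0}
    for i in range(n):
        c = labels[i]
        if c >= 0 and sizes[c] >= min_cluster_size:
            out[i] = remap.setdefault(c, len(remap))
    return out


class TestMerge:
    @pytest.mark.parametrize("rows,expected", [
        ([(5, 0, 0, 1, 20, "A"), (30, 0, 0, 1, 20, "A")], 1),   # gap 25
        ([(5, 0, 0, 1, 20, "A"), (100, 0, 0, 1, 20, "A")], 2),  # gap 95
        ([(5, 0, 0, 1, 20, "A"), (6, 150, 0, 1, 20, "A")], 2),  # 150 nm apart
    ])
    def test_merge_rules(self, rows, expected):
        assert len(merge_localizations(make_locs(rows))) == expected

    def test_conservation_of_localizations(self, rng):
        rows = [(int(f), x, y, 1.0, 20.0, "A")
                for f, x, y in zip(rng.integers(0, 500, 300),
                                   rng.uniform(0, 2000, 300),
                                   rng.uniform(0, 2000, 300))]
        merged = merge_localizations(make_locs(rows))
        assert merged.n_merged.sum() == 300

    def test_channels_never_merge_together(self):
        rows = [(5, 0, 0, 1, 20, "A"), (6, 0, 0, 1, 20, "B")]
        assert len(merge_localizations(make_locs(rows))) == 2

    def test_weighted_centroid(self):
        rows = [(0, 0.0, 0.0, 1, 10.0, "A"), (1, 30.0, 0.0, 1, 30.0, "A")]
        m = merge_localizations(make_locs(rows))
        # weights 1/100 vs 1/900: centroid at 30*(1/900)/(1/100+1/900) = 3
        assert m.x_nm.iloc[0] == pytest.approx(3.0)


class TestDbscan:
    def test_dense_clump_plus_outlier(self, rng):
        pts = np.vstack([rng.normal(0, 2, (12, 2)), [[1000.0, 1000.0]]])
        mols = make_locs([(0, x, y, 1, 20, "A") for x, y in pts])
        cs = dbscan(mols)
        assert cs.n_clusters == 1
        assert (cs.labels >= 0).sum() == 12
        assert cs.labels[-1] == -1

    def test_nine_molecules_below_min_cluster_size(self, rng):
        pts = rng.normal(0, 2, (9, 2))
        mols = make_locs([(0, x, y, 1, 20, "A") for x, y in pts])
        cs = dbscan(mols)
        assert cs.n_clusters == 0
        assert np.all(cs.labels == -1)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_clusters = rng.integers(1, 6)
        pts = [rng.uniform(0, 1500, (rng.integers(5, 60), 2))
               * 0.02 + rng.uniform(0, 1500, 2) for _ in range(n_clusters)]
        pts.append(rng.uniform(0, 1500, (rng.integers(10, 120), 2)))
        points = np.vstack(pts)
        mols = make_locs([(0, x, y, 1, 20, "A") for x, y in points])
        got = dbscan(mols).labels
        want = brute_force_dbscan(points)
        assert np.array_equal(got, want)


class TestStatistics:
    def test_no_clusters(self, rng):
        mols = make_locs([(0, x, y, 1, 20, "A")
                          for x, y in rng.uniform(0, 4000, (30, 2))])
        cs = dbscan(mols)
        stats = cluster_statistics(cs, 16.0)
        assert stats["percent_in_cluster"] == 0.0
        assert stats["clusters_per_um2"] == 0.0

    def test_percent_in_cluster_arithmetic(self, rng):
        clustered = rng.normal(0, 3, (10, 2))
        background = rng.uniform(500, 4000, (90, 2))
        mols = make_locs([(0, x, y, 1, 20, "A")
                          for x, y in np.vstack([clustered, background])])
        stats = cluster_statistics(dbscan(mols), 16.0)
        assert stats["percent_in_cluster"] == pytest.approx(10.0)

    def test_invariant_under_rigid_motion(self, rng):
        pts = np.vstack([rng.normal(0, 5, (40, 2)) + [800, 900],
                         rng.uniform(0, 2000, (60, 2))])
        mols = make_locs([(0, x, y, 1, 20, "A") for x, y in pts])
        base = cluster_statistics(dbscan(mols), 4.0)
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        moved = pts @ rot.T + [123.0, -77.0]
        mols2 = make_locs([(0, x, y, 1, 20, "A") for x, y in moved])
        stats2 = cluster_statistics(dbscan(mols2), 4.0)
        assert stats2["percent_in_cluster"] == pytest.approx(
            base["percent_in_cluster"])
        assert stats2["mean_cluster_area_nm2"] == pytest.approx(
            base["mean_cluster_area_nm2"], rel=1e-6)

    def test_collinear_cluster_buffered_and_flagged(self):
        pts = [(0, float(i), 0.0, 1, 20, "A") for i in range(12)]
        cs = dbscan(make_locs(pts))
        assert cs.n_clusters == 1
        stats = cluster_statistics(cs, 16.0)
        assert stats["n_degenerate_hulls"] == 1
        assert stats["mean_cluster_area_nm2"] > 0
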