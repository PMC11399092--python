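"""Clustering, crosshair identification and relative specificity."""

import numpy as np
import pandas as pd
import pytest

from paintbench.exceptions import InsufficientDataError
from paintbench.locio import CircularRegion, LocalizationTable, RegionSet
from paintbench.sim import SimConfig, SiteLayout, emit_localizations
from paintbench.sites import (
    cluster_smlm,
    find_crosshairs,
    mask_specificity,
    relative_specificity,
)


def brute_force_clusters(pts, radius, min_locs):
    """O(n^2) reference implementation: core points, components, borders."""
    n = len(pts)
    d = np.hypot(pts[:, 0][:, None] - pts[:, 0], pts[:, 1][:, None] - pts[:, 1])
    nbr = d <= radius
    core = nbr.sum(axis=1) >= min_locs
    labels = np.full(n, -1)
    cid = 0
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    for i in order:
        if not core[i] or labels[i] != -1:
            continue
        stack = [i]
        labels[i] = cid
        while stack:
            j = stack.pop()
            for k in np.flatnonzero(nbr[j] & core):
                if labels[k] == -1:
                    labels[k] = cid
                    stack.append(k)
        cid += 1
    for i in range(n):
        if core[i]:
            continue
        ids = labels[np.flatnonzero(nbr[i] & core)]
        if len(ids):
            labels[i] = ids.min()
    return labels, cid


class TestClusterSMLM:
    def test_below_min_locs_threshold_no_cluster(self, rng):
        pts = rng.normal(scale=0.01, size=(14, 2))
        assert cluster_smlm(pts[:, 0], pts[:, 1], radius=0.04, min_locs=15) == []

    def test_two_separated_blobs(self, rng):
        a = rng.normal(scale=0.02, size=(20, 2))
        b = rng.normal(scale=0.02, size=(20, 2)) + [1.0, 0.0]
        pts = np.vstack([a, b])
        clusters = cluster_smlm(pts[:, 0], pts[:, 1], radius=0.04, min_locs=15)
        assert len(clusters) == 2
        cents = sorted(c.centroid[0] for c in clusters)
        assert cents[0] == pytest.approx(0.0, abs=0.05)
        assert cents[1] == pytest.approx(1.0, abs=0.05)

    @pytest.mark.parametrize("seed", range(5))
    def test_sparse_noise_yields_no_clusters(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 50, size=(500, 2))  # density far below min_locs/(pi r^2)
        assert cluster_smlm(pts[:, 0], pts[:, 1], radius=0.04, min_locs=15) == []

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        blobs = [
            rng.normal(loc=c, scale=0.03, size=(rng.integers(10, 40), 2))
            for c in rng.uniform(0, 3, size=(6, 2))
        ]
        pts = np.vstack(blobs + [rng.uniform(0, 3, size=(80, 2))])
        assert len(pts) <= 500
        clusters = cluster_smlm(pts[:, 0], pts[:, 1], radius=0.1, min_locs=12)
        labels, n_ref = brute_force_clusters(pts, 0.1, 12)
        assert len(clusters) == n_ref
        got = {frozenset(c.members.tolist()) for c in clusters}
        ref = {frozenset(np.flatnonzero(labels == cid).tolist()) for cid in range(n_ref)}
        assert got == ref

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_sklearn_dbscan(self, seed):
        """Independent cross-check: same cores and cluster count as DBSCAN."""
        sklearn_cluster = pytest.importorskip("sklearn.cluster")
        rng = np.random.default_rng(200 + seed)
        blobs = [
            rng.normal(loc=c, scale=0.05, size=(30, 2))
            for c in rng.uniform(0, 5, size=(5, 2))
        ]
        pts = np.vstack(blobs + [rng.uniform(0, 5, size=(60, 2))])
        clusters = cluster_smlm(pts[:, 0], pts[:, 1], radius=0.15, min_locs=10)
        db = sklearn_cluster.DBSCAN(eps=0.15, min_samples=10).fit(pts)
        assert len(clusters) == db.labels_.max() + 1
        core = set(db.core_sample_indices_.tolist())
        clustered = set(int(i) for c in clusters for i in c.members)
        assert core <= clustered

    def test_order_independence(self, rng):
        pts = np.vstack(
            [rng.normal(scale=0.02, size=(25, 2)), rng.normal(loc=2.0, scale=0.02, size=(25, 2))]
        )
        perm = rng.permutation(len(pts))
        c1 = cluster_smlm(pts[:, 0], pts[:, 1], 0.04, 15)
        c2 = cluster_smlm(pts[perm, 0], pts[perm, 1], 0.04, 15)
        s1 = {frozenset(np.sort(perm[np.isin(perm, c.members)]).tolist()) for c in c1}
        s2 = {frozenset(perm[c.members].tolist()) for c in c2}
        assert {frozenset(c.members.tolist()) for c in c1} == {
            frozenset(perm[c.members].tolist()) for c in c2
        }


def simulate_crosshairs(n_structures, destroy_fraction=0.0, seed=0, n_frames=1500):
    layout = SiteLayout.crosshair(n_structures, fov=(150, 150), margin=4.0)
    cfg = SimConfig(
        n_frames=n_frames,
        width=150,
        height=150,
        layout=layout,
        destroy_fraction=destroy_fraction,
        destroy_at_start=True,
        seed=seed,
    )
    table, truth = emit_localizations(cfg)
    centers = layout.positions.reshape(n_structures, 5, 2)[:, 0, :]
    x = table.locs["x"].to_numpy()
    y = table.locs["y"].to_numpy()
    pick_clusters = []
    for cx, cy in centers:
        sel = (np.abs(x - cx) < 1.5) & (np.abs(y - cy) < 1.5)
        pick_clusters.append(cluster_smlm(x[sel], y[sel], radius=0.04, min_locs=15))
    return pick_clusters, centers


class TestCrosshairs:
    def test_complete_structures_accepted(self):
        picks, centers = simulate_crosshairs(20, seed=1)
        pos, accepted, n_rej = find_crosshairs(picks, centers)
        assert len(accepted) == 20 and n_rej == 0
        # target position is the center docking site
        assert np.allclose(pos, centers, atol=0.05)

    def test_incomplete_structure_rejected(self):
        picks, centers = simulate_crosshairs(30, destroy_fraction=0.35, seed=2)
        pos, accepted, n_rej = find_crosshairs(picks, centers)
        assert n_rej > 0
        for i in accepted:
            assert len(picks[i]) == 5

    def test_six_cluster_pick_rejected(self, rng):
        # a complete crosshair plus one spurious sticking cluster
        picks, centers = simulate_crosshairs(1, seed=3)
        extra = cluster_smlm(
            rng.normal(loc=centers[0, 0] + 1.0, scale=0.01, size=30),
            rng.normal(loc=centers[0, 1], scale=0.01, size=30),
            radius=0.04,
            min_locs=15,
        )
        contaminated = [picks[0] + extra]
        _, accepted, n_rej = find_crosshairs(contaminated, centers)
        assert len(accepted) == 0 and n_rej == 1

    def test_acceptance_rate_is_binomial_in_destruction(self):
        """Independent per-site destruction at t=0 gives acceptance ~ (1-f)^5."""
        f = 0.2
        picks, centers = simulate_crosshairs(800, destroy_fraction=f, seed=4)
        _, accepted, _ = find_crosshairs(picks, centers)
        rate = len(accepted) / 800
        expect = (1 - f) ** 5
        se = np.sqrt(expect * (1 - expect) / 800)
        assert rate == pytest.approx(expect, abs=4 * se)


def uniform_table(n, width, height, seed, frame_count=100):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "frame": rng.integers(0, frame_count, n),
            "x": rng.uniform(0, width, n),
            "y": rng.uniform(0, height, n),
            "photons": np.full(n, 500.0),
            "sx": np.full(n, 0.85),
            "sy": np.full(n, 0.85),
            "bg": np.full(n, 10.0),
        }
    )
    return LocalizationTable(df, 0.1, 130.0, width, height)


class TestSpecificity:
    def signal_regions(self):
        return RegionSet.from_circles([CircularRegion(16.0, 16.0, 12.0, "signal")])

    def background_regions(self):
        return RegionSet.from_circles([CircularRegion(48.0, 48.0, 12.0, "background")])

    def test_self_comparison_is_unity(self):
        t = uniform_table(3000, 64, 64, seed=0)
        res = relative_specificity(t, t, self.signal_regions(), self.background_regions())
        assert res.r_dye == 1.0

    def test_doubled_background_density_halves_specificity(self):
        ref = uniform_table(3000, 64, 64, seed=1)
        # imaging round: same signal counts, twice the background counts
        extra_bg = uniform_table(3000, 64, 64, seed=2).locs
        extra_bg = extra_bg[
            np.hypot(extra_bg["x"] - 48.0, extra_bg["y"] - 48.0) < 6.0
        ]
        img_locs = pd.concat([ref.locs, extra_bg], ignore_index=True)
        img = LocalizationTable(img_locs, 0.1, 130.0, 64, 64)
        res = relative_specificity(img, ref, self.signal_regions(), self.background_regions())
        n_bg_ref = res.counts["reference_background"]
        n_bg_img = res.counts["imaging_background"]
        assert res.r_dye == pytest.approx(n_bg_ref / n_bg_img, rel=1e-9)
        assert res.r_dye == pytest.approx(0.5, abs=0.1)

    def test_global_count_scaling_invariance(self):
        ref = uniform_table(2000, 64, 64, seed=3)
        doubled = LocalizationTable(
            pd.concat([ref.locs, ref.locs], ignore_index=True), 0.1, 130.0, 64, 64
        )
        r1 = relative_specificity(
            doubled, ref, self.signal_regions(), self.background_regions()
        )
        assert r1.r_dye == pytest.approx(1.0, rel=1e-9)

    def test_zero_background_count_is_error(self):
        t = uniform_table(100, 64, 64, seed=4)
        empty_bg = RegionSet.from_circles([CircularRegion(200.0, 200.0, 1.0, "background")])
        t2 = LocalizationTable(t.locs, 0.1, 130.0, 256, 256)
        with pytest.raises(InsufficientDataError):
            relative_specificity(t2, t2, self.signal_regions(), empty_bg)

    def test_mask_path_matches_unity_self_comparison(self):
        t = uniform_table(4000, 64, 64, seed=5)
        mask = np.zeros((64, 64), dtype=np.uint8)
        mask[10:40, 10:40] = 1
        res = mask_specificity(t, t, mask)
        assert res.r_dye == 1.0
        assert res.signal_area_um2 == pytest.approx(900 * 0.13**2)
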