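"""Protrusions, geodesic profiles, screening, radial binning, targeting."""

import networkx as nx
import numpy as np
import pytest

from optofret import (detect_protrusion, edge_distance_profile,
                      geodesic_distance, radial_profile,
                      screen_center_stim_cell, select_edge_target)
from optofret.spatial import detect_protrusions, register_stage_offsets

from conftest import disk_mask


def dijkstra_oracle(mask, source):
    """Independent shortest-path oracle on the 8-connected pixel graph."""
    g = nx.Graph()
    pix = set(map(tuple, np.argwhere(mask)))
    for r, c in pix:
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if (dr, dc) == (0, 0):
                    continue
                nb = (r + dr, c + dc)
                if nb in pix:
                    g.add_edge((r, c), nb,
                               weight=np.hypot(dr, dc))
    sources = set(map(tuple, np.argwhere(source)))
    for s in sources:
        g.add_node(s)
    lengths = nx.multi_source_dijkstra_path_length(g, sources)
    out = np.full(mask.shape, np.inf)
    out[~mask] = np.nan
    for (r, c), d in lengths.items():
        out[r, c] = d
    return out


class TestProtrusion:
    def test_stationary_mask_has_no_protrusion(self):
        m = disk_mask((64, 64), (32, 32), 10)
        assert detect_protrusion(m, m) is None

    def test_translated_disk_gives_crescent_of_lens_area(self):
        R, d = 14, 2
        m0 = disk_mask((64, 64), (32, 30), R)
        m1 = disk_mask((64, 64), (32, 32), R)
        prot = detect_protrusion(m0, m1)
        inter = (2 * R ** 2 * np.arccos(d / (2 * R))
                 - d / 2 * np.sqrt(4 * R ** 2 - d ** 2))
        expected = np.pi * R ** 2 - inter
        assert prot.mask.sum() == pytest.approx(expected, rel=0.10)
        # crescent lies on the advancing (right) side
        rr, cc = np.nonzero(prot.mask)
        assert cc.mean() > 32

    def test_transient_blob_rejected_by_neighbor_consistency(self):
        base = disk_mask((64, 64), (32, 32), 10)
        blob = base | disk_mask((64, 64), (32, 46), 4)
        masks = [base, base, blob, base, base]
        # frame 2 gains a blob that is gone again at frame 3
        prots = detect_protrusions(masks)
        assert prots[2] is None

    def test_steady_motion_keeps_consistent_protrusions(self):
        masks = [disk_mask((64, 96), (32, 24 + 2 * t), 12) for t in range(6)]
        prots = detect_protrusions(masks)
        for t in (2, 3):
            assert prots[t] is not None
            assert prots[t].mask.any()


class TestGeodesic:
    def test_source_pixel_is_at_zero_distance(self):
        m = disk_mask((32, 32), (16, 16), 8)
        src = np.zeros_like(m)
        src[16, 16] = True
        d = geodesic_distance(m, src)
        assert d[16, 16] == 0.0

    def test_corridor_distance_is_chain_length(self):
        m = np.zeros((5, 40), bool)
        m[2, 5:35] = True
        src = np.zeros_like(m)
        src[2, 5] = True
        d = geodesic_distance(m, src, pixel_size=0.5)
        assert d[2, 34] == pytest.approx(29 * 0.5, rel=1e-12)

    def test_agrees_exactly_with_dijkstra_oracle(self, rng):
        for _ in range(20):
            m = np.zeros((30, 30), bool)
            for _k in range(rng.integers(2, 6)):
                m |= disk_mask((30, 30), rng.uniform(5, 25, 2),
                               rng.uniform(3, 8))
            src = np.zeros_like(m)
            pick = np.argwhere(m)[rng.integers(0, m.sum())]
            src[pick[0], pick[1]] = True
            ours = geodesic_distance(m, src)
            oracle = dijkstra_oracle(m, src)
            both = m
            assert np.allclose(ours[both], oracle[both], rtol=1e-9,
                               equal_nan=True)

    def test_geodesic_bounds_euclidean_on_disks(self):
        m = disk_mask((64, 64), (32, 32), 20)
        src = np.zeros_like(m)
        src[32, 32] = True
        d = geodesic_distance(m, src)
        rr = np.arange(64)[:, None] - 32.0
        cc = np.arange(64)[None, :] - 32.0
        euclid = np.hypot(rr, cc)
        # quasi-Euclidean metric: never below Euclidean, at most the
        # 8-connected metrication factor sqrt(2)/sqrt(1+tan^2(22.5deg))
        assert np.all(d[m] >= euclid[m] - 1e-9)
        assert np.all(d[m] <= 1.083 * euclid[m] + 1e-9)

    def test_empty_source_rejected(self):
        m = disk_mask((16, 16), (8, 8), 4)
        with pytest.raises(ValueError, match="empty source"):
            geodesic_distance(m, np.zeros_like(m))


class TestEdgeProfile:
    def _corridor(self, slope=0.0, length=60, halfwidth=4):
        """Rectangle with the protrusion at the right end: geodesic
        distance is exactly the horizontal pixel distance."""
        m = np.zeros((2 * halfwidth + 1, length + 2), bool)
        m[:, 1:length + 1] = True
        prot = np.zeros_like(m)
        prot[:, length] = True
        cols = np.arange(m.shape[1])[None, :] * np.ones((m.shape[0], 1))
        # front-high: ratio is 1 at the protrusion and falls linearly
        # with distance from it
        ratio = np.where(m, 1.0 - slope * (length - cols), np.nan)
        return ratio, m, prot

    def test_uniform_ratio_gives_flat_profile_of_ones(self):
        ratio, m, prot = self._corridor(slope=0.0)
        from optofret.spatial import ProtrusionMask
        df = edge_distance_profile([ratio], [m],
                                   [ProtrusionMask(0, prot, {})],
                                   pixel_size=1.0)
        assert np.allclose(df["ratio"].dropna(), 1.0, atol=1e-12)

    def test_front_high_gradient_recovered_with_correct_slope(self):
        s = 0.004
        ratio, m, prot = self._corridor(slope=s)
        from optofret.spatial import ProtrusionMask
        df = edge_distance_profile([ratio], [m],
                                   [ProtrusionMask(0, prot, {})],
                                   pixel_size=1.0)
        vals = df["ratio"].to_numpy()
        assert np.all(np.diff(vals[np.isfinite(vals)]) < 0)
        fit = np.polyfit(df["distance_um"][:40], vals[:40], 1)[0]
        assert fit == pytest.approx(-s, rel=0.10)

    def test_first_bin_is_exactly_one_after_normalization(self, rng):
        ratio, m, prot = self._corridor(slope=0.002)
        ratio = ratio * rng.uniform(0.9, 1.1)  # arbitrary scaling
        from optofret.spatial import ProtrusionMask
        df = edge_distance_profile([ratio], [m],
                                   [ProtrusionMask(0, prot, {})],
                                   pixel_size=1.0)
        assert df["ratio"].iloc[0] == 1.0


class TestScreening:
    def _track(self, drift_um=0.0, n=6, stim_frame=2):
        masks = [disk_mask((64, 64), (32, 32), 14) for _ in range(n)]
        cents = np.tile([32 * 0.5, 32 * 0.5], (n, 1))
        for t in range(stim_frame + 1, n):
            cents[t, 0] += drift_um
        return masks, cents

    def test_compliant_cell_kept(self):
        masks, cents = self._track()
        keep, reason = screen_center_stim_cell(masks, cents, (32, 32), 2, 0.5)
        assert keep and reason == "ok"

    def test_centroid_drift_beyond_4um_rejected(self):
        masks, cents = self._track(drift_um=5.0)
        keep, reason = screen_center_stim_cell(masks, cents, (32, 32), 2, 0.5)
        assert not keep and reason == "motion"

    def test_target_near_edge_rejected(self):
        masks, cents = self._track()
        # 3 px inside the disk boundary: radius 14, so r=11.5 from centre
        keep, reason = screen_center_stim_cell(masks, cents, (32, 44), 2, 0.5)
        assert not keep and reason == "edge-proximity"

    def test_target_outside_mask_rejected(self):
        masks, cents = self._track()
        keep, reason = screen_center_stim_cell(masks, cents, (5, 5), 2, 0.5)
        assert not keep and reason == "frap-outside-mask"


class TestRadialProfile:
    def test_uniform_response_gives_uniform_fold_change(self):
        m = disk_mask((64, 64), (32, 32), 24)
        donor = np.full((64, 64), 4000.0)
        pre_a = donor * 1.3
        post_a = donor * 1.3 * 1.08
        df = radial_profile([donor, donor], [pre_a, post_a],
                            [m, m], (32.0, 32.0), 0, 0.3)
        post = df[(df.frame == 1) & df.fold_change.notna()]
        assert len(post) > 5
        assert np.allclose(post["fold_change"], 1.08, rtol=1e-9)

    def test_gaussian_response_matches_annulus_quadrature_oracle(self):
        px = 0.3
        sigma_um, amp = 2.0, 0.08
        m = disk_mask((96, 96), (48, 48), 40)
        rr = (np.arange(96)[:, None] - 48.0) * px
        cc = (np.arange(96)[None, :] - 48.0) * px
        r_um = np.hypot(rr, cc)
        donor = np.full((96, 96), 4000.0)
        g = np.exp(-r_um ** 2 / (2 * sigma_um ** 2))
        pre_a = donor * 1.3
        post_a = donor * 1.3 * (1 + amp * g)
        df = radial_profile([donor, donor], [pre_a, post_a],
                            [m, m], (48.0, 48.0), 0, px)
        post = df[(df.frame == 1) & df.fold_change.notna()]
        for _, row in post.iterrows():
            r1, r2 = (row.bin_um - 1), row.bin_um
            if r2 * 1.0 > 40 * px:  # annuli clipped by the mask edge
                continue
            # analytic annulus mean of a radial Gaussian
            mean_g = (2 * sigma_um ** 2
                      * (np.exp(-r1 ** 2 / (2 * sigma_um ** 2))
                         - np.exp(-r2 ** 2 / (2 * sigma_um ** 2)))
                      / (r2 ** 2 - r1 ** 2))
            expected = 1 + amp * mean_g
            assert row.fold_change == pytest.approx(expected,
                                                    abs=0.05 * amp)

    def test_pre_frame_fold_change_is_unity(self):
        m = disk_mask((64, 64), (32, 32), 20)
        donor = np.full((64, 64), 4000.0)
        acc = donor * 1.25
        df = radial_profile([donor], [acc], [m], (32.0, 32.0), 0, 0.3)
        pre = df[df.fold_change.notna()]
        assert np.allclose(pre["fold_change"], 1.0, rtol=1e-12)

    def test_bins_partition_the_mask(self):
        m = disk_mask((64, 64), (30, 34), 18)
        donor = np.full((64, 64), 4000.0)
        acc = donor * 1.3
        df = radial_profile([donor], [acc], [m], (30.0, 34.0), 0, 0.3,
                            min_pixels=1)
        assert df["n_px"].sum() == m.sum()

    def test_sparse_bins_reported_missing(self):
        m = np.zeros((64, 64), bool)
        m[32, 30:35] = True  # 5-pixel sliver
        donor = np.full((64, 64), 4000.0)
        acc = donor * 1.3
        df = radial_profile([donor], [acc], [m], (32.0, 32.0), 0, 0.9,
                            min_pixels=5)
        far_bins = df[df.bin_um >= 2]
        assert far_bins["ratio"].isna().all()

    def test_stage_offsets_register_frames(self):
        img = np.zeros((32, 32))
        img[10:20, 10:20] = 7.0
        shifted = np.roll(img, (2, -3), axis=(0, 1))
        out = register_stage_offsets([img, shifted],
                                     np.array([[0.0, 0.0], [2.0, -3.0]]),
                                     pixel_size=1.0)
        ok = np.isfinite(out[1])
        assert np.allclose(out[1][ok], img[ok])


class TestEdgeTarget:
    def test_disk_angle_zero_is_rightmost_pixel(self):
        m = disk_mask((64, 64), (32, 32), 15)
        r, c = select_edge_target(m, 0.0)
        assert c == 47 and r == 32

    def test_disk_angle_ninety_is_topmost_pixel(self):
        m = disk_mask((64, 64), (32, 32), 15)
        r, c = select_edge_target(m, 90.0)
        assert r == 17 and c == 32  # y-up: smaller row = larger y

    def test_matches_exhaustive_perimeter_oracle(self, rng):
        from skimage.morphology import erosion
        m = disk_mask((64, 64), (30, 34), 16) | disk_mask((64, 64),
                                                          (40, 20), 10)
        perim = m & ~erosion(m, np.ones((3, 3), bool))
        rr, cc = np.nonzero(m)
        centroid = (rr.mean(), cc.mean())
        for angle in rng.uniform(-180, 180, 100):
            got = select_edge_target(m, angle)
            best, key = None, None
            for r, c in np.argwhere(perim):
                dx, dy = c - centroid[1], -(r - centroid[0])
                a = np.degrees(np.arctan2(dy, dx))
                diff = abs((a - angle + 180) % 360 - 180)
                k = (diff, -np.hypot(dx, dy))
                if key is None or k < key:
                    best, key = (r, c), k
            assert got == best

    def test_degenerate_single_pixel_mask_rejected(self):
        m = np.zeros((8, 8), bool)
        m[4, 4] = True
        with pytest.raises(ValueError, match="degenerate"):
            select_edge_target(m, 0.0)
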