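"""Watershed, skeletonization, branch decomposition, morphometry."""

import numpy as np
import pytest
from scipy import ndimage as ndi

import myoseg as ms
from myoseg.postprocess import WL, BACKGROUND_MARKER

from conftest import straight_tube_mask


# ---------------------------------------------------------------------------
# brute-force watershed oracle: repeatedly scan the whole grid for the
# frontier pixel with minimal (relief, row, col) and assign it
# ---------------------------------------------------------------------------

def watershed_oracle(markers, nuclei_mask, relief=None):
    nuclei_mask = np.asarray(nuclei_mask) > 0
    if relief is None:
        relief = -ndi.distance_transform_edt(nuclei_mask)
    out = markers.labels.astype(np.int64).copy()
    h, w = out.shape

    def nbrs4(r, c):
        for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
            if 0 <= rr < h and 0 <= cc < w:
                yield rr, cc

    while True:
        best = None
        for r in range(h):
            for c in range(w):
                if out[r, c] != 0:
                    continue
                if any(out[rr, cc] > 0 for rr, cc in nbrs4(r, c)):
                    key = (relief[r, c], r, c)
                    if best is None or key < best[0]:
                        best = (key, r, c)
        if best is None:
            break
        _, r, c = best
        labs = {int(out[rr, cc]) for rr, cc in nbrs4(r, c) if out[rr, cc] > 0}
        out[r, c] = labs.pop() if len(labs) == 1 else WL
    final = np.zeros_like(out)
    sel = nuclei_mask & (out > BACKGROUND_MARKER)
    final[sel] = out[sel] - 1
    final[nuclei_mask & (out == WL)] = WL
    return final


def random_disk_scene(seed, shape=(48, 48), n_disks=4, r_range=(5, 9)):
    rng = np.random.default_rng(seed)
    mask = np.zeros(shape, np.uint8)
    cen = np.zeros(shape, np.uint8)
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    for _ in range(n_disks):
        r = rng.integers(*r_range)
        y, x = rng.integers(r + 1, shape[0] - r - 1), rng.integers(r + 1, shape[1] - r - 1)
        if cen[y, x]:
            continue
        mask[(rr - y) ** 2 + (cc - x) ** 2 <= r * r] = 1
        cen[y, x] = 1
    return mask, cen


class TestMarkers:
    def test_single_disk_single_marker(self):
        mask, cen = np.zeros((32, 32), np.uint8), np.zeros((32, 32), np.uint8)
        rr, cc = np.mgrid[0:32, 0:32]
        mask[(rr - 16) ** 2 + (cc - 16) ** 2 <= 64] = 1
        cen[16, 16] = 1
        mk = ms.build_markers(mask, cen)
        assert mk.n_nuclei == 1
        assert set(np.unique(mk.labels)) == {0, 1, 2}

    def test_two_touching_disks_two_markers(self):
        mask = np.zeros((40, 60), np.uint8)
        cen = np.zeros_like(mask)
        rr, cc = np.mgrid[0:40, 0:60]
        mask[(rr - 20) ** 2 + (cc - 22) ** 2 <= 100] = 1
        mask[(rr - 20) ** 2 + (cc - 36) ** 2 <= 100] = 1
        cen[20, 22] = cen[20, 36] = 1
        mk = ms.build_markers(mask, cen)
        assert mk.n_nuclei == 2
        assert (mk.labels == 2).sum() == 1 and (mk.labels == 3).sum() == 1

    def test_centroid_outside_mask_dropped_with_warning(self, caplog):
        import logging

        mask, cen = np.zeros((32, 32), np.uint8), np.zeros((32, 32), np.uint8)
        rr, cc = np.mgrid[0:32, 0:32]
        mask[(rr - 10) ** 2 + (cc - 10) ** 2 <= 25] = 1
        cen[10, 10] = 1
        cen[28, 28] = 1  # stray dot far from any nucleus
        with caplog.at_level(logging.WARNING, logger="myoseg.postprocess"):
            mk = ms.build_markers(mask, cen)
        assert mk.n_nuclei == 1
        assert "dropped" in caplog.text

    def test_empty_centroids_give_background_only(self):
        mask = np.zeros((16, 16), np.uint8)
        mask[4:10, 4:10] = 1
        mk = ms.build_markers(mask, np.zeros_like(mask))
        assert mk.n_nuclei == 0
        lm = ms.watershed_segment(mk, mask)
        assert ms.count_nuclei(lm) == 0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            ms.build_markers(np.zeros((8, 8)), np.zeros((9, 9)))


class TestWatershed:
    def test_single_disk_single_label_no_wl(self):
        mask, cen = np.zeros((32, 32), np.uint8), np.zeros((32, 32), np.uint8)
        rr, cc = np.mgrid[0:32, 0:32]
        disk = (rr - 16) ** 2 + (cc - 16) ** 2 <= 81
        mask[disk] = 1
        cen[16, 16] = 1
        lm = ms.watershed_segment(ms.build_markers(mask, cen), mask)
        assert ms.count_nuclei(lm) == 1
        assert (lm.labels == WL).sum() == 0
        assert np.array_equal(lm.labels > 0, disk)

    def test_two_overlapping_disks_separated_by_wl(self):
        mask, cen = np.zeros((40, 54), np.uint8), np.zeros((40, 54), np.uint8)
        rr, cc = np.mgrid[0:40, 0:54]
        mask[(rr - 20) ** 2 + (cc - 20) ** 2 <= 100] = 1
        mask[(rr - 20) ** 2 + (cc - 34) ** 2 <= 100] = 1
        cen[20, 20] = cen[20, 34] = 1
        lm = ms.watershed_segment(ms.build_markers(mask, cen), mask)
        assert sorted(lm.instance_ids) == [1, 2]
        wl = np.argwhere(lm.labels == WL)
        assert len(wl)
        # the separating chain lies within the overlap lens, near column 27
        assert wl[:, 1].min() >= 24 and wl[:, 1].max() <= 30

    def test_empty_foreground(self):
        mask = np.zeros((16, 16), np.uint8)
        lm = ms.watershed_segment(ms.build_markers(mask, mask), mask)
        assert (lm.labels == 0).all()

    def test_non_finite_relief_rejected(self):
        mask = np.ones((8, 8), np.uint8)
        mk = ms.build_markers(mask, np.zeros_like(mask))
        with pytest.raises(ValueError, match="finite"):
            ms.watershed_segment(mk, mask, relief=np.full((8, 8), np.nan))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        """Heap-based flooding equals the exhaustive scan oracle exactly."""
        mask, cen = random_disk_scene(seed)
        mk = ms.build_markers(mask, cen)
        lm = ms.watershed_segment(mk, mask)
        assert np.array_equal(lm.labels, watershed_oracle(mk, mask))
        # conservation: foreground = instances + WL; background untouched
        fg = mask.astype(bool)
        assert (((lm.labels > 0) | (lm.labels == WL)) == fg).all()
        assert ms.count_nuclei(lm) == mk.n_nuclei

    def test_marker_monotonicity(self):
        mask, cen = random_disk_scene(3, n_disks=5)
        full = ms.count_nuclei(ms.watershed_segment(ms.build_markers(mask, cen), mask))
        # drop one centroid: count can only go down
        pts = np.argwhere(cen)
        cen2 = cen.copy()
        cen2[tuple(pts[0])] = 0
        fewer = ms.count_nuclei(ms.watershed_segment(ms.build_markers(mask, cen2), mask))
        assert fewer <= full

    def test_count_with_roi(self, small_scene):
        _, _, gt = small_scene
        lm = ms.watershed_segment(ms.build_markers(gt.nuclei_mask, gt.centroid_mask), gt.nuclei_mask)
        total = ms.count_nuclei(lm)
        assert total == gt.nuclei_labels.max()
        inside = ms.count_nuclei(lm, roi_mask=gt.myotube_mask)
        truth_inside = sum(
            gt.myotube_mask[r, c] > 0 for r, c in np.argwhere(gt.centroid_mask)
        )
        assert 0 <= inside <= total
        assert inside == truth_inside
        assert ms.count_nuclei(lm, roi_mask=np.zeros_like(gt.nuclei_mask)) == 0

    @pytest.mark.parametrize("overlap", [0.0, 0.2, 0.4])
    def test_exact_count_up_to_heavy_overlap(self, overlap):
        spec = ms.SceneSpec(height=128, width=128, n_tubes=0, n_nuclei=12,
                            nucleus_radius_range=(3, 6), overlap_fraction=overlap, seed=77)
        _, gt = ms.generate_scene(spec)
        lm = ms.watershed_segment(
            ms.build_markers(gt.nuclei_mask, gt.centroid_mask), gt.nuclei_mask
        )
        assert ms.count_nuclei(lm) == 12


class TestSkeleton:
    def test_empty_and_single_pixel(self):
        assert ms.skeletonize(np.zeros((8, 8))).pixels.sum() == 0
        one = np.zeros((8, 8))
        one[4, 4] = 1
        assert ms.skeletonize(one).pixels[4, 4]

    def test_bar_skeleton_is_middle_row(self):
        bar = np.zeros((9, 35), np.uint8)
        bar[3:6, 2:33] = 1
        sk = ms.skeletonize(bar)
        rows = np.unique(np.argwhere(sk.pixels)[:, 0])
        assert rows.tolist() == [4]
        assert 29 <= sk.pixels.sum() <= 31

    def test_idempotent_and_contained(self, small_scene):
        _, _, gt = small_scene
        sk = ms.skeletonize(gt.myotube_mask)
        assert (sk.pixels & ~gt.myotube_mask.astype(bool)).sum() == 0
        again = ms.skeletonize(sk.pixels)
        assert np.array_equal(again.pixels, sk.pixels)


class TestBranches:
    def test_straight_line(self):
        sk = np.zeros((9, 20), bool)
        sk[4, 2:18] = True
        bs = ms.extract_branches(ms.Skeleton(sk))
        assert len(bs.branches) == 1
        assert len(bs.junctions) == 0 and len(bs.endpoints) == 2

    def test_y_shape_three_branches_one_junction(self):
        # three 15-px arms meeting at one pixel (two diagonals + one vertical)
        sk = np.zeros((40, 40), bool)
        c = (20, 20)
        for i in range(1, 16):
            sk[c[0] - i, c[1] - i] = True
            sk[c[0] - i, c[1] + i] = True
            sk[c[0] + i, c[1]] = True
        sk[c] = True
        bs = ms.extract_branches(ms.Skeleton(sk))
        assert len(bs.junctions) == 1 and tuple(bs.junctions[0]) == c
        assert len(bs.branches) == 3
        assert len(bs.endpoints) == 3
        assert sorted(len(b) for b in bs.branches) == [16, 16, 16]

    def test_ring_single_cyclic_branch(self):
        ring = np.zeros((21, 21), bool)
        for a in np.linspace(0, 2 * np.pi, 400):
            ring[int(round(10 + 7 * np.sin(a))), int(round(10 + 7 * np.cos(a)))] = True
        sk = ms.skeletonize(ring)
        bs = ms.extract_branches(sk)
        assert len(bs.branches) == 1
        assert len(bs.endpoints) == 0
        path = bs.branches[0]
        assert tuple(path[0]) == tuple(path[-1])  # closed

    def test_branch_pixels_cover_skeleton(self, small_scene):
        _, _, gt = small_scene
        sk = ms.skeletonize(gt.myotube_mask)
        bs = ms.extract_branches(sk)
        covered = np.zeros_like(sk.pixels)
        for b in bs.branches:
            covered[b[:, 0], b[:, 1]] = True
        assert np.array_equal(covered, sk.pixels)


class TestMeasurement:
    @pytest.mark.parametrize("width", [5, 7, 9, 11, 15])
    def test_diameter_recovery_straight_tube(self, width):
        mask = straight_tube_mask(width)
        bs = ms.extract_branches(ms.skeletonize(mask))
        path = max(bs.branches, key=len)
        mean_d, prof = ms.measure_diameter(mask, path, junctions=bs.junctions)
        assert abs(mean_d - width) <= 1.0
        assert prof.size > 0

    def test_micron_scaling_halves(self):
        mask = straight_tube_mask(9)
        bs = ms.extract_branches(ms.skeletonize(mask))
        path = max(bs.branches, key=len)
        d1, _ = ms.measure_diameter(mask, path)
        d2, _ = ms.measure_diameter(mask, path, um_per_px=0.5)
        assert d2 == pytest.approx(d1 / 2)

    def test_disk_diameter_near_2r(self):
        r = 9
        rr, cc = np.mgrid[0:32, 0:32]
        disk = ((rr - 16) ** 2 + (cc - 16) ** 2 <= r * r).astype(np.uint8)
        sk = ms.skeletonize(disk)
        path = np.argwhere(sk.pixels)
        d, _ = ms.measure_diameter(disk, path)
        assert abs(d - 2 * r) <= 2.0

    def test_branch_off_mask_rejected(self):
        mask = straight_tube_mask(5)
        with pytest.raises(ValueError, match="mask"):
            ms.measure_diameter(mask, np.array([[0, 0]]))

    def test_length_rules(self):
        horiz = np.array([[5, c] for c in range(3, 13)])
        assert ms.measure_length(horiz) == pytest.approx(9.0)
        diag = np.array([[i, i] for i in range(10)])
        assert ms.measure_length(diag) == pytest.approx(9 * np.sqrt(2))
        ell = np.array([[0, c] for c in range(6)] + [[r, 5] for r in range(1, 6)])
        assert ms.measure_length(ell) == pytest.approx(10.0)
        assert ms.measure_length(ell, um_per_px=2.0) == pytest.approx(20.0)

    def test_unordered_path_rejected(self):
        with pytest.raises(ValueError, match="ordered"):
            ms.measure_length(np.array([[0, 0], [0, 5]]))


class TestQuantifyImage:
    def test_empty_outputs_empty_records(self):
        zeros = np.zeros((64, 64), np.float32)
        assert ms.quantify_image((zeros, zeros, zeros)) == []

    def test_two_disjoint_tubes_two_ids(self):
        mask = np.zeros((64, 96), np.uint8)
        mask[10:17, 5:90] = 1
        mask[40:49, 5:90] = 1
        zeros = np.zeros_like(mask, np.float32)
        recs = ms.quantify_image((mask.astype(np.float32), zeros, zeros))
        assert sorted({r.myotube_id for r in recs}) == [1, 2]

    def test_truth_mask_closure_widths_and_counts(self):
        """Ground-truth masks in -> spec widths and exact nuclei counts out."""
        spec = ms.SceneSpec(height=128, width=128, n_tubes=1, tube_width_range=(9, 9),
                            tube_curvature=0.03, branch_prob=0.0, n_nuclei=8,
                            nucleus_radius_range=(3, 5), overlap_fraction=0.25, seed=21)
        _, gt = ms.generate_scene(spec)
        recs = ms.quantify_image(
            (gt.myotube_mask.astype(np.float32),
             gt.nuclei_mask.astype(np.float32),
             gt.centroid_mask.astype(np.float32)),
            min_object_px=0,
        )
        rollups = [r for r in recs if r.branch_id == -1]
        assert len(rollups) == 1
        assert abs(rollups[0].diameter_um - 9) <= 1.0
        assert sum(r.n_nuclei for r in rollups) == sum(
            gt.myotube_mask[r, c] > 0 for r, c in np.argwhere(gt.centroid_mask)
        )

    def test_short_branches_flagged_and_excluded(self):
        mask = straight_tube_mask(5, shape=(20, 40))
        zeros = np.zeros_like(mask, np.float32)
        recs = ms.quantify_image((mask.astype(np.float32), zeros, zeros), min_branch_px=100)
        branch_rows = [r for r in recs if r.branch_id >= 0]
        assert all(r.short_branch for r in branch_rows)
        rollup = next(r for r in recs if r.branch_id == -1)
        assert np.isnan(rollup.diameter_um)
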