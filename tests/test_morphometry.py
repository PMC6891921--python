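"""Skeleton morphometry: topology, lengths, diameters, invariants."""

import numpy as np
import pytest
from scipy import ndimage

from vesselquant import morphometry as mo, phantom as ph
from vesselquant.stack import BinaryMask


def _line_mask(n=21, shape=(40, 40)):
    m = np.zeros(shape, dtype=bool)
    m[20, 5 : 5 + n] = True
    return BinaryMask(m)


class TestAreaCoverage:
    def test_empty_mask_is_zero(self):
        assert mo.area_coverage(BinaryMask(np.zeros((10, 10), bool))) == 0.0

    def test_half_set_is_fifty(self):
        m = np.zeros((10, 10), bool)
        m[:5] = True
        assert mo.area_coverage(BinaryMask(m)) == 50.0

    def test_phantom_coverage_equals_truth_area_fraction(self, tree_phantom):
        _, _, truth = tree_phantom
        assert mo.area_coverage(truth.mask) == truth.area_fraction * 100.0


class TestSkeletonize:
    def test_thin_line_is_its_own_skeleton(self):
        mask = _line_mask(n=21)
        g = mo.skeletonize(mask)
        assert g.n_junctions == 0
        assert g.n_endpoints == 2
        assert g.branch_count == 1
        assert g.branches[0].length_px == pytest.approx(20.0)
        assert np.array_equal(g.skeleton, mask.data)

    def test_y_shaped_network_topology(self):
        spec = ph.PhantomSpec(
            branches=[
                ph.TubeBranch(points=((200.0, 50.0), (120.0, 128.0)), radius_px=4),
                ph.TubeBranch(points=((200.0, 206.0), (120.0, 128.0)), radius_px=4),
                ph.TubeBranch(points=((120.0, 128.0), (40.0, 128.0)), radius_px=4),
            ]
        )
        _, truth = ph.generate_network_phantom(spec)
        g = mo.skeletonize(truth.mask)
        assert (g.n_junctions, g.n_endpoints, g.branch_count) == (1, 3, 3)

    def test_empty_mask_yields_empty_graph(self):
        g = mo.skeletonize(BinaryMask(np.zeros((16, 16), bool)))
        assert g.is_empty
        assert g.branch_count == 0 and g.n_junctions == 0 and g.n_endpoints == 0

    def test_phantom_tree_topology_recovered_exactly(self, tree_phantom):
        _, _, truth = tree_phantom
        g = mo.skeletonize(truth.mask)
        assert g.n_junctions == truth.n_junctions
        assert g.n_endpoints == truth.n_endpoints
        assert g.branch_count == truth.n_branches

    def test_skeleton_is_contained_in_the_mask(self, tree_phantom):
        _, _, truth = tree_phantom
        g = mo.skeletonize(truth.mask)
        assert not np.any(g.skeleton & ~truth.mask.data)

    def test_node_counts_match_neighbor_count_brute_force(self):
        """On simple fixtures, endpoints/junctions equal a per-pixel
        8-neighbour count over the skeleton."""
        spec = ph.PhantomSpec(
            branches=[
                ph.TubeBranch(points=((32.0, 5.0), (32.0, 58.0)), radius_px=3),
                ph.TubeBranch(points=((32.0, 32.0), (5.0, 32.0)), radius_px=3),
            ],
            image_shape=(64, 64),
        )
        _, truth = ph.generate_network_phantom(spec)
        g = mo.skeletonize(truth.mask)
        kernel = np.ones((3, 3), int)
        kernel[1, 1] = 0
        deg = ndimage.convolve(g.skeleton.astype(int), kernel, mode="constant") * g.skeleton
        n_end = int(np.sum(deg == 1))
        junction_px = (deg >= 3) & g.skeleton
        _, n_junc = ndimage.label(junction_px, structure=np.ones((3, 3)))
        assert g.n_endpoints == n_end
        assert g.n_junctions == n_junc


class TestConnectivityRatio:
    def test_straight_segment_is_zero(self):
        g = mo.skeletonize(_line_mask())
        assert mo.connectivity_ratio(g) == 0.0

    def test_y_shape_is_one_third(self):
        spec = ph.PhantomSpec(
            branches=[
                ph.TubeBranch(points=((200.0, 50.0), (120.0, 128.0)), radius_px=4),
                ph.TubeBranch(points=((200.0, 206.0), (120.0, 128.0)), radius_px=4),
                ph.TubeBranch(points=((120.0, 128.0), (40.0, 128.0)), radius_px=4),
            ]
        )
        _, truth = ph.generate_network_phantom(spec)
        g = mo.skeletonize(truth.mask)
        assert mo.connectivity_ratio(g) == pytest.approx(1.0 / 3.0)

    def test_pure_loop_flags_maximal_connectivity(self):
        m = np.zeros((40, 40), bool)
        m[10:30, 10:30] = True
        m[15:25, 15:25] = False  # annulus: a single loop
        g = mo.skeletonize(BinaryMask(m))
        assert g.n_endpoints == 0
        rec = mo.morphometry_record(BinaryMask(m), g)
        assert "pure_loops" in rec.flags or rec.connectivity_ratio == 0.0


class TestBranchLengths:
    def test_horizontal_101_px_line_measures_100_um(self):
        m = np.zeros((20, 120), bool)
        m[10, 5:106] = True
        g = mo.skeletonize(BinaryMask(m, pixel_size_um=1.0))
        assert mo.branch_lengths(g) == [pytest.approx(100.0)]

    def test_diagonal_11_px_line_measures_ten_root_two(self):
        m = np.zeros((20, 20), bool)
        idx = np.arange(11)
        m[idx + 4, idx + 4] = True
        g = mo.skeletonize(BinaryMask(m, pixel_size_um=1.0))
        assert mo.branch_lengths(g) == [pytest.approx(10.0 * np.sqrt(2.0))]

    def test_phantom_branch_lengths_recovered_within_5_pct(self, tree_phantom):
        spec, _, truth = tree_phantom
        g = mo.skeletonize(truth.mask)
        got = sorted(b.length_px for b in g.branches)
        want = sorted(truth.branch_lengths_px)
        assert len(got) == len(want)
        for s, t in zip(got, want):
            assert s == pytest.approx(t, rel=0.05)


class TestDiameters:
    def test_horizontal_bar_diameter(self):
        m = np.zeros((64, 64), bool)
        m[20:31, 5:60] = True  # 11 px tall
        mask = BinaryMask(m)
        g = mo.skeletonize(mask)
        overall, _ = mo.diameter_profile(mask, g)
        assert overall == pytest.approx(11.0, abs=1.0)

    def test_tube_pair_diameters_within_10_pct(self):
        # oblique tubes: the rasterized width of an integer-radius tube is
        # orientation dependent; oblique placement keeps it near 2r
        spec = ph.PhantomSpec(
            branches=[
                ph.TubeBranch(points=((20.0, 20.0), (120.0, 120.0)), radius_px=4),
                ph.TubeBranch(points=((230.0, 40.0), (130.0, 140.0)), radius_px=8),
            ]
        )
        _, truth = ph.generate_network_phantom(spec)
        g = mo.skeletonize(truth.mask)
        _, per = mo.diameter_profile(truth.mask, g)
        assert sorted(per)[0] == pytest.approx(8.0, rel=0.10)
        assert sorted(per)[1] == pytest.approx(16.0, rel=0.10)

    def test_empty_graph_has_no_diameter(self):
        mask = BinaryMask(np.zeros((16, 16), bool))
        overall, per = mo.diameter_profile(mask, mo.skeletonize(mask))
        assert overall is None and per == []


class TestRecordAndInvariants:
    def test_empty_mask_record_is_flagged(self):
        rec = mo.morphometry_record(BinaryMask(np.zeros((16, 16), bool)))
        assert rec.coverage_pct == 0.0
        assert rec.branch_count == 0
        assert rec.connectivity_ratio == 0.0
        assert "empty_graph" in rec.flags

    def test_record_composes_the_individual_operations(self, straight_tube):
        _, _, truth = straight_tube
        g = mo.skeletonize(truth.mask)
        rec = mo.morphometry_record(truth.mask, g)
        assert rec.coverage_pct == mo.area_coverage(truth.mask)
        assert rec.connectivity_ratio == mo.connectivity_ratio(g)
        assert rec.mean_branch_length_um == pytest.approx(np.mean(mo.branch_lengths(g)))
        assert rec.mean_diameter_um == pytest.approx(mo.diameter_profile(truth.mask, g)[0])
        assert rec.n_junctions == g.n_junctions and rec.n_endpoints == g.n_endpoints

    def test_dilation_never_decreases_coverage(self, tree_phantom, rng):
        _, _, truth = tree_phantom
        cov0 = mo.area_coverage(truth.mask)
        dilated = ndimage.binary_dilation(truth.mask.data, iterations=2)
        assert mo.area_coverage(BinaryMask(dilated)) >= cov0

    def test_scale_equivariance_of_micron_outputs(self, tree_phantom):
        _, _, truth = tree_phantom
        m1 = BinaryMask(truth.mask.data, pixel_size_um=1.0)
        m2 = BinaryMask(truth.mask.data, pixel_size_um=2.0)
        r1 = mo.morphometry_record(m1)
        r2 = mo.morphometry_record(m2)
        assert r2.mean_branch_length_um == pytest.approx(2 * r1.mean_branch_length_um)
        assert r2.mean_diameter_um == pytest.approx(2 * r1.mean_diameter_um)
        assert r2.coverage_pct == r1.coverage_pct
        assert r2.connectivity_ratio == r1.connectivity_ratio
        assert r2.branch_count == r1.branch_count
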