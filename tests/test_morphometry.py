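"""Segmentation, skeleton-graph, and morphology-metric contracts."""

import numpy as np
import pytest

import vasckit as vk
from vasckit.images import RasterImage
from vasckit.synthetic import rasterize_strokes


class TestSegmentation:
    def test_recovers_generator_mask(self, network):
        mask, _ = network
        img = vk.render_fluorescence(mask, blur_sigma=1.0, background=10,
                                     noise_scale=1.0, amplitude=100, seed=0)
        seg = vk.segment_vessels(img, sigma=0.5, outlier_radius=2.0)
        inter = (seg.pixels & mask.pixels).sum()
        union = (seg.pixels | mask.pixels).sum()
        assert inter / union >= 0.95

    def test_constant_image_errors(self):
        with pytest.raises(ValueError, match="gray levels"):
            vk.segment_vessels(RasterImage(np.ones((50, 50)), 1.0))

    def test_degenerate_threshold_names_value(self):
        # a lone hot pixel is flattened by outlier removal, leaving no
        # second gray level for the threshold to separate
        img = np.zeros((60, 60))
        img[30, 30] = 1.0
        with pytest.raises(ValueError, match="threshold"):
            vk.segment_vessels(RasterImage(img, 1.0), sigma=0.0,
                               outlier_radius=2.0)

    def test_salt_noise_robustness(self, network):
        """1% salt pixels change the mask by well under 2% after outlier
        removal."""
        mask, _ = network
        img = vk.render_fluorescence(mask, blur_sigma=1.0, background=10,
                                     noise_scale=1.0, amplitude=100, seed=0)
        seg = vk.segment_vessels(img, sigma=0.5, outlier_radius=2.0)
        rng = np.random.default_rng(7)
        noisy = img.pixels.copy()
        salt = rng.random(noisy.shape) < 0.01
        noisy[salt] = noisy.max() * 10
        seg2 = vk.segment_vessels(RasterImage(noisy, 1.0), sigma=0.5,
                                  outlier_radius=2.0)
        assert (seg.pixels ^ seg2.pixels).mean() < 0.02

    def test_stack_is_max_projected(self, bar):
        img = vk.render_fluorescence(bar, blur_sigma=0.0, noise_scale=0.0)
        from vasckit.images import ImageStack
        stack = ImageStack(np.stack([np.full_like(img.pixels, 10.0),
                                     img.pixels]),
                           img.pixel_size, np.array([0.0, 1.0]))
        seg = vk.segment_vessels(stack, sigma=0.5, outlier_radius=0.0)
        inter = (seg.pixels & bar.pixels).sum()
        union = (seg.pixels | bar.pixels).sum()
        assert inter / union >= 0.95


class TestSkeletonGraph:
    def test_bar_topology_and_length(self, bar, bar_graph):
        assert bar_graph.n_junctions == 0
        assert bar_graph.n_endpoints == 2
        assert bar_graph.n_branches == 1
        assert bar_graph.total_length == pytest.approx(500.0, abs=3.0)

    def test_filled_circle_degenerates(self):
        mask = rasterize_strokes([((100.0, 100.0), (100.0, 100.0))], [60.0],
                                 (200.0, 200.0), 1.0)
        g = vk.skeletonize_network(mask)
        assert g.n_branches == 0
        assert g.total_length == 0.0

    def test_empty_mask_empty_graph(self):
        g = vk.skeletonize_network(RasterImage(np.zeros((40, 40), bool), 1.0))
        assert g.n_branches == 0
        assert g.nodes == []

    def test_plus_sign_single_junction(self):
        segs = [((20.0, 100.0), (180.0, 100.0)), ((100.0, 20.0), (100.0, 180.0))]
        mask = rasterize_strokes(segs, [15.0, 15.0], (200.0, 200.0), 1.0)
        g = vk.skeletonize_network(mask)
        assert g.n_junctions == 1
        assert g.n_endpoints == 4
        assert g.n_branches == 4

    def test_skeleton_subset_of_mask(self, network):
        mask, _ = network
        g = vk.skeletonize_network(mask)
        assert not np.any(g.skeleton & ~mask.pixels)

    def test_spur_pruning(self):
        # long bar with a 6-μm stub: stub pruned at the 10-μm default
        segs = [((20.0, 50.0), (280.0, 50.0)), ((150.0, 50.0), (150.0, 44.0))]
        mask = rasterize_strokes(segs, [10.0, 4.0], (300.0, 100.0), 1.0)
        g = vk.skeletonize_network(mask, prune_length=10.0)
        assert g.n_branches == 1
        g2 = vk.skeletonize_network(mask, prune_length=0.0)
        assert g2.n_branches >= 1  # unpruned graph keeps the stub


class TestMorphologyMetrics:
    def test_bar_effective_diameter(self, bar, bar_graph):
        m = vk.compute_morphology(bar, bar_graph)
        assert m.effective_diameter == pytest.approx(40.0, rel=0.05)

    @pytest.mark.parametrize("width", [10.0, 20.0, 40.0, 60.0, 80.0])
    def test_effective_diameter_width_sweep(self, width):
        """d_eff equals the bar width within 5% for widths ≥ 5 px."""
        mask = vk.bar_mask(500.0, width, pixel_size=1.0, pad=width + 10)
        g = vk.skeletonize_network(mask)
        m = vk.compute_morphology(mask, g)
        assert m.effective_diameter == pytest.approx(width, rel=0.05)

    def test_h_connectivity_exact(self, h_fixture):
        g = vk.skeletonize_network(h_fixture)
        m = vk.compute_morphology(h_fixture, g)
        assert m.connectivity == 0.5
        assert m.connectivity_defined

    def test_empty_mask_metrics(self):
        empty = RasterImage(np.zeros((50, 50), bool), 1.0)
        g = vk.skeletonize_network(empty)
        m = vk.compute_morphology(empty, g)
        assert m.total_vessel_area == 0.0
        assert m.effective_diameter == 0.0
        assert m.area_coverage == 0.0
        assert not m.connectivity_defined
        assert np.isnan(m.connectivity)

    def test_loop_has_no_endpoints_connectivity_undefined(self):
        segs = [((50.0, 50.0), (150.0, 50.0)), ((150.0, 50.0), (150.0, 150.0)),
                ((150.0, 150.0), (50.0, 150.0)), ((50.0, 150.0), (50.0, 50.0))]
        mask = rasterize_strokes(segs, [12.0] * 4, (200.0, 200.0), 1.0)
        g = vk.skeletonize_network(mask)
        m = vk.compute_morphology(mask, g)
        assert g.n_endpoints == 0
        assert not m.connectivity_defined

    def test_upsampling_invariance(self):
        """Physical-unit metrics stable (±5%) under 2× finer sampling."""
        coarse = vk.h_mask(pixel_size=1.0)
        fine = vk.h_mask(pixel_size=0.5)
        mc = vk.compute_morphology(coarse, vk.skeletonize_network(coarse))
        mf = vk.compute_morphology(fine, vk.skeletonize_network(fine))
        assert mf.effective_diameter == pytest.approx(mc.effective_diameter,
                                                      rel=0.05)
        assert mf.total_skeleton_length == pytest.approx(
            mc.total_skeleton_length, rel=0.05)
        assert mf.area_coverage == pytest.approx(mc.area_coverage, rel=0.05)

    @pytest.mark.parametrize("angle_deg, branch_tol", [(90, 0), (45, 1)])
    def test_rotation_invariance(self, angle_deg, branch_tol):
        """Connectivity and branch counts survive rotation of the scene."""
        th = np.deg2rad(angle_deg)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        ctr = np.array([300.0, 300.0])

        def rot(p):
            return tuple(ctr + R @ (np.asarray(p) - ctr))

        base = [((180.0, 100.0), (180.0, 500.0)),
                ((420.0, 100.0), (420.0, 500.0)),
                ((180.0, 300.0), (420.0, 300.0))]
        m0 = rasterize_strokes(base, [20.0] * 3, (600.0, 600.0), 1.0)
        mr = rasterize_strokes([(rot(p), rot(q)) for p, q in base],
                               [20.0] * 3, (600.0, 600.0), 1.0)
        g0 = vk.skeletonize_network(m0)
        gr = vk.skeletonize_network(mr)
        assert gr.n_junctions == g0.n_junctions
        assert gr.n_endpoints == g0.n_endpoints
        assert abs(gr.n_branches - g0.n_branches) <= branch_tol


class TestPerfusedFraction:
    def test_full_overlap(self, bar):
        assert vk.compute_perfused_fraction(bar, bar) == 100.0

    def test_disjoint_is_zero(self, bar):
        shifted = RasterImage(np.roll(bar.pixels, 40, axis=0), 1.0)
        assert vk.compute_perfused_fraction(bar, shifted) == 0.0

    def test_half_overlap(self):
        v = np.zeros((10, 10), bool)
        v[:, :4] = True
        d = np.zeros((10, 10), bool)
        d[:5, :] = True
        frac = vk.compute_perfused_fraction(RasterImage(v, 1.0),
                                            RasterImage(d, 1.0))
        assert frac == 50.0

    def test_empty_vessel_errors(self):
        empty = RasterImage(np.zeros((10, 10), bool), 1.0)
        with pytest.raises(ValueError, match="empty"):
            vk.compute_perfused_fraction(empty, empty)


class TestMatrixIntensity:
    def test_uniform_stain_closed_form(self, bar):
        c = 3.5
        stain = RasterImage(np.full(bar.shape, c), 1.0)
        got = vk.measure_matrix_intensity(stain, bar)
        area = bar.pixels.sum() * bar.pixel_area
        assert got == pytest.approx(c * stain.pixels.size / area)

    def test_linearity_and_zero(self, bar):
        rng = np.random.default_rng(0)
        stain = RasterImage(rng.random(bar.shape), 1.0)
        one = vk.measure_matrix_intensity(stain, bar)
        two = vk.measure_matrix_intensity(
            RasterImage(2 * stain.pixels, 1.0), bar)
        assert two == pytest.approx(2 * one)
        zero = vk.measure_matrix_intensity(
            RasterImage(np.zeros(bar.shape), 1.0), bar)
        assert zero == 0.0

    def test_zero_vessel_area_errors(self, bar):
        empty = RasterImage(np.zeros(bar.shape, bool), 1.0)
        stain = RasterImage(np.ones(bar.shape), 1.0)
        with pytest.raises(ValueError, match="vessel area"):
            vk.measure_matrix_intensity(stain, empty)
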