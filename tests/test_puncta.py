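import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from cochleaquant import puncta
from cochleaquant.thresholds import ThresholdConfig

from _oracles import flood_fill_components


def full_roi(shape):
    return puncta.Roi2D(cell_id=1, mask=np.ones(shape, dtype=bool))


class TestMaxProjection:
    def test_single_slice_identity(self, rng):
        grid = rng.random((1, 8, 9))
        assert np.array_equal(puncta.max_projection(grid), grid[0])

    def test_all_zero(self):
        assert not puncta.max_projection(np.zeros((4, 5, 5))).any()

    def test_single_voxel_lands_at_its_xy(self):
        grid = np.zeros((6, 10, 12))
        grid[3, 4, 7] = 7
        proj = puncta.max_projection(grid)
        assert proj[4, 7] == 7 and proj.sum() == 7

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            puncta.max_projection(np.zeros((0, 4, 4)))


class TestBinarize:
    def test_constant_image_yields_empty_mask(self):
        img = np.full((16, 16), 3.0)
        for method in ("robust_background", "otsu"):
            mask = puncta.binarize(img, ThresholdConfig(method=method))
            assert not mask.any()

    @pytest.mark.parametrize("method", ["robust_background", "otsu"])
    def test_two_level_image_selects_bright_pixels(self, method):
        img = np.zeros((20, 20))
        img[5:8, 5:8] = 100.0
        mask = puncta.binarize(img, ThresholdConfig(method=method))
        assert np.array_equal(mask, img == 100.0)

    def test_threshold_recorded_in_provenance(self, rng):
        prov = {}
        puncta.binarize(rng.random((10, 10)), provenance=prov, key="t")
        assert "t" in prov and "value" in prov["t"]

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            ThresholdConfig(method="magic")

    @given(
        img=hnp.arrays(
            float,
            (12, 12),
            elements=st.floats(0, 100, allow_nan=False),
        ),
        k_lo=st.floats(0.5, 3.0),
        k_hi=st.floats(3.5, 8.0),
    )
    @settings(max_examples=40, deadline=None)
    def test_raising_threshold_never_grows_foreground(self, img, k_lo, k_hi):
        lo = puncta.binarize(img, ThresholdConfig(k=k_lo))
        hi = puncta.binarize(img, ThresholdConfig(k=k_hi))
        assert hi.sum() <= lo.sum()

    def test_foreground_fraction_tracks_planted_footprint(self, small_field, default_psf):
        # the binarized footprint should match the planted rasterization
        # pushed through the same blur and the same threshold, noise-free
        from cochleaquant._fft import ReflectConvolver
        from cochleaquant.synth import VOLUMETRIC_VOXELS, default_field_shape, rasterize_puncta
        from cochleaquant.synth.imaging import CHANNEL_AMPLITUDES

        from skimage.measure import label as sk_label

        gt, stack = small_field
        proj = puncta.max_projection(stack.channels["ribbon"])
        prov = {}
        mask = puncta.binarize(proj, provenance=prov, key="t")
        # drop sub-particle noise speckle, as the counting stage does
        lab = sk_label(mask, connectivity=2)
        areas = np.bincount(lab.ravel())
        keep = np.flatnonzero(areas >= 4)
        frac_measured = np.isin(lab, keep[keep > 0]).mean()
        shape = default_field_shape(5, VOLUMETRIC_VOXELS, gt.geometry)
        truth = rasterize_puncta(
            gt, "ribbon", shape, VOLUMETRIC_VOXELS,
            amplitude=CHANNEL_AMPLITUDES["ribbon"],
        )
        conv = ReflectConvolver(shape, default_psf.kernel, default_psf.profiles)
        # baseline of the measured projection (background plus the upward
        # bias of max-projecting noise) anchors the noise-free analog
        blurred_proj = puncta.max_projection(conv.convolve(truth)) + np.median(proj)
        frac_truth = (blurred_proj > prov["t"]["value"]).mean()
        assert frac_measured == pytest.approx(frac_truth, rel=0.2)


class TestProductImage:
    def test_zero_annihilates(self, rng):
        a = rng.random((6, 6))
        assert not puncta.product_image(a, np.zeros_like(a)).any()

    def test_ones_identity(self, rng):
        a = rng.random((6, 6))
        assert np.allclose(puncta.product_image(a, np.ones_like(a)), a)

    def test_wide_accumulation_no_overflow(self):
        a = np.full((4, 4), 255, dtype=np.uint8)
        prod = puncta.product_image(a, a)
        assert prod.max() == 65025

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            puncta.product_image(np.zeros((3, 3)), np.zeros((4, 3)))


class TestCountParticles:
    def test_empty_mask_counts_zero(self):
        assert puncta.count_particles(np.zeros((10, 10), bool), full_roi((10, 10))) == 0

    def test_three_blobs_counted(self):
        mask = np.zeros((20, 20), bool)
        for r, c in [(2, 2), (10, 10), (16, 4)]:
            mask[r : r + 2, c : c + 2] = True
        assert puncta.count_particles(mask, full_roi((20, 20)), min_area_px=1) == 3

    def test_min_area_gate(self):
        mask = np.zeros((10, 10), bool)
        mask[1, 1] = True  # 1 px
        mask[5:7, 5:7] = True  # 4 px
        assert puncta.count_particles(mask, full_roi((10, 10)), min_area_px=4) == 1

    def test_centroid_membership_assigns_to_one_roi(self):
        mask = np.zeros((10, 20), bool)
        mask[4:6, 8:12] = True  # centroid at column ~9.5
        left = puncta.Roi2D(1, np.arange(20)[None, :].repeat(10, 0) < 10)
        right = puncta.Roi2D(2, ~left.mask)
        counts = [
            puncta.count_particles(mask, roi, min_area_px=1) for roi in (left, right)
        ]
        assert sorted(counts) == [0, 1]

    @given(
        mask=hnp.arrays(bool, (24, 24), elements=st.booleans()),
    )
    @settings(max_examples=50, deadline=None)
    def test_matches_flood_fill_oracle(self, mask):
        ours = puncta.count_particles(mask, full_roi(mask.shape), min_area_px=1)
        assert ours == len(flood_fill_components(mask))


class TestDeriveRois:
    def test_external_passthrough(self):
        labels = np.zeros((30, 30), int)
        for i in range(1, 13):
            labels[(i - 1) // 4 * 8 : (i - 1) // 4 * 8 + 4, (i - 1) % 4 * 6 : (i - 1) % 4 * 6 + 4] = i
        rois = puncta.derive_rois(np.zeros((30, 30)), mode="external", roi_source=labels)
        assert [r.cell_id for r in rois] == list(range(1, 13))

    def test_blank_cell_channel_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            rois = puncta.derive_rois(np.zeros((40, 40)))
        assert rois == []

    def test_auto_rois_capture_planted_cells(self, small_field):
        gt, stack = small_field
        rois = puncta.derive_rois(puncta.max_projection(stack.channels["cell"]))
        assert len(rois) == len(gt.cells)
        dx = stack.voxel_dims[0]
        for cell in gt.cells:
            cx, cy = cell.center_um
            iy, ix = int(cy / dx), int(cx / dx)
            assert sum(roi.mask[iy, ix] for roi in rois) == 1

    def test_rois_mutually_disjoint(self, small_field):
        _, stack = small_field
        rois = puncta.derive_rois(puncta.max_projection(stack.channels["cell"]))
        total = np.zeros(rois[0].mask.shape, int)
        for roi in rois:
            total += roi.mask
        assert total.max() == 1


class TestCountSynapses:
    def test_zero_receptor_channel_kills_colocalization(self, small_field):
        gt, stack = small_field
        dark = dict(stack.channels)
        dark["receptor"] = np.zeros_like(dark["receptor"])
        from cochleaquant.stack import ConfocalStack

        s2 = ConfocalStack(channels=dark, voxel_dims=stack.voxel_dims)
        rois = puncta.derive_rois(puncta.max_projection(s2.channels["cell"]))
        records, _ = puncta.count_synapses(s2, rois)
        assert all(r.n_colocalized == 0 for r in records)

    def test_counts_invariant_to_global_intensity_scale(self, small_field):
        _, stack = small_field
        from cochleaquant.stack import ConfocalStack

        s2 = ConfocalStack(
            channels={ch: 2.0 * g for ch, g in stack.channels.items()},
            voxel_dims=stack.voxel_dims,
        )
        rois = puncta.derive_rois(puncta.max_projection(stack.channels["cell"]))
        a, _ = puncta.count_synapses(stack, rois)
        b, _ = puncta.count_synapses(s2, rois)
        assert a == b

    def test_recovers_planted_counts(self, small_field):
        gt, stack = small_field
        rois = puncta.derive_rois(puncta.max_projection(stack.channels["cell"]))
        records, prov = puncta.count_synapses(stack, rois)
        mean_c = np.mean([r.n_colocalized for r in records])
        assert 15.0 <= mean_c <= 17.0
        assert "ribbon_threshold" in prov and "product_threshold" in prov

    def test_colocalization_bound(self, small_field):
        _, stack = small_field
        rois = puncta.derive_rois(puncta.max_projection(stack.channels["cell"]))
        records, prov = puncta.count_synapses(stack, rois)
        slack = prov["colocalized_multiblob_particles"]
        for r in records:
            assert r.n_colocalized <= min(r.n_ribbon, r.n_receptor) + slack

    def test_empty_roi_list_rejected(self, small_field):
        _, stack = small_field
        with pytest.raises(ValueError):
            puncta.count_synapses(stack, [])
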