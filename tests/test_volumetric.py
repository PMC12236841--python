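import math

import numpy as np
import pytest

from cochleaquant import volumetric as vol
from cochleaquant.psf import make_psf
from cochleaquant.synth import (
    NoiseModel,
    VOLUMETRIC_VOXELS,
    plant_ground_truth,
    render_stack,
)

from _oracles import flood_fill_components

VOX = VOLUMETRIC_VOXELS


def make_blob(grid, z, y, x, dz, dy, dx):
    grid[z : z + dz, y : y + dy, x : x + dx] = 50.0


class TestRichardsonLucy:
    def test_delta_psf_is_identity(self, rng):
        img = rng.random((6, 8, 8)) + 0.5
        delta = make_psf(0.11, 0.2, VOX, truncate=0.0)
        out = vol.richardson_lucy(img, delta, n_iter=7)
        assert np.allclose(out, img)

    def test_zero_iterations_returns_input(self, default_psf, rng):
        img = rng.random((20, 24, 24))
        assert np.array_equal(vol.richardson_lucy(img, default_psf, 0), img)

    def test_uniform_image_is_fixed_point(self, default_psf):
        img = np.full((20, 24, 24), 3.7)
        out = vol.richardson_lucy(img, default_psf, 10)
        assert np.allclose(out, img, rtol=1e-9)

    def test_deconvolution_sharpens_point_source(self, default_psf):
        from cochleaquant._fft import ReflectConvolver

        img = np.zeros((24, 32, 32))
        img[12, 16, 16] = 1000.0
        conv = ReflectConvolver(img.shape, default_psf.kernel, default_psf.profiles)
        blurred = conv.convolve(img) + 1.0

        def fwhm(profile):
            half = profile.max() / 2
            return (profile > half).sum()

        restored = vol.richardson_lucy(blurred, default_psf, 10)
        assert fwhm(restored[12, 16, :]) < fwhm(blurred[12, 16, :])
        assert np.all(restored >= 0)

    def test_flux_conservation_interior_supported(self, default_psf):
        img = np.zeros((26, 30, 30))
        make_blob(img, 10, 12, 12, 5, 6, 6)
        img += 2.0  # uniform pedestal keeps RL well-defined everywhere
        total = img.sum()
        u = img.copy()
        for _ in range(5):
            u = vol.richardson_lucy(u, default_psf, 1)
            assert u.sum() == pytest.approx(total, rel=1e-3)

    def test_oversized_psf_rejected(self, default_psf):
        with pytest.raises(ValueError):
            vol.richardson_lucy(np.ones((4, 4, 4)), default_psf, 1)

    def test_matches_reference_implementation_at_convergence(self, default_psf):
        # cross-check against the independent skimage implementation on a
        # noise-free interior-supported image; the two differ in starting
        # point (data vs constant) and boundary handling, so agreement is
        # asserted near convergence
        from skimage.restoration import richardson_lucy as sk_rl
        from cochleaquant._fft import ReflectConvolver

        img = np.zeros((48, 40, 40))
        make_blob(img, 22, 18, 18, 4, 5, 5)
        conv = ReflectConvolver(img.shape, default_psf.kernel, default_psf.profiles)
        blurred = conv.convolve(img) + 1e-6
        ours = vol.richardson_lucy(blurred, default_psf, 25)
        theirs = sk_rl(blurred, default_psf.kernel, num_iter=25, clip=False)
        assert np.max(np.abs(ours - theirs)) / theirs.max() < 0.05
        assert ours.sum() == pytest.approx(theirs.sum(), rel=1e-3)


class TestSegmentObjects:
    def _plain_cfg(self, **kw):
        defaults = dict(voxel_dims=VOX, refine="none")
        defaults.update(kw)
        return vol.SegmentationConfig(**defaults)

    def test_voxel_gate_drops_small_and_oversized(self):
        grid = np.zeros((10, 40, 40))
        grid[2, 2, 2:21] = 50.0  # 19 voxels -> below gate
        grid[5, 10:15, 10:15] = 50.0  # 25 voxels -> inside gate
        objs = vol.segment_objects(grid, self._plain_cfg())
        assert len(objs) == 1 and objs[0].n_vox == 25

    def test_upper_gate_excludes_huge_blob(self):
        grid = np.zeros((15, 40, 40))
        grid[2:11, 5:20, 5:20] = 50.0  # 2025 voxels
        assert vol.segment_objects(grid, self._plain_cfg()) == []

    def test_labels_deterministic_and_sorted(self):
        grid = np.zeros((10, 30, 30))
        make_blob(grid, 6, 20, 20, 2, 4, 4)
        make_blob(grid, 1, 2, 2, 2, 4, 4)
        objs = vol.segment_objects(grid, self._plain_cfg())
        assert [o.label for o in objs] == [1, 2]
        assert objs[0].voxels[:, 0].min() < objs[1].voxels[:, 0].min()

    def test_partition_matches_flood_fill_oracle(self, rng):
        for _ in range(10):
            mask = rng.random((12, 16, 16)) < 0.25
            grid = mask.astype(float)
            objs = vol.segment_objects(
                grid, self._plain_cfg(size_min_vox=1, size_max_vox=10**6)
            )
            ours = {frozenset(map(tuple, o.voxels)) for o in objs}
            oracle = {frozenset(c) for c in flood_fill_components(mask)}
            assert ours == oracle

    def test_connectivity_6_splits_diagonal_touch(self):
        grid = np.zeros((6, 10, 10))
        grid[1, 1:4, 1:4] = 9.0
        grid[2, 4, 4] = 9.0  # touches only diagonally
        c26 = vol.segment_objects(
            grid, self._plain_cfg(size_min_vox=1, size_max_vox=100, connectivity=26)
        )
        c6 = vol.segment_objects(
            grid, self._plain_cfg(size_min_vox=1, size_max_vox=100, connectivity=6)
        )
        assert len(c26) == 1 and len(c6) == 2

    def test_border_and_resolution_flags(self):
        grid = np.zeros((8, 20, 20))
        grid[0, 0:5, 0:5] = 9.0  # touches border, 1 voxel thick in z
        objs = vol.segment_objects(
            grid, self._plain_cfg(size_min_vox=1, size_max_vox=100)
        )
        assert objs[0].touches_border and objs[0].below_resolution

    def test_model_refine_requires_psf(self):
        with pytest.raises(ValueError):
            vol.segment_objects(np.ones((6, 6, 6)), vol.SegmentationConfig(voxel_dims=VOX))

    def test_gate_bounds_validated(self):
        with pytest.raises(ValueError):
            vol.SegmentationConfig(size_min_vox=100, size_max_vox=50)


class TestObjectVolume:
    @pytest.mark.parametrize(
        "n,vox,expected",
        [
            (20, (0.11, 0.11, 0.2), 0.0484),
            (2000, (0.11, 0.11, 0.2), 4.84),
            (1, (1.0, 1.0, 1.0), 1.0),
        ],
    )
    def test_volume_arithmetic(self, n, vox, expected):
        assert vol.object_volume(n, vox) == pytest.approx(expected)

    def test_nonpositive_count_rejected(self):
        with pytest.raises(ValueError):
            vol.object_volume(0, VOX)


def _obj(label, coords, channel="ribbon"):
    coords = np.asarray(coords)
    n = coords.shape[0]
    cz, cy, cx = coords.mean(axis=0)
    return vol.Object3D(
        label=label,
        voxels=coords,
        n_vox=n,
        volume_um3=vol.object_volume(n, VOX),
        centroid_um=((cx + 0.5) * VOX[0], (cy + 0.5) * VOX[1], (cz + 0.5) * VOX[2]),
        channel=channel,
    )


class TestPairSynapses:
    def test_overlapping_objects_pair(self):
        r = _obj(1, [(1, 1, 1), (1, 1, 2), (1, 2, 1), (1, 2, 2), (2, 1, 1)])
        g = _obj(1, [(1, 1, 2), (1, 2, 2), (1, 2, 1), (2, 1, 1), (1, 1, 1)], "receptor")
        res = vol.pair_synapses([r], [g])
        assert len(res.pairs) == 1 and res.pairs[0].overlap_vox == 5

    def test_distant_objects_stay_orphans(self):
        r = _obj(1, [(1, 1, 1)])
        g = _obj(1, [(1, 28, 28)], "receptor")  # ~3 um away laterally
        res = vol.pair_synapses([r], [g], vol.PairingConfig(radius_um=1.0))
        assert res.pairs == () and len(res.orphan_ribbons) == 1

    def test_one_to_one_matching(self):
        r1 = _obj(1, [(1, 1, 1), (1, 1, 2)])
        g1 = _obj(1, [(1, 1, 2), (1, 1, 3)], "receptor")
        g2 = _obj(2, [(1, 2, 1)], "receptor")
        res = vol.pair_synapses([r1], [g1, g2])
        assert len(res.pairs) == 1
        assert res.pairs[0].receptor is g1
        assert res.orphan_receptors == (g2,)

    def test_planted_pair_recovery_with_orphans(self, default_psf):
        gt = plant_ground_truth(
            n_cells=5, pairs_per_cell=10, orphan_rate=(0.2, 0.2), seed=77
        )
        stack = render_stack(gt, default_psf, NoiseModel(), VOX, seed=77)
        objs = {}
        for ch in ("ribbon", "receptor"):
            dec = vol.richardson_lucy(stack.channels[ch], default_psf, 10)
            objs[ch] = vol.segment_objects(
                dec, vol.SegmentationConfig(voxel_dims=VOX), ch, psf=default_psf
            )
        res = vol.pair_synapses(objs["ribbon"], objs["receptor"])
        planted = {p.pair_id: p for p in gt.puncta if p.channel == "ribbon" and p.pair_id}
        recovered = set()
        for sp in res.pairs:
            pid, pr = min(
                planted.items(),
                key=lambda kv: math.dist(kv[1].center_um, sp.ribbon.centroid_um),
            )
            if math.dist(pr.center_um, sp.ribbon.centroid_um) <= 0.5:
                recovered.add(pid)
        assert len(recovered) >= 0.95 * len(planted)
        # orphans should not be press-ganged into pairs: pair count cannot
        # exceed the planted pairing
        assert len(res.pairs) <= len(planted) + 2
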