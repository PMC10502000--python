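"""Normalization, unit conversion, resizing and augmentation contracts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gutgaze.preprocessing import (
    AugmentParams,
    TrainingSample,
    augment,
    diameter_to_voxels,
    make_weights,
    resize_for_model,
    voxels_to_mm,
    window_normalize,
)
from gutgaze.reconstruction import DiameterMap, VolumeGrid


class TestWindowNormalize:
    @pytest.mark.parametrize(
        "hu,expected",
        [(40.0, 0.0), (240.0, 1.0), (-160.0, -1.0), (1000.0, 1.0), (-2000.0, -1.0)],
    )
    def test_soft_tissue_window(self, hu, expected):
        assert window_normalize(np.array([hu]))[0] == pytest.approx(expected)

    @given(st.floats(-2000, 3000), st.floats(-2000, 3000))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_hu(self, a, b):
        lo, hi = sorted((a, b))
        va, vb = window_normalize(np.array([lo, hi]))
        assert va <= vb + 1e-12

    def test_bad_window_rejected(self):
        with pytest.raises(ValueError):
            window_normalize(np.zeros(3), window=0.0)


class TestDiameterUnits:
    def test_mm_to_voxels_at_typical_spacing(self):
        grid = VolumeGrid((4, 4, 4), (0.75, 0.75, 3.72))
        diam = DiameterMap(grid, np.full((4, 4, 4), 30.0), units="mm")
        vox = diameter_to_voxels(diam)
        assert vox.units == "voxels"
        assert np.allclose(vox.values, 40.0)

    def test_zero_stays_zero_and_roundtrip(self):
        grid = VolumeGrid((3, 3, 3), (0.6, 0.6, 2.0))
        values = np.zeros((3, 3, 3))
        values[1, 1, 1] = 17.3
        diam = DiameterMap(grid, values, units="mm")
        back = voxels_to_mm(diameter_to_voxels(diam))
        assert np.allclose(back.values, values, atol=1e-9)

    def test_anisotropic_in_plane_rejected(self):
        grid = VolumeGrid((3, 3, 3), (0.6, 0.8, 2.0))
        diam = DiameterMap(grid, np.zeros((3, 3, 3)), units="mm")
        with pytest.raises(ValueError):
            diameter_to_voxels(diam)


def _sample(shape, rng=None, grid=None):
    rng = rng or np.random.default_rng(0)
    labels = (rng.random(shape) > 0.8).astype(np.uint8) * rng.integers(1, 4, shape).astype(
        np.uint8
    )
    diam = np.where(labels > 0, rng.uniform(5, 30, shape), 0.0)
    return TrainingSample(
        np.clip(rng.normal(0, 0.4, shape), -1, 1),
        labels,
        diam,
        make_weights(labels),
        grid=grid,
    )


class TestResize:
    def test_constant_slice_stays_constant(self):
        sample = TrainingSample(
            np.full((512, 512), 0.5), np.zeros((512, 512), np.uint8),
            np.zeros((512, 512)), np.ones((512, 512)),
        )
        out = resize_for_model(sample, (256, 256))
        assert out.image.shape == (256, 256)
        assert np.allclose(out.image, 0.5)

    def test_3d_path_pads_then_decimates(self):
        # 100 slices -> zero padded to 128 -> decimated by 2 to 64
        sample = _sample((96, 96, 100))
        out = resize_for_model(sample, (48, 48, 64))
        assert out.image.shape == (48, 48, 64)

    def test_labels_never_gain_codes(self, rng):
        sample = _sample((64, 64, 20), rng)
        sample.labels3[sample.labels3 == 2] = 0  # remove midgut entirely
        out = resize_for_model(sample, (32, 32, 10))
        assert set(np.unique(out.labels3)) <= set(np.unique(sample.labels3))

    def test_diameter_values_unchanged_by_resize(self, rng):
        sample = _sample((64, 64, 8), rng)
        out = resize_for_model(sample, (32, 32, 8))
        assert set(np.unique(out.diam_vox)) <= set(np.unique(sample.diam_vox))


class TestAugment:
    GRID = VolumeGrid((32, 32, 16), (1.0, 1.0, 3.0))

    def test_identity_is_noop(self, rng):
        sample = _sample(self.GRID.shape, rng, self.GRID)
        out = augment(sample, AugmentParams(), self.GRID)
        assert (out.image == sample.image).all()
        assert (out.labels3 == sample.labels3).all()
        assert (out.diam_vox == sample.diam_vox).all()

    def test_magnification_scales_diameters_exactly(self, rng):
        sample = _sample(self.GRID.shape, rng, self.GRID)
        params = AugmentParams(magnification=1.2)
        out = augment(sample, params, self.GRID)
        nz = out.diam_vox > 0
        assert nz.any()
        # nearest-neighbour resampling carries original values, then scales by m
        source_values = set(np.round(sample.diam_vox[sample.diam_vox > 0] * 1.2, 9))
        assert set(np.round(out.diam_vox[nz], 9)) <= source_values

    def test_magnification_roundtrip_restores_diameters(self, rng):
        sample = _sample(self.GRID.shape, rng, self.GRID)
        up = augment(sample, AugmentParams(magnification=1.25), self.GRID)
        down = augment(up, AugmentParams(magnification=0.8), self.GRID)
        nz = (down.diam_vox > 0) & (sample.diam_vox > 0)
        assert nz.any()
        surviving = set(np.round(down.diam_vox[nz], 6))
        original = set(np.round(sample.diam_vox[sample.diam_vox > 0], 6))
        assert surviving <= original

    def test_rotation_preserves_shape_on_anisotropic_grid(self):
        """A sphere stays a sphere under 30 deg rotation despite 1x1x3 voxels."""
        grid = VolumeGrid((64, 64, 32), (1.0, 1.0, 3.0))
        px, py, pz = grid.voxel_center_components()
        center = np.array([31.5, 31.5, 46.5])
        offset_center = center + np.array([12.0, 5.0, 0.0])
        r = 15.0
        sphere = (
            (px - offset_center[0]) ** 2
            + (py - offset_center[1]) ** 2
            + (pz - offset_center[2]) ** 2
        ) <= r**2
        sample = TrainingSample(
            np.zeros(grid.shape), sphere.astype(np.uint8),
            np.where(sphere, 10.0, 0.0), np.ones(grid.shape),
        )
        params = AugmentParams(rotation=(0.0, 0.0, 30.0))
        out = augment(sample, params, grid)
        # analytic oracle: the sphere's center rotates about the volume center
        th = np.radians(30.0)
        Rz = np.array(
            [[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]]
        )
        new_center = center + Rz @ (offset_center - center)
        expected = (
            (px - new_center[0]) ** 2
            + (py - new_center[1]) ** 2
            + (pz - new_center[2]) ** 2
        ) <= r**2
        from gutgaze.agreement import dice

        assert dice(out.labels3 > 0, expected) >= 0.95

    def test_out_of_range_params_rejected(self):
        with pytest.raises(ValueError):
            AugmentParams(translation=(40.0, 0.0))
        with pytest.raises(ValueError):
            AugmentParams(magnification=1.5)

    def test_random_params_reproducible(self):
        assert AugmentParams.random(99) == AugmentParams.random(99)


class TestWeights:
    def test_background_only_gives_ones(self):
        assert (make_weights(np.zeros((5, 5), np.uint8)) == 1.0).all()

    def test_single_foreground_voxel(self):
        labels = np.zeros((4, 4), np.uint8)
        labels[2, 1] = 3
        w = make_weights(labels, 10.0)
        assert w[2, 1] == 10.0
        assert w.sum() == pytest.approx(15 + 10)

    def test_mean_weight_closed_form(self, rng):
        labels = (rng.random((30, 30, 10)) > 0.7).astype(np.uint8)
        for fw in (2.0, 10.0):
            w = make_weights(labels, fw)
            frac = (labels > 0).mean()
            assert w.mean() == pytest.approx(1 + (fw - 1) * frac)

    def test_subunit_weight_rejected(self):
        with pytest.raises(ValueError):
            make_weights(np.zeros((2, 2)), 0.5)
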