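import numpy as np
import pytest

from mtef.defield import (DisplacementField, compose,
                          jacobian_nonpositive_fraction, read_field,
                          resize_field, upsample_field, warp, write_field)
from mtef.volio import LabelMap, Volume


def constant_field(shape, vec):
    u = np.zeros((3, *shape))
    for c in range(3):
        u[c] = vec[c]
    return DisplacementField(u)


class TestWarp:
    @pytest.mark.parametrize("interp", ["trilinear", "nearest"])
    def test_zero_field_is_identity(self, rng, interp):
        vol = Volume(rng.random((8, 8, 8)))
        out = warp(vol, DisplacementField.zeros(vol.shape), interp)
        np.testing.assert_allclose(out.data, vol.data, atol=1e-12)

    def test_unit_translation_matches_index_shift(self, rng):
        data = rng.integers(0, 100, (8, 8, 8)).astype(float)
        out = warp(Volume(data), constant_field((8, 8, 8), (1, 0, 0)))
        # out(x) = in(x+1) for interior x
        np.testing.assert_allclose(out.data[:-1], data[1:], atol=1e-9)

    def test_label_warp_invents_no_labels(self, rng):
        lab = LabelMap(rng.integers(0, 4, (8, 8, 8)))
        u = DisplacementField(rng.normal(0, 2, (3, 8, 8, 8)))
        out = warp(lab, u)
        assert set(np.unique(out.data)) <= set(np.unique(lab.data))

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            warp(Volume(np.ones((4, 4, 4))), DisplacementField.zeros((5, 4, 4)))


class TestCompose:
    def test_identity_inner(self, rng):
        outer = DisplacementField(rng.normal(0, 1, (3, 6, 6, 6)))
        res = compose(outer, DisplacementField.zeros((6, 6, 6)))
        np.testing.assert_allclose(res.vectors, outer.vectors, atol=1e-12)

    def test_identity_outer(self, rng):
        inner = DisplacementField(rng.normal(0, 1, (3, 6, 6, 6)))
        res = compose(DisplacementField.zeros((6, 6, 6)), inner)
        np.testing.assert_allclose(res.vectors, inner.vectors, atol=1e-12)

    def test_constant_translations_add(self):
        ta, tb = (1.0, -0.5, 0.25), (0.5, 1.0, 0.0)
        a = constant_field((8, 8, 8), ta)
        b = constant_field((8, 8, 8), tb)
        res = compose(a, b)
        for c in range(3):
            np.testing.assert_allclose(res.vectors[c], ta[c] + tb[c], atol=1e-9)

    def test_compose_equals_sequential_warps(self, rng):
        # smooth fields: warp(warp(img, inner), outer) ≈ warp(img, compose)
        from scipy.ndimage import gaussian_filter

        img = Volume(gaussian_filter(rng.random((16, 16, 16)), 2.0))
        mk = lambda: DisplacementField(np.stack([
            gaussian_filter(rng.normal(0, 1.0, (16, 16, 16)), 4.0) * 4
            for _ in range(3)
        ]))
        inner, outer = mk(), mk()
        two_step = warp(warp(img, outer), inner)
        one_step = warp(img, compose(outer, inner))
        err = np.abs(two_step.data - one_step.data)[2:-2, 2:-2, 2:-2].max()
        assert err < 5e-2

    def test_associativity_on_smooth_fields(self, rng):
        from scipy.ndimage import gaussian_filter

        mk = lambda: DisplacementField(np.stack([
            gaussian_filter(rng.normal(0, 1.0, (12, 12, 12)), 4.0) * 3
            for _ in range(3)
        ]))
        a, b, c = mk(), mk(), mk()
        left = compose(compose(a, b), c)
        right = compose(a, compose(b, c))
        interior = (slice(None), slice(2, -2), slice(2, -2), slice(2, -2))
        assert np.abs(left.vectors - right.vectors)[interior].max() < 1e-3


class TestUpsample:
    def test_constant_field_doubles(self):
        f = constant_field((4, 4, 4), (0.5, -1.0, 2.0))
        up = upsample_field(f, 2)
        assert up.grid_shape == (8, 8, 8)
        for c, v in enumerate((0.5, -1.0, 2.0)):
            np.testing.assert_allclose(up.vectors[c], 2 * v, atol=1e-12)

    def test_zero_field_stays_zero(self):
        up = upsample_field(DisplacementField.zeros((4, 4, 4)), 2)
        np.testing.assert_array_equal(up.vectors, 0.0)

    def test_bad_factor(self):
        with pytest.raises(ValueError):
            upsample_field(DisplacementField.zeros((4, 4, 4)), 1)

    def test_multiresolution_consistency(self, rng):
        # warping the fine image with the upsampled field agrees with
        # warping the coarse image with the coarse field, after coarsening
        from scipy.ndimage import gaussian_filter

        from mtef.volio import resample_to

        fine = Volume(gaussian_filter(rng.random((32, 32, 32)), 3.0))
        coarse = resample_to(fine, (16, 16, 16))
        f_coarse = DisplacementField(np.stack([
            gaussian_filter(rng.normal(0, 1.0, (16, 16, 16)), 4.0) * 2
            for _ in range(3)
        ]))
        a = warp(coarse, f_coarse)
        b = resample_to(warp(fine, upsample_field(f_coarse, 2)), (16, 16, 16))
        rel = np.linalg.norm(a.data - b.data) / np.linalg.norm(coarse.data)
        assert rel < 0.05


class TestJacobian:
    def test_zero_field(self):
        frac, det = jacobian_nonpositive_fraction(DisplacementField.zeros((6, 6, 6)))
        assert frac == 0.0
        np.testing.assert_allclose(det, 1.0, atol=1e-12)

    def test_foldover_linear_field(self):
        # u_x = -2x makes x + u = -x: determinant -1 everywhere
        u = np.zeros((3, 6, 6, 6))
        u[0] = -2.0 * np.arange(6)[:, None, None]
        frac, det = jacobian_nonpositive_fraction(DisplacementField(u))
        assert frac == 1.0
        np.testing.assert_allclose(det, -1.0, atol=1e-9)

    def test_isotropic_expansion_closed_form(self):
        u = np.zeros((3, 6, 6, 6))
        grids = np.meshgrid(*[np.arange(6.0)] * 3, indexing="ij")
        for c in range(3):
            u[c] = 0.1 * grids[c]
        _, det = jacobian_nonpositive_fraction(DisplacementField(u))
        np.testing.assert_allclose(det, 1.1**3, atol=1e-6)

    def test_invariant_to_constant_translation(self, rng):
        from scipy.ndimage import gaussian_filter

        u = np.stack([
            gaussian_filter(rng.normal(0, 1, (8, 8, 8)), 2.0) * 3
            for _ in range(3)
        ])
        f1, _ = jacobian_nonpositive_fraction(DisplacementField(u))
        f2, _ = jacobian_nonpositive_fraction(DisplacementField(u + 2.5))
        assert f1 == f2


class TestFieldIO:
    def test_round_trip(self, tmp_path, rng):
        f = DisplacementField(rng.normal(0, 1, (3, 5, 6, 7)))
        write_field(f, tmp_path / "f.nii.gz")
        back = read_field(tmp_path / "f.nii.gz")
        np.testing.assert_allclose(back.vectors, f.vectors, atol=1e-6)
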