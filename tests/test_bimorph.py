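import numpy as np
import pytest

from mtef.bimorph import (DEFAULT_RADII, StructuringPair, ball_element,
                          black_tophat_dual, dilate, dual_close, dual_open,
                          erode, preset_pair, white_tophat_dual)


from oracles import brute_dilate, brute_erode


class TestBallElement:
    def test_radius_one_is_cross(self):
        b = ball_element(1)
        assert b.sum() == 7
        expected = np.zeros((3, 3, 3), bool)
        expected[1, 1, 1] = expected[0, 1, 1] = expected[2, 1, 1] = True
        expected[1, 0, 1] = expected[1, 2, 1] = True
        expected[1, 1, 0] = expected[1, 1, 2] = True
        np.testing.assert_array_equal(b, expected)

    def test_exhaustive_distance_check(self):
        for r in (1, 2, 3):
            b = ball_element(r)
            for idx in np.ndindex(b.shape):
                d2 = sum((i - r) ** 2 for i in idx)
                assert b[idx] == (d2 <= r * r)

    def test_symmetry_under_axis_permutations(self):
        b = ball_element(3)
        for axes in [(1, 0, 2), (2, 1, 0), (0, 2, 1)]:
            np.testing.assert_array_equal(b, b.transpose(axes))
        for ax in range(3):
            np.testing.assert_array_equal(b, np.flip(b, axis=ax))

    def test_side_length(self):
        for r in (1, 4, 9):
            assert ball_element(r).shape == (2 * r + 1,) * 3

    def test_invalid_radius(self):
        with pytest.raises(ValueError):
            ball_element(0)


class TestErodeDilate:
    def test_constant_unchanged(self):
        f = np.full((6, 6, 6), 2.5)
        elem = ball_element(2)
        np.testing.assert_array_equal(erode(f, elem), f)
        np.testing.assert_array_equal(dilate(f, elem), f)

    def test_single_voxel_dilation_is_cross(self):
        f = np.zeros((7, 7, 7))
        f[3, 3, 3] = 1.0
        out = dilate(f, ball_element(1))
        np.testing.assert_array_equal(out, brute_dilate(f, ball_element(1)))
        assert out.sum() == 7

    def test_opening_closing_bounds(self, rng):
        f = rng.random((6, 6, 6))
        elem = ball_element(1)
        assert (dilate(erode(f, elem), elem) <= f + 1e-12).all()
        assert (erode(dilate(f, elem), elem) >= f - 1e-12).all()

    @pytest.mark.parametrize("radius", DEFAULT_RADII)
    def test_matches_brute_force_all_radii(self, rng, radius):
        f = rng.random((6, 6, 6))
        elem = ball_element(radius)
        np.testing.assert_allclose(erode(f, elem), brute_erode(f, elem))
        np.testing.assert_allclose(dilate(f, elem), brute_dilate(f, elem))


class TestDualOperators:
    def test_pair_invariants(self):
        pair = StructuringPair(outer=5, inner=3)
        assert pair.rc == 4
        assert pair.ring_width == 2
        ring = pair.ring_element()
        assert ring.any() and not ring[5, 5, 5]

    def test_degenerate_pair_rejected(self):
        with pytest.raises(ValueError):
            StructuringPair(outer=3, inner=3)

    def test_constant_unchanged(self):
        pair = StructuringPair(outer=3, inner=1)
        f = np.full((8, 8, 8), 1.5)
        np.testing.assert_array_equal(dual_open(f, pair), f)
        np.testing.assert_array_equal(dual_close(f, pair), f)

    def test_matches_brute_force(self, rng):
        pair = StructuringPair(outer=3, inner=1)
        f = rng.random((6, 6, 6))
        ring, rc = pair.ring_element(), pair.rc_element()
        np.testing.assert_allclose(
            dual_open(f, pair), brute_erode(brute_dilate(f, ring), rc)
        )
        np.testing.assert_allclose(
            dual_close(f, pair), brute_dilate(brute_erode(f, ring), rc)
        )

    def test_differs_from_plain_opening(self, rng):
        # the ring element sees different structure than a solid ball
        pair = StructuringPair(outer=3, inner=1)
        f = rng.random((8, 8, 8))
        ball = ball_element(3)
        plain_opening = brute_dilate(brute_erode(f, ball), ball)
        assert not np.allclose(dual_open(f, pair), plain_opening)

    def test_output_within_input_envelope(self, rng):
        pair = StructuringPair(outer=4, inner=2)
        f = rng.random((8, 8, 8))
        for out in (dual_open(f, pair), dual_close(f, pair)):
            assert out.min() >= f.min() - 1e-12
            assert out.max() <= f.max() + 1e-12


class TestTopHats:
    def test_constant_gives_zero(self):
        pair = StructuringPair(outer=3, inner=1)
        f = np.full((8, 8, 8), 0.7)
        np.testing.assert_allclose(white_tophat_dual(f, pair), 0.0, atol=1e-12)
        np.testing.assert_allclose(black_tophat_dual(f, pair), 0.0, atol=1e-12)

    def test_offset_invariance(self, rng):
        pair = StructuringPair(outer=3, inner=1)
        f = rng.random((7, 7, 7))
        np.testing.assert_allclose(
            white_tophat_dual(f, pair), white_tophat_dual(f + 3.0, pair),
            atol=1e-12,
        )

    def test_narrow_blob_detected(self):
        # a blob narrower than the inner radius is missed by the ring and
        # leaves a positive white residue at the blob
        pair = StructuringPair(outer=3, inner=2)
        f = np.zeros((8, 8, 8))
        f[4, 4, 4] = 1.0
        wth = white_tophat_dual(f, pair)
        oracle = f - brute_erode(brute_dilate(f, pair.ring_element()),
                                 pair.rc_element())
        np.testing.assert_allclose(wth, oracle)
        assert wth[4, 4, 4] > 0


class TestPresets:
    @pytest.mark.parametrize("radius", DEFAULT_RADII)
    def test_presets_valid(self, radius):
        pair = preset_pair(radius)
        assert pair.outer == radius
        assert pair.outer > pair.inner >= 1

    def test_unknown_radius(self):
        with pytest.raises(ValueError):
            preset_pair(4)
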