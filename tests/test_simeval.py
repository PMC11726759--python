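import numpy as np
import pytest

from mtef.nn import autodiff as ad
from mtef.simeval import (Evaluator, TransformSpec, apply_transform,
                          make_sample, ncc, sample_transform, similarity,
                          train_evaluator)
from mtef.volio import Volume


@pytest.fixture
def smooth_volume(rng):
    from scipy.ndimage import gaussian_filter

    data = gaussian_filter(rng.random((20, 20, 12)), 2.0)
    data = (data - data.min()) / (data.max() - data.min())
    return Volume(data)


class TestTransforms:
    def test_identity_spec_is_noop(self, smooth_volume):
        out = apply_transform(smooth_volume, TransformSpec())
        np.testing.assert_allclose(out.data, smooth_volume.data, atol=1e-6)

    def test_pure_translation_matches_index_shift(self, smooth_volume):
        spec = TransformSpec(translation=(2.0, 0.0, 0.0))
        out = apply_transform(smooth_volume, spec)
        np.testing.assert_allclose(out.data[:-2], smooth_volume.data[2:],
                                   atol=1e-9)

    def test_seed_determinism(self):
        a = sample_transform(np.random.default_rng(5))
        b = sample_transform(np.random.default_rng(5))
        c = sample_transform(np.random.default_rng(6))
        assert a == b
        assert a != c

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            TransformSpec(translation=(5.0, 0.0, 0.0))
        with pytest.raises(ValueError):
            TransformSpec(scale=1.2)

    def test_magnitude_shrinks_towards_identity(self):
        spec = sample_transform(np.random.default_rng(3), magnitude=0.0)
        assert spec.rotation_deg == (0.0, 0.0, 0.0)
        assert spec.translation == (0.0, 0.0, 0.0)
        assert spec.scale == 1.0


class TestMakeSample:
    def test_identity_transforms_give_zero_target(self, smooth_volume):
        ident = TransformSpec()
        s = make_sample(smooth_volume, seed=0, specs=(ident, ident))
        assert s.target == 0.0

    def test_target_ignores_corruption(self, smooth_volume):
        spec_pair = (TransformSpec(translation=(1.0, 0, 0)), TransformSpec())
        a = make_sample(smooth_volume, noise_sd=0.0, seed=1, specs=spec_pair)
        b = make_sample(smooth_volume, noise_sd=0.3, seed=1, specs=spec_pair)
        assert a.target == b.target
        assert not np.allclose(a.corrupted, b.corrupted)

    def test_target_monotone_in_translation_gap(self, smooth_volume):
        targets = []
        for gap in (0.0, 1.0, 2.0, 3.0):
            pair = (TransformSpec(translation=(gap, 0, 0)), TransformSpec())
            s = make_sample(smooth_volume, seed=2, specs=pair)
            targets.append(s.target)
        assert all(b > a for a, b in zip(targets, targets[1:]))

    def test_reproducible_from_seed(self, smooth_volume):
        a = make_sample(smooth_volume, seed=7)
        b = make_sample(smooth_volume, seed=7)
        np.testing.assert_array_equal(a.corrupted, b.corrupted)
        assert a.target == b.target


class TestEvaluator:
    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train_evaluator([])

    def test_constant_zero_targets_fit(self, smooth_volume):
        ident = TransformSpec()
        samples = [make_sample(smooth_volume, seed=i, specs=(ident, ident),
                               noise_sd=0.01)
                   for i in range(6)]
        ev = train_evaluator(samples, epochs=60, seed=0, lr=3e-3, width=4)
        X = np.stack([np.stack([s.reference, s.corrupted]) for s in samples])
        with ad.no_grad():
            preds = ev.forward(X).data
        assert np.abs(preds).mean() < 1e-3

    def test_prediction_finite_and_clipped(self, smooth_volume, rng):
        ev = Evaluator(width=4, seed=0)
        p = ev.predict(rng.random((16, 16, 8)), rng.random((16, 16, 8)))
        assert np.isfinite(p) and p >= 0.0

    def test_checkpoint_round_trip(self, tmp_path, rng):
        ev = Evaluator(width=4, seed=3)
        ev.trained = True
        ev.save(tmp_path / "eval")
        back = Evaluator.load(tmp_path / "eval")
        x = rng.random((1, 2, 12, 12, 8)).astype(np.float32)
        with ad.no_grad():
            np.testing.assert_allclose(ev.forward(x).data,
                                       back.forward(x).data, atol=1e-6)
        assert back.trained


class TestSimilarities:
    def test_ncc_self_is_zero(self, rng):
        v = rng.random((16, 16, 12))
        assert abs(float(ncc(v, v, window=5).data)) < 1e-6

    def test_ncc_affine_invariance(self, rng):
        v = rng.random((16, 16, 12))
        assert abs(float(ncc(v, 1.7 * v + 0.4, window=5).data)) < 1e-6

    def test_ncc_shape_mismatch(self, rng):
        with pytest.raises(ValueError):
            ncc(rng.random((8, 8, 8)), rng.random((8, 8, 4)))

    def test_ncc_increases_with_misalignment(self, smooth_volume):
        v = smooth_volume.data
        scores = [float(ncc(np.roll(v, s, axis=0), v, window=5).data)
                  for s in (0, 2, 4)]
        assert scores[0] < scores[1] < scores[2]

    def test_evaluator_similarity_differentiable(self, smooth_volume):
        ev = Evaluator(width=4, seed=1)
        warped = ad.Tensor(smooth_volume.data.astype(np.float32),
                           requires_grad=True)
        score = similarity(ev, warped, smooth_volume.data)
        score.backward()
        assert warped.grad is not None
        assert np.isfinite(warped.grad).all()
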