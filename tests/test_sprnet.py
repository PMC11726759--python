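import numpy as np
import pytest

from mtef.nn import autodiff as ad
from mtef.sprnet import NetConfig, SPRNet, patch_embed, patch_tokens

TINY = dict(embed_dim=8, depths=(1, 1), heads=(2, 4), window=4,
            decoder_hidden=8)


class TestPatchEmbed:
    def test_token_count(self, rng):
        cfg = NetConfig(**TINY)
        tokens = patch_embed(rng.random((8, 8, 8)), cfg)
        assert tokens.shape == (64, 8)  # S = 8·8·8 / 2³

    def test_zero_volume_zero_raw_tokens(self):
        cfg = NetConfig(**TINY)
        raw = patch_tokens(np.zeros((8, 8, 8)), cfg)
        np.testing.assert_array_equal(raw.data, 0.0)

    def test_indivisible_shape_names_axis(self):
        cfg = NetConfig(**TINY)
        with pytest.raises(ValueError, match="axis 1"):
            patch_tokens(np.zeros((8, 7, 8)), cfg)

    def test_permutation_equivariance(self, rng):
        # no positional term: shuffling patches shuffles raw tokens identically
        cfg = NetConfig(**TINY)
        vol = rng.random((8, 8, 8))
        K = cfg.patch_size
        raw = patch_tokens(vol, cfg).data
        # permute patches along the first patch axis
        blocks = vol.reshape(4, K, 4, K, 4, K)
        perm = np.array([2, 0, 3, 1])
        shuffled = blocks[perm].reshape(8, 8, 8)
        raw_shuffled = patch_tokens(shuffled, cfg).data
        np.testing.assert_allclose(
            raw.reshape(4, 4, 4, -1)[perm].reshape(-1, K**3), raw_shuffled
        )


class TestEncoder:
    def test_channel_progression_four_stages(self, rng):
        cfg = NetConfig(embed_dim=8, depths=(1, 1, 1, 1), heads=(2, 4, 4, 8),
                        window=4)
        net = SPRNet(cfg)
        pyr = net.encode(rng.random((32, 32, 32)).astype(np.float32), "fixed")
        channels = [s.shape[-1] for s in pyr.stages]
        assert channels == [8, 16, 32, 64]
        shapes = [s.shape[:3] for s in pyr.stages]
        assert shapes == [(16,) * 3, (8,) * 3, (4,) * 3, (2,) * 3]

    def test_window_partition_count(self):
        from mtef.nn.layers import _window_partition

        x = ad.Tensor(np.zeros((16, 16, 16, 4), dtype=np.float32))
        tokens, grid = _window_partition(x, (8, 8, 8))
        assert tokens.shape[0] == 8  # 2×2×2 windows
        assert grid == (2, 2, 2)

    def test_independent_encoders_differ(self, rng):
        net = SPRNet(NetConfig(**TINY))
        v = rng.random((16, 16, 8)).astype(np.float32)
        fm = net.encode(v, "moving").stages[-1].data
        ff = net.encode(v, "fixed").stages[-1].data
        assert not np.allclose(fm, ff)

    def test_deterministic_forward(self, rng):
        v = rng.random((16, 16, 8)).astype(np.float32)
        a = SPRNet(NetConfig(**TINY, seed=5)).encode(v, "fixed").stages[0].data
        b = SPRNet(NetConfig(**TINY, seed=5)).encode(v, "fixed").stages[0].data
        np.testing.assert_array_equal(a, b)

    def test_oversized_window_is_clamped(self, rng):
        cfg = NetConfig(embed_dim=8, depths=(1,), heads=(2,), window=64)
        net = SPRNet(cfg)
        pyr = net.encode(rng.random((8, 8, 8)).astype(np.float32), "fixed")
        assert pyr.stages[0].shape == (4, 4, 4, 8)


class TestDecoder:
    def test_identical_inputs_zero_fields(self, rng):
        # zero-initialised refinement heads make the untrained net an
        # exact identity transform
        net = SPRNet(NetConfig(**TINY))
        v = rng.random((16, 16, 8)).astype(np.float32)
        final, fields = net(v, v)
        np.testing.assert_array_equal(final.data, 0.0)
        for f in fields:
            np.testing.assert_array_equal(f.data, 0.0)

    def test_four_fields_with_doubling_shapes(self, rng):
        cfg = NetConfig(embed_dim=8, depths=(1, 1, 1, 1), heads=(2, 4, 4, 8),
                        window=4)
        net = SPRNet(cfg)
        v = rng.random((32, 32, 32)).astype(np.float32)
        final, fields = net(v, rng.random((32, 32, 32)).astype(np.float32))
        shapes = [f.shape[1:] for f in fields]
        assert shapes == [(2,) * 3, (4,) * 3, (8,) * 3, (16,) * 3]
        assert final.shape == (3, 32, 32, 32)

    def test_skip_toggle_changes_output(self, rng):
        v1 = rng.random((16, 16, 8)).astype(np.float32)
        v2 = rng.random((16, 16, 8)).astype(np.float32)
        outs = {}
        for skip in (True, False):
            net = SPRNet(NetConfig(**TINY, use_skip=skip, seed=3))
            for flow in net.decoder.flow:  # make heads non-trivial
                flow.weight.data[...] = 0.01
            outs[skip] = net(v1, v2)[0].data
        assert not np.allclose(outs[True], outs[False])

    def test_cnn_encoder_same_contract(self, rng):
        net = SPRNet(NetConfig(**TINY, encoder="cnn"))
        v1 = rng.random((16, 16, 8)).astype(np.float32)
        final, fields = net(v1, v1)
        assert final.shape == (3, 16, 16, 8)
        np.testing.assert_array_equal(final.data, 0.0)

    def test_shape_mismatch_rejected(self, rng):
        net = SPRNet(NetConfig(**TINY))
        with pytest.raises(ValueError):
            net(rng.random((16, 16, 8)).astype(np.float32),
                rng.random((8, 8, 8)).astype(np.float32))


class TestConfig:
    def test_heads_must_divide_channels(self):
        with pytest.raises(ValueError, match="heads"):
            NetConfig(embed_dim=8, depths=(1,), heads=(3,))

    def test_round_trip_dict(self):
        cfg = NetConfig(**TINY)
        assert NetConfig.from_dict(cfg.to_dict()) == cfg
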