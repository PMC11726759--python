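"""Gradient-correctness checks for the autodiff engine via central
finite differences on small operands."""

import numpy as np
import pytest

from mtef.nn import autodiff as ad


def numeric_grad(fn, x, proj, eps=1e-2):
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        xp, xm = x.copy(), x.copy()
        xp[i] += eps
        xm[i] -= eps
        g[i] = ((fn(ad.Tensor(xp)).data * proj).sum()
                - (fn(ad.Tensor(xm)).data * proj).sum()) / (2 * eps)
    return g


def analytic_grad(fn, x, proj):
    t = ad.Tensor(x, requires_grad=True)
    ad.reduce_sum(fn(t) * ad.Tensor(proj)).backward()
    return t.grad


def check(fn, x, rng, tol=3e-2):
    proj = rng.standard_normal(fn(ad.Tensor(x)).shape).astype(np.float32)
    a = analytic_grad(fn, x, proj)
    n = numeric_grad(fn, x, proj)
    assert np.abs(a - n).max() / (np.abs(n).max() + 1e-6) < tol


@pytest.fixture
def x(rng):
    return rng.standard_normal((2, 3, 4)).astype(np.float32)


class TestElementwiseGrads:
    def test_softmax(self, x, rng):
        check(lambda t: ad.softmax(t, axis=-1), x, rng)

    def test_layer_norm(self, x, rng):
        check(ad.layer_norm, x, rng)

    def test_relu_leaky_abs(self, x, rng):
        check(ad.relu, x, rng)
        check(ad.leaky_relu, x, rng)
        check(ad.absolute, x + 0.1, rng)  # keep away from the kink

    def test_matmul_both_sides(self, x, rng):
        B = ad.Tensor(rng.standard_normal((4, 5)).astype(np.float32))
        check(lambda t: ad.matmul(t, B), x, rng)
        A = ad.Tensor(x)
        xb = rng.standard_normal((4, 5)).astype(np.float32)
        check(lambda t: ad.matmul(A, t), xb, rng)

    def test_broadcast_add_mul(self, x, rng):
        b = ad.Tensor(rng.standard_normal((1, 3, 1)).astype(np.float32))
        check(lambda t: t * b + b, x, rng)


class TestConvGrads:
    def test_conv3d_input_weight_stride(self, rng):
        xc = rng.standard_normal((1, 2, 4, 4, 4)).astype(np.float32)
        w = ad.Tensor(0.3 * rng.standard_normal((3, 2, 3, 3, 3)).astype(np.float32))
        check(lambda t: ad.conv3d(t, w, stride=1, padding=1), xc, rng)
        check(lambda t: ad.conv3d(t, w, stride=2, padding=1), xc, rng)
        wd = w.data.copy()
        xt = ad.Tensor(xc)
        check(lambda t: ad.conv3d(xt, t, stride=1, padding=1), wd, rng)


class TestSamplingGrads:
    def test_warp_image_gradient(self, rng):
        img = rng.standard_normal((1, 5, 5, 5)).astype(np.float32)
        fld = ad.Tensor(rng.uniform(0.2, 0.45, (3, 5, 5, 5)).astype(np.float32))
        check(lambda t: ad.warp3d(t, fld), img, rng)

    def test_warp_field_gradient_interior(self, rng):
        # smooth image, fractional offsets away from integer crossings
        H = 6
        g = np.meshgrid(*[np.arange(H, dtype=np.float32)] * 3, indexing="ij")
        img = (np.sin(0.7 * g[0]) + np.cos(0.5 * g[1]) + 0.3 * g[2])[None]
        fld = rng.uniform(0.25, 0.45, (3, H, H, H)).astype(np.float32)
        proj = rng.standard_normal((1, H, H, H)).astype(np.float32)
        a = analytic_grad(lambda t: ad.warp3d(ad.Tensor(img), t), fld, proj)
        n = numeric_grad(lambda t: ad.warp3d(ad.Tensor(img), t), fld, proj,
                         eps=5e-3)
        interior = (slice(None), slice(0, H - 1), slice(0, H - 1), slice(0, H - 1))
        assert np.abs(a - n)[interior].max() < 5e-3

    def test_resize_gradient(self, rng):
        xr = rng.standard_normal((2, 4, 4, 2)).astype(np.float32)
        check(lambda t: ad.resize3(t, (8, 8, 4), scale=2.0), xr, rng)


class TestEngineBehaviour:
    def test_no_grad_blocks_graph(self, rng):
        t = ad.Tensor(rng.random(4).astype(np.float32), requires_grad=True)
        with ad.no_grad():
            out = t * 2.0
        assert not out.requires_grad

    def test_grad_accumulates_over_reuse(self):
        t = ad.Tensor(np.array([2.0]), requires_grad=True)
        out = t * t  # d/dt = 2t via two paths
        ad.reduce_sum(out).backward()
        np.testing.assert_allclose(t.grad, [4.0])

    def test_adam_reduces_quadratic(self):
        from mtef.nn.layers import Parameter
        from mtef.nn.optim import Adam

        p = Parameter(np.array([5.0, -3.0]))
        opt = Adam([p], lr=0.1)
        for _ in range(300):
            lossv = ad.reduce_sum(p * p)
            opt.zero_grad()
            lossv.backward()
            opt.step()
        assert np.abs(p.data).max() < 1e-2
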