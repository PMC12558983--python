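"""Unit tests for the NumPy autodiff engine (tensor ops, layers, optimizer)."""

import numpy as np
import pytest

from conftest import numeric_gradcheck
from purecl import nn
from purecl.nn import Tensor


@pytest.fixture()
def rng64():
    return np.random.default_rng(99)


class TestConv2d:
    @pytest.mark.parametrize("kernel,stride,padding", [
        (3, 1, 1),   # im2col, same-size
        (3, 2, 1),   # im2col, strided
        (1, 1, 0),   # pointwise fast path
        (1, 2, 0),   # strided pointwise
    ])
    def test_gradients_match_finite_differences(self, rng64, kernel, stride, padding):
        x = Tensor(rng64.random((2, 3, 6, 6)), requires_grad=True)
        w = Tensor((rng64.random((4, 3, kernel, kernel)) - 0.5) * 0.5, requires_grad=True)
        b = Tensor(rng64.random(4), requires_grad=True)
        numeric_gradcheck(lambda: nn.conv2d(x, w, b, stride=stride, padding=padding),
                          [x, w, b])

    @pytest.mark.parametrize("kernel", [5, 7])
    def test_fft_path_gradients(self, rng64, kernel):
        # 16x16 stride-1 same-padding triggers the frequency-domain branch
        x = Tensor(rng64.random((1, 2, 16, 16)), requires_grad=True)
        w = Tensor((rng64.random((2, 2, kernel, kernel)) - 0.5) * 0.3, requires_grad=True)
        b = Tensor(rng64.random(2), requires_grad=True)
        numeric_gradcheck(lambda: nn.conv2d(x, w, b, stride=1, padding=kernel // 2),
                          [x, w, b], atol=1e-4)

    def test_fft_path_matches_direct_correlation(self, rng64):
        from scipy.signal import correlate
        x = rng64.random((2, 3, 16, 16), dtype=np.float32)
        w = ((rng64.random((4, 3, 5, 5)) - 0.5) * 0.2).astype(np.float32)
        out = nn.conv2d(Tensor(x), Tensor(w), None, stride=1, padding=2).data
        xp = np.pad(x, ((0, 0), (0, 0), (2, 2), (2, 2)))
        ref = np.stack([[correlate(xp[n], w[f], mode="valid")[0] for f in range(4)]
                        for n in range(2)])
        np.testing.assert_allclose(out, ref, atol=1e-4)

    def test_channel_mismatch_raises(self, rng64):
        x = Tensor(rng64.random((1, 3, 8, 8)))
        w = Tensor(rng64.random((4, 2, 3, 3)))
        with pytest.raises(ValueError, match="channel mismatch"):
            nn.conv2d(x, w)


class TestFusedOps:
    def test_batch_norm_gradients(self, rng64):
        x = Tensor(rng64.random((3, 4, 5, 5)) + 0.1, requires_grad=True)
        g = Tensor(rng64.random((1, 4, 1, 1)) + 0.5, requires_grad=True)
        b = Tensor(rng64.random((1, 4, 1, 1)), requires_grad=True)
        numeric_gradcheck(lambda: nn.batch_norm(x, g, b)[0], [x, g, b], atol=1e-4)
        numeric_gradcheck(lambda: nn.batch_norm(x, g, b, relu=True)[0], [x, g, b],
                          atol=1e-4)

    def test_batch_norm_normalizes(self, rng64):
        x = Tensor(rng64.random((8, 4, 6, 6)).astype(np.float32) * 3 + 1)
        g = Tensor(np.ones((1, 4, 1, 1), dtype=np.float32))
        b = Tensor(np.zeros((1, 4, 1, 1), dtype=np.float32))
        out, mu, var = nn.batch_norm(x, g, b)
        np.testing.assert_allclose(out.data.mean(axis=(0, 2, 3)), 0, atol=1e-5)
        np.testing.assert_allclose(out.data.std(axis=(0, 2, 3)), 1, atol=1e-3)
        np.testing.assert_allclose(mu.ravel(), x.data.mean(axis=(0, 2, 3)), rtol=1e-5)

    def test_add_relu_gradients(self, rng64):
        a = Tensor(rng64.standard_normal((2, 3, 4, 4)), requires_grad=True)
        b = Tensor(rng64.standard_normal((2, 3, 4, 4)), requires_grad=True)
        numeric_gradcheck(lambda: nn.add_relu(a, b), [a, b], atol=1e-4)

    def test_max_gradients_route_to_argmax(self, rng64):
        x = Tensor(rng64.random((2, 5, 3, 3)), requires_grad=True)
        numeric_gradcheck(lambda: x.max(axis=1, keepdims=True), [x])


class TestElementwiseGraph:
    def test_composite_expression_gradients(self, rng64):
        a = Tensor(rng64.random((3, 4)) + 0.5, requires_grad=True)
        b = Tensor(rng64.random((1, 4)) + 0.5, requires_grad=True)
        numeric_gradcheck(
            lambda: ((a * b + a).exp().sum(axis=1).log() * 0.5).sum(), [a, b])

    def test_logsumexp_matches_scipy(self, rng64):
        from scipy.special import logsumexp as sp_lse
        x = rng64.standard_normal((5, 7)) * 10
        out = nn.logsumexp(Tensor(x), axis=1)
        np.testing.assert_allclose(out.data, sp_lse(x, axis=1), rtol=1e-12)

    def test_l2_normalize_unit_rows(self, rng64):
        x = Tensor(rng64.standard_normal((6, 9)), requires_grad=True)
        out = nn.l2_normalize(x, axis=1)
        np.testing.assert_allclose(np.linalg.norm(out.data, axis=1), 1, atol=1e-6)

    def test_split_concat_roundtrip_and_gradients(self, rng64):
        x = Tensor(rng64.random((2, 8, 3, 3)), requires_grad=True)

        def f():
            parts = nn.split(x, 4, axis=1)
            return nn.concat([p * (i + 1.0) for i, p in enumerate(parts)], axis=1).sum()

        numeric_gradcheck(f, [x])

    def test_shared_gradient_buffers_are_not_aliased(self):
        # one node fanning out to two consumers must accumulate, not overwrite
        x = Tensor(np.array([1.0, 2.0]), requires_grad=True)
        y = x * 3.0
        z = (y * 1.0 + y * 1.0).sum()
        z.backward()
        np.testing.assert_allclose(x.grad, [6.0, 6.0])


class TestOptimAndSerialization:
    def test_sgd_momentum_matches_reference_recursion(self):
        p = Tensor(np.array([1.0], dtype=np.float32), requires_grad=True)
        opt = nn.SGD([p], lr=0.1, momentum=0.9)
        v_ref, x_ref = 0.0, 1.0
        for _ in range(4):
            p.grad = np.array([2.0 * x_ref], dtype=np.float32)  # d/dx x^2
            opt.step()
            v_ref = 0.9 * v_ref - 0.1 * 2.0 * x_ref
            x_ref += v_ref
            assert p.data[0] == pytest.approx(x_ref, rel=1e-6)

    def test_checkpoint_roundtrip(self, tmp_path, rng64):
        rng_np = np.random.default_rng(0)
        m1 = nn.Sequential([nn.Conv2d(3, 4, 3, rng_np, padding=1), nn.BatchNorm2d(4)])
        m2 = nn.Sequential([nn.Conv2d(3, 4, 3, np.random.default_rng(5), padding=1),
                            nn.BatchNorm2d(4)])
        nn.save_checkpoint(tmp_path / "m.npz", m1, meta={"tag": "x"})
        meta = nn.load_checkpoint(tmp_path / "m.npz", m2)
        assert meta == {"tag": "x"}
        for (n1, a), (n2, b) in zip(sorted(m1.state_dict().items()),
                                    sorted(m2.state_dict().items())):
            assert n1 == n2
            np.testing.assert_array_equal(a, b)

    def test_state_dict_mismatch_raises(self, rng64):
        m = nn.Linear(3, 2, np.random.default_rng(0))
        with pytest.raises(ValueError, match="state mismatch"):
            m.load_state_dict({"weight": np.zeros((3, 2))})  # bias missing
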