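"""Projection head and supervised contrastive loss.

The vectorized loss is checked against a literal triple-loop oracle and
against closed forms (identical projections, infinite temperature).
"""

import numpy as np
import pytest

from purecl.contrastive import (MultiviewBatch, ProjectionHead,
                                build_multiview_batch, project, supcon_loss,
                                supcon_loss_oracle)
from purecl.augment import PositivePair
from purecl.encoder import FeaturePurificationEncoder, FilterMode
from purecl.exceptions import DataError, DegenerateInputError
from purecl.nn import Tensor


def random_batch(rng, n_sources, dim=8, n_classes=2, tau=0.5):
    """2N unit vectors with duplicated per-pair labels (every anchor has a
    positive by construction)."""
    z = rng.standard_normal((2 * n_sources, dim))
    z /= np.linalg.norm(z, axis=1, keepdims=True)
    labels = np.repeat(rng.integers(n_classes, size=n_sources), 2)
    return MultiviewBatch(Tensor(z), labels, tau)


class TestProjectionHead:
    def test_outputs_unit_norm_256(self, rng):
        head = ProjectionHead(0)
        emb = rng.standard_normal((5, 2048)).astype(np.float32)
        z = project(emb, head)
        assert z.shape == (5, 256)
        np.testing.assert_allclose(np.linalg.norm(z.data, axis=1), 1, atol=1e-5)

    def test_deterministic(self, rng):
        head = ProjectionHead(0)
        emb = rng.standard_normal((3, 2048)).astype(np.float32)
        np.testing.assert_array_equal(project(emb, head).data, project(emb, head).data)

    def test_zero_input_with_zero_bias_raises_degeneracy(self):
        head = ProjectionHead(0)
        with pytest.raises(DegenerateInputError, match="zero vector"):
            project(np.zeros((1, 2048), dtype=np.float32), head)

    def test_non_finite_input_raises(self):
        head = ProjectionHead(0)
        bad = np.full((1, 2048), np.nan, dtype=np.float32)
        with pytest.raises(DegenerateInputError, match="non-finite"):
            project(bad, head)


class TestSupConLoss:
    def test_identical_projections_hit_log_2n_minus_1(self, rng):
        for n in (2, 4, 8):
            z = np.tile(rng.standard_normal(16) / np.sqrt(16), (2 * n, 1))
            z /= np.linalg.norm(z, axis=1, keepdims=True)
            labels = np.repeat(np.arange(n) % 2, 2)
            batch = MultiviewBatch(Tensor(z), labels, 0.5)
            per_anchor = supcon_loss(batch, reduction="mean_over_anchors").item()
            assert per_anchor == pytest.approx(np.log(2 * n - 1), abs=1e-9)
            total = supcon_loss(batch, reduction="sum").item()
            assert total == pytest.approx(2 * n * np.log(2 * n - 1), abs=1e-8)

    def test_matches_hand_built_two_pair_batch(self):
        # 4 views on the unit circle, labels (0,0,1,1), tau=1
        angles = np.array([0.0, 0.3, 1.8, 2.4])
        z = np.stack([np.cos(angles), np.sin(angles)], axis=1)
        batch = MultiviewBatch(Tensor(z), np.array([0, 0, 1, 1]), 1.0)
        expected = supcon_loss_oracle(batch, reduction="sum")
        got = supcon_loss(batch, reduction="sum").item()
        assert got == pytest.approx(expected, abs=1e-6)

    def test_infinite_temperature_limit(self, rng):
        for _ in range(5):
            batch = random_batch(rng, 4, tau=1e6)
            val = supcon_loss(batch, reduction="mean_over_anchors").item()
            assert val == pytest.approx(np.log(7), abs=1e-3)

    def test_oracle_equivalence_sweep(self, rng):
        for _ in range(60):
            n = int(rng.integers(2, 9))
            tau = float(rng.choice([0.07, 0.5, 1.0]))
            batch = random_batch(rng, n, dim=int(rng.integers(2, 17)), tau=tau)
            got = supcon_loss(batch, reduction="sum").item()
            want = supcon_loss_oracle(batch, reduction="sum")
            assert got == pytest.approx(want, abs=1e-6)

    def test_permutation_invariance(self, rng):
        batch = random_batch(rng, 6, tau=0.07)
        base = supcon_loss(batch, reduction="sum").item()
        perm = rng.permutation(12)
        shuffled = MultiviewBatch(Tensor(batch.projections.data[perm]),
                                  batch.labels[perm], 0.07)
        assert supcon_loss(shuffled, reduction="sum").item() == pytest.approx(base, abs=1e-8)

    def test_single_class_batch_agrees_with_oracle(self, rng):
        z = rng.standard_normal((6, 8))
        z /= np.linalg.norm(z, axis=1, keepdims=True)
        batch = MultiviewBatch(Tensor(z), np.zeros(6, dtype=int), 0.5)
        assert supcon_loss(batch, reduction="sum").item() == pytest.approx(
            supcon_loss_oracle(batch, reduction="sum"), abs=1e-6)

    def test_translation_safety_of_stabilization(self, rng):
        # scaling every projection by a common rotation leaves all inner
        # products intact; the stabilized value must not drift
        batch = random_batch(rng, 5, dim=4, tau=0.07)
        q, _ = np.linalg.qr(rng.standard_normal((4, 4)))
        rotated = MultiviewBatch(Tensor(batch.projections.data @ q),
                                 batch.labels, 0.07)
        a = supcon_loss(batch, reduction="sum").item()
        b = supcon_loss(rotated, reduction="sum").item()
        assert a == pytest.approx(b, abs=1e-6)

    def test_anchor_without_positive_raises_naming_anchor(self, rng):
        z = rng.standard_normal((3, 4))
        z /= np.linalg.norm(z, axis=1, keepdims=True)
        batch = MultiviewBatch(Tensor(z), np.array([0, 0, 1]), 0.5)
        with pytest.raises(DataError, match="anchor 2"):
            supcon_loss(batch)
        with pytest.raises(DataError, match="anchor 2"):
            supcon_loss_oracle(batch)

    def test_gradient_step_decreases_loss_on_circle(self, rng):
        angles = np.array([0.0, 0.4, 1.5, 2.1])
        z0 = np.stack([np.cos(angles), np.sin(angles)], axis=1)
        z = Tensor(z0, requires_grad=True)
        labels = np.array([0, 0, 1, 1])
        loss = supcon_loss(MultiviewBatch(z, labels, 0.5))
        loss.backward()
        stepped = z0 - 0.05 * z.grad
        stepped /= np.linalg.norm(stepped, axis=1, keepdims=True)
        new = supcon_loss(MultiviewBatch(Tensor(stepped), labels, 0.5)).item()
        assert new < loss.item()


class TestBuildMultiviewBatch:
    def _pairs(self, images, rng):
        from purecl.augment import WPasteConfig, make_positive_pair
        return [make_positive_pair(im, images, WPasteConfig(), rng) for im in images]

    def test_eight_pairs_give_sixteen_views(self, tiny_images, rng):
        enc = FeaturePurificationEncoder(0)
        head = ProjectionHead(1)
        extra = tiny_images + [
            type(tiny_images[0])(pixels=im.pixels[:, ::-1].copy(), label=im.label,
                                 id=im.id + "x") for im in tiny_images[:2]]
        pairs = self._pairs(extra, rng)
        batch = build_multiview_batch(pairs, enc, head, temperature=0.07,
                                      mode=FilterMode.SUBTRACT)
        assert batch.projections.shape == (16, 256)
        assert len(batch.labels) == 16
        np.testing.assert_array_equal(batch.labels[::2], batch.labels[1::2])

    def test_loss_invariant_to_pair_ordering(self, tiny_images, rng):
        enc = FeaturePurificationEncoder(0).eval()
        head = ProjectionHead(1).eval()
        pairs = self._pairs(tiny_images, rng)
        a = supcon_loss(build_multiview_batch(pairs, enc, head, 0.5,
                                              FilterMode.ADD), "sum").item()
        b = supcon_loss(build_multiview_batch(pairs[::-1], enc, head, 0.5,
                                              FilterMode.ADD), "sum").item()
        assert a == pytest.approx(b, rel=1e-5)

    def test_distinct_sources_have_exactly_one_positive_each(self, rng):
        z = rng.standard_normal((8, 16))
        z /= np.linalg.norm(z, axis=1, keepdims=True)
        labels = np.repeat(np.arange(4), 2)  # every source its own class
        eq = labels[:, None] == labels[None, :]
        np.fill_diagonal(eq, False)
        assert (eq.sum(axis=1) == 1).all()
        # loss still defined
        supcon_loss(MultiviewBatch(Tensor(z), labels, 0.5))

    def test_single_class_warns(self, tiny_images, rng):
        enc = FeaturePurificationEncoder(0)
        head = ProjectionHead(1)
        same = [im for im in tiny_images if im.label == 0]
        pairs = self._pairs(same, rng)
        with pytest.warns(UserWarning, match="single class"):
            build_multiview_batch(pairs, enc, head, 0.07, FilterMode.SUBTRACT)

    def test_fewer_than_two_pairs_rejected(self, tiny_images, rng):
        enc = FeaturePurificationEncoder(0)
        head = ProjectionHead(1)
        pairs = self._pairs(tiny_images, rng)[:1]
        with pytest.raises(DataError, match="two positive pairs"):
            build_multiview_batch(pairs, enc, head, 0.07, FilterMode.SUBTRACT)
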