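"""The feature-purification encoder.

Five residual (bottleneck) stages produce a 2048-dimensional L2-normalized
embedding.  The first two stages carry most of the low-level noise in leaf
imagery (background texture, lighting), so each is followed by an
interference-feature-filtering module:

* a multi-scale attention block splits the stage output into four
  channel-contiguous subspaces, convolves each with a 1x1 / 3x3 / 5x5 /
  7x7 kernel, builds a 2-channel descriptor from the channel-wise mean and
  max of the candidate map, and turns it into a sigmoid spatial weight map
  through a shared 3x3 fusion convolution;
* a feature-subtraction block aligns the attention output (the captured
  interference features) to a deeper stage's shape with average pooling
  plus a 1x1 projection and removes it elementwise from that stage.

During early training the interference features are *subtracted* from the
stage-3 and stage-4 outputs ("reverse learning"); after ``switch_epoch``
epochs the subtraction flips to addition, letting the now-informative
low-level channels re-enter the representation.

Input images must be (N, 3, H, W) with H and W multiples of 32 (five
levels of downsampling), H, W >= 32.
"""

from __future__ import annotations

import enum

import numpy as np

from . import nn
from .exceptions import ShapeError
from .nn import Tensor

__all__ = [
    "FilterMode",
    "filter_mode_for_epoch",
    "MultiScaleAttention",
    "AlignmentProjection",
    "feature_subtraction",
    "Bottleneck",
    "FeaturePurificationEncoder",
    "EMBED_DIM",
]

EMBED_DIM = 2048


class FilterMode(enum.Enum):
    SUBTRACT = "subtract"
    ADD = "add"


def filter_mode_for_epoch(epoch: int, switch_epoch: int) -> FilterMode:
    """Subtract while ``epoch < switch_epoch``; add from then on.

    "After 15 epochs" therefore means the 16th epoch (0-based index 15) is
    the first additive one.
    """
    if epoch < 0:
        raise ValueError(f"epoch must be non-negative, got {epoch}")
    return FilterMode.SUBTRACT if epoch < switch_epoch else FilterMode.ADD


def _avg_pool(x: Tensor, factor: int) -> Tensor:
    """Non-overlapping average pooling by an integer factor (reshape trick)."""
    n, c, h, w = x.shape
    if h % factor or w % factor:
        raise ShapeError(f"cannot pool {h}x{w} by a factor of {factor}")
    x = x.reshape(n, c, h // factor, factor, w // factor, factor)
    return x.mean(axis=(3, 5))


class MultiScaleAttention(nn.Module):
    """Four-subspace multi-scale spatial attention.

    The input is split along channels into four equal subspaces; each is
    convolved at its own scale (kernels 1, 3, 5, 7).  A shared 3x3 fusion
    convolution maps every subspace's channel-wise mean/max descriptor to
    a single-channel logit map; its sigmoid reweights the candidate map,
    and the four results are concatenated back.  Output shape == input
    shape.  After a forward pass ``last_weight_maps`` holds the four
    sigmoid maps (plain arrays, detached).
    """

    KERNELS = (1, 3, 5, 7)

    def __init__(self, channels: int, rng: np.random.Generator):
        super().__init__()
        if channels % 4:
            raise ShapeError(f"attention input channels must be divisible by 4, got {channels}")
        sub = channels // 4
        self.channels = channels
        self.branch_convs = nn.ModuleList([
            nn.Conv2d(sub, sub, k, rng, padding=k // 2) for k in self.KERNELS
        ])
        self.fusion = nn.Conv2d(2, 1, 3, rng, padding=1)
        self.last_weight_maps: list[np.ndarray] = []

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.channels:
            raise ShapeError(f"expected {self.channels} channels, got {x.shape[1]}")
        subspaces = nn.split(x, 4, axis=1)
        outputs = []
        weight_maps = []
        for xi, conv in zip(subspaces, self.branch_convs):
            cand = conv(xi)
            descriptor = nn.concat(
                [cand.mean(axis=1, keepdims=True), cand.max(axis=1, keepdims=True)],
                axis=1,
            )
            wmap = nn.sigmoid(self.fusion(descriptor))
            weight_maps.append(wmap.data.copy())
            outputs.append(cand * wmap)
        self.last_weight_maps = weight_maps
        return nn.concat(outputs, axis=1)


class AlignmentProjection(nn.Module):
    """Shape aligner for feature subtraction: average-pool to the deep
    stage's spatial size, then a learned 1x1 channel projection."""

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator):
        super().__init__()
        self.proj = nn.Conv2d(in_channels, out_channels, 1, rng)

    def forward(self, shallow: Tensor, target_hw: tuple[int, int]) -> Tensor:
        h, w = shallow.shape[2], shallow.shape[3]
        th, tw = target_hw
        if h % th or w % tw or h // th != w // tw:
            raise ShapeError(f"cannot align {h}x{w} onto {th}x{tw}: non-integer stride ratio")
        factor = h // th
        pooled = _avg_pool(shallow, factor) if factor > 1 else shallow
        return self.proj(pooled)


def feature_subtraction(deep: Tensor, shallow_filtered: Tensor,
                        align: AlignmentProjection | None,
                        mode: FilterMode) -> Tensor:
    """Purify a deep stage: remove (or, after the schedule switch, re-add)
    the aligned interference features captured at a shallow stage."""
    aligned = shallow_filtered if align is None else align(shallow_filtered, (deep.shape[2], deep.shape[3]))
    if aligned.shape != deep.shape:
        raise ShapeError(f"aligned shape {aligned.shape} != deep shape {deep.shape}")
    if mode is FilterMode.SUBTRACT:
        return deep - aligned
    return deep + aligned


class Bottleneck(nn.Module):
    """1x1 -> 3x3 -> 1x1 residual bottleneck with batch norm."""

    def __init__(self, cin: int, cout: int, stride: int, rng: np.random.Generator):
        super().__init__()
        mid = cout // 4
        self.conv1 = nn.Conv2d(cin, mid, 1, rng, bias=False)
        self.bn1 = nn.BatchNorm2d(mid, relu=True)
        self.conv2 = nn.Conv2d(mid, mid, 3, rng, stride=stride, padding=1, bias=False)
        self.bn2 = nn.BatchNorm2d(mid, relu=True)
        self.conv3 = nn.Conv2d(mid, cout, 1, rng, bias=False)
        self.bn3 = nn.BatchNorm2d(cout)
        if stride != 1 or cin != cout:
            self.short_conv = nn.Conv2d(cin, cout, 1, rng, stride=stride, bias=False)
            self.short_bn = nn.BatchNorm2d(cout)
        else:
            self.short_conv = None

    def forward(self, x: Tensor) -> Tensor:
        y = self.bn2(self.conv2(self.bn1(self.conv1(x))))
        y = self.bn3(self.conv3(y))
        s = x if self.short_conv is None else self.short_bn(self.short_conv(x))
        return nn.add_relu(y, s)


class FeaturePurificationEncoder(nn.Module):
    """Five-stage residual encoder with interference-feature filtering.

    Stage widths follow the standard bottleneck ladder 256/512/1024/2048
    with a fifth stride-1 block, the weakest layout consistent with a
    2048-d pooled embedding.  ``forward`` returns unit-norm row vectors.
    """

    WIDTHS = (256, 512, 1024, 2048, 2048)
    STEM_CHANNELS = 64

    def __init__(self, rng: np.random.Generator | int = 0):
        super().__init__()
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        c = self.STEM_CHANNELS
        self.stem_conv = nn.Conv2d(3, c, 3, rng, stride=2, padding=1, bias=False)
        self.stem_bn = nn.BatchNorm2d(c, relu=True)
        w1, w2, w3, w4, w5 = self.WIDTHS
        self.block1 = Bottleneck(c, w1, 1, rng)
        self.block2 = Bottleneck(w1, w2, 2, rng)
        self.block3 = Bottleneck(w2, w3, 2, rng)
        self.block4 = Bottleneck(w3, w4, 2, rng)
        self.block5 = Bottleneck(w4, w5, 1, rng)
        self.attention1 = MultiScaleAttention(w1, rng)
        self.attention2 = MultiScaleAttention(w2, rng)
        self.align1 = AlignmentProjection(w1, w3, rng)
        self.align2 = AlignmentProjection(w2, w4, rng)

    def forward(self, images, mode: FilterMode = FilterMode.ADD) -> Tensor:
        x = images if isinstance(images, Tensor) else Tensor(np.asarray(images, dtype=np.float32))
        if x.ndim != 4 or x.shape[1] != 3:
            raise ShapeError(f"expected (N, 3, H, W), got {x.shape}")
        h, w = x.shape[2], x.shape[3]
        if h < 32 or w < 32 or h % 32 or w % 32:
            raise ShapeError(
                f"input {h}x{w} incompatible with five downsampling stages; "
                "H and W must be multiples of 32"
            )
        x = self.stem_bn(self.stem_conv(x))
        x = _avg_pool(x, 2)
        x1 = self.block1(x)
        f1 = self.attention1(x1)
        x2 = self.block2(x1)
        f2 = self.attention2(x2)
        x3 = self.block3(x2)
        g1 = feature_subtraction(x3, f1, self.align1, mode)
        x4 = self.block4(g1)
        g2 = feature_subtraction(x4, f2, self.align2, mode)
        x5 = self.block5(g2)
        pooled = x5.mean(axis=(2, 3))
        return nn.l2_normalize(pooled, axis=1)

    def embed(self, images, mode: FilterMode = FilterMode.ADD,
              batch_size: int = 32) -> np.ndarray:
        """Inference helper: eval-mode embeddings as a plain (N, 2048) array."""
        was_training = self.training
        self.eval()
        chunks = []
        arr = np.asarray(images, dtype=np.float32)
        for lo in range(0, len(arr), batch_size):
            chunks.append(self.forward(Tensor(arr[lo:lo + batch_size]), mode).data)
        if was_training:
            self.train()
        return np.concatenate(chunks, axis=0)
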