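"""Positive-pair augmentations for contrastive training.

The core operation is W-Paste: cut ``n_patches`` small rectangles (15x15
by default) out of a sample and fill each cut with a rectangle of the same
size copied from another sample in the donor pool.  The perturbation is
local and semantic — the pasted content is real image content, not a
constant — which is what pushes the encoder toward out-of-distribution
robustness.  Rotation, Cutout and CutMix are provided as the baseline
comparators for the augmentation ablation.

All augmentations are pure functions of (inputs, rng state): passing a
generator with the same state reproduces the output bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .exceptions import ConfigError, DataError
from .synthetic import LabeledImage

__all__ = [
    "WPasteConfig",
    "PasteRecord",
    "PositivePair",
    "w_paste",
    "w_paste_detailed",
    "make_positive_pair",
    "rotate_aug",
    "cutout_aug",
    "cutmix_pair",
]


@dataclass(frozen=True)
class WPasteConfig:
    n_patches: int = 2
    patch_size: tuple[int, int] = (15, 15)
    donor_policy: str = "any_sample"  # any_sample | other_class | same_class

    def validate(self, image_shape: tuple[int, int, int]) -> "WPasteConfig":
        if self.n_patches < 1:
            raise ConfigError("n_patches: must be >= 1")
        h, w = self.patch_size
        if h < 1 or w < 1:
            raise ConfigError("patch_size: sides must be >= 1")
        if h > image_shape[1] or w > image_shape[2]:
            raise ConfigError(
                f"patch_size {self.patch_size} does not fit image {image_shape[1:]}"
            )
        if self.donor_policy not in ("any_sample", "other_class", "same_class"):
            raise ConfigError(f"donor_policy: unknown policy {self.donor_policy!r}")
        return self


@dataclass(frozen=True)
class PasteRecord:
    """One executed paste: target rectangle and its donor provenance."""

    target_origin: tuple[int, int]
    donor_index: int
    donor_origin: tuple[int, int]
    size: tuple[int, int]


@dataclass(frozen=True)
class PositivePair:
    view_a: np.ndarray
    view_b: np.ndarray
    source_id: str
    label: int


def _eligible_donors(image: LabeledImage, donor_pool: list[LabeledImage],
                     policy: str) -> list[LabeledImage]:
    pool = [d for d in donor_pool if d.id != image.id]
    if policy == "other_class":
        pool = [d for d in pool if d.label != image.label]
    elif policy == "same_class":
        pool = [d for d in pool if d.label == image.label]
    return pool


def w_paste_detailed(image: LabeledImage, donor_pool: list[LabeledImage],
                     cfg: WPasteConfig, rng: np.random.Generator
                     ) -> tuple[np.ndarray, list[PasteRecord]]:
    """W-Paste with provenance: returns the augmented pixels and one
    :class:`PasteRecord` per pasted rectangle."""
    cfg.validate(image.pixels.shape)
    pool = _eligible_donors(image, donor_pool, cfg.donor_policy)
    if not pool:
        raise DataError("w_paste: donor pool is empty after excluding the anchor")
    ph, pw = cfg.patch_size
    _, h, w = image.pixels.shape
    out = image.pixels.copy()
    records: list[PasteRecord] = []
    for _ in range(cfg.n_patches):
        di = int(rng.integers(len(pool)))
        donor = pool[di]
        _, dh, dw = donor.pixels.shape
        if ph > dh or pw > dw:
            raise ConfigError(
                f"patch {cfg.patch_size} larger than donor image {donor.id} ({dh}x{dw})"
            )
        ty = int(rng.integers(h - ph + 1))
        tx = int(rng.integers(w - pw + 1))
        dy = int(rng.integers(dh - ph + 1))
        dx = int(rng.integers(dw - pw + 1))
        out[:, ty:ty + ph, tx:tx + pw] = donor.pixels[:, dy:dy + ph, dx:dx + pw]
        records.append(PasteRecord((ty, tx), di, (dy, dx), (ph, pw)))
    return out, records


def w_paste(image: LabeledImage, donor_pool: list[LabeledImage],
            cfg: WPasteConfig, rng: np.random.Generator) -> np.ndarray:
    """Cut ``cfg.n_patches`` rectangles and fill each with a same-size crop
    from a donor sample; the output equals the input everywhere else."""
    out, _ = w_paste_detailed(image, donor_pool, cfg, rng)
    return out


def make_positive_pair(image: LabeledImage, donor_pool: list[LabeledImage],
                       cfg: WPasteConfig, rng: np.random.Generator) -> PositivePair:
    """Two independent W-Paste draws from the same source image."""
    view_a = w_paste(image, donor_pool, cfg, rng)
    view_b = w_paste(image, donor_pool, cfg, rng)
    return PositivePair(view_a=view_a, view_b=view_b,
                        source_id=image.id, label=image.label)


# ---------------------------------------------------------- baselines

def rotate_aug(image: LabeledImage, angle_range: tuple[float, float] = (-30.0, 30.0),
               rng: np.random.Generator | None = None,
               angle: float | None = None) -> np.ndarray:
    """Rigid rotation with reflection padding (bilinear interpolation)."""
    if angle is None:
        if rng is None:
            raise ConfigError("rotate_aug: provide either rng or an explicit angle")
        angle = float(rng.uniform(*angle_range))
    out = ndimage.rotate(image.pixels, angle, axes=(1, 2), reshape=False,
                         order=1, mode="reflect")
    return np.clip(out, 0.0, 1.0).astype(np.float32)


def cutout_aug(image: LabeledImage, hole_size: tuple[int, int] = (15, 15),
               n_holes: int = 2, rng: np.random.Generator | None = None) -> np.ndarray:
    """Zero-fill ``n_holes`` rectangles of ``hole_size``."""
    hh, hw = hole_size
    _, h, w = image.pixels.shape
    if hh > h or hw > w:
        raise ConfigError(f"hole_size {hole_size} larger than image {h}x{w}")
    if rng is None:
        raise ConfigError("cutout_aug: rng is required")
    out = image.pixels.copy()
    for _ in range(n_holes):
        ty = int(rng.integers(h - hh + 1))
        tx = int(rng.integers(w - hw + 1))
        out[:, ty:ty + hh, tx:tx + hw] = 0.0
    return out


def cutmix_pair(image_a: LabeledImage, image_b: LabeledImage, lam: float,
                rng: np.random.Generator) -> tuple[np.ndarray, tuple[float, float]]:
    """Paste a rectangle of ``image_b`` into ``image_a`` covering an area
    fraction of about ``1 - lam``; returns the mixed image and the label
    weights ``(lam_eff, 1 - lam_eff)`` computed from the actual area."""
    if not (0.0 < lam < 1.0):
        raise ConfigError("cutmix: lambda must lie strictly in (0, 1)")
    _, h, w = image_a.pixels.shape
    if image_b.pixels.shape != image_a.pixels.shape:
        raise ConfigError("cutmix: images must share a shape")
    rh = int(round(h * np.sqrt(1.0 - lam)))
    rw = int(round(w * np.sqrt(1.0 - lam)))
    rh, rw = min(rh, h), min(rw, w)
    out = image_a.pixels.copy()
    if rh > 0 and rw > 0:
        ty = int(rng.integers(h - rh + 1))
        tx = int(rng.integers(w - rw + 1))
        out[:, ty:ty + rh, tx:tx + rw] = image_b.pixels[:, ty:ty + rh, tx:tx + rw]
    frac = (rh * rw) / (h * w)
    return out, (1.0 - frac, frac)
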