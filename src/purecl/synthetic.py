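"""Synthetic leaf-disease image generation, dataset splitting and folder I/O.

The generator emulates the statistical regime that makes field imagery of
cereal leaf diseases hard: cluttered low-contrast backgrounds, a leaf
occupying only part of the frame, small localized lesion spots whose color
and density carry the class signal, and strong per-image lighting and hue
jitter so that intra-class variance is high relative to inter-class
variance.  It exists so every downstream stage (augmentation, contrastive
pretraining, linear probing) is testable offline, with no photographic
dataset.

Images are float32 arrays of shape (3, H, W) with values in [0, 1]; on
disk they are 8-bit PNG files in the conventional image-folder layout
(one subdirectory per class, subdirectory names in lexicographic order
defining the 0-based label indices).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from PIL import Image

from .exceptions import ConfigError, DataError

__all__ = [
    "LabeledImage",
    "LesionParams",
    "SyntheticDatasetSpec",
    "DatasetSplit",
    "generate_synthetic_dataset",
    "stratified_split",
    "read_image_folder",
    "write_image_folder",
    "scale_class_separation",
    "default_lesion_params",
]

MIN_SIZE = 32  # must admit 15x15 paste patches with margin


@dataclass(frozen=True)
class LabeledImage:
    """An RGB image with a class label — the atomic dataset record."""

    pixels: np.ndarray  # float32, (3, H, W), values in [0, 1]
    label: int
    id: str

    def validate(self, n_classes: int | None = None) -> "LabeledImage":
        p = self.pixels
        if p.ndim != 3 or p.shape[0] != 3:
            raise ConfigError(f"image {self.id}: expected (3, H, W), got {p.shape}")
        if p.shape[1] < MIN_SIZE or p.shape[2] < MIN_SIZE:
            raise ConfigError(f"image {self.id}: spatial size must be >= {MIN_SIZE}")
        if not np.isfinite(p).all():
            raise ConfigError(f"image {self.id}: non-finite pixel values")
        if p.min() < 0 or p.max() > 1:
            raise ConfigError(f"image {self.id}: pixel values outside [0, 1]")
        if n_classes is not None and not (0 <= self.label < n_classes):
            raise ConfigError(f"image {self.id}: label {self.label} outside [0, {n_classes})")
        return self


@dataclass(frozen=True)
class LesionParams:
    """Class-conditional lesion statistics.

    spot_count: inclusive (low, high) range of spots per image.
    spot_radius: (low, high) radius range in pixels.
    color: mean RGB triple of the lesion in [0, 1].
    color_jitter: s.d. of the per-spot Gaussian color perturbation.
    """

    spot_count: tuple[int, int]
    spot_radius: tuple[float, float]
    color: tuple[float, float, float]
    color_jitter: float = 0.10


def default_lesion_params(n_classes: int) -> list[LesionParams]:
    """Distinct lesion palettes for up to eight classes.

    Colors are deliberately close in hue (rusty browns/yellows/grays) so
    inter-class differences are small next to the lighting jitter.
    """
    palette = [
        (0.62, 0.28, 0.08),  # brown rust
        (0.85, 0.72, 0.10),  # yellow rust
        (0.22, 0.20, 0.18),  # dark necrotic
        (0.88, 0.86, 0.78),  # pale mildew
        (0.55, 0.08, 0.06),  # deep red-brown
        (0.68, 0.52, 0.28),  # tan spot
        (0.25, 0.12, 0.22),  # smut-like
        (0.78, 0.42, 0.12),  # orange blight
    ]
    counts = [(8, 16), (10, 18), (7, 14), (8, 17), (9, 16), (7, 15), (8, 18), (7, 16)]
    radii = [(2.5, 5.0), (2.5, 5.5), (3.0, 5.5), (2.5, 4.5), (3.0, 5.0), (2.5, 5.5), (3.0, 5.0), (2.5, 5.0)]
    if n_classes > len(palette):
        raise ConfigError(f"default lesion palettes cover at most {len(palette)} classes")
    return [
        LesionParams(spot_count=counts[i], spot_radius=radii[i], color=palette[i])
        for i in range(n_classes)
    ]


@dataclass(frozen=True)
class SyntheticDatasetSpec:
    n_classes: int = 3
    n_per_class: int = 100
    image_size: tuple[int, int] = (64, 64)
    lesion_params: tuple[LesionParams, ...] | None = None
    background_clutter: float = 0.6
    intra_class_jitter: float = 0.5
    seed: int = 0

    def resolved_lesions(self) -> list[LesionParams]:
        if self.lesion_params is None:
            return default_lesion_params(self.n_classes)
        return list(self.lesion_params)

    def to_yaml(self, path) -> None:
        import yaml

        d = {
            "n_classes": self.n_classes,
            "n_per_class": self.n_per_class,
            "image_size": list(self.image_size),
            "background_clutter": self.background_clutter,
            "intra_class_jitter": self.intra_class_jitter,
            "seed": self.seed,
        }
        if self.lesion_params is not None:
            d["lesion_params"] = [
                {"spot_count": list(lp.spot_count), "spot_radius": list(lp.spot_radius),
                 "color": list(lp.color), "color_jitter": lp.color_jitter}
                for lp in self.lesion_params
            ]
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "SyntheticDatasetSpec":
        import yaml

        d = yaml.safe_load(Path(path).read_text())
        if "image_size" in d:
            d["image_size"] = tuple(d["image_size"])
        if d.get("lesion_params") is not None:
            d["lesion_params"] = tuple(
                LesionParams(spot_count=tuple(lp["spot_count"]),
                             spot_radius=tuple(lp["spot_radius"]),
                             color=tuple(lp["color"]),
                             color_jitter=lp.get("color_jitter", 0.10))
                for lp in d["lesion_params"]
            )
        return cls(**d).validate()

    def validate(self) -> "SyntheticDatasetSpec":
        if self.n_classes < 2:
            raise ConfigError("n_classes: must be >= 2")
        if self.n_per_class < 1:
            raise ConfigError("n_per_class: must be >= 1")
        h, w = self.image_size
        if h < MIN_SIZE or w < MIN_SIZE:
            raise ConfigError(f"image_size: each side must be >= {MIN_SIZE}")
        if not (0.0 <= self.background_clutter <= 1.0):
            raise ConfigError("background_clutter: must be in [0, 1]")
        if self.intra_class_jitter < 0:
            raise ConfigError("intra_class_jitter: must be >= 0")
        lesions = self.resolved_lesions()
        if len(lesions) != self.n_classes:
            raise ConfigError("lesion_params: need one entry per class")
        for i, lp in enumerate(lesions):
            if lp.spot_radius[1] * 2 >= min(h, w):
                raise ConfigError(f"lesion_params[{i}].spot_radius: spot diameter exceeds image size")
            if lp.spot_count[0] < 0 or lp.spot_count[0] > lp.spot_count[1]:
                raise ConfigError(f"lesion_params[{i}].spot_count: invalid range")
        if len({(lp.spot_count, lp.spot_radius, lp.color) for lp in lesions}) != self.n_classes:
            raise ConfigError("lesion_params: class parameter sets must be pairwise distinct")
        return self


@dataclass
class DatasetSplit:
    train: list[LabeledImage]
    val: list[LabeledImage]
    test: list[LabeledImage]
    ratios: tuple[float, float, float] = (0.7, 0.2, 0.1)

    def __iter__(self):
        yield from (self.train, self.val, self.test)


# ------------------------------------------------------------ generation

def _coord_grids(h: int, w: int):
    yy, xx = np.mgrid[0:h, 0:w]
    return yy.astype(np.float32), xx.astype(np.float32)


def _render_background(rng, h, w, clutter: float) -> np.ndarray:
    """Soil/straw-like backdrop: smooth color field plus random elliptical blobs."""
    base = np.array([0.45, 0.40, 0.28], dtype=np.float32)
    img = np.empty((3, h, w), dtype=np.float32)
    yy, xx = _coord_grids(h, w)
    grad = (yy / h - 0.5) * rng.uniform(-0.2, 0.2) + (xx / w - 0.5) * rng.uniform(-0.2, 0.2)
    for c in range(3):
        img[c] = base[c] + rng.uniform(-0.08, 0.08) + grad
    n_blobs = int(round(clutter * 12))
    for _ in range(n_blobs):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        ry, rx = rng.uniform(2, h / 4), rng.uniform(2, w / 4)
        theta = rng.uniform(0, np.pi)
        color = rng.uniform(0.15, 0.75, size=3).astype(np.float32)
        yr = (yy - cy) * np.cos(theta) + (xx - cx) * np.sin(theta)
        xr = -(yy - cy) * np.sin(theta) + (xx - cx) * np.cos(theta)
        mask = ((yr / ry) ** 2 + (xr / rx) ** 2 < 1.0).astype(np.float32)
        alpha = clutter * rng.uniform(0.3, 0.8) * mask
        img += alpha * (color[:, None, None] - img)
    img += (clutter * 0.05 * rng.standard_normal((3, h, w))).astype(np.float32)
    return img


def _leaf_mask(rng, h, w, jitter: float):
    yy, xx = _coord_grids(h, w)
    cy = h / 2 + rng.uniform(-jitter * h / 8, jitter * h / 8)
    cx = w / 2 + rng.uniform(-jitter * w / 8, jitter * w / 8)
    ry = h * rng.uniform(0.32, 0.42)
    rx = w * rng.uniform(0.18, 0.28)
    theta = rng.uniform(0, np.pi)
    yr = (yy - cy) * np.cos(theta) + (xx - cx) * np.sin(theta)
    xr = -(yy - cy) * np.sin(theta) + (xx - cx) * np.cos(theta)
    d = (yr / ry) ** 2 + (xr / rx) ** 2
    return (d < 1.0).astype(np.float32), (cy, cx, ry, rx, theta)


def _render_image(rng, spec: SyntheticDatasetSpec, lesion: LesionParams) -> np.ndarray:
    h, w = spec.image_size
    jitter = spec.intra_class_jitter
    img = _render_background(rng, h, w, spec.background_clutter)

    mask, (cy, cx, ry, rx, theta) = _leaf_mask(rng, h, w, jitter)
    leaf_color = np.array([0.22, 0.45, 0.16], dtype=np.float32)
    leaf_color = leaf_color * (1.0 + jitter * rng.uniform(-0.35, 0.35, size=3)).astype(np.float32)
    yy, xx = _coord_grids(h, w)
    vein = 0.03 * np.sin((np.cos(theta) * yy + np.sin(theta) * xx) * 0.9)
    for c in range(3):
        img[c] = img[c] * (1 - mask) + mask * np.clip(leaf_color[c] + vein, 0, 1)

    n_spots = int(rng.integers(lesion.spot_count[0], lesion.spot_count[1] + 1))
    color = np.asarray(lesion.color, dtype=np.float32)
    for _ in range(n_spots):
        # rejection-free placement inside the leaf ellipse
        u, v = rng.uniform(-0.8, 0.8), rng.uniform(-0.8, 0.8)
        sy = cy + u * ry * np.cos(theta) - v * rx * np.sin(theta)
        sx = cx + u * ry * np.sin(theta) + v * rx * np.cos(theta)
        r = rng.uniform(*lesion.spot_radius)
        spot_color = np.clip(color + lesion.color_jitter * rng.standard_normal(3).astype(np.float32), 0, 1)
        d2 = (yy - sy) ** 2 + (xx - sx) ** 2
        soft = np.clip(1.0 - d2 / (r * r), 0.0, 1.0) ** 0.5
        soft *= mask  # lesions live on the leaf
        for c in range(3):
            img[c] = img[c] * (1 - soft) + soft * spot_color[c]

    # global lighting jitter: brightness/contrast drift across the class
    gain = 1.0 + jitter * rng.uniform(-0.3, 0.3)
    offset = jitter * rng.uniform(-0.1, 0.1)
    img = img * gain + offset
    return np.clip(img, 0.0, 1.0).astype(np.float32)


def generate_synthetic_dataset(spec: SyntheticDatasetSpec) -> list[LabeledImage]:
    """Generate ``n_classes * n_per_class`` labeled images, bit-reproducible
    from ``spec.seed`` (images appear class-by-class, index-by-index)."""
    spec.validate()
    lesions = spec.resolved_lesions()
    rng = np.random.default_rng(spec.seed)
    images: list[LabeledImage] = []
    for label in range(spec.n_classes):
        for i in range(spec.n_per_class):
            pixels = _render_image(rng, spec, lesions[label])
            images.append(LabeledImage(pixels=pixels, label=label, id=f"c{label}_{i:04d}"))
    return images


def scale_class_separation(spec: SyntheticDatasetSpec, factor: float) -> SyntheticDatasetSpec:
    """Move class lesion colors away from (factor > 1) or toward (factor < 1)
    their common mean — a dial for class separability studies."""
    lesions = spec.resolved_lesions()
    mean = np.mean([lp.color for lp in lesions], axis=0)
    scaled = tuple(
        replace(lp, color=tuple(np.clip(mean + factor * (np.asarray(lp.color) - mean), 0, 1)))
        for lp in lesions
    )
    return replace(spec, lesion_params=scaled)


# -------------------------------------------------------------- splitting

def stratified_split(images: list[LabeledImage], ratios=(0.7, 0.2, 0.1),
                     seed: int = 0) -> DatasetSplit:
    """Deterministic stratified partition into train/val/test.

    Per-class allocation uses largest-remainder rounding, so each class's
    split sizes deviate from the exact ratios by at most one sample.
    """
    ratios = tuple(float(r) for r in ratios)
    if len(ratios) != 3 or any(r < 0 for r in ratios) or abs(sum(ratios) - 1.0) > 1e-9:
        raise ConfigError(f"ratios must be three non-negatives summing to 1, got {ratios}")
    by_class: dict[int, list[int]] = {}
    for idx, img in enumerate(images):
        by_class.setdefault(img.label, []).append(idx)
    for label, idxs in sorted(by_class.items()):
        if len(idxs) < 3:
            raise DataError(f"class {label} has only {len(idxs)} images; need >= 3 to split")
    rng = np.random.default_rng(seed)
    parts: tuple[list[LabeledImage], ...] = ([], [], [])
    for label in sorted(by_class):
        idxs = np.array(by_class[label])
        rng.shuffle(idxs)
        n = len(idxs)
        exact = np.array(ratios) * n
        counts = np.floor(exact).astype(int)
        remainder = exact - counts
        for _ in range(n - counts.sum()):
            k = int(np.argmax(remainder))
            counts[k] += 1
            remainder[k] = -1
        bounds = np.cumsum(counts)
        for part, lo, hi in zip(parts, np.concatenate([[0], bounds[:-1]]), bounds):
            part.extend(images[i] for i in idxs[lo:hi])
    return DatasetSplit(train=parts[0], val=parts[1], test=parts[2], ratios=ratios)


# ------------------------------------------------------------- folder I/O

def write_image_folder(images: list[LabeledImage], path,
                       class_names: list[str] | None = None) -> None:
    """Write as 8-bit PNGs under ``path/<class>/<id>.png``.

    Default class names are ``class_0 ... class_{k-1}``, which sort
    lexicographically in label order for k <= 10.
    """
    if not images:
        raise DataError("write_image_folder: no images to write")
    path = Path(path)
    labels = sorted({img.label for img in images})
    if class_names is None:
        class_names = [f"class_{k}" for k in labels]
    name_of = dict(zip(labels, class_names))
    for img in images:
        sub = path / name_of[img.label]
        sub.mkdir(parents=True, exist_ok=True)
        arr = np.clip(np.round(img.pixels * 255.0), 0, 255).astype(np.uint8)
        Image.fromarray(arr.transpose(1, 2, 0)).save(sub / f"{img.id}.png")


def read_image_folder(path) -> list[LabeledImage]:
    """Read an image-folder dataset; lexicographic subdirectory order
    defines the 0-based label indices."""
    path = Path(path)
    if not path.is_dir():
        raise IOError(f"not a directory: {path}")
    class_dirs = sorted(d for d in path.iterdir() if d.is_dir())
    if not class_dirs:
        raise IOError(f"no class subdirectories under {path}")
    images: list[LabeledImage] = []
    for label, d in enumerate(class_dirs):
        files = sorted(f for f in d.iterdir() if f.is_file())
        if not files:
            raise IOError(f"empty class directory: {d}")
        for f in files:
            try:
                with Image.open(f) as im:
                    arr = np.asarray(im.convert("RGB"), dtype=np.float32) / 255.0
            except Exception as exc:  # non-image / unreadable file
                raise IOError(f"cannot read image file {f}: {exc}") from exc
            images.append(LabeledImage(pixels=np.ascontiguousarray(arr.transpose(2, 0, 1)),
                                       label=label, id=f.stem))
    return images
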