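"""Two-stage training orchestration.

Stage 1 pretrains the feature-purification encoder with the supervised
contrastive loss on W-Paste positive pairs (interference features are
subtracted until ``switch_epoch``, then added — "reverse learning").
Stage 2 freezes the encoder and trains a single linear classifier on its
2048-d embeddings with cross-entropy, selecting the epoch with the best
validation accuracy.  ``run_experiment`` wires data splitting, both
stages, evaluation and artifact writing into one reproducible run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import nn
from .augment import (PositivePair, WPasteConfig, cutmix_pair, cutout_aug,
                      make_positive_pair, rotate_aug)
from .contrastive import ProjectionHead, build_multiview_batch, supcon_loss
from .encoder import (EMBED_DIM, FeaturePurificationEncoder, FilterMode,
                      filter_mode_for_epoch)
from .exceptions import ConfigError, DataError
from .metrics import ClassificationMetrics, confusion_matrix, metrics_from_confusion
from .nn import Tensor
from .synthetic import (DatasetSplit, LabeledImage, SyntheticDatasetSpec,
                        generate_synthetic_dataset, read_image_folder,
                        stratified_split)

__all__ = [
    "TrainConfig",
    "LinearClassifier",
    "train_contrastive",
    "train_linear_probe",
    "train_probe_on_embeddings",
    "evaluate",
    "run_experiment",
    "run_ablation",
    "untrained_baseline",
    "params_checksum",
    "inference_mode_for",
    "ExperimentResult",
    "cross_entropy",
]

AUGMENTATIONS = ("w_paste", "rotate", "cutout", "cutmix")


@dataclass(frozen=True)
class TrainConfig:
    """All schedule hyperparameters for the two training stages.

    Defaults follow the published schedule where one exists (batch size 8,
    200 contrastive epochs with the subtract-to-add switch after epoch 15,
    20 probe epochs, 7:2:1 split); the optimizer settings (SGD with
    momentum, lr 0.01 for both stages) and the temperature 0.07 are
    conventional small-batch contrastive choices.
    """

    stage1_epochs: int = 200
    stage2_epochs: int = 20
    batch_size: int = 8
    switch_epoch: int = 15
    temperature: float = 0.07
    lr_stage1: float = 0.01
    lr_stage2: float = 0.01
    momentum: float = 0.9
    weight_decay: float = 0.0
    stage2_batch_size: int = 32
    seed: int = 0
    augmentation: str = "w_paste"
    wpaste: WPasteConfig = field(default_factory=WPasteConfig)
    rotate_range: tuple[float, float] = (-30.0, 30.0)
    cutout_size: tuple[int, int] = (15, 15)
    cutout_holes: int = 2
    split_ratios: tuple[float, float, float] = (0.7, 0.2, 0.1)
    export_embeddings: bool = False
    # optional departure from the frozen-encoder design: stage 2 updates
    # the whole network with cross-entropy instead of only the linear head
    stage2_fine_tune: bool = False

    def validate(self) -> "TrainConfig":
        if self.stage1_epochs < 0 or self.stage2_epochs < 1:
            raise ConfigError("epoch counts: stage1 >= 0, stage2 >= 1 required")
        if self.batch_size < 2:
            raise ConfigError("batch_size: must be >= 2 (a batch needs a donor)")
        if self.switch_epoch < 0 or self.switch_epoch > max(self.stage1_epochs, 0):
            raise ConfigError("switch_epoch: must lie in [0, stage1_epochs]")
        if self.temperature <= 0:
            raise ConfigError("temperature: must be positive")
        if self.augmentation not in AUGMENTATIONS:
            raise ConfigError(f"augmentation: unknown choice {self.augmentation!r}")
        return self

    # ------------------------------------------------------------- YAML
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["wpaste"] = dataclasses.asdict(self.wpaste)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        d = dict(d)
        if "wpaste" in d and isinstance(d["wpaste"], dict):
            wp = dict(d["wpaste"])
            if "patch_size" in wp:
                wp["patch_size"] = tuple(wp["patch_size"])
            d["wpaste"] = WPasteConfig(**wp)
        for key in ("rotate_range", "cutout_size", "split_ratios"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d).validate()

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "TrainConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def inference_mode_for(config: TrainConfig) -> FilterMode:
    """FilterMode used at embedding time: the mode of the final pretraining
    epoch (epoch 0's mode if no pretraining ran)."""
    return filter_mode_for_epoch(max(config.stage1_epochs - 1, 0), config.switch_epoch)


def _seed_rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, stream]))


def params_checksum(module: nn.Module) -> str:
    """SHA-256 over all parameters and buffers — the frozen-encoder witness."""
    h = hashlib.sha256()
    for name, arr in sorted(module.state_dict().items()):
        h.update(name.encode())
        h.update(np.ascontiguousarray(arr).tobytes())
    return h.hexdigest()


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy for integer labels."""
    labels = np.asarray(labels, dtype=int)
    n, k = logits.shape
    onehot = np.zeros((n, k), dtype=logits.dtype)
    onehot[np.arange(n), labels] = 1.0
    lse = nn.logsumexp(logits, axis=1)
    picked = (logits * Tensor(onehot)).sum(axis=1)
    return (lse - picked).mean()


# --------------------------------------------------------------- stage 1

def _make_pair(image: LabeledImage, batch: list[LabeledImage], config: TrainConfig,
               rng: np.random.Generator) -> PositivePair:
    aug = config.augmentation
    if aug == "w_paste":
        return make_positive_pair(image, batch, config.wpaste, rng)
    if aug == "rotate":
        views = [rotate_aug(image, config.rotate_range, rng) for _ in range(2)]
    elif aug == "cutout":
        views = [cutout_aug(image, config.cutout_size, config.cutout_holes, rng)
                 for _ in range(2)]
    elif aug == "cutmix":
        # ablation harness: the anchor's label is kept; lambda stays > 0.5
        # so the anchor dominates each view
        others = [b for b in batch if b.id != image.id]
        views = []
        for _ in range(2):
            partner = others[int(rng.integers(len(others)))]
            lam = float(rng.uniform(0.5, 0.95))
            mixed, _ = cutmix_pair(image, partner, lam, rng)
            views.append(mixed)
    else:  # pragma: no cover - guarded by validate()
        raise ConfigError(f"unknown augmentation {aug!r}")
    return PositivePair(view_a=views[0], view_b=views[1],
                        source_id=image.id, label=image.label)


def train_contrastive(train_images: list[LabeledImage], config: TrainConfig,
                      verbose: bool = False):
    """Stage-1 pretraining.

    Returns ``(encoder, projector, log)`` where ``log`` is a list of
    per-epoch records ``{"epoch", "mode", "mean_loss"}``.
    """
    config.validate()
    if len({img.label for img in train_images}) < 2:
        raise DataError("contrastive pretraining needs at least two classes "
                        "(a single-class set has no negatives)")
    encoder = FeaturePurificationEncoder(_seed_rng(config.seed, 0))
    projector = ProjectionHead(_seed_rng(config.seed, 1))
    if config.stage1_epochs == 0:
        return encoder, projector, []
    data_rng = _seed_rng(config.seed, 2)
    opt = nn.SGD(encoder.parameters() + projector.parameters(),
                 lr=config.lr_stage1, momentum=config.momentum,
                 weight_decay=config.weight_decay)
    n = len(train_images)
    log: list[dict] = []
    encoder.train()
    projector.train()
    for epoch in range(config.stage1_epochs):
        mode = filter_mode_for_epoch(epoch, config.switch_epoch)
        order = data_rng.permutation(n)
        losses = []
        for lo in range(0, n, config.batch_size):
            idx = order[lo:lo + config.batch_size]
            if len(idx) < 2:
                continue
            batch = [train_images[i] for i in idx]
            pairs = [_make_pair(img, batch, config, data_rng) for img in batch]
            mv = build_multiview_batch(pairs, encoder, projector,
                                       temperature=config.temperature, mode=mode)
            loss = supcon_loss(mv, reduction="mean_over_anchors")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        record = {"epoch": epoch, "mode": mode.value,
                  "mean_loss": float(np.mean(losses)) if losses else float("nan")}
        log.append(record)
        if verbose:
            print(f"[stage1] epoch {epoch:3d} mode={mode.value:8s} "
                  f"loss={record['mean_loss']:.4f}")
    return encoder, projector, log


# --------------------------------------------------------------- stage 2

class LinearClassifier(nn.Module):
    """Single linear layer on frozen encoder embeddings."""

    def __init__(self, n_classes: int, rng: np.random.Generator | int = 0,
                 in_dim: int = EMBED_DIM):
        super().__init__()
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        self.n_classes = n_classes
        self.fc = nn.Linear(in_dim, n_classes, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc(x)

    def predict(self, embeddings: np.ndarray) -> np.ndarray:
        logits = self.fc(Tensor(np.asarray(embeddings, dtype=np.float32)))
        return np.argmax(logits.data, axis=1)


def train_probe_on_embeddings(embeddings: np.ndarray, labels: np.ndarray,
                              n_classes: int, config: TrainConfig,
                              val: tuple[np.ndarray, np.ndarray] | None = None
                              ) -> LinearClassifier:
    """Train the linear probe with cross-entropy on precomputed embeddings.

    With a validation pair the parameters from the best-validation-accuracy
    epoch are restored at the end.
    """
    embeddings = np.asarray(embeddings, dtype=np.float32)
    labels = np.asarray(labels, dtype=int)
    present = set(labels.tolist())
    missing = [c for c in range(n_classes) if c not in present]
    if missing:
        raise DataError(f"classes absent from probe training data: {missing}")
    clf = LinearClassifier(n_classes, _seed_rng(config.seed, 3),
                           in_dim=embeddings.shape[1])
    opt = nn.SGD(clf.parameters(), lr=config.lr_stage2, momentum=config.momentum)
    rng = _seed_rng(config.seed, 4)
    n = len(labels)
    best_state, best_acc = None, -1.0
    for _ in range(config.stage2_epochs):
        order = rng.permutation(n)
        for lo in range(0, n, config.stage2_batch_size):
            idx = order[lo:lo + config.stage2_batch_size]
            logits = clf(Tensor(embeddings[idx]))
            loss = cross_entropy(logits, labels[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
        if val is not None:
            acc = float(np.mean(clf.predict(val[0]) == val[1]))
            if acc > best_acc:
                best_acc = acc
                best_state = clf.state_dict()
    if best_state is not None:
        clf.load_state_dict(best_state)
    return clf


def train_linear_probe(encoder: FeaturePurificationEncoder,
                       train_images: list[LabeledImage], config: TrainConfig,
                       val_images: list[LabeledImage] | None = None,
                       mode: FilterMode | None = None) -> LinearClassifier:
    """Stage 2: freeze the encoder, train the linear classifier.

    By default the encoder's parameters are untouched (eval-mode embedding
    only; ``params_checksum`` before and after is identical).  With
    ``config.stage2_fine_tune`` the whole network is updated instead.
    """
    config.validate()
    mode = mode or inference_mode_for(config)
    labels = np.array([img.label for img in train_images])
    n_classes = int(labels.max()) + 1
    if config.stage2_fine_tune:
        return _fine_tune_stage2(encoder, train_images, labels, n_classes,
                                 config, mode, val_images)
    emb = encoder.embed(np.stack([i.pixels for i in train_images]), mode)
    val = None
    if val_images:
        val_emb = encoder.embed(np.stack([i.pixels for i in val_images]), mode)
        val = (val_emb, np.array([i.label for i in val_images]))
    return train_probe_on_embeddings(emb, labels, n_classes, config, val=val)


def _fine_tune_stage2(encoder, train_images, labels, n_classes, config, mode,
                      val_images) -> LinearClassifier:
    """Joint cross-entropy update of encoder + classifier (opt-in)."""
    present = set(labels.tolist())
    missing = [c for c in range(n_classes) if c not in present]
    if missing:
        raise DataError(f"classes absent from stage-2 training data: {missing}")
    clf = LinearClassifier(n_classes, _seed_rng(config.seed, 3))
    opt = nn.SGD(encoder.parameters() + clf.parameters(),
                 lr=config.lr_stage2, momentum=config.momentum)
    rng = _seed_rng(config.seed, 5)
    pixels = np.stack([i.pixels for i in train_images]).astype(np.float32)
    n = len(labels)
    best = None
    best_acc = -1.0
    for _ in range(config.stage2_epochs):
        encoder.train()
        order = rng.permutation(n)
        for lo in range(0, n, config.batch_size):
            idx = order[lo:lo + config.batch_size]
            emb = encoder(Tensor(pixels[idx]), mode)
            loss = cross_entropy(clf(emb), labels[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
        if val_images:
            val_emb = encoder.embed(np.stack([i.pixels for i in val_images]), mode)
            acc = float(np.mean(clf.predict(val_emb) ==
                                np.array([i.label for i in val_images])))
            if acc > best_acc:
                best_acc = acc
                best = (encoder.state_dict(), clf.state_dict())
    if best is not None:
        encoder.load_state_dict(best[0])
        clf.load_state_dict(best[1])
    encoder.eval()
    return clf


def evaluate(encoder: FeaturePurificationEncoder, classifier: LinearClassifier,
             test_images: list[LabeledImage], mode: FilterMode = FilterMode.ADD,
             class_names: list[str] | None = None) -> ClassificationMetrics:
    """Frozen-encoder evaluation on a held-out split."""
    if not test_images:
        raise DataError("test split is empty")
    y_true = np.array([img.label for img in test_images])
    unseen = sorted(set(y_true.tolist()) - set(range(classifier.n_classes)))
    if unseen:
        raise DataError(f"test set contains labels unseen in training: {unseen}")
    emb = encoder.embed(np.stack([i.pixels for i in test_images]), mode)
    y_pred = classifier.predict(emb)
    cm = confusion_matrix(y_true, y_pred, classifier.n_classes)
    return metrics_from_confusion(cm, class_names)


def untrained_baseline(config: TrainConfig, split: DatasetSplit) -> ClassificationMetrics:
    """Linear probe on the embeddings of a freshly initialized (untrained)
    encoder — the random-feature control an end-to-end run must beat."""
    encoder = FeaturePurificationEncoder(_seed_rng(config.seed, 0))
    mode = inference_mode_for(config)
    clf = train_linear_probe(encoder, split.train, config,
                             val_images=split.val, mode=mode)
    return evaluate(encoder, clf, split.test, mode)


# ------------------------------------------------------------ experiment

@dataclass
class ExperimentResult:
    config: TrainConfig
    metrics: ClassificationMetrics
    encoder: FeaturePurificationEncoder
    classifier: LinearClassifier
    train_log: list[dict]
    inference_mode: FilterMode
    split: DatasetSplit
    run_dir: Path | None = None


def _resolve_images(data_source) -> list[LabeledImage]:
    if isinstance(data_source, SyntheticDatasetSpec):
        return generate_synthetic_dataset(data_source)
    if isinstance(data_source, (str, Path)):
        return read_image_folder(data_source)
    return list(data_source)


def run_experiment(config: TrainConfig, data_source,
                   out_dir=None, verbose: bool = False) -> ExperimentResult:
    """Full two-stage run: stratified split, contrastive pretraining,
    linear probe, evaluation; artifacts written under ``out_dir``."""
    config.validate()
    images = _resolve_images(data_source)
    split = stratified_split(images, config.split_ratios, seed=config.seed)
    encoder, projector, log = train_contrastive(split.train, config, verbose=verbose)
    mode = inference_mode_for(config)
    classifier = train_linear_probe(encoder, split.train, config,
                                    val_images=split.val, mode=mode)
    metrics = evaluate(encoder, classifier, split.test, mode)
    result = ExperimentResult(config=config, metrics=metrics, encoder=encoder,
                              classifier=classifier, train_log=log,
                              inference_mode=mode, split=split)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out_dir / "config.yaml")
        (out_dir / "metrics.json").write_text(json.dumps(metrics.to_dict(), indent=2))
        metrics.per_class.to_csv(out_dir / "per_class.csv", index=False)
        pd.DataFrame(metrics.confusion).to_csv(out_dir / "confusion.csv", index=False)
        pd.DataFrame(log).to_csv(out_dir / "train_log.csv", index=False)
        nn.save_checkpoint(out_dir / "encoder.npz", encoder,
                           meta={"inference_mode": mode.value, "seed": config.seed})
        nn.save_checkpoint(out_dir / "classifier.npz", classifier,
                           meta={"n_classes": classifier.n_classes})
        if config.export_embeddings:
            emb = encoder.embed(np.stack([i.pixels for i in split.test]), mode)
            cols = pd.DataFrame(emb)
            cols.insert(0, "label", [i.label for i in split.test])
            cols.to_csv(out_dir / "test_embeddings.csv", index=False)
        result.run_dir = out_dir
    return result


def run_ablation(config: TrainConfig, data_source,
                 augmentations=AUGMENTATIONS, verbose: bool = False) -> pd.DataFrame:
    """Augmentation sweep with a shared seed: one experiment per positive-
    pair strategy, reported as a four-column metrics table."""
    rows = []
    for aug in augmentations:
        res = run_experiment(replace(config, augmentation=aug), data_source,
                             verbose=verbose)
        m = res.metrics
        rows.append({"augmentation": aug, "accuracy": m.accuracy,
                     "precision": m.macro_precision, "recall": m.macro_recall,
                     "f1": m.macro_f1})
    return pd.DataFrame(rows)
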