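"""Splitting, pretraining, fine-tuning and the two experiment protocols.

The transfer-learning recipe: pretrain the classifier on analytically
simulated wavefields, then freeze the convolutional block (conv weights and
batch-norm statistics stay bit-identical), replace the softmax classifier
with a freshly initialized one, and retrain the dense head on the small
physical-format dataset with a learning rate decaying from 1e-3 to 1e-4.
The "no fine-tuning" baseline trains the same architecture from scratch on
the physical-format data alone.

Splits are stratified per class: test = ⌊0.2·n⌋, then the remaining pool is
divided 70:30 into train and validation (val = round(0.3·pool)). With 52
samples per class this gives 10 test, 13 validation and 29 training samples
per class.
"""

from __future__ import annotations

import copy
import json
import tempfile
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal

import numpy as np

from . import _nn
from .augment import AugmentConfig, augment_training_set
from .cnn_model import CNNClassifier, ModelSpec, build_model
from .errors import ConfigError, ProtocolError
from .metrics import EvalReport, evaluate_predictions
from .patches import LabeledDataset
from .sldv_io import ingest_fixture_dir, write_fixture
from .wavesim import (
    BINARY_CLASSES_KPA,
    MULTICLASS_CLASSES_KPA,
    GridSpec,
    SourcePlacementSpec,
    estimate_wavelength,
    make_synthetic_dataset,
    wavelength,
    ViscoelasticMedium,
)


def stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage seed from the run seed and the stage name.

    Documented derivation (CRC-32 of the stage name mixed with the run
    seed, reduced mod 2³¹) so any stage can be reproduced in isolation.
    """
    return (seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass(frozen=True)
class DataSplit:
    """Disjoint train/validation/test index sets over one dataset."""

    train: tuple[int, ...]
    val: tuple[int, ...]
    test: tuple[int, ...]

    def __post_init__(self) -> None:
        sets = [set(self.train), set(self.val), set(self.test)]
        if sum(len(s) for s in sets) != len(set().union(*sets)):
            raise ConfigError("train/val/test index sets must be pairwise disjoint")

    @property
    def n_total(self) -> int:
        return len(self.train) + len(self.val) + len(self.test)


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters for (pre)training.

    The binary protocol uses binary cross-entropy, lr 1e-4 and batch 10;
    the 5-class protocol categorical cross-entropy, lr 1e-3 and batch 16;
    both run 30 epochs with Adam. (With a softmax output the two losses
    coincide numerically; the name records the protocol.)
    """

    loss: Literal["bce", "cce"]
    learning_rate: float
    batch_size: int
    epochs: int = 30
    seed: int = 0


@dataclass(frozen=True)
class FineTuneConfig:
    """Hyperparameters of the freeze-and-fine-tune stage."""

    lr_start: float = 1e-3
    lr_end: float = 1e-4
    schedule: Literal["geometric", "linear"] = "geometric"
    batch_size: int = 12
    epochs: int = 30
    seed: int = 0
    freeze_conv_block: bool = True


def binary_train_config(seed: int = 0, epochs: int = 30) -> TrainConfig:
    return TrainConfig("bce", 1e-4, 10, epochs=epochs, seed=seed)


def multiclass_train_config(seed: int = 0, epochs: int = 30) -> TrainConfig:
    return TrainConfig("cce", 1e-3, 16, epochs=epochs, seed=seed)


def split_dataset(dataset: LabeledDataset, seed: int = 0) -> DataSplit:
    """Stratified 80:20 train-pool/test split, then 70:30 train/val."""
    labels = dataset.labels
    rng = np.random.default_rng(seed)
    train: list[int] = []
    val: list[int] = []
    test: list[int] = []
    for c in range(dataset.n_classes):
        idx = np.flatnonzero(labels == c)
        if len(idx) < 5:
            raise ConfigError(
                f"class {c} has only {len(idx)} samples; need ≥ 5 to split"
            )
        idx = idx[rng.permutation(len(idx))]
        n_test = int(np.floor(0.2 * len(idx)))
        pool = idx[n_test:]
        n_val = int(np.floor(0.3 * len(pool) + 0.5))
        test.extend(idx[:n_test].tolist())
        val.extend(pool[:n_val].tolist())
        train.extend(pool[n_val:].tolist())
    return DataSplit(tuple(sorted(train)), tuple(sorted(val)), tuple(sorted(test)))


def _lr_schedule(config: FineTuneConfig, epoch: int) -> float:
    if config.epochs == 1:
        return config.lr_start
    frac = epoch / (config.epochs - 1)
    if config.schedule == "geometric":
        return config.lr_start * (config.lr_end / config.lr_start) ** frac
    return config.lr_start + frac * (config.lr_end - config.lr_start)


def _epoch_metrics(model: CNNClassifier, X: np.ndarray, y: np.ndarray
                   ) -> tuple[float, float]:
    probs = model.predict_proba(X)
    loss = _nn.cross_entropy(probs, y)
    acc = float(np.mean(probs.argmax(axis=1) == y))
    return loss, acc


def _train_loop(
    model: CNNClassifier,
    dataset: LabeledDataset,
    split: DataSplit,
    epochs: int,
    batch_size: int,
    seed: int,
    lr_for_epoch,
    trainable: set[str] | None = None,
) -> dict[str, list[float]]:
    X_train, y_train = dataset.as_arrays(split.train)
    X_val, y_val = dataset.as_arrays(split.val) if split.val else (None, None)
    rng = np.random.default_rng(seed)
    optimizer = _nn.Adam(model.params(), lr=lr_for_epoch(0), trainable=trainable)
    stop = 0
    if trainable is not None:
        stop = model.lowest_trainable_index(set(trainable))
    history: dict[str, list[float]] = {
        "train_loss": [], "train_acc": [], "val_loss": [], "val_acc": [],
        "lr": [],
    }
    n = len(X_train)
    for epoch in range(epochs):
        optimizer.lr = lr_for_epoch(epoch)
        order = rng.permutation(n)
        # train metrics accumulated over the epoch's own batches
        loss_sum = 0.0
        correct = 0
        for start in range(0, n, batch_size):
            batch = order[start:start + batch_size]
            logits = model.forward(X_train[batch], training=True)
            probs = _nn.softmax(logits)
            yb = y_train[batch]
            loss_sum += _nn.cross_entropy(probs, yb) * len(batch)
            correct += int(np.sum(probs.argmax(axis=1) == yb))
            model.backward(_nn.cross_entropy_grad(probs, yb), stop_index=stop)
            optimizer.step(model.grads())
        history["train_loss"].append(loss_sum / n)
        history["train_acc"].append(correct / n)
        history["lr"].append(optimizer.lr)
        if X_val is not None:
            v_loss, v_acc = _epoch_metrics(model, X_val, y_val)
            history["val_loss"].append(v_loss)
            history["val_acc"].append(v_acc)
    return history


def pretrain(
    model: CNNClassifier,
    dataset: LabeledDataset,
    split: DataSplit,
    config: TrainConfig,
) -> tuple[CNNClassifier, dict[str, list[float]]]:
    """Train all parameters on the (synthetic) dataset's training split."""
    if dataset.n_classes != model.spec.n_classes:
        raise ConfigError(
            f"dataset has {dataset.n_classes} classes but model expects "
            f"{model.spec.n_classes}"
        )
    history = _train_loop(
        model, dataset, split, config.epochs, config.batch_size, config.seed,
        lr_for_epoch=lambda e: config.learning_rate,
    )
    return model, history


def train_from_scratch(
    spec: ModelSpec,
    dataset: LabeledDataset,
    split: DataSplit,
    config: TrainConfig,
) -> tuple[CNNClassifier, dict[str, list[float]]]:
    """The no-fine-tuning baseline: fresh model on the physical-format set."""
    model = build_model(spec, seed=config.seed)
    return pretrain(model, dataset, split, config)


def fine_tune(
    pretrained: CNNClassifier,
    dataset: LabeledDataset,
    split: DataSplit,
    config: FineTuneConfig,
) -> tuple[CNNClassifier, dict[str, list[float]]]:
    """Freeze the conv block, re-initialize the softmax head, retrain the rest.

    The frozen stage (conv weights + batch-norm parameters and running
    statistics) is bit-identical before and after; batch norm runs in
    inference mode during fine-tuning so the frozen statistics are not
    updated. The optimizer state covers only the trainable head.
    """
    if not config.freeze_conv_block:
        raise ProtocolError(
            "the fine-tuning protocol requires the conv block to be frozen"
        )
    if dataset.n_classes != pretrained.spec.n_classes:
        raise ConfigError(
            f"dataset has {dataset.n_classes} classes but model expects "
            f"{pretrained.spec.n_classes}"
        )
    model = copy.deepcopy(pretrained)
    # fresh softmax classifier, seeded independently of the discarded one
    head_rng = np.random.default_rng(stage_seed(config.seed, "finetune-head"))
    d2 = model.spec.dense_sizes[1]
    model.head.W = head_rng.standard_normal((d2, model.spec.n_classes)) \
        * np.sqrt(2.0 / d2)
    model.head.b = np.zeros(model.spec.n_classes)
    model.bn.frozen = True
    trainable = set(model.params()) - set(model.CONV_BLOCK_PARAMS)
    history = _train_loop(
        model, dataset, split, config.epochs, config.batch_size, config.seed,
        lr_for_epoch=lambda e: _lr_schedule(config, e),
        trainable=trainable,
    )
    return model, history


def evaluate(model: CNNClassifier, dataset: LabeledDataset,
             indices: tuple[int, ...]) -> EvalReport:
    """Score a model on one split of a dataset."""
    X, y = dataset.as_arrays(indices)
    return evaluate_predictions(y, model.predict_proba(X), dataset.n_classes)


# ---------------------------------------------------------------------------
# Wavelength-threshold oracle (lower bound on learnability)
# ---------------------------------------------------------------------------

def wavelength_threshold_classifier(
    dataset: LabeledDataset,
    indices: tuple[int, ...],
    classes_kpa: tuple[float, ...],
    pitch: float,
    frequency: float = 350.0,
    loss_ratio: float = 0.15,
    density: float = 1000.0,
) -> np.ndarray:
    """Classify patches by nearest analytic class wavelength.

    A deliberately trivial physics baseline: estimate each patch's
    wavelength from zero crossings and assign the class whose analytic
    wavelength is nearest (in log space, since wavelengths scale with √μ′).
    """
    lams = np.array([
        wavelength(ViscoelasticMedium(mu * 1e3, loss_ratio, density), frequency)
        for mu in sorted(classes_kpa)
    ])
    preds = []
    for i in indices:
        lam_est = estimate_wavelength(dataset[i].values, pitch)
        preds.append(int(np.argmin(np.abs(np.log(lams) - np.log(lam_est)))))
    return np.array(preds, dtype=np.int64)


# ---------------------------------------------------------------------------
# Experiment protocols
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one experiment end to end."""

    protocol: Literal["binary", "multiclass"]
    seed: int = 0
    n_per_class_synthetic: int = 52
    n_images_per_class: int = 13
    fixture_snr_db: float | None = 20.0
    n_filters: int = 32
    epochs: int = 30
    finetune_epochs: int = 30
    augment_multiplier: int = 4
    pitch: float = 0.5e-3
    frequency: float = 350.0
    loss_ratio: float = 0.15
    density: float = 1000.0

    @property
    def classes_kpa(self) -> tuple[float, ...]:
        return BINARY_CLASSES_KPA if self.protocol == "binary" else MULTICLASS_CLASSES_KPA

    def train_config(self, seed: int) -> TrainConfig:
        base = (binary_train_config if self.protocol == "binary"
                else multiclass_train_config)
        return base(seed=seed, epochs=self.epochs)


def run_experiment(
    config: RunConfig,
    out_dir: str | Path | None = None,
) -> dict:
    """Execute one full protocol: simulate → fixtures → ingest → split →
    augment → pretrain → fine-tune → evaluate (plus the scratch baseline).

    Returns the report dict; if ``out_dir`` is given, writes the report,
    training histories, model checkpoint, fixtures and the exact config.
    Fully reproducible from ``config.seed``.
    """
    if config.protocol not in ("binary", "multiclass"):
        raise ConfigError(f"unknown protocol {config.protocol!r}")
    classes = config.classes_kpa
    grid_patch = GridSpec(71, 11, pitch=config.pitch)
    spec = ModelSpec(n_classes=len(classes), n_filters=config.n_filters)

    # 1. synthetic pretraining data (clean analytic wavefields)
    synthetic = make_synthetic_dataset(
        classes, config.n_per_class_synthetic,
        SourcePlacementSpec(), grid_patch,
        seed=stage_seed(config.seed, "simulate"),
        loss_ratio=config.loss_ratio, density=config.density,
        frequency=config.frequency,
    )
    syn_split = split_dataset(synthetic, seed=stage_seed(config.seed, "split-synthetic"))
    # offline augmentation of the synthetic TRAINING split: with only 52
    # clean patches per class the dense head memorizes source positions
    # instead of wavelength; augmentation restores generalization
    synthetic_aug, syn_split_aug = augment_training_set(
        synthetic, syn_split,
        AugmentConfig(multiplier=config.augment_multiplier),
        seed=stage_seed(config.seed, "augment-synthetic"),
    )

    # 2–3. physical-format fixtures → ingest into patches
    if out_dir is not None:
        out_dir = Path(out_dir)
        fixture_dir = out_dir / "fixtures"
        fixture_ctx = None
    else:
        fixture_ctx = tempfile.TemporaryDirectory()
        fixture_dir = Path(fixture_ctx.name)
    write_fixture(
        fixture_dir, classes,
        n_images_per_class=config.n_images_per_class,
        snr_db=config.fixture_snr_db,
        seed=stage_seed(config.seed, "fixtures"),
        loss_ratio=config.loss_ratio, density=config.density,
        frequency=config.frequency,
    )
    physical = ingest_fixture_dir(fixture_dir, frequency=config.frequency)
    phys_split = split_dataset(physical, seed=stage_seed(config.seed, "split-physical"))

    # 4. offline augmentation of the physical training split only
    physical_aug, phys_split_aug = augment_training_set(
        physical, phys_split,
        AugmentConfig(multiplier=config.augment_multiplier),
        seed=stage_seed(config.seed, "augment"),
    )

    # 5. pretrain on (augmented) synthetic
    model = build_model(spec, seed=stage_seed(config.seed, "init"))
    model, pre_history = pretrain(
        model, synthetic_aug, syn_split_aug,
        config.train_config(seed=stage_seed(config.seed, "pretrain")),
    )

    # 6. fine-tune the head on physical-format data
    ft_config = FineTuneConfig(
        epochs=config.finetune_epochs, seed=stage_seed(config.seed, "finetune")
    )
    tuned, ft_history = fine_tune(model, physical_aug, phys_split_aug, ft_config)

    # 7. no-fine-tuning baseline: same architecture from scratch on physical
    scratch, scratch_history = train_from_scratch(
        spec, physical_aug, phys_split_aug,
        config.train_config(seed=stage_seed(config.seed, "scratch")),
    )

    # 8. evaluate both on the untouched physical test split
    report_tuned = evaluate(tuned, physical_aug, phys_split_aug.test)
    report_scratch = evaluate(scratch, physical_aug, phys_split_aug.test)
    report_synthetic = evaluate(model, synthetic_aug, syn_split_aug.test)

    report = {
        "protocol": config.protocol,
        "seed": config.seed,
        "classes_kpa": list(classes),
        "n_physical_patches": len(physical),
        "n_synthetic_samples": len(synthetic),
        "fine_tuned": report_tuned.to_dict(),
        "no_fine_tuning_baseline": report_scratch.to_dict(),
        "synthetic_pretrain_test": report_synthetic.to_dict(),
    }

    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        with open(out_dir / "history.json", "w") as fh:
            json.dump(
                {"pretrain": pre_history, "finetune": ft_history,
                 "scratch": scratch_history},
                fh, indent=2, sort_keys=True,
            )
        with open(out_dir / "config.json", "w") as fh:
            json.dump(asdict(config), fh, indent=2, sort_keys=True)
        tuned.save(out_dir / "model_finetuned.npz")
    if fixture_ctx is not None:
        fixture_ctx.cleanup()
    return report
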