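"""The four prognostic network families and their training loop.

* 2D-CNN / 3D-CNN: three convolutional blocks (convolution, max-pooling,
  parametric rectifier) that reduce the cropped masked CT to a flat feature
  vector, followed by two dense layers, dropout and a sigmoid output head.
* clinical ANN: one 14-unit hidden layer (ReLU), dropout, sigmoid head, fed
  with seven clinical covariates (age and total GTV volume divided by 100,
  the five categorical covariates one-hot encoded).
* CNN+Clinical fusion: the CNN with the clinical vector concatenated onto
  the flattened convolutional features before the dense head.

Each family exists in a binary-classification variant (single output unit)
and a time-to-event variant (one output unit per follow-up interval, each a
conditional event-free probability).  Training uses Adam with L2 weight
decay, online augmentation, per-epoch validation (AUC for binary, horizon
concordance for time-to-event), best-checkpoint retention and early
stopping.

The per-block kernel/stride/pool numbers and dense widths are configurable;
the defaults reduce a 128-voxel crop to a single spatial cell with 128
channels.  A scaled-down block set for 32-voxel crops is provided for
desk-scale experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import evaluation
from .nn import (Adam, Conv, Dense, Dropout, Flatten, MaxPool, Network,
                 PReLU, ReLU, Sigmoid)
from .preprocessing import AugmentConfig, PreprocessConfig, preprocess_record
from .survival import DiscreteTimeGrid, assemble_curve, risk_at_horizon, \
    survival_loss, survival_loss_grad
from .synthetic import (N_STAGE_LEVELS, PatientRecord, SEX_LEVELS,
                        SITE_LEVELS, STAGE_LEVELS, T_STAGE_LEVELS)

__all__ = [
    "ConvBlock", "ArchitectureConfig", "TrainConfig", "clinical_vector",
    "clinical_vector_width", "build_cnn", "build_ann", "build_fusion",
    "train", "TrainingHistory", "ImageDataset", "ClinicalDataset", "predict",
    "DESK_BLOCKS_3D", "DESK_BLOCKS_2D",
]


@dataclass(frozen=True)
class ConvBlock:
    n_kernels: int
    kernel_size: int
    stride: int
    pool_size: int
    pool_stride: int


#: full-scale defaults: 128-voxel crop -> 1 spatial cell, 128 channels
FULL_BLOCKS = (
    ConvBlock(32, 5, 1, 4, 4),
    ConvBlock(64, 5, 1, 4, 4),
    ConvBlock(128, 3, 1, 8, 8),
)

#: desk-scale blocks: 32-voxel crop -> 1 spatial cell, 32 channels
DESK_BLOCKS_3D = (
    ConvBlock(8, 3, 1, 4, 4),
    ConvBlock(16, 3, 1, 4, 4),
    ConvBlock(32, 3, 1, 2, 2),
)
DESK_BLOCKS_2D = DESK_BLOCKS_3D


@dataclass(frozen=True)
class ArchitectureConfig:
    """Network architecture parameters shared by CNN and fusion models."""

    dimensionality: str = "3D"  # "2D" | "3D"
    conv_blocks: tuple[ConvBlock, ...] = FULL_BLOCKS
    fc_sizes: tuple[int, int] = (64, 32)
    dropout_rate: float = 0.25
    head: str = "time_to_event"  # "binary" | "time_to_event"
    n_intervals: int = 10
    crop_extent: int = 128

    def __post_init__(self) -> None:
        if self.dimensionality.upper() not in ("2D", "3D"):
            raise ValueError("dimensionality must be 2D or 3D")
        if self.head not in ("binary", "time_to_event"):
            raise ValueError("head must be binary or time_to_event")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")

    @property
    def ndim(self) -> int:
        return 3 if self.dimensionality.upper() == "3D" else 2

    @property
    def n_outputs(self) -> int:
        return 1 if self.head == "binary" else self.n_intervals

    @property
    def feature_width(self) -> int:
        return self.conv_blocks[-1].n_kernels


@dataclass(frozen=True)
class TrainConfig:
    """Optimization schedule.

    Full-scale defaults mirror the published protocol (Adam, constant
    learning rate, weight decay 1e-4, batch size 4 for 3D and 32 for 2D,
    best-validation checkpointing with early stopping); epochs and patience
    scale down for desk-scale runs.
    """

    learning_rate: float = 3e-4
    weight_decay: float = 1e-4
    batch_size: int = 4
    epochs: int = 300
    early_stopping_patience: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("learning_rate", "batch_size", "epochs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


# ---------------------------------------------------------------------------
# clinical covariate encoding

_CATEGORICAL = (
    ("sex", SEX_LEVELS),
    ("site", SITE_LEVELS),
    ("overall_stage", STAGE_LEVELS),
    ("t_stage", T_STAGE_LEVELS),
    ("n_stage", N_STAGE_LEVELS),
)


def clinical_vector_width() -> int:
    return 2 + sum(len(levels) for _, levels in _CATEGORICAL)


def clinical_vector(record: PatientRecord) -> np.ndarray:
    """Seven covariates: age/100 and GTV volume/100 continuous, the five
    categorical covariates one-hot encoded against fixed vocabularies."""
    parts = [record.age_years / 100.0, record.gtv_total_volume_cm3 / 100.0]
    for attr, levels in _CATEGORICAL:
        value = getattr(record, attr)
        if value not in levels:
            raise ValueError(f"unknown {attr} level {value!r} (known: {levels})")
        onehot = [1.0 if value == lv else 0.0 for lv in levels]
        parts.extend(onehot)
    return np.asarray(parts, dtype=np.float32)


# ---------------------------------------------------------------------------
# builders

def _conv_branch(arch: ArchitectureConfig, rng: np.random.Generator):
    layers = []
    extent = arch.crop_extent
    channels = 1
    for i, blk in enumerate(arch.conv_blocks):
        if blk.stride != 1:
            raise ValueError(f"block {i}: only stride-1 convolutions supported")
        if blk.pool_size != blk.pool_stride:
            raise ValueError(f"block {i}: pool stride must equal pool size")
        if extent % blk.pool_size != 0:
            raise ValueError(
                f"block {i}: extent {extent} not divisible by pool {blk.pool_size}")
        layers.append(Conv(channels, blk.n_kernels, blk.kernel_size, arch.ndim, rng))
        layers.append(MaxPool(blk.pool_size, arch.ndim))
        layers.append(PReLU(blk.n_kernels))
        channels = blk.n_kernels
        extent //= blk.pool_size
    if extent != 1:
        raise ValueError(
            f"conv blocks reduce crop {arch.crop_extent} to {extent} per axis; "
            "expected 1 (adjust pool sizes)")
    layers.append(Flatten())
    return layers, channels


def _dense_head(in_width: int, arch: ArchitectureConfig,
                rng: np.random.Generator, rectifier: str = "prelu"):
    act = (lambda n: PReLU(n)) if rectifier == "prelu" else (lambda n: ReLU())
    f1, f2 = arch.fc_sizes
    return [
        Dense(in_width, f1, rng), act(f1),
        Dense(f1, f2, rng), act(f2),
        Dropout(arch.dropout_rate),
        Dense(f2, arch.n_outputs, rng),
        Sigmoid(),
    ]


def build_cnn(arch: ArchitectureConfig, seed: int = 0) -> Network:
    """Image-only CNN: conv blocks + flatten + dense head."""
    rng = np.random.default_rng(seed)
    branch, width = _conv_branch(arch, rng)
    return Network(branch, _dense_head(width, arch, rng))


def build_ann(head: str = "time_to_event", n_intervals: int = 10,
              hidden: int = 14, dropout_rate: float = 0.25, seed: int = 0) -> Network:
    """Clinical-covariate ANN: one hidden ReLU layer, dropout, sigmoid head."""
    rng = np.random.default_rng(seed)
    width = clinical_vector_width()
    n_out = 1 if head == "binary" else n_intervals
    layers = [
        Dense(width, hidden, rng), ReLU(),
        Dropout(dropout_rate),
        Dense(hidden, n_out, rng),
        Sigmoid(),
    ]
    return Network(None, layers, clinical_width=width)


def build_fusion(arch: ArchitectureConfig, seed: int = 0) -> Network:
    """CNN+Clinical: clinical vector concatenated at the flatten layer."""
    rng = np.random.default_rng(seed)
    branch, width = _conv_branch(arch, rng)
    head = _dense_head(width + clinical_vector_width(), arch, rng)
    return Network(branch, head, clinical_width=clinical_vector_width())


# ---------------------------------------------------------------------------
# datasets

class ImageDataset:
    """Preprocessed canvases with on-the-fly crop/augmentation.

    The deterministic part of preprocessing (resampling, windowing, masking,
    centroid centering) runs once at construction; the random crop and the
    other augmentations run per batch during training.
    """

    def __init__(self, records: list[PatientRecord], pre: PreprocessConfig,
                 aug: AugmentConfig, dimensionality: str = "3D",
                 with_clinical: bool = False) -> None:
        from .preprocessing import augment as _augment  # avoid cycle at import
        self._augment = _augment
        self.pre = pre
        self.aug = aug
        self.dimensionality = dimensionality
        self.with_clinical = with_clinical
        # canvases before the final crop: use a no-crop preprocess pass
        canvas_cfg = replace(pre, crop_extent=pre.input_extent)
        self.canvases = [
            preprocess_record(r, canvas_cfg, aug, training=False,
                              dimensionality=dimensionality)
            for r in records
        ]
        self.clinical = (
            np.stack([clinical_vector(r) for r in records])
            if with_clinical else None
        )
        self.patient_ids = [r.patient_id for r in records]

    def __len__(self) -> int:
        return len(self.canvases)

    def batch(self, idx: np.ndarray, training: bool,
              rng: np.random.Generator | None) -> dict:
        imgs = np.stack([
            self._augment(self.canvases[i], self.aug, training,
                          self.pre.crop_extent, rng=rng,
                          fill=self.pre.background)
            for i in idx
        ])[:, None]  # channel axis
        out = {"x_image": imgs}
        if self.with_clinical:
            out["x_clinical"] = self.clinical[idx]
        return out


class ClinicalDataset:
    """Clinical vectors only (for the ANN); no image reads."""

    def __init__(self, records: list[PatientRecord]) -> None:
        self.clinical = np.stack([clinical_vector(r) for r in records])
        self.patient_ids = [r.patient_id for r in records]

    def __len__(self) -> int:
        return len(self.clinical)

    def batch(self, idx: np.ndarray, training: bool,
              rng: np.random.Generator | None) -> dict:
        return {"x_clinical": self.clinical[idx]}


def predict(model: Network, dataset, batch_size: int = 16) -> np.ndarray:
    """Deterministic (evaluation-mode) predictions for a whole dataset."""
    outputs = []
    for start in range(0, len(dataset), batch_size):
        idx = np.arange(start, min(start + batch_size, len(dataset)))
        outputs.append(model.forward(**dataset.batch(idx, False, None), training=False))
    return np.concatenate(outputs)


# ---------------------------------------------------------------------------
# losses

def _binary_loss_and_grad(p: np.ndarray, y: np.ndarray):
    eps = 1e-7
    p = np.clip(p[:, 0], eps, 1 - eps)
    loss = float(-(y * np.log(p) + (1 - y) * np.log1p(-p)).mean())
    grad = (-(y / p) + (1 - y) / (1 - p))[:, None] / len(y)
    return loss, grad


@dataclass
class TrainingHistory:
    epochs: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    best_metric: float = -np.inf
    stopped_early: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.epochs)


def train(model: Network, train_data, train_outcomes, val_data, val_outcomes,
          cfg: TrainConfig, task: str = "time_to_event",
          grid: DiscreteTimeGrid | None = None,
          targets: np.ndarray | None = None,
          val_targets: np.ndarray | None = None) -> TrainingHistory:
    """Mini-batch Adam training with per-epoch validation checkpointing.

    ``train_outcomes`` / ``val_outcomes`` are ``(times, events)`` tuples for
    the time-to-event task and label vectors for the binary task.  For the
    time-to-event task ``targets`` must hold the encoded per-interval
    supervision for the training set.  The weights achieving the best
    validation metric (AUC for binary, 3-year-horizon concordance for
    time-to-event) are restored into the model at the end; training aborts
    on a non-finite loss and stops early after
    ``early_stopping_patience`` epochs without improvement.
    """
    if task == "time_to_event":
        if grid is None or targets is None:
            raise ValueError("time_to_event training needs grid and encoded targets")
        val_times, val_events = np.asarray(val_outcomes[0]), np.asarray(val_outcomes[1])
    else:
        train_labels = np.asarray(train_outcomes, dtype=float)
        val_labels = np.asarray(val_outcomes, dtype=float)

    rng = np.random.default_rng(cfg.seed)
    optimizer = Adam(model, cfg.learning_rate, cfg.weight_decay)
    history = TrainingHistory()
    best_weights = model.get_weights()
    n = len(train_data)

    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            batch = train_data.batch(idx, True, rng)
            p = model.forward(**batch, training=True, rng=rng)
            if task == "time_to_event":
                loss = survival_loss(p, targets[idx])
                grad = survival_loss_grad(p, targets[idx])
            else:
                loss, grad = _binary_loss_and_grad(p, train_labels[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch} (learning rate too high?)")
            model.backward(grad.astype(np.float32))
            optimizer.step()
            epoch_loss += loss * len(idx)
        epoch_loss /= n

        val_pred = predict(model, val_data)
        if task == "time_to_event":
            risks = risk_at_horizon(assemble_curve(val_pred), grid)
            metric = evaluation.concordance_index(risks, val_times, val_events)
        else:
            metric = evaluation.auc(val_pred[:, 0], val_labels)
        history.epochs.append(
            {"epoch": epoch, "train_loss": epoch_loss, "val_metric": metric})

        if metric > history.best_metric:
            history.best_metric = metric
            history.best_epoch = epoch
            best_weights = model.get_weights()
        elif epoch - history.best_epoch >= cfg.early_stopping_patience:
            history.stopped_early = True
            break

    model.set_weights(best_weights)
    return history
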