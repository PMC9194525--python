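"""The interpretable 1D-CNN: configuration, training, and weight access.

The architecture follows the long-first-layer-filter design for raw
single-channel signals: a 1-D convolution whose kernels are long enough
(2 s at the default scale) to hold a whole physiological waveform, max
pooling, a 2-D convolution spanning time x first-layer-filter axes, a second
max pooling, and two ReLU dense layers before a softmax output.  The long
first layer is what makes the downstream explainability meaningful — its
kernels can be read directly as waveforms and spectra.

Default sizes are the full-scale sleep-staging configuration (30 filters of
length 200 on 30-s windows at 100 Hz, 5 classes).  Reduced configurations
are first-class: every size is a constructor argument and the layer cascade
validates itself, naming the first layer a too-short window breaks.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import nn
from .datasets import SignalDataset
from .errors import ConfigurationError, ShapeError

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "FilterBank",
    "TrainedModel",
    "build_model",
    "train",
    "predict",
    "get_first_layer_filters",
    "set_first_layer_filters",
    "first_layer_activations",
]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture sizes.  Defaults are the full-scale configuration.

    ``filter2_shape`` is (extent along pooled time positions, extent along
    the first-layer filter axis); ``pool2_size``/``pool2_stride`` likewise
    are (time, filter-axis) pairs.
    """

    input_len: int = 3000
    fs: float = 100.0
    n_filters1: int = 30
    filter_len1: int = 200
    pool1_size: int = 15
    pool1_stride: int = 10
    n_filters2: int = 400
    filter2_shape: tuple[int, int] = (30, 25)
    pool2_size: tuple[int, int] = (10, 1)
    pool2_stride: tuple[int, int] = (1, 2)
    dense_sizes: tuple[int, ...] = (500, 500)
    n_classes: int = 5
    conv1_init_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.filter_len1 < 2:
            raise ConfigurationError("filter_len1 must be >= 2 (must admit an FFT)")
        if self.n_classes < 2:
            raise ConfigurationError("n_classes must be >= 2")
        sizes = (
            self.input_len, self.n_filters1, self.pool1_size, self.pool1_stride,
            self.n_filters2, *self.filter2_shape, *self.pool2_size,
            *self.pool2_stride, *self.dense_sizes,
        )
        if any(s <= 0 for s in sizes):
            raise ConfigurationError("all architecture sizes must be positive")
        if self.conv1_init_scale <= 0:
            raise ConfigurationError("conv1_init_scale must be positive")
        if self.filter2_shape[1] > self.n_filters1:
            raise ConfigurationError(
                f"filter2_shape[1]={self.filter2_shape[1]} exceeds the "
                f"first-layer filter axis ({self.n_filters1})"
            )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        for k in ("filter2_shape", "pool2_size", "pool2_stride", "dense_sizes"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass(frozen=True)
class TrainConfig:
    """SGD schedule: adaptive learning rate with patience-based decay and
    early stopping, both keyed to validation accuracy."""

    batch_size: int = 100
    lr_init: float = 0.015
    lr_decay_factor: float = 0.9
    lr_patience_epochs: int = 5
    early_stop_patience: int = 20
    max_epochs: int = 30
    class_weighting: bool = True
    shuffle_each_epoch: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.lr_decay_factor < 1.0:
            raise ConfigurationError("lr_decay_factor must be in (0, 1)")
        if self.lr_patience_epochs <= 0 or self.early_stop_patience <= 0:
            raise ConfigurationError("patience values must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        return cls(**d)


@dataclass(frozen=True)
class FilterBank:
    """First-layer kernel weights, (n_filters, filter_len), with the
    sampling rate that gives the kernels their time axis."""

    weights: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=np.float64)
        if w.ndim != 2:
            raise ShapeError(f"filter bank must be 2-D, got {w.shape}")
        if not np.isfinite(w).all():
            raise ShapeError("filter bank contains non-finite values")
        if self.fs <= 0:
            raise ConfigurationError("fs must be positive")
        object.__setattr__(self, "weights", w)

    @property
    def n_filters(self) -> int:
        return self.weights.shape[0]

    @property
    def filter_len(self) -> int:
        return self.weights.shape[1]

    @property
    def duration_s(self) -> float:
        return self.filter_len / self.fs


class TrainedModel:
    """Network handle: layer registry by name, weight get/set, prediction,
    first-layer readouts, and per-epoch training history."""

    def __init__(self, net: nn.Sequential, config: ModelConfig, seed: int) -> None:
        self.net = net
        self.config = config
        self.seed = seed
        self.history: list[dict] = []
        self.layers_by_name = {layer.name: layer for layer in net.layers}

    # ----------------------------------------------------------- weights
    def get_weights(self, layer: str | None = None):
        if layer is None:
            return self.net.get_weights()
        return {k: v.copy() for k, v in self.layers_by_name[layer].params.items()}

    def set_weights(self, weights, layer: str | None = None) -> None:
        if layer is None:
            self.net.set_weights(weights)
            return
        target = self.layers_by_name[layer]
        for k, v in weights.items():
            if v.shape != target.params[k].shape:
                raise ShapeError(
                    f"layer {layer!r} param {k!r}: shape {v.shape} != "
                    f"{target.params[k].shape}"
                )
        for k, v in weights.items():
            target.params[k] = v.copy()

    # -------------------------------------------------------- persistence
    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        flat = {}
        for i, layer in enumerate(self.net.layers):
            for k, v in layer.params.items():
                flat[f"{i}:{layer.name}:{k}"] = v
        np.savez(directory / "weights.npz", **flat)
        sidecar = {
            "model_config": self.config.to_dict(),
            "seed": self.seed,
            "initialization": "glorot_uniform, zero biases",
            "history": self.history,
        }
        (directory / "model.json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "TrainedModel":
        directory = Path(directory)
        sidecar = json.loads((directory / "model.json").read_text())
        config = ModelConfig.from_dict(sidecar["model_config"])
        model = build_model(config, seed=sidecar["seed"])
        with np.load(directory / "weights.npz") as npz:
            for key in npz.files:
                i, _, k = key.split(":")
                model.net.layers[int(i)].params[k] = npz[key].astype(np.float64)
        model.history = sidecar.get("history", [])
        return model


def build_model(config: ModelConfig, seed: int) -> TrainedModel:
    """Assemble the untrained network for ``config``.

    Raises :class:`~filterscope.errors.ShapeError` naming the first layer
    whose input is too small, so the minimum viable window length for a
    configuration is discoverable by construction.
    """
    layers: list[nn.Layer] = [
        nn.Conv1D(config.n_filters1, config.filter_len1, name="conv1d"),
        nn.MaxPool1D(config.pool1_size, config.pool1_stride, name="pool1d"),
        nn.ToImage(),
        nn.Conv2D(config.n_filters2, *config.filter2_shape, name="conv2d"),
        nn.MaxPool2D(config.pool2_size, config.pool2_stride, name="pool2d"),
        nn.Flatten(),
    ]
    for i, units in enumerate(config.dense_sizes):
        layers.append(nn.Dense(units, relu=True, name=f"dense{i + 1}"))
    layers.append(nn.Dense(config.n_classes, relu=False, name="output"))
    net = nn.Sequential(layers, input_shape=(config.input_len,), seed=seed)
    if config.conv1_init_scale != 1.0:
        # shrinking the visualized layer's starting point lets the trained
        # kernels reflect learned structure rather than the random draw
        layers[0].params["W"] = layers[0].params["W"] * config.conv1_init_scale
    return TrainedModel(net, config, seed)


def _class_weights(labels: np.ndarray, n_classes: int) -> np.ndarray:
    """Inverse-frequency weights n_total / (n_classes * n_k); absent classes
    get weight 0 (they contribute no samples)."""
    counts = np.bincount(labels, minlength=n_classes).astype(float)
    w = np.zeros(n_classes)
    present = counts > 0
    w[present] = len(labels) / (n_classes * counts[present])
    return w


def train(
    model: TrainedModel,
    train_ds: SignalDataset,
    val_ds: SignalDataset,
    tc: TrainConfig,
) -> TrainedModel:
    """SGD with weighted cross-entropy and the patience schedule.

    The learning rate is multiplied by ``lr_decay_factor`` after every
    ``lr_patience_epochs`` consecutive epochs without a strict improvement
    in validation accuracy; training stops after ``early_stop_patience``
    such epochs or at ``max_epochs``.  Both patiences read one shared
    no-improvement counter that resets whenever the best-so-far validation
    accuracy is exceeded.
    """
    if len(np.unique(train_ds.labels)) < 2:
        raise ConfigurationError("training set must contain at least 2 classes")
    shared = set(np.unique(train_ds.subjects)) & set(np.unique(val_ds.subjects))
    if shared:
        raise ConfigurationError(
            f"train and validation sets share subjects: {sorted(shared)}"
        )
    n_classes = model.config.n_classes
    if tc.class_weighting:
        cw = _class_weights(train_ds.labels, n_classes)
    else:
        cw = np.ones(n_classes)

    rng = np.random.default_rng(tc.seed)
    x, y = train_ds.windows, train_ds.labels
    lr = tc.lr_init
    best_val = -np.inf
    no_improve = 0

    for epoch in range(tc.max_epochs):
        order = rng.permutation(len(x)) if tc.shuffle_each_epoch else np.arange(len(x))
        losses = []
        for start in range(0, len(x), tc.batch_size):
            idx = order[start : start + tc.batch_size]
            losses.append(
                model.net.train_batch(x[idx], y[idx], cw[y[idx]], lr)
            )
        val_labels, _ = predict(model, val_ds)
        val_acc = float(np.mean(val_labels == val_ds.labels))
        model.history.append(
            {"epoch": epoch, "loss": float(np.mean(losses)),
             "val_accuracy": val_acc, "lr": lr}
        )
        if val_acc > best_val:
            best_val = val_acc
            no_improve = 0
        else:
            no_improve += 1
            if no_improve % tc.lr_patience_epochs == 0:
                lr *= tc.lr_decay_factor
            if no_improve >= tc.early_stop_patience:
                break
    return model


def predict(model: TrainedModel, dataset: SignalDataset) -> tuple[np.ndarray, np.ndarray]:
    """Predicted labels (argmax) and the full probability matrix."""
    if dataset.n_timepoints != model.config.input_len:
        raise ShapeError(
            f"dataset windows have {dataset.n_timepoints} timepoints, model "
            f"expects {model.config.input_len}"
        )
    proba = model.net.predict_proba(dataset.windows)
    return proba.argmax(axis=1), proba


def get_first_layer_filters(model: TrainedModel) -> FilterBank:
    return FilterBank(
        weights=model.layers_by_name["conv1d"].params["W"].copy(),
        fs=model.config.fs,
    )


def set_first_layer_filters(model: TrainedModel, bank: FilterBank) -> None:
    conv1 = model.layers_by_name["conv1d"]
    if bank.weights.shape != conv1.params["W"].shape:
        raise ShapeError(
            f"filter bank shape {bank.weights.shape} != "
            f"{conv1.params['W'].shape}"
        )
    conv1.params["W"] = bank.weights.copy()


def first_layer_activations(model: TrainedModel, dataset: SignalDataset) -> np.ndarray:
    """Post-ReLU first-convolution activations, (n_windows, positions,
    n_filters1); all values >= 0."""
    if dataset.n_timepoints != model.config.input_len:
        raise ShapeError(
            f"dataset windows have {dataset.n_timepoints} timepoints, model "
            f"expects {model.config.input_len}"
        )
    conv1 = model.layers_by_name["conv1d"]
    out = conv1.forward(dataset.windows)
    conv1.clear_cache()
    return out
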