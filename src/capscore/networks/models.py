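"""Network assembly, training and prediction.

Three preset architectures are provided, one per classifier family:

* ``lstm_table1`` — input 100 -> LSTM 400 cells -> dense 30 (SELU) -> softmax
* ``gru_table1``  — input 100 -> GRU 200 cells -> dense 20 (SELU) -> softmax
* ``cnn_table1``  — input 100 -> conv 64x3 -> batch norm -> RELU -> max pool 3
  -> conv 128x3 -> batch norm -> RELU -> global average pool -> softmax

For the recurrent presets each one-second epoch is one time step carrying a
100-dimensional feature vector; a training sequence is a window of
``context_length`` consecutive epochs of one recording, trained
sequence-to-sequence so that every epoch receives a label.  CAP phases have
a temporal dependency across epochs, which is what the recurrence is meant
to capture.  The alternative reading — recurrence over the 100 samples
within a single epoch — is reachable via ``sequence_mode="samples"``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from ..errors import DegenerateLabelError, NotTrainedError
from .layers import (
    GRU, LSTM, Activation, Adam, BatchNorm1D, Conv1D, Dense, GlobalAvgPool1D,
    Layer, MaxPool1D, OPTIMIZERS, SoftmaxCrossEntropy,
)

N_EPOCH_SAMPLES = 100


# ----------------------------------------------------------------------------
# Specs


@dataclass(frozen=True)
class NetworkSpec:
    """Ordered layer descriptors for one classifier.

    Each descriptor is a dict with a ``kind`` key (``input``, ``lstm``,
    ``gru``, ``dense``, ``conv``, ``batchnorm``, ``relu``, ``selu``,
    ``maxpool``, ``globalavgpool``, ``softmax``) plus kind-specific fields.
    The final two descriptors must form a 2-way dense softmax output.
    """

    name: str
    layers: tuple = field(default_factory=tuple)

    def __post_init__(self):
        object.__setattr__(self, "layers", tuple(dict(d) for d in self.layers))
        if len(self.layers) < 3 or self.layers[0]["kind"] != "input":
            raise ValueError("spec needs an input layer and an output head")
        if (self.layers[-1]["kind"] != "softmax"
                or self.layers[-2]["kind"] != "dense"
                or self.layers[-2]["units"] != 2):
            raise ValueError("final layers must be a 2-way dense + softmax head")

    @property
    def kind(self) -> str:
        kinds = {d["kind"] for d in self.layers}
        if "lstm" in kinds:
            return "lstm"
        if "gru" in kinds:
            return "gru"
        return "cnn"

    @property
    def is_recurrent(self) -> bool:
        return self.kind in ("lstm", "gru")


def lstm_spec(cells: int = 400, dense_units: int = 30,
              name: str | None = None) -> NetworkSpec:
    return NetworkSpec(name or f"lstm_{cells}", (
        {"kind": "input", "units": N_EPOCH_SAMPLES},
        {"kind": "lstm", "units": cells},
        {"kind": "dense", "units": dense_units, "activation": "selu"},
        {"kind": "dense", "units": 2, "activation": "linear"},
        {"kind": "softmax"},
    ))


def gru_spec(cells: int = 200, dense_units: int = 20,
             name: str | None = None) -> NetworkSpec:
    return NetworkSpec(name or f"gru_{cells}", (
        {"kind": "input", "units": N_EPOCH_SAMPLES},
        {"kind": "gru", "units": cells},
        {"kind": "dense", "units": dense_units, "activation": "selu"},
        {"kind": "dense", "units": 2, "activation": "linear"},
        {"kind": "softmax"},
    ))


def cnn_spec(filters: tuple[int, int] = (64, 128), kernel_len: int = 3,
             pool_size: int = 3, name: str | None = None) -> NetworkSpec:
    return NetworkSpec(name or "cnn", (
        {"kind": "input", "units": N_EPOCH_SAMPLES},
        {"kind": "conv", "filters": filters[0], "kernel_len": kernel_len},
        {"kind": "batchnorm"},
        {"kind": "relu"},
        {"kind": "maxpool", "size": pool_size},
        {"kind": "conv", "filters": filters[1], "kernel_len": kernel_len},
        {"kind": "batchnorm"},
        {"kind": "relu"},
        {"kind": "globalavgpool"},
        {"kind": "dense", "units": 2, "activation": "linear"},
        {"kind": "softmax"},
    ))


PRESETS = {
    "lstm_table1": lambda: lstm_spec(400, 30, name="lstm_table1"),
    "gru_table1": lambda: gru_spec(200, 20, name="gru_table1"),
    "cnn_table1": lambda: cnn_spec((64, 128), 3, 3, name="cnn_table1"),
}


def resolve_spec(preset_or_spec) -> NetworkSpec:
    if isinstance(preset_or_spec, NetworkSpec):
        return preset_or_spec
    if isinstance(preset_or_spec, str):
        try:
            return PRESETS[preset_or_spec]()
        except KeyError:
            raise ValueError(
                f"unknown preset {preset_or_spec!r}; choose from {sorted(PRESETS)}"
            ) from None
    raise TypeError("expected a preset name or a NetworkSpec")


# ----------------------------------------------------------------------------
# Configuration and outputs


@dataclass
class TrainingConfig:
    """Knobs of the training procedure.

    ``context_length`` is the number of consecutive epochs per recurrent
    training sequence; ``sequence_mode`` chooses whether the recurrence
    runs across epochs (``"epochs"``, default) or across the 100 samples
    within one epoch (``"samples"``).  ``candidate`` selects the LSTM cell
    candidate nonlinearity (``"tanh"`` default; ``"sigmoid"`` reproduces
    the literal reference cell).
    """

    optimizer: str = "adam"
    learning_rate: float = 1e-3
    batch_size: int = 256
    n_passes: int = 30
    seed: int = 0
    class_weighting: bool = False
    context_length: int = 60
    sequence_mode: str = "epochs"
    candidate: str = "tanh"
    threshold: float = 0.5

    def __post_init__(self):
        if min(self.learning_rate, self.batch_size, self.n_passes,
               self.context_length) <= 0:
            raise ValueError("numeric training fields must be positive")
        if self.sequence_mode not in ("epochs", "samples"):
            raise ValueError("sequence_mode must be 'epochs' or 'samples'")
        if self.optimizer not in OPTIMIZERS:
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


@dataclass
class PhaseScores:
    """Per-epoch A-phase probability and hard A/B decision (1 = A)."""

    proba: np.ndarray
    labels: np.ndarray
    threshold: float = 0.5

    def __post_init__(self):
        self.proba = np.asarray(self.proba, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.proba.shape != self.labels.shape:
            raise ValueError("proba and labels must align")
        if self.proba.size and (self.proba.min() < 0 or self.proba.max() > 1):
            raise ValueError("probabilities must lie in [0, 1]")


# ----------------------------------------------------------------------------
# Model


class Network:
    """A sequential stack of trainable layers plus the softmax head."""

    def __init__(self, spec: NetworkSpec, seed: int = 0,
                 candidate: str = "tanh", sequence_mode: str = "epochs"):
        self.spec = spec
        self.seed = seed
        self.candidate = candidate
        self.sequence_mode = sequence_mode
        self.trained_ = False
        self.training_log_: list[float] = []
        rng = np.random.default_rng(seed)
        self.layers: list[Layer] = []
        n_in = spec.layers[0]["units"]
        if spec.is_recurrent and sequence_mode == "samples":
            n_in = 1  # one scalar sample per recurrent step
        n_channels = 1
        for d in spec.layers[1:]:
            kind = d["kind"]
            if kind == "lstm":
                self.layers.append(LSTM(n_in, d["units"], candidate=candidate,
                                        return_sequences=sequence_mode == "epochs",
                                        rng=rng))
                n_in = d["units"]
            elif kind == "gru":
                self.layers.append(GRU(n_in, d["units"],
                                       return_sequences=sequence_mode == "epochs",
                                       rng=rng))
                n_in = d["units"]
            elif kind == "dense":
                self.layers.append(Dense(n_in, d["units"],
                                         activation=d.get("activation", "linear"),
                                         rng=rng))
                n_in = d["units"]
            elif kind == "conv":
                self.layers.append(Conv1D(n_channels, d["filters"],
                                          d["kernel_len"], rng=rng))
                n_channels = d["filters"]
                n_in = n_channels
            elif kind == "batchnorm":
                self.layers.append(BatchNorm1D(n_channels))
            elif kind in ("relu", "selu", "tanh", "sigmoid"):
                self.layers.append(Activation(kind))
            elif kind == "maxpool":
                self.layers.append(MaxPool1D(d["size"]))
            elif kind == "globalavgpool":
                self.layers.append(GlobalAvgPool1D())
            elif kind == "softmax":
                pass  # handled by the loss / predict head
            else:
                raise ValueError(f"unknown layer kind {kind!r}")

    # -- plumbing ------------------------------------------------------------

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    @property
    def n_parameters(self) -> int:
        return sum(layer.n_params for layer in self.layers)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, grad: np.ndarray) -> None:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def zero_grads(self) -> None:
        for layer in self.layers:
            layer.zero_grads()

    def predict_logits(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x, training=False)


def build_network(preset_or_spec, seed: int = 0, candidate: str = "tanh",
                  sequence_mode: str = "epochs") -> Network:
    """Instantiate an untrained model from a preset name or explicit spec."""
    return Network(resolve_spec(preset_or_spec), seed=seed,
                   candidate=candidate, sequence_mode=sequence_mode)


# ----------------------------------------------------------------------------
# Data arrangement


def _recurrent_windows(values: np.ndarray, labels: np.ndarray | None,
                       recording_ids: np.ndarray, context_length: int):
    """Cut each recording into non-overlapping context windows.

    Windows shorter than the context (trailing remainders) are dropped from
    training; prediction never windows (the full recording is one sequence).
    """
    xs, ys = [], []
    for rid in np.unique(recording_ids):
        idx = np.flatnonzero(recording_ids == rid)
        for start in range(0, idx.size - context_length + 1, context_length):
            sel = idx[start:start + context_length]
            xs.append(values[sel])
            if labels is not None:
                ys.append(labels[sel])
    if not xs:
        raise ValueError(
            "no training window fits: recordings shorter than context_length"
        )
    x = np.stack(xs)
    y = np.stack(ys) if labels is not None else None
    return x, y


def _arrange_inputs(model: Network, values: np.ndarray) -> np.ndarray:
    """Shape an (n_epochs, 100) matrix for the given architecture at predict time."""
    if model.spec.is_recurrent:
        if model.sequence_mode == "epochs":
            return values[None, :, :]  # one long sequence
        return values[:, :, None]      # per-epoch scalar sequences
    return values[:, :, None]          # CNN: (batch, length, 1 channel)


# ----------------------------------------------------------------------------
# Training / prediction


def train_classifier(model: Network, values: np.ndarray, labels: np.ndarray,
                     config: TrainingConfig,
                     recording_ids: np.ndarray | None = None) -> Network:
    """Train a model in place on an epoch matrix with per-epoch A/B labels.

    Deterministic for a fixed ``config.seed`` on a single-threaded run.
    The per-pass mean cross-entropy is appended to ``model.training_log_``.

    Raises
    ------
    DegenerateLabelError
        If the training labels contain a single class.
    """
    values = np.asarray(values, dtype=np.float64)
    labels = np.asarray(labels).astype(np.int64).ravel()
    if values.shape[0] != labels.shape[0]:
        raise ValueError("labels must align with epoch rows")
    if np.unique(labels).size < 2:
        raise DegenerateLabelError("training labels contain a single class")
    if recording_ids is None:
        recording_ids = np.zeros(labels.shape[0], dtype=np.int64)
    else:
        recording_ids = np.asarray(recording_ids).ravel()

    if model.spec.is_recurrent and model.sequence_mode == "epochs":
        x, y = _recurrent_windows(values, labels, recording_ids,
                                  config.context_length)
    elif model.spec.is_recurrent:  # samples mode: seq-to-one over 100 samples
        x, y = values[:, :, None], labels
    else:
        x, y = values[:, :, None], labels

    class_weight = None
    if config.class_weighting:
        counts = np.bincount(labels, minlength=2).astype(float)
        class_weight = counts.sum() / (2.0 * np.maximum(counts, 1.0))

    rng = np.random.default_rng(config.seed)
    opt = OPTIMIZERS[config.optimizer](lr=config.learning_rate)
    n = x.shape[0]
    for _ in range(config.n_passes):
        order = rng.permutation(n)
        losses = []
        for lo in range(0, n, config.batch_size):
            sel = order[lo:lo + config.batch_size]
            xb, yb = x[sel], y[sel]
            logits = model.forward(xb, training=True)
            sw = class_weight[yb] if class_weight is not None else None
            loss, dlogits = SoftmaxCrossEntropy.loss_and_grad(logits, yb, sw)
            model.zero_grads()
            model.backward(dlogits)
            opt.step(model.params, model.grads)
            losses.append(loss * yb.size)
        model.training_log_.append(sum(losses) / y.size)
    model.trained_ = True
    return model


def predict_phases(model: Network, values: np.ndarray,
                   threshold: float = 0.5) -> PhaseScores:
    """Per-epoch A-phase probability and hard label for an epoch matrix.

    Recurrent models run the recurrence over the full recording as a single
    sequence, so every epoch is labelled without windowing.

    Raises
    ------
    NotTrainedError
        If the model has not been trained.
    """
    if not model.trained_:
        raise NotTrainedError("model must be trained before prediction")
    values = np.asarray(values, dtype=np.float64)
    if values.ndim != 2 or values.shape[1] != N_EPOCH_SAMPLES:
        raise ValueError("expected an (n_epochs, 100) matrix")
    logits = model.predict_logits(_arrange_inputs(model, values))
    proba = SoftmaxCrossEntropy.probabilities(logits)[..., 1].reshape(-1)
    return PhaseScores(proba=proba, labels=(proba >= threshold).astype(np.int8),
                       threshold=threshold)


# ----------------------------------------------------------------------------
# Checkpoints


def save_model(model: Network, path, config: TrainingConfig | None = None) -> None:
    """Serialize weights plus spec/seed/config to a single ``.npz`` checkpoint."""
    meta = {
        "spec": {"name": model.spec.name, "layers": list(model.spec.layers)},
        "seed": model.seed,
        "candidate": model.candidate,
        "sequence_mode": model.sequence_mode,
        "trained": model.trained_,
        "training_log": model.training_log_,
        "config": asdict(config) if config is not None else None,
    }
    arrays = {f"param_{i}": p for i, p in enumerate(model.params)}
    for j, layer in enumerate(model.layers):
        if isinstance(layer, BatchNorm1D):
            arrays[f"bnmean_{j}"] = layer.running_mean
            arrays[f"bnvar_{j}"] = layer.running_var
    np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_model(path) -> tuple[Network, TrainingConfig | None]:
    """Restore a checkpoint written by :func:`save_model`."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        spec = NetworkSpec(meta["spec"]["name"], tuple(meta["spec"]["layers"]))
        model = Network(spec, seed=meta["seed"], candidate=meta["candidate"],
                        sequence_mode=meta["sequence_mode"])
        for i, p in enumerate(model.params):
            p[...] = data[f"param_{i}"]
        for j, layer in enumerate(model.layers):
            if isinstance(layer, BatchNorm1D):
                layer.running_mean[...] = data[f"bnmean_{j}"]
                layer.running_var[...] = data[f"bnvar_{j}"]
        model.trained_ = bool(meta["trained"])
        model.training_log_ = list(meta["training_log"])
        cfg = TrainingConfig(**meta["config"]) if meta["config"] else None
    return model, cfg
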