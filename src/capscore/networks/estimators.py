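"""scikit-learn style estimators wrapping the three phase classifiers.

The estimators follow the usual contract — ``fit(X, y)``, ``predict``,
``predict_proba``, ``get_params``/``set_params``, fitted attributes with a
trailing underscore — so they compose with sklearn pipelines and model
selection.  ``X`` is the ``(n_epochs, 100)`` normalized epoch matrix; ``y``
holds per-epoch A/B labels (1 = A phase).  Consecutive rows are assumed to
be consecutive seconds of one recording unless ``recording_ids`` is passed
to ``fit``, which keeps context windows from straddling recordings.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .models import (
    Network, TrainingConfig, build_network, cnn_spec, gru_spec, lstm_spec,
    predict_phases, train_classifier,
)


class _PhaseClassifierBase(ClassifierMixin, BaseEstimator):
    """Shared fit/predict machinery of the three architectures."""

    _kind: str = ""

    def __init__(self, cells: int | None = None, dense_units: int | None = None,
                 context_length: int = 60, n_passes: int = 30,
                 batch_size: int = 256, learning_rate: float = 1e-3,
                 optimizer: str = "adam", class_weighting: bool = False,
                 sequence_mode: str = "epochs", candidate: str = "tanh",
                 threshold: float = 0.5, seed: int = 0):
        self.cells = cells
        self.dense_units = dense_units
        self.context_length = context_length
        self.n_passes = n_passes
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.optimizer = optimizer
        self.class_weighting = class_weighting
        self.sequence_mode = sequence_mode
        self.candidate = candidate
        self.threshold = threshold
        self.seed = seed

    # -- architecture -------------------------------------------------------

    def _make_spec(self):
        if self._kind == "lstm":
            return lstm_spec(self.cells or 400, self.dense_units or 30)
        if self._kind == "gru":
            return gru_spec(self.cells or 200, self.dense_units or 20)
        return cnn_spec()

    def _make_config(self) -> TrainingConfig:
        return TrainingConfig(
            optimizer=self.optimizer, learning_rate=self.learning_rate,
            batch_size=self.batch_size, n_passes=self.n_passes,
            seed=self.seed, class_weighting=self.class_weighting,
            context_length=self.context_length,
            sequence_mode=self.sequence_mode, candidate=self.candidate,
            threshold=self.threshold,
        )

    # -- sklearn contract ---------------------------------------------------

    def fit(self, X, y, recording_ids=None):
        """Train on an epoch matrix with per-epoch binary labels (1 = A)."""
        X, y = check_X_y(X, y, dtype=np.float64)
        if X.shape[1] != 100:
            raise ValueError("X must have exactly 100 columns (1 s at 100 Hz)")
        y = np.asarray(y).astype(np.int64)
        self.classes_ = np.unique(y)
        self.model_ = build_network(self._make_spec(), seed=self.seed,
                                    candidate=self.candidate,
                                    sequence_mode=self.sequence_mode)
        train_classifier(self.model_, X, y, self._make_config(),
                         recording_ids=recording_ids)
        self.n_parameters_ = self.model_.n_parameters
        self.training_log_ = list(self.model_.training_log_)
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        X = check_array(X, dtype=np.float64)
        scores = predict_phases(self.model_, X, threshold=self.threshold)
        return np.column_stack([1.0 - scores.proba, scores.proba])

    def decision_function(self, X):
        return self.predict_proba(X)[:, 1]

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= self.threshold).astype(np.int8)

    def score_phases(self, X):
        """Full :class:`PhaseScores` record (probability + hard label)."""
        check_is_fitted(self, "model_")
        X = check_array(X, dtype=np.float64)
        return predict_phases(self.model_, X, threshold=self.threshold)


class LSTMPhaseClassifier(_PhaseClassifierBase):
    """A-phase detector built on a long short-term memory layer.

    Default architecture: 400 LSTM cells, a 30-unit SELU dense layer and a
    2-way softmax head; each epoch is one recurrent time step.
    """

    _kind = "lstm"


class GRUPhaseClassifier(_PhaseClassifierBase):
    """A-phase detector built on a gated recurrent unit layer (200 cells)."""

    _kind = "gru"


class CNNPhaseClassifier(_PhaseClassifierBase):
    """A-phase detector built on a two-block 1-D convolutional network."""

    _kind = "cnn"


_ESTIMATORS = {
    "lstm": LSTMPhaseClassifier,
    "gru": GRUPhaseClassifier,
    "cnn": CNNPhaseClassifier,
    "lstm_table1": LSTMPhaseClassifier,
    "gru_table1": GRUPhaseClassifier,
    "cnn_table1": CNNPhaseClassifier,
}


def make_phase_classifier(preset: str, **kwargs) -> _PhaseClassifierBase:
    """Instantiate the estimator matching a preset name."""
    try:
        cls = _ESTIMATORS[preset]
    except KeyError:
        raise ValueError(f"unknown preset {preset!r}") from None
    return cls(**kwargs)
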