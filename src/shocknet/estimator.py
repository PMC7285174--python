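"""scikit-learn estimator facade over the convolutional shock-advisory model.

``CNNShockClassifier`` is a standard ``fit``/``predict`` binary classifier:
``X`` holds raw ECG windows (rows of uV amplitudes at 125 Hz) and ``y`` the
class codes 0 (shockable) / 1 (nonshockable), matching the network's output
convention.  It composes with sklearn tools (``clone``, pipelines, model
selection); the hyperparameter-search and optimization layers build on it.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .dataset import DatasetSplit
from .evaluate import roc_bac_max
from .model import HPConfig, count_params, forward, layer_shapes
from .train import TrainSettings, train_model


class CNNShockClassifier(BaseEstimator, ClassifierMixin):
    """Fully-convolutional 1D network for shockable-rhythm detection.

    Parameters
    ----------
    filters, kernels : sequences of int
        Per-block filter counts and kernel sizes; their common length is the
        network depth N.
    pool_size, dropout : fixed architectural settings (2 and 0.3 by default).
    dense_hidden : optional dense hidden widths for comparative architectures.
    learning_rate, decay, epochs, patience, batch_size, beta1, beta2 :
        training protocol; ``decay=None`` resolves to ``learning_rate/epochs``.
    balance_factor : int
        Shockable-case replication applied to the training rows before
        fitting (4 restores rough class balance in the emulated corpus).
    random_state : int
        Seeds initialization, dropout and epoch shuffling.

    Attributes
    ----------
    config_ : HPConfig            resolved architecture (input length from X)
    params_ : ModelParams         checkpointed best weights
    history_ : DataFrame          per-epoch loss/accuracy/lr
    best_epoch_, best_accuracy_, epochs_trained_, stopped_early_ : training log
    threshold_ : float            decision threshold (0.5 until tuned)
    n_params_ : int               trainable-parameter count
    """

    def __init__(
        self,
        filters=(20, 15, 15, 10, 5),
        kernels=(10, 10, 10, 10, 10),
        pool_size=2,
        dropout=0.3,
        dense_hidden=(),
        learning_rate=0.001,
        decay=None,
        epochs=400,
        patience=150,
        batch_size=256,
        beta1=0.9,
        beta2=0.999,
        balance_factor=1,
        random_state=0,
    ):
        self.filters = filters
        self.kernels = kernels
        self.pool_size = pool_size
        self.dropout = dropout
        self.dense_hidden = dense_hidden
        self.learning_rate = learning_rate
        self.decay = decay
        self.epochs = epochs
        self.patience = patience
        self.batch_size = batch_size
        self.beta1 = beta1
        self.beta2 = beta2
        self.balance_factor = balance_factor
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _make_config(self, input_len: int) -> HPConfig:
        return HPConfig(
            n_blocks=len(tuple(self.filters)),
            filters=tuple(self.filters),
            kernels=tuple(self.kernels),
            pool_size=self.pool_size,
            dropout=self.dropout,
            input_len=input_len,
            dense_hidden=tuple(self.dense_hidden),
        )

    def fit(self, X, y, monitor_split: DatasetSplit | None = None):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64).ravel()
        if X.ndim != 2:
            raise ValueError("X must be 2D (n_windows, window_len)")
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        if not set(np.unique(y)) <= {0.0, 1.0}:
            raise ValueError("y must contain only 0 (shockable) and 1 (nonshockable)")
        self.classes_ = np.array([0.0, 1.0])
        config = self._make_config(X.shape[1])
        if not layer_shapes(config).feasible:
            raise ValueError("architecture infeasible at this window length")
        split = DatasetSplit(
            X=X, y=y,
            sources=np.full(len(y), "UNKNOWN"),
            patient_ids=np.array([f"row{i}" for i in range(len(y))]),
            role="TRAIN", l1_seconds=X.shape[1] / 125.0,
        )
        if self.balance_factor > 1:
            from .dataset import balance_by_replication
            split = balance_by_replication(split, self.balance_factor)
        settings = TrainSettings(
            epochs=self.epochs, patience=self.patience,
            batch_size=self.batch_size, lr=self.learning_rate,
            decay=self.decay, beta1=self.beta1, beta2=self.beta2,
            seed=self.random_state,
            monitor="train" if monitor_split is None else "validation",
        )
        result = train_model(config, split, settings, monitor_split=monitor_split)
        self.config_ = config
        self.params_ = result.best_params
        self.history_ = result.history
        self.best_epoch_ = result.best_epoch
        self.best_accuracy_ = result.best_accuracy
        self.epochs_trained_ = result.epochs_trained
        self.stopped_early_ = result.stopped_early
        self.threshold_ = 0.5
        self.n_params_ = count_params(config)
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "params_")
        p_nsh = forward(self.config_, self.params_, np.asarray(X, dtype=np.float64))
        return np.column_stack([1.0 - p_nsh, p_nsh])

    def decision_function(self, X):
        return self.predict_proba(X)[:, 1]

    def predict(self, X):
        p_nsh = self.predict_proba(X)[:, 1]
        return np.where(p_nsh < self.threshold_, 0.0, 1.0)

    def tune_threshold(self, X, y):
        """Set the decision threshold to the max-BAC ROC operating point."""
        check_is_fitted(self, "params_")
        roc = roc_bac_max(self.decision_function(X), np.asarray(y, dtype=np.float64))
        self.threshold_ = roc.selected_threshold
        return self

    def validation_bac(self, X, y) -> float:
        """Balanced accuracy (percent) at the max-BAC ROC point on (X, y)."""
        check_is_fitted(self, "params_")
        return roc_bac_max(self.decision_function(X), np.asarray(y, dtype=np.float64)).selected_bac
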