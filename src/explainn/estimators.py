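"""scikit-learn style estimators wrapping the model and training loop.

``ExplaiNNClassifier`` (binary multi-task or multiclass) and
``ExplaiNNRegressor`` accept DNA sequences (list of strings) or pre-encoded
(N, L, 4) one-hot arrays as X. They follow the sklearn contract:
``get_params``/``set_params``, ``fit`` returning self, fitted attributes
with trailing underscores, and composition with ``sklearn.base.clone``.

Interpretation is exposed on the fitted estimator: ``unit_importances()``,
``filter_pwms()``, and ``final_layer_weights_``.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin

from .data import LabeledDataset
from .model import ModelConfig, ExplaiNNModel, TWO_FC
from .train import TrainConfig, train, sigmoid
from .interpret import visualize_filters, unit_importance


class _BaseExplaiNN(BaseEstimator):
    _task_type = "regression"

    def __init__(self, num_units=100, filter_width=19, pool_size=7,
                 pool_stride=7, fc_hidden=100, dropout_rate=0.3,
                 unit_head=TWO_FC, learning_rate=0.003, batch_size=100,
                 max_epochs=100, patience=10, rc_augment=True,
                 validation_fraction=0.1, random_state=0):
        self.num_units = num_units
        self.filter_width = filter_width
        self.pool_size = pool_size
        self.pool_stride = pool_stride
        self.fc_hidden = fc_hidden
        self.dropout_rate = dropout_rate
        self.unit_head = unit_head
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.rc_augment = rc_augment
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    # -- plumbing ----------------------------------------------------------

    def _to_dataset(self, X, y) -> LabeledDataset:
        y = np.asarray(y, dtype=float)
        if y.ndim == 1:
            y = y[:, None]
        if isinstance(X, np.ndarray) and X.ndim == 3:
            lut = np.array(list("ACGT"))
            seqs = ["".join(lut[x.argmax(axis=1)]) for x in X]
        else:
            seqs = [str(s) for s in X]
        ids = [f"seq{i}" for i in range(len(seqs))]
        return LabeledDataset(ids=ids, sequences=seqs, labels=y,
                              task_type=self._task_type)

    def fit(self, X, y):
        dataset = self._to_dataset(X, y)
        dataset, discard_log = dataset.drop_n_sequences()
        self.n_discarded_ = discard_log.n_discarded
        rng = np.random.default_rng(self.random_state)
        idx = rng.permutation(len(dataset))
        n_val = max(1, int(round(self.validation_fraction * len(dataset))))
        va = dataset.subset(np.sort(idx[:n_val]))
        tr = dataset.subset(np.sort(idx[n_val:]))
        L = len(dataset.sequences[0])
        config = ModelConfig(num_units=self.num_units, input_length=L,
                             num_tasks=dataset.num_tasks,
                             filter_width=self.filter_width,
                             pool_size=self.pool_size,
                             pool_stride=self.pool_stride,
                             fc_hidden=self.fc_hidden,
                             dropout_rate=self.dropout_rate,
                             unit_head=self.unit_head)
        model = ExplaiNNModel(config, seed=self.random_state)
        tcfg = TrainConfig(learning_rate=self.learning_rate,
                           batch_size=self.batch_size,
                           max_epochs=self.max_epochs,
                           patience=self.patience,
                           rc_augment=self.rc_augment,
                           seed=self.random_state)
        self.model_, self.history_ = train(model, tr, va, tcfg)
        self.n_features_in_ = L
        self.num_tasks_ = dataset.num_tasks
        self.final_layer_weights_ = self.model_.params["final_w"].copy()
        self.final_layer_bias_ = self.model_.params["final_b"].copy()
        self._train_dataset = tr
        return self

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted; call fit first")

    def _encode_X(self, X) -> np.ndarray:
        if isinstance(X, np.ndarray) and X.ndim == 3:
            return X
        from .encoding import encode_batch
        x, _, log = encode_batch([str(s) for s in X])
        if log.n_discarded:
            raise ValueError(
                f"{log.n_discarded} sequences contain N and cannot be scored")
        return x

    def decision_function(self, X) -> np.ndarray:
        self._check_fitted()
        x = self._encode_X(X)
        out = self.model_.predict(x)
        return out[:, 0] if out.shape[1] == 1 else out

    def unit_outputs(self, X) -> np.ndarray:
        """(N, U) per-unit scalar outputs, the model's internal features."""
        self._check_fitted()
        _, units = self.model_.forward(self._encode_X(X), training=False)
        return units

    def transform(self, X) -> np.ndarray:
        return self.unit_outputs(X)

    # -- interpretation ----------------------------------------------------

    def filter_pwms(self, X, y, fraction=0.5):
        """PWMs of every unit's filter, built from sequences in X."""
        self._check_fitted()
        dataset = self._to_dataset(X, y)
        x = dataset.encode()
        preds, _ = self.model_.forward(x, training=False)
        _, pwms = visualize_filters(self.model_, x, preds, dataset.labels,
                                    fraction=fraction,
                                    task_type=self._task_type)
        return pwms

    def unit_importances(self, X, y, fraction=0.5):
        """U x T median importance matrix measured on (X, y)."""
        self._check_fitted()
        dataset = self._to_dataset(X, y)
        x = dataset.encode()
        preds, _ = self.model_.forward(x, training=False)
        return unit_importance(self.model_, x, preds, dataset.labels,
                               fraction=fraction, task_type=self._task_type)


class ExplaiNNClassifier(_BaseExplaiNN, ClassifierMixin):
    """Binary (multi-task) sequence classifier with a linear final layer."""

    _task_type = "binary_multitask"

    def fit(self, X, y):
        y_arr = np.asarray(y)
        self.classes_ = np.unique(y_arr)
        return super().fit(X, y)

    def predict_proba(self, X) -> np.ndarray:
        self._check_fitted()
        logits = self.model_.predict(self._encode_X(X))
        p = sigmoid(logits)
        if p.shape[1] == 1:
            return np.hstack([1 - p, p])
        return p

    def predict(self, X) -> np.ndarray:
        p = self.predict_proba(X)
        if hasattr(self, "classes_") and p.shape[1] == 2 and len(self.classes_) == 2:
            return self.classes_[(p[:, 1] >= 0.5).astype(int)]
        return (p >= 0.5).astype(int)


class ExplaiNNRegressor(_BaseExplaiNN, RegressorMixin):
    """Real-valued sequence-to-activity regressor (MSE loss)."""

    _task_type = "regression"

    def predict(self, X) -> np.ndarray:
        return self.decision_function(X)
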