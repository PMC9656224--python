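"""Classifier factory: SVM, random forest, gradient-boosted trees and the
1-D CNN, all behind the sklearn fit/predict interface.

The gradient-boosted "xgb" kind is backed by sklearn's histogram gradient
boosting (same algorithm family; no external booster dependency).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import HistGradientBoostingClassifier, RandomForestClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from . import _cnn

__all__ = ["CLASSIFIER_KINDS", "CNNArchitecture", "CNNClassifier", "make_classifier"]

CLASSIFIER_KINDS = ("svm", "rf", "xgb", "cnn")


@dataclass
class CNNArchitecture:
    """Three conv blocks (filters, kernel, pool) + dense head, Adam, BCE."""

    conv_blocks: tuple[tuple[int, int, int], ...] = ((32, 3, 2), (64, 3, 2), (128, 3, 2))
    dense_units: int = 64
    learning_rate: float = 1e-3
    epochs: int = 50
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.conv_blocks) != 3:
            raise ValueError("architecture requires exactly three conv blocks")


class CNNClassifier:
    """Binary classifier treating each feature vector as a 1-channel sequence."""

    def __init__(self, arch: CNNArchitecture | None = None):
        self.arch = arch or CNNArchitecture()
        self._net: _cnn.Network | None = None
        self.loss_trace_: list[float] = []

    def _build(self, length: int, rng: np.random.Generator) -> _cnn.Network:
        layers: list[_cnn.Layer] = []
        channels = 1
        for filters, kernel, pool in self.arch.conv_blocks:
            if length < kernel:
                raise ValueError(
                    f"input length too short for conv kernel {kernel} "
                    f"(remaining length {length})"
                )
            layers += [
                _cnn.Conv1D(channels, filters, kernel, rng),
                _cnn.ReLU(),
                _cnn.MaxPool1D(pool),
            ]
            length = (length - kernel + 1) // pool
            channels = filters
            if length < 1:
                raise ValueError("input length too short for the pooling stack")
        layers += [
            _cnn.Flatten(),
            _cnn.Dense(channels * length, self.arch.dense_units, rng),
            _cnn.ReLU(),
            _cnn.Dense(self.arch.dense_units, 1, rng),
        ]
        return _cnn.Network(layers)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "CNNClassifier":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        if not np.isfinite(X).all():
            raise ValueError("non-finite feature values passed to the CNN")
        if X.ndim != 2:
            raise ValueError("X must be 2-D [samples x features]")
        self._mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        self._sd = sd
        Xs = (X - self._mu) / self._sd
        rng = np.random.default_rng(self.arch.seed)
        self._net = self._build(X.shape[1], rng)
        optimizer = _cnn.Adam(self._net.params(), lr=self.arch.learning_rate)
        n = X.shape[0]
        batch = min(self.arch.batch_size, n)
        self.loss_trace_ = []
        for _ in range(self.arch.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            n_batches = 0
            for start in range(0, n, batch):
                idx = order[start : start + batch]
                xb = Xs[idx][:, None, :]
                logits = self._net.forward(xb)
                loss, dlogits = _cnn.bce_with_logits(logits, y[idx])
                self._net.backward(dlogits)
                optimizer.step(self._net.grads())
                epoch_loss += loss
                n_batches += 1
            self.loss_trace_.append(epoch_loss / max(n_batches, 1))
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if self._net is None:
            raise RuntimeError("classifier is not fitted")
        X = np.asarray(X, dtype=np.float64)
        Xs = (X - self._mu) / self._sd
        logits = self._net.forward(Xs[:, None, :])
        p = 1.0 / (1.0 + np.exp(-logits))
        return np.column_stack([1.0 - p, p])

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


def make_classifier(kind: str, seed: int = 0, **params):
    """Instantiate one of the supported classifier kinds, seeded.

    svm: RBF SVC on standardized inputs; rf: 500-tree random forest;
    xgb: histogram gradient boosting; cnn: the numpy 1-D CNN.
    """
    if kind == "svm":
        return make_pipeline(
            StandardScaler(), SVC(kernel="rbf", random_state=seed, **params)
        )
    if kind == "rf":
        params.setdefault("n_estimators", 500)
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if kind == "xgb":
        return HistGradientBoostingClassifier(random_state=seed, **params)
    if kind == "cnn":
        arch = params.pop("arch", None) or CNNArchitecture(seed=seed, **params)
        return CNNClassifier(arch)
    raise ValueError(f"unknown classifier kind {kind!r}; "
                     f"expected one of {CLASSIFIER_KINDS}")
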