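"""Supervised training, prediction and persistence for the deep classifiers.

One independent flat model is trained per taxonomic rank; no hierarchical
consistency is enforced between ranks. Training is plain mini-batch SGD
on the categorical cross-entropy; all randomness (weight init, shuffling,
RBM sampling) flows from explicit seeds, so a fixed seed reproduces the
fitted parameters bit for bit on the same platform.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import joblib
import numpy as np

from .cnn import CNNSpec, build_cnn
from .dbn import DBN, DBNSpec, build_dbn, pretrain_rbm_stack
from .layers import DTYPE, Network, softmax_cross_entropy


@dataclass(frozen=True, slots=True)
class TrainParams:
    """Optimiser settings (the published work leaves these unstated)."""

    epochs: int = 30
    batch_size: int = 64
    learning_rate: float = 0.01
    momentum: float = 0.9
    pretrain_epochs: int = 10
    pretrain_learning_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.epochs, self.batch_size) < 0 or self.learning_rate <= 0:
            raise ValueError("epochs/batch_size must be >= 0, learning_rate > 0")
        if not 0.0 <= self.momentum < 1.0:
            raise ValueError("momentum must be in [0, 1)")


#: Era-typical defaults (SGD with classical momentum); the DBN fine-tune
#: uses a larger step because sigmoid stacks train far slower than ReLU ones.
CNN_DEFAULTS = TrainParams(epochs=30, batch_size=64, learning_rate=0.01, momentum=0.9)
DBN_DEFAULTS = TrainParams(epochs=50, batch_size=64, learning_rate=0.1, momentum=0.9,
                           pretrain_epochs=10)


@dataclass
class TrainedModel:
    """A fitted classifier plus the metadata needed to apply it."""

    kind: str  # "CNN" | "DBN"
    rank: str
    k: int | None
    network: Network
    classes: list[str]

    @property
    def input_len(self) -> int:
        return self.network.input_len

    def save(self, path) -> None:
        joblib.dump({"format_version": 1, "model": self}, path)

    @staticmethod
    def load(path) -> "TrainedModel":
        payload = joblib.load(path)
        if payload.get("format_version") != 1:
            raise ValueError("unrecognised model file format")
        return payload["model"]


def _fit_network(net: Network, X: np.ndarray, y: np.ndarray, params: TrainParams,
                 rng: np.random.Generator) -> None:
    X = X.astype(DTYPE)
    n = X.shape[0]
    for _ in range(params.epochs):
        order = rng.permutation(n)
        for i in range(0, n, params.batch_size):
            idx = order[i:i + params.batch_size]
            logits = net.forward(X[idx])
            _, dlogits = softmax_cross_entropy(logits, y[idx])
            net.backward(dlogits)
            net.sgd_step(params.learning_rate, params.momentum)


def train_supervised(
    model: Network | DBN,
    X: np.ndarray,
    y: np.ndarray,
    params: TrainParams,
    classes: Sequence[str] | None = None,
    rank: str = "genus",
    k: int | None = None,
) -> TrainedModel:
    """Fit *model* (a built CNN network or a pre-trained DBN) on encoded
    labels *y*; returns the fitted model with its label dictionary.

    *classes* decodes integer labels; when omitted the classes are the
    string labels occurring in *y* (which is then re-encoded).
    """
    y = np.asarray(y)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y disagree on sample count")
    if classes is None:
        classes = sorted(np.unique(y).tolist())
        lut = {c: i for i, c in enumerate(classes)}
        y = np.array([lut[v] for v in y.tolist()], dtype=np.int64)
        classes = [str(c) for c in classes]
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")

    rng = np.random.default_rng(params.seed)
    if isinstance(model, DBN):
        net = model.unroll()
        kind = "DBN"
    else:
        net = model
        kind = "CNN"
    _fit_network(net, X, np.asarray(y, dtype=np.int64), params, rng)
    return TrainedModel(kind=kind, rank=rank, k=k, network=net, classes=list(classes))


def predict(model: TrainedModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Predicted labels and the full softmax probability matrix."""
    if X.ndim != 2 or X.shape[1] != model.input_len:
        raise ValueError(
            f"feature matrix must be 2-D with {model.input_len} columns "
            f"(4**k for the model's k); got shape {X.shape}"
        )
    probs = model.network.predict_proba(X)
    labels = np.array([model.classes[i] for i in probs.argmax(axis=1)])
    return labels, probs


class _DeepClassifier:
    """Shared sklearn-style fit/predict wrapper for CV drivers."""

    kind = "base"

    def __init__(self, params: TrainParams, rank: str = "genus", k: int | None = None):
        self.params = params
        self.rank = rank
        self.k = k
        self.model_: TrainedModel | None = None

    def _build(self, input_len: int, n_classes: int) -> Network | DBN:  # pragma: no cover
        raise NotImplementedError

    def fit(self, X: np.ndarray, labels: Sequence[str]) -> "_DeepClassifier":
        classes = sorted(set(map(str, labels)))
        lut = {c: i for i, c in enumerate(classes)}
        y = np.array([lut[str(l)] for l in labels], dtype=np.int64)
        model = self._build(X.shape[1], len(classes))
        self.model_ = train_supervised(model, X, y, self.params, classes=classes,
                                       rank=self.rank, k=self.k)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.model_ is None:
            raise RuntimeError("classifier is not fitted")
        return predict(self.model_, X)[0]


class CNNClassifier(_DeepClassifier):
    kind = "CNN"

    def __init__(self, spec: CNNSpec | None = None, params: TrainParams = CNN_DEFAULTS,
                 rank: str = "genus", k: int | None = None):
        super().__init__(params, rank, k)
        self.spec = spec

    def _build(self, input_len: int, n_classes: int):
        spec = self.spec or CNNSpec(input_len=input_len, n_classes=n_classes)
        return build_cnn(spec, seed=self.params.seed)


class DBNClassifier(_DeepClassifier):
    kind = "DBN"

    def __init__(self, spec: DBNSpec | None = None, params: TrainParams = DBN_DEFAULTS,
                 rank: str = "genus", k: int | None = None, hidden_scheme: str = "table"):
        super().__init__(params, rank, k)
        self.spec = spec
        self.hidden_scheme = hidden_scheme
        self._train_X: np.ndarray | None = None

    def _build(self, input_len: int, n_classes: int):
        if self.spec is not None:
            spec = self.spec
        elif self.k is not None and 4**self.k == input_len:
            spec = DBNSpec.for_k(self.k, n_classes, scheme=self.hidden_scheme)
        else:
            spec = DBNSpec(input_len=input_len, n_classes=n_classes)
        dbn = build_dbn(spec, seed=self.params.seed)
        rng = np.random.default_rng(self.params.seed + 1)
        pretrain_rbm_stack(dbn, self._train_X, self.params.pretrain_epochs,
                           self.params.pretrain_learning_rate,
                           self.params.batch_size, rng)
        return dbn

    def fit(self, X: np.ndarray, labels: Sequence[str]) -> "DBNClassifier":
        self._train_X = np.clip(X.astype(DTYPE), 0.0, 1.0)
        try:
            return super().fit(self._train_X, labels)
        finally:
            self._train_X = None
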