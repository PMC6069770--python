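"""Deep belief network: a two-RBM stack with a logistic-regression head.

Each restricted Boltzmann machine has real-valued visible units in [0,1]
(interpreted as activation probabilities, appropriate for min-max scaled
count data) and binary stochastic hidden units, trained by contrastive
divergence (CD-k, default k=1). Pre-training is greedy and layer-wise:
the second RBM is trained on the hidden activation probabilities of the
first. Fine-tuning unrolls the stack into a sigmoid MLP with a softmax
output layer and backpropagates through all weights.

Default hidden-layer sizes depend on the k-mer order (both RBM layers get
the same width): k=3 -> 32, k=4 -> 128, k>=5 -> 256. An alternative
``scheme="formula"`` uses 4**(k-1) capped at 4**4.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layers import DTYPE, Dense, Network, Sigmoid, sigmoid


def dbn_hidden_units(k: int, scheme: str = "table") -> int:
    """Default RBM width for k-mer order *k* under either sizing scheme."""
    if scheme == "table":
        return {3: 32, 4: 128}.get(k, 256)
    if scheme == "formula":
        return min(4 ** (k - 1), 4**4)
    raise ValueError("scheme must be 'table' or 'formula'")


@dataclass(frozen=True, slots=True)
class DBNSpec:
    input_len: int
    n_classes: int
    rbm1_hidden: int = 256
    rbm2_hidden: int = 256
    cd_steps: int = 1

    @classmethod
    def for_k(cls, k: int, n_classes: int, scheme: str = "table", cd_steps: int = 1) -> "DBNSpec":
        h = dbn_hidden_units(k, scheme)
        return cls(input_len=4**k, n_classes=n_classes, rbm1_hidden=h, rbm2_hidden=h,
                   cd_steps=cd_steps)

    def __post_init__(self) -> None:
        if self.rbm1_hidden < 1 or self.rbm2_hidden < 1:
            raise ValueError("hidden sizes must be >= 1")
        if self.cd_steps < 1:
            raise ValueError("cd_steps must be >= 1")


class RBM:
    """Restricted Boltzmann machine with [0,1] visible units."""

    def __init__(self, n_visible: int, n_hidden: int, rng: np.random.Generator) -> None:
        self.W = (rng.standard_normal((n_visible, n_hidden)) * 0.01).astype(DTYPE)
        self.b_visible = np.zeros(n_visible, dtype=DTYPE)
        self.b_hidden = np.zeros(n_hidden, dtype=DTYPE)

    def hidden_probs(self, v: np.ndarray) -> np.ndarray:
        return sigmoid(v @ self.W + self.b_hidden)

    def visible_probs(self, h: np.ndarray) -> np.ndarray:
        return sigmoid(h @ self.W.T + self.b_visible)

    def cd_update(self, v0: np.ndarray, lr: float, rng: np.random.Generator,
                  k: int = 1) -> None:
        """One CD-k gradient step on a mini-batch (rows of *v0* in [0,1])."""
        B = v0.shape[0]
        h_prob = self.hidden_probs(v0)
        h0_prob = h_prob
        h_sample = (rng.random(h_prob.shape) < h_prob).astype(DTYPE)
        for _ in range(k):
            v_prob = self.visible_probs(h_sample)
            h_prob = self.hidden_probs(v_prob)
            h_sample = (rng.random(h_prob.shape) < h_prob).astype(DTYPE)
        self.W += (lr / B) * (v0.T @ h0_prob - v_prob.T @ h_prob).astype(DTYPE)
        self.b_visible += (lr / B) * (v0 - v_prob).sum(axis=0).astype(DTYPE)
        self.b_hidden += (lr / B) * (h0_prob - h_prob).sum(axis=0).astype(DTYPE)

    def reconstruction_error(self, X: np.ndarray) -> float:
        """Mean squared error of the deterministic one-step reconstruction."""
        v1 = self.visible_probs(self.hidden_probs(X))
        return float(np.mean((X - v1) ** 2))


class DBN:
    """RBM stack plus softmax output; fine-tuned as a sigmoid MLP."""

    def __init__(self, spec: DBNSpec, seed: int = 0) -> None:
        self.spec = spec
        rng = np.random.default_rng(seed)
        self.rbm1 = RBM(spec.input_len, spec.rbm1_hidden, rng)
        self.rbm2 = RBM(spec.rbm1_hidden, spec.rbm2_hidden, rng)
        self._out_rng_state = rng  # used once when unrolling
        self._network: Network | None = None

    def unroll(self) -> Network:
        """Build (once) the MLP view sharing the RBM weight arrays."""
        if self._network is None:
            rng = self._out_rng_state
            layers = [
                Dense(self.spec.input_len, self.spec.rbm1_hidden, rng,
                      W=self.rbm1.W, b=self.rbm1.b_hidden),
                Sigmoid(),
                Dense(self.spec.rbm1_hidden, self.spec.rbm2_hidden, rng,
                      W=self.rbm2.W, b=self.rbm2.b_hidden),
                Sigmoid(),
                Dense(self.spec.rbm2_hidden, self.spec.n_classes, rng),
            ]
            self._network = Network(layers, input_len=self.spec.input_len,
                                    n_classes=self.spec.n_classes)
        return self._network


def build_dbn(spec: DBNSpec, seed: int = 0) -> DBN:
    """Assemble the untrained DBN; weight initialisation is seeded."""
    if spec.n_classes < 2:
        raise ValueError("need at least 2 classes")
    return DBN(spec, seed=seed)


def pretrain_rbm_stack(model: DBN, X: np.ndarray, epochs: int, lr: float,
                       batch_size: int, rng: np.random.Generator) -> DBN:
    """Greedy layer-wise CD pre-training; *X* rows must lie in [0,1]."""
    if X.size and (X.min() < 0 or X.max() > 1):
        raise ValueError("RBM visible units require inputs in [0, 1]")
    X = X.astype(DTYPE)
    k = model.spec.cd_steps
    for rbm, data in ((model.rbm1, X), (model.rbm2, None)):
        if data is None:
            data = model.rbm1.hidden_probs(X)
        n = data.shape[0]
        for _ in range(epochs):
            order = rng.permutation(n)
            for i in range(0, n, batch_size):
                rbm.cd_update(data[order[i:i + batch_size]], lr, rng, k=k)
    return model
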