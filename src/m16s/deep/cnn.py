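"""1-D convolutional classifier for k-mer frequency vectors.

LeNet-style topology: two convolution + max-pool stages extract local
co-occurrence patterns from the (sparse) k-mer vector, a 500-unit ReLU
hidden layer and a softmax head perform the classification. Default
hyper-parameters: both convolutions use kernel size 5 (5 kernels in the
first stage, 10 in the second), pooling size 2, hidden layer 500 units.
Small kernels suit the representation: non-zero entries are mostly
isolated, so informative patterns are local.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layers import Conv1D, Dense, Flatten, MaxPool1D, Network, ReLU


@dataclass(frozen=True, slots=True)
class CNNSpec:
    """Architecture parameters; defaults are the published configuration."""

    input_len: int
    n_classes: int
    conv1_kernel_size: int = 5
    conv1_n_kernels: int = 5
    pool1_size: int = 2
    conv2_kernel_size: int = 5
    conv2_n_kernels: int = 10
    pool2_size: int = 2
    hidden_units: int = 500

    def feature_len(self) -> int:
        """Flattened feature count after the conv/pool stages."""
        t1 = self.input_len - self.conv1_kernel_size + 1
        p1 = t1 // self.pool1_size
        t2 = p1 - self.conv2_kernel_size + 1
        p2 = t2 // self.pool2_size
        if t1 < 1 or p1 < 1 or t2 < 1 or p2 < 1:
            raise ValueError(
                f"input length {self.input_len} too short for the conv/pool stack"
            )
        return p2 * self.conv2_n_kernels

    def n_parameters(self) -> int:
        """Closed-form trainable parameter count."""
        conv1 = self.conv1_n_kernels * (1 * self.conv1_kernel_size) + self.conv1_n_kernels
        conv2 = (
            self.conv2_n_kernels * (self.conv1_n_kernels * self.conv2_kernel_size)
            + self.conv2_n_kernels
        )
        dense1 = self.feature_len() * self.hidden_units + self.hidden_units
        dense2 = self.hidden_units * self.n_classes + self.n_classes
        return conv1 + conv2 + dense1 + dense2


def build_cnn(spec: CNNSpec, seed: int = 0) -> Network:
    """Assemble the untrained network; weight initialisation is seeded."""
    if spec.n_classes < 2:
        raise ValueError("need at least 2 classes")
    flat = spec.feature_len()  # validates geometry
    rng = np.random.default_rng(seed)
    layers = [
        Conv1D(1, spec.conv1_n_kernels, spec.conv1_kernel_size, rng),
        MaxPool1D(spec.pool1_size),
        Conv1D(spec.conv1_n_kernels, spec.conv2_n_kernels, spec.conv2_kernel_size, rng),
        MaxPool1D(spec.pool2_size),
        ReLU(),
        Flatten(),
        Dense(flat, spec.hidden_units, rng),
        ReLU(),
        Dense(spec.hidden_units, spec.n_classes, rng),
    ]
    return Network(layers, input_len=spec.input_len, n_classes=spec.n_classes)
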