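"""1-D convolutional classifier with a projection skip connection.

The network treats each subject's fused F-dimensional representation as a
one-channel sequence.  Each conv block applies, in order: same-padded 1-D
convolution, rectifier, batch normalisation, max pooling, dropout.  A skip
connection spans a pair of blocks: the block-span input is passed through a
1x1 convolution that adjusts its channel count (identity when shapes already
match), max-pooled by the same factors as the main path so lengths align,
and added to the main path's output — ``output = shortcut(x) + main(x)``.
A flatten / dense-rectifier / dense head with softmax yields two-class
probabilities; column 0 is the control class (HC), column 1 the positive
class (ASD).

Cross-entropy is regularised by an L2 penalty over convolution and dense
weights (biases and batch-norm parameters excluded).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import (Conv1d, BatchNorm1d, MaxPool1d, Dropout, Dense, ReLU, Flatten,
                 Param, softmax)
from . import nn as _nn

__all__ = ["CNNConfig", "ConvBlock", "SkipProjection", "CNN1D",
           "skip_connect", "l2_penalty"]

l2_penalty = _nn.l2_penalty


@dataclass
class CNNConfig:
    """Architecture and regularisation knobs for the classifier.

    ``skip_span`` gives the (start, stop) block indices the shortcut wraps,
    half-open; the default one shortcut spans the first two blocks.
    """

    input_dim: int = 2000
    n_blocks: int = 3
    channels: tuple[int, ...] = (16, 32, 64)
    kernel_size: int = 5
    pool_factor: int = 2
    dropout_rate: float = 0.3
    l2_coefficient: float = 1e-4
    dense_width: int = 128
    skip_span: tuple[int, int] | None = (0, 2)
    learning_rate: float = 1e-4
    momentum: float = 0.9
    epochs: int = 200
    batch_size: int = 32

    def __post_init__(self) -> None:
        if len(self.channels) != self.n_blocks:
            raise ValueError(
                f"channels has {len(self.channels)} entries for {self.n_blocks} blocks")
        if self.input_dim // (self.pool_factor ** self.n_blocks) < 1:
            raise ValueError(
                f"input length {self.input_dim} pools to nothing after "
                f"{self.n_blocks} blocks of factor {self.pool_factor}")
        if self.skip_span is not None:
            a, b = self.skip_span
            if not (0 <= a < b <= self.n_blocks):
                raise ValueError(f"invalid skip_span {self.skip_span}")


class ConvBlock:
    """conv -> relu -> batchnorm -> maxpool -> dropout."""

    def __init__(self, c_in: int, c_out: int, cfg: CNNConfig, rng: np.random.Generator,
                 index: int):
        self.index = index
        self.conv = Conv1d(c_in, c_out, cfg.kernel_size, rng)
        self.relu = ReLU()
        self.bn = BatchNorm1d(c_out)
        self.pool = MaxPool1d(cfg.pool_factor)
        self.drop = Dropout(cfg.dropout_rate, rng)
        self._ops = [self.conv, self.relu, self.bn, self.pool, self.drop]

    def params(self):
        return [p for op in self._ops for p in op.params()]

    def forward(self, x, training=False):
        if x.shape[2] < self.pool.factor:
            raise ValueError(
                f"block {self.index}: input length {x.shape[2]} < pool factor "
                f"{self.pool.factor}")
        for op in self._ops:
            x = op.forward(x, training=training)
        return x

    def backward(self, dy):
        for op in reversed(self._ops):
            dy = op.backward(dy)
        return dy


class SkipProjection:
    """Shortcut path of a skip connection: optional 1x1 channel projection
    followed by pooling matching the main path's total pool factor."""

    def __init__(self, c_in: int, c_out: int, total_pool: int, rng: np.random.Generator):
        self.identity = (c_in == c_out)
        self.proj = None if self.identity else Conv1d(c_in, c_out, 1, rng)
        self.pool = MaxPool1d(total_pool) if total_pool > 1 else None

    def params(self):
        return [] if self.proj is None else self.proj.params()

    def forward(self, x, training=False):
        if self.proj is not None:
            x = self.proj.forward(x, training=training)
        if self.pool is not None:
            x = self.pool.forward(x, training=training)
        return x

    def backward(self, dy):
        if self.pool is not None:
            dy = self.pool.backward(dy)
        if self.proj is not None:
            dy = self.proj.backward(dy)
        return dy


def skip_connect(x: np.ndarray, main_out: np.ndarray,
                 projection: SkipProjection) -> np.ndarray:
    """``main_out + projection(x)`` with a shape check on the aligned shortcut."""
    shortcut = projection.forward(x)
    if shortcut.shape != main_out.shape:
        raise ValueError(
            f"irreconcilable skip shapes: shortcut {shortcut.shape} vs "
            f"main path {main_out.shape}")
    return main_out + shortcut


class CNN1D:
    """The full classifier; ``forward`` returns logits, ``predict_proba``
    softmax probabilities with rows summing to one."""

    def __init__(self, cfg: CNNConfig, rng: np.random.Generator):
        self.cfg = cfg
        chans = (1,) + tuple(cfg.channels)
        self.blocks = [ConvBlock(chans[i], chans[i + 1], cfg, rng, i)
                       for i in range(cfg.n_blocks)]
        self.skip = None
        if cfg.skip_span is not None:
            a, b = cfg.skip_span
            self.skip = SkipProjection(
                chans[a], chans[b], cfg.pool_factor ** (b - a), rng)
        final_len = cfg.input_dim // (cfg.pool_factor ** cfg.n_blocks)
        flat = cfg.channels[-1] * final_len
        self.flatten = Flatten()
        self.dense1 = Dense(flat, cfg.dense_width, rng)
        self.relu = ReLU()
        self.dense2 = Dense(cfg.dense_width, 2, rng)

    def params(self) -> list[Param]:
        out = [p for b in self.blocks for p in b.params()]
        if self.skip is not None:
            out += self.skip.params()
        return out + self.dense1.params() + self.dense2.params()

    def weight_params(self) -> list[Param]:
        """Convolution and dense weights only — the L2-penalised set."""
        out = [b.conv.W for b in self.blocks]
        if self.skip is not None and self.skip.proj is not None:
            out.append(self.skip.proj.W)
        return out + [self.dense1.W, self.dense2.W]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if x.ndim == 2:
            x = x[:, None, :]
        if x.shape[2] != self.cfg.input_dim:
            raise ValueError(
                f"expected input length {self.cfg.input_dim}, got {x.shape[2]}")
        span = self.cfg.skip_span
        for i, block in enumerate(self.blocks):
            if span is not None and i == span[0]:
                skip_input = x
            x = block.forward(x, training=training)
            if span is not None and i == span[1] - 1:
                x = skip_connect(skip_input, x, self.skip)
        x = self.flatten.forward(x)
        x = self.relu.forward(self.dense1.forward(x))
        logits = self.dense2.forward(x)
        if not np.isfinite(logits).all():
            raise FloatingPointError("non-finite activations in the dense head")
        return logits

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        dy = self.dense1.backward(self.relu.backward(self.dense2.backward(dlogits)))
        dy = self.flatten.backward(dy)
        span = self.cfg.skip_span
        d_skip_input = None
        for i in reversed(range(len(self.blocks))):
            if span is not None and i == span[1] - 1:
                d_skip_input = self.skip.backward(dy)
            dy = self.blocks[i].backward(dy)
            if span is not None and i == span[0]:
                dy = dy + d_skip_input
        return dy[:, 0, :]

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x, training=False))

    def predict(self, x: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        """Class labels; ties at the threshold break toward HC (class 0)."""
        return (self.predict_proba(x)[:, 1] > threshold).astype(int)
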