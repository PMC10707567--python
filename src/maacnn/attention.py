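"""Attention-based fusion of per-view encoded representations.

Given encoded features ``X'`` of shape (n_views, N, F), a squeeze-excitation
style branch drives the fusion: global average pooling collapses each view of
each subject to a scalar summary, a one-hidden-layer MLP maps the n summaries
to n logits, and a softmax over views yields nonnegative weights summing to
one.  The fused representation is the convex combination
``x_hat = sum_i c_i x'_i`` per subject.

By default summaries and weights are per subject; ``global_weights=True``
averages summaries over the batch first, giving a single weight vector for
all subjects.  ``normalize="none"`` skips the softmax (raw logits as
weights), trading the convex-combination guarantee for unconstrained scaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Dense, ReLU, Param, softmax

__all__ = ["AttentionConfig", "AttentionMLP", "global_average_pool",
           "view_weights", "fuse"]


@dataclass
class AttentionConfig:
    n_views: int
    hidden_width: int | None = None  # default max(4, 2 n)
    global_weights: bool = False
    normalize: str = "softmax"  # softmax | none

    def __post_init__(self) -> None:
        if self.n_views < 1:
            raise ValueError("need at least one view")
        if self.hidden_width is None:
            self.hidden_width = max(4, 2 * self.n_views)
        if self.normalize not in ("softmax", "none"):
            raise ValueError(f"unknown normalize mode {self.normalize!r}")


def global_average_pool(xp: np.ndarray) -> np.ndarray:
    """(n_views, N, F) -> (N, n_views) per-subject view summaries (mean over F)."""
    xp = np.asarray(xp, dtype=np.float64)
    if xp.ndim != 3:
        raise ValueError(f"expected (n_views, N, F), got shape {xp.shape}")
    if xp.shape[2] == 0:
        raise ValueError("empty feature dimension")
    return xp.mean(axis=2).T


class AttentionMLP:
    """One-hidden-layer rectifier MLP mapping view summaries to view logits."""

    def __init__(self, cfg: AttentionConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.dense1 = Dense(cfg.n_views, cfg.hidden_width, rng)
        self.relu = ReLU()
        self.dense2 = Dense(cfg.hidden_width, cfg.n_views, rng)

    def params(self) -> list[Param]:
        return self.dense1.params() + self.dense2.params()

    def weight_params(self) -> list[Param]:
        return [self.dense1.W, self.dense2.W]

    def forward(self, summaries: np.ndarray) -> np.ndarray:
        return self.dense2.forward(self.relu.forward(self.dense1.forward(summaries)))

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        return self.dense1.backward(self.relu.backward(self.dense2.backward(dlogits)))


def view_weights(summaries: np.ndarray, mlp: AttentionMLP) -> np.ndarray:
    """(N, n) summaries -> (N, n) attention weights.

    With softmax normalisation every weight row is a probability vector; with
    ``global_weights`` the batch-mean summary produces one shared row.
    """
    summaries = np.asarray(summaries, dtype=np.float64)
    if summaries.ndim != 2 or summaries.shape[1] != mlp.cfg.n_views:
        raise ValueError(
            f"expected (N, {mlp.cfg.n_views}) summaries, got {summaries.shape}")
    if mlp.cfg.global_weights:
        summaries = np.broadcast_to(
            summaries.mean(axis=0, keepdims=True), summaries.shape)
    logits = mlp.forward(np.ascontiguousarray(summaries))
    if mlp.cfg.normalize == "softmax":
        weights = softmax(logits)
        assert np.all(weights >= 0.0)
        assert np.allclose(weights.sum(axis=1), 1.0, atol=1e-6)
        return weights
    return logits


def fuse(xp: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Attention-weighted sum over views: (n, N, F), (N, n) -> (N, F)."""
    xp = np.asarray(xp, dtype=np.float64)
    weights = np.asarray(weights, dtype=np.float64)
    if xp.ndim != 3:
        raise ValueError(f"expected (n_views, N, F) features, got {xp.shape}")
    if weights.shape != (xp.shape[1], xp.shape[0]):
        raise ValueError(
            f"misaligned weights: got {weights.shape}, expected "
            f"({xp.shape[1]}, {xp.shape[0]})")
    return np.einsum("vnf,nv->nf", xp, weights)
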