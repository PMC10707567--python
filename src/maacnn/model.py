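"""Joint attention-fusion + CNN classification head.

The per-view encoders (SDA) are frozen after pretraining; this module trains
the attention MLP and the 1-D CNN together by backpropagating the
classification loss through the fusion:

    summaries = GAP(X')            (N, n)
    C         = softmax(MLP(summaries))
    x_hat     = sum_i C_i x'_i     (N, F)
    p         = softmax(CNN(x_hat))

The gradient w.r.t. the weights of view i is ``dL/dC_i = dL/dx_hat . x'_i``,
which is pushed through the softmax and the MLP; encoded features themselves
receive no updates.
"""

from __future__ import annotations


import numpy as np

from .attention import AttentionConfig, AttentionMLP, global_average_pool, fuse
from .cnn import CNNConfig, CNN1D
from .leakage import guard
from .nn import SGDMomentum, softmax, softmax_cross_entropy, l2_penalty, add_l2_gradients

__all__ = ["MAACNNHead", "train_head"]


class MAACNNHead:
    """Attention fusion followed by the CNN classifier."""

    def __init__(self, att_cfg: AttentionConfig, cnn_cfg: CNNConfig,
                 rng: np.random.Generator):
        self.att_cfg = att_cfg
        self.mlp = AttentionMLP(att_cfg, rng)
        self.cnn = CNN1D(cnn_cfg, rng)
        self.loss_history: list[float] = []
        self.trained = False

    def params(self):
        return self.mlp.params() + self.cnn.params()

    def weight_params(self):
        return self.mlp.weight_params() + self.cnn.weight_params()

    def forward(self, xp: np.ndarray, training: bool = False) -> np.ndarray:
        """(n_views, N, F) encoded features -> (N, 2) logits."""
        summaries = global_average_pool(xp)
        if self.att_cfg.global_weights:
            summaries = np.broadcast_to(
                summaries.mean(axis=0, keepdims=True), summaries.shape)
        logits_v = self.mlp.forward(np.ascontiguousarray(summaries))
        if self.att_cfg.normalize == "softmax":
            weights = softmax(logits_v)
        else:
            weights = logits_v
        assert self.att_cfg.normalize != "softmax" or (
            np.all(weights >= 0.0)
            and np.allclose(weights.sum(axis=1), 1.0, atol=1e-6))
        xhat = fuse(xp, weights)
        self._cache = (xp, weights)
        self.last_weights = weights
        return self.cnn.forward(xhat, training=training)

    def backward(self, dlogits: np.ndarray) -> None:
        xp, weights = self._cache
        dxhat = self.cnn.backward(dlogits)  # (N, F)
        dweights = np.einsum("vnf,nf->nv", xp, dxhat)
        if self.att_cfg.normalize == "softmax":
            dlogits_v = weights * (dweights
                                   - (weights * dweights).sum(axis=1, keepdims=True))
        else:
            dlogits_v = dweights
        self.mlp.backward(dlogits_v)

    def predict_proba(self, xp: np.ndarray) -> np.ndarray:
        """(N, 2) class probabilities, columns (HC, ASD)."""
        return softmax(self.forward(xp, training=False))

    def predict(self, xp: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(xp)[:, 1] > threshold).astype(int)

    def mean_view_weights(self, xp: np.ndarray) -> np.ndarray:
        """Mean attention weight per view over the given subjects."""
        self.forward(xp, training=False)
        return self.last_weights.mean(axis=0)


def train_head(xp: np.ndarray, y: np.ndarray, att_cfg: AttentionConfig,
               cnn_cfg: CNNConfig, rng: np.random.Generator,
               row_ids=None) -> MAACNNHead:
    """Train the fused head with minibatch SGD + momentum on cross-entropy
    plus the L2 weight penalty."""
    guard.check_fit(row_ids, what="train_head")
    xp = np.asarray(xp, dtype=np.float64)
    y = np.asarray(y, dtype=int)
    if xp.ndim != 3 or xp.shape[0] != att_cfg.n_views:
        raise ValueError(f"expected ({att_cfg.n_views}, N, F) features, got {xp.shape}")
    if xp.shape[1] != y.shape[0]:
        raise ValueError("subject count mismatch between features and labels")
    head = MAACNNHead(att_cfg, cnn_cfg, rng)
    opt = SGDMomentum(head.params(), lr=cnn_cfg.learning_rate, momentum=cnn_cfg.momentum)
    n = xp.shape[1]
    lam = cnn_cfg.l2_coefficient
    for _epoch in range(cnn_cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cnn_cfg.batch_size):
            idx = order[start:start + cnn_cfg.batch_size]
            logits = head.forward(xp[:, idx], training=True)
            loss, dlogits = softmax_cross_entropy(logits, y[idx])
            loss += l2_penalty(head.weight_params(), lam)
            if not np.isfinite(loss):
                raise FloatingPointError("training loss became non-finite")
            epoch_loss += loss * len(idx)
            opt.zero_grad()
            head.backward(dlogits)
            add_l2_gradients(head.weight_params(), lam)
            opt.step()
        head.loss_history.append(epoch_loss / n)
    head.trained = True
    return head
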