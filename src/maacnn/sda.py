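"""Stacked denoising autoencoder (SDA) for per-view feature compression.

Two denoising autoencoders (DAEs) are trained greedily: the first maps the
raw S-dimensional FC features to a hidden code of roughly half the width, the
second maps those codes to a fixed F-dimensional representation shared by all
views (F = 2000 at full scale).  During training, each input vector is
corrupted by masking noise — every coordinate is independently zeroed with
probability ``corruption_rate`` — and the network is asked to reconstruct the
*clean* vector, which forces robust features.  At inference the encoders are
applied without corruption and without the decoders.

Inputs are standardised per feature (statistics fit on training rows only)
before entering DAE-1; the encoder hidden layer is a rectifier and the
decoder output is linear with a mean-squared reconstruction loss, which suits
unbounded z-scored inputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .atlas import AtlasSpec
from .leakage import guard
from .nn import Dense, ReLU, SGDMomentum, Param

__all__ = [
    "DAEConfig", "DAE", "SDAModel", "Standardizer",
    "default_sda_config", "corrupt", "train_dae", "pretrain_sda", "sda_transform",
    "save_sda", "load_sda",
]

#: Encoder hidden widths for the named parcellations.  Stage-1 input width is
#: always n(n-1)/2 from the atlas itself.
_NAMED_HIDDEN = {"AAL": 3330, "CC200": 9950, "HO": 3050, "Dosenbach160": 6440, "EZ": 3380}


@dataclass
class DAEConfig:
    input_dim: int
    hidden_dim: int
    corruption_rate: float
    learning_rate: float = 1e-4
    momentum: float = 0.9
    epochs: int = 200
    batch_size: int = 32

    def __post_init__(self) -> None:
        if self.hidden_dim >= self.input_dim:
            raise ValueError(
                f"non-compressive DAE: hidden_dim {self.hidden_dim} >= "
                f"input_dim {self.input_dim}"
            )
        if not 0.0 <= self.corruption_rate <= 1.0:
            raise ValueError(f"corruption_rate must be in [0,1], got {self.corruption_rate}")


def default_sda_config(atlas: AtlasSpec, code_dim: int = 2000, *,
                       learning_rate: float = 1e-4, momentum: float = 0.9,
                       epochs: int = 200, batch_size: int = 32,
                       ) -> tuple[DAEConfig, DAEConfig]:
    """Default two-stage configuration for an atlas.

    Named atlases use the published hidden widths; custom atlases use the
    halving rule ``(M -> ceil(M/2) -> M)`` then ``(ceil(M/2) -> code_dim)``.
    Corruption is 0.30 for stage 1 and 0.10 for stage 2.
    """
    m = atlas.feature_dim
    h1 = _NAMED_HIDDEN.get(atlas.name, (m + 1) // 2)
    if code_dim >= h1:
        raise ValueError(
            f"non-compressive stage 2: code_dim {code_dim} >= hidden width {h1} "
            f"for atlas {atlas.name}"
        )
    common = dict(learning_rate=learning_rate, momentum=momentum,
                  epochs=epochs, batch_size=batch_size)
    return (
        DAEConfig(input_dim=m, hidden_dim=h1, corruption_rate=0.30, **common),
        DAEConfig(input_dim=h1, hidden_dim=code_dim, corruption_rate=0.10, **common),
    )


def corrupt(x: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Masking noise: zero each coordinate independently with probability ``rate``."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"corruption rate must be in [0,1], got {rate}")
    if rate == 0.0:
        return np.array(x, copy=True)
    return np.where(rng.random(np.shape(x)) < rate, 0.0, x)


class Standardizer:
    """Per-feature zero-mean unit-variance scaler; statistics from fit rows only."""

    def __init__(self) -> None:
        self.mean_: np.ndarray | None = None
        self.scale_: np.ndarray | None = None

    def fit(self, x: np.ndarray, row_ids=None) -> "Standardizer":
        guard.check_fit(row_ids, what="standardizer.fit")
        x = np.asarray(x, dtype=np.float64)
        self.mean_ = x.mean(axis=0)
        std = x.std(axis=0)
        self.scale_ = np.where(std > 1e-12, std, 1.0)
        return self

    def transform(self, x: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise RuntimeError("Standardizer not fitted")
        return (np.asarray(x, dtype=np.float64) - self.mean_) / self.scale_


class DAE:
    """One denoising autoencoder: rectifier encoder, linear decoder."""

    def __init__(self, cfg: DAEConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.encoder = Dense(cfg.input_dim, cfg.hidden_dim, rng)
        self.relu = ReLU()
        self.decoder = Dense(cfg.hidden_dim, cfg.input_dim, rng)
        self.loss_history: list[float] = []
        self.trained = False

    def params(self) -> list[Param]:
        return self.encoder.params() + self.decoder.params()

    def encode(self, x: np.ndarray) -> np.ndarray:
        return self.relu.forward(self.encoder.forward(x))


def train_dae(x: np.ndarray, cfg: DAEConfig, rng: np.random.Generator,
              row_ids=None) -> DAE:
    """Train one DAE by minibatch SGD with momentum.

    Each epoch draws a fresh corruption mask per sample; the loss recorded per
    epoch is the mean squared reconstruction error of the *clean* input.
    """
    guard.check_fit(row_ids, what="train_dae")
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 2 or x.shape[1] != cfg.input_dim:
        raise ValueError(f"expected (N, {cfg.input_dim}) input, got {x.shape}")
    if x.shape[0] < 2:
        raise ValueError("need at least 2 training rows")
    dae = DAE(cfg, rng)
    opt = SGDMomentum(dae.params(), lr=cfg.learning_rate, momentum=cfg.momentum)
    n = x.shape[0]
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            clean = x[idx]
            noisy = corrupt(clean, cfg.corruption_rate, rng)
            h = dae.relu.forward(dae.encoder.forward(noisy))
            recon = dae.decoder.forward(h)
            diff = recon - clean
            loss = float((diff ** 2).mean())
            if not np.isfinite(loss):
                raise FloatingPointError(
                    "DAE reconstruction loss became non-finite; "
                    "reduce the learning rate or standardise the input"
                )
            epoch_loss += loss * len(idx)
            opt.zero_grad()
            dae.encoder.backward(dae.relu.backward(dae.decoder.backward(
                2.0 * diff / diff.size)))
            opt.step()
        dae.loss_history.append(epoch_loss / n)
    dae.trained = True
    return dae


@dataclass
class SDAModel:
    """Two chained DAEs plus the standardiser fitted with them."""

    atlas: AtlasSpec
    standardizer: Standardizer
    dae1: DAE
    dae2: DAE

    @property
    def code_dim(self) -> int:
        return self.dae2.cfg.hidden_dim

    @property
    def loss_history(self) -> dict[str, list[float]]:
        return {"dae1": self.dae1.loss_history, "dae2": self.dae2.loss_history}


def pretrain_sda(x_raw: np.ndarray, atlas: AtlasSpec, rng: np.random.Generator,
                 configs: tuple[DAEConfig, DAEConfig] | None = None,
                 row_ids=None) -> SDAModel:
    """Greedy layerwise pretraining: standardise, train DAE-1 on the features,
    then train DAE-2 on DAE-1's codes."""
    x_raw = np.asarray(x_raw, dtype=np.float64)
    if x_raw.ndim != 2 or x_raw.shape[1] != atlas.feature_dim:
        raise ValueError(
            f"atlas {atlas.name} expects feature dimension {atlas.feature_dim}, "
            f"got input of shape {x_raw.shape}"
        )
    cfg1, cfg2 = configs if configs is not None else default_sda_config(atlas)
    scaler = Standardizer().fit(x_raw, row_ids=row_ids)
    x = scaler.transform(x_raw)
    dae1 = train_dae(x, cfg1, rng, row_ids=row_ids)
    codes = dae1.encode(x)
    dae2 = train_dae(codes, cfg2, rng, row_ids=row_ids)
    return SDAModel(atlas=atlas, standardizer=scaler, dae1=dae1, dae2=dae2)


def sda_transform(model: SDAModel, x_raw: np.ndarray) -> np.ndarray:
    """Encode raw features through both (frozen) encoders, no corruption."""
    if not (model.dae1.trained and model.dae2.trained):
        raise RuntimeError("SDA model is not trained")
    x = model.standardizer.transform(x_raw)
    return model.dae2.encode(model.dae1.encode(x))


def save_sda(model: SDAModel, path: str | Path) -> None:
    """Checkpoint: JSON manifest + npz arrays, one archive directory per view."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "format": "maacnn-sda/1",
        "atlas": {"name": model.atlas.name, "n_rois": model.atlas.n_rois},
        "dae1": asdict(model.dae1.cfg),
        "dae2": asdict(model.dae2.cfg),
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))
    np.savez(
        path / "arrays.npz",
        mean=model.standardizer.mean_, scale=model.standardizer.scale_,
        enc1_W=model.dae1.encoder.W.value, enc1_b=model.dae1.encoder.b.value,
        dec1_W=model.dae1.decoder.W.value, dec1_b=model.dae1.decoder.b.value,
        enc2_W=model.dae2.encoder.W.value, enc2_b=model.dae2.encoder.b.value,
        dec2_W=model.dae2.decoder.W.value, dec2_b=model.dae2.decoder.b.value,
        loss1=np.asarray(model.dae1.loss_history),
        loss2=np.asarray(model.dae2.loss_history),
    )


def load_sda(path: str | Path) -> SDAModel:
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    if manifest.get("format") != "maacnn-sda/1":
        raise ValueError(f"unrecognised checkpoint format in {path}")
    arrays = np.load(path / "arrays.npz")
    atlas = AtlasSpec(manifest["atlas"]["name"], manifest["atlas"]["n_rois"])
    rng = np.random.default_rng(0)  # weights are overwritten below
    dae1 = DAE(DAEConfig(**manifest["dae1"]), rng)
    dae2 = DAE(DAEConfig(**manifest["dae2"]), rng)
    for dae, tag in ((dae1, "1"), (dae2, "2")):
        dae.encoder.W.value = arrays[f"enc{tag}_W"]
        dae.encoder.b.value = arrays[f"enc{tag}_b"]
        dae.decoder.W.value = arrays[f"dec{tag}_W"]
        dae.decoder.b.value = arrays[f"dec{tag}_b"]
        dae.loss_history = arrays[f"loss{tag}"].tolist()
        dae.trained = True
    scaler = Standardizer()
    scaler.mean_, scaler.scale_ = arrays["mean"], arrays["scale"]
    return SDAModel(atlas=atlas, standardizer=scaler, dae1=dae1, dae2=dae2)
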