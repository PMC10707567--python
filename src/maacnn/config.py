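"""Run configuration: bundled settings for every pipeline stage.

Two scales are shipped.  The full-scale defaults mirror the published
training settings (F = 2000 codes, SGD with momentum 0.9, learning rate 1e-4,
200 epochs, corruption 0.30/0.10).  ``ModelConfig.test_scale()`` is the
desk-scale counterpart used with the synthetic presets: the same pipeline
with small widths (F = 16) and a larger learning rate appropriate for the
tiny feature spaces, so end-to-end runs finish in minutes on one CPU.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

from .cnn import CNNConfig

__all__ = ["SDATrainConfig", "AttentionSettings", "ModelConfig"]


@dataclass
class SDATrainConfig:
    code_dim: int = 2000  # F, shared across views
    epochs: int = 200
    learning_rate: float = 1e-4
    momentum: float = 0.9
    batch_size: int = 32


@dataclass
class AttentionSettings:
    global_weights: bool = False
    normalize: str = "softmax"
    hidden_width: int | None = None


@dataclass
class ModelConfig:
    sda: SDATrainConfig = field(default_factory=SDATrainConfig)
    cnn: CNNConfig = field(default_factory=CNNConfig)
    attention: AttentionSettings = field(default_factory=AttentionSettings)
    folds: int = 10
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.cnn.input_dim != self.sda.code_dim:
            raise ValueError(
                f"CNN input length {self.cnn.input_dim} must equal the SDA "
                f"code dimension {self.sda.code_dim}")

    @classmethod
    def test_scale(cls, folds: int = 5) -> "ModelConfig":
        """Desk-scale configuration for the synthetic presets."""
        return cls(
            sda=SDATrainConfig(code_dim=16, epochs=150, learning_rate=0.05),
            cnn=CNNConfig(
                input_dim=16, n_blocks=2, channels=(8, 16), kernel_size=3,
                pool_factor=2, dropout_rate=0.1, l2_coefficient=1e-4,
                dense_width=32, skip_span=(0, 2), learning_rate=0.01,
                epochs=100, batch_size=32),
            folds=folds,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        sda = SDATrainConfig(**d.get("sda", {}))
        cnn_d = dict(d.get("cnn", {}))
        for key in ("channels", "skip_span"):
            if cnn_d.get(key) is not None:
                cnn_d[key] = tuple(cnn_d[key])
        cnn = CNNConfig(**cnn_d) if cnn_d else CNNConfig()
        att = AttentionSettings(**d.get("attention", {}))
        return cls(sda=sda, cnn=cnn, attention=att,
                   folds=d.get("folds", 10), threshold=d.get("threshold", 0.5))

    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
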