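"""Convolutional whinny detector.

Conv blocks each followed by squeeze-and-excitation channel recalibration,
then multi-head attention pooling of the frame sequence into one fixed
vector, then a linear classifier producing a confidence in [0, 1].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .autodiff import Tensor, conv2d, maxpool2d, softmax, concat

__all__ = ["DetectorConfig", "SEBlock", "AttentionPool", "WhinnyDetector", "build_model"]


@dataclass
class DetectorConfig:
    """Desk-scale defaults: 4 conv blocks, SE reduction 4, 4 attention heads."""

    conv_channels: tuple = (16, 32, 64, 64)
    kernel: int = 3
    pool: int = 2
    se_reduction: int = 4
    attention_heads: int = 4
    dropout: float = 0.2
    threshold: float = 0.5
    lr: float = 1e-3
    epochs: int = 30
    batch_size: int = 16
    seed: int = 0
    use_se: bool = True

    def __post_init__(self):
        if not (0.0 <= self.threshold <= 1.0):
            raise ValueError("threshold must be in [0, 1]")
        if self.attention_heads < 1:
            raise ValueError("attention_heads must be >= 1")
        if self.se_reduction < 1:
            raise ValueError("se_reduction must be >= 1")


class SEBlock:
    """Squeeze-and-excitation: global-average squeeze -> bottleneck -> sigmoid gate."""

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator):
        hidden = max(1, channels // reduction)
        self.w1 = Tensor(rng.standard_normal((channels, hidden)) * np.sqrt(2.0 / channels),
                         requires_grad=True)
        self.b1 = Tensor(np.zeros(hidden), requires_grad=True)
        self.w2 = Tensor(rng.standard_normal((hidden, channels)) * np.sqrt(2.0 / hidden),
                         requires_grad=True)
        self.b2 = Tensor(np.zeros(channels), requires_grad=True)
        self.gate_override: np.ndarray | None = None  # e.g. all-ones -> identity

    def params(self):
        return [self.w1, self.b1, self.w2, self.b2]

    def __call__(self, x: Tensor) -> Tensor:
        if self.gate_override is not None:
            gate = Tensor(np.broadcast_to(self.gate_override, (x.shape[0], x.shape[1])))
        else:
            s = x.mean(axis=(2, 3))  # (B, C)
            gate = ((s @ self.w1 + self.b1).relu() @ self.w2 + self.b2).sigmoid()
        b, c = x.shape[0], x.shape[1]
        return x * gate.reshape(b, c, 1, 1)


class AttentionPool:
    """Multi-head attention pooling over frames.

    Per head: a learned scoring vector gives per-frame importance weights
    (softmax over frames); the head's value projection is averaged under
    those weights. Heads are concatenated into one fixed vector.
    """

    def __init__(self, dim: int, heads: int, rng: np.random.Generator):
        if dim % heads != 0:
            raise ValueError(f"feature dim {dim} not divisible by heads {heads}")
        self.heads = heads
        self.dim = dim
        hd = dim // heads
        self.score_w = [Tensor(rng.standard_normal((dim, 1)) * np.sqrt(1.0 / dim),
                               requires_grad=True) for _ in range(heads)]
        self.value_w = [Tensor(rng.standard_normal((dim, hd)) * np.sqrt(1.0 / dim),
                               requires_grad=True) for _ in range(heads)]
        self.force_uniform = False  # uniform weights == mean pooling

    def params(self):
        return self.score_w + self.value_w

    def __call__(self, frames: Tensor) -> Tensor:
        # frames: (B, T, D) -> (B, D)
        b, t, _ = frames.shape
        ctxs = []
        for wq, wv in zip(self.score_w, self.value_w):
            if self.force_uniform:
                alpha = Tensor(np.full((b, t, 1), 1.0 / t))
            else:
                scores = frames @ wq  # (B, T, 1)
                alpha = softmax(scores, axis=1)
            vals = frames @ wv  # (B, T, hd)
            ctxs.append((alpha * vals).sum(axis=1))  # (B, hd)
        return concat(ctxs, axis=-1)


class WhinnyDetector:
    def __init__(self, cfg: DetectorConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.conv_w: list[Tensor] = []
        self.conv_b: list[Tensor] = []
        self.se: list[SEBlock] = []
        in_c = 1
        k = cfg.kernel
        for out_c in cfg.conv_channels:
            fan_in = in_c * k * k
            self.conv_w.append(
                Tensor(rng.standard_normal((out_c, in_c, k, k)) * np.sqrt(2.0 / fan_in),
                       requires_grad=True)
            )
            self.conv_b.append(Tensor(np.zeros(out_c), requires_grad=True))
            self.se.append(SEBlock(out_c, cfg.se_reduction, rng))
            in_c = out_c
        d = cfg.conv_channels[-1]
        self.pool = AttentionPool(d, cfg.attention_heads, rng)
        self.cls_w = Tensor(rng.standard_normal((d, 1)) * np.sqrt(1.0 / d), requires_grad=True)
        self.cls_b = Tensor(np.zeros(1), requires_grad=True)
        self.trained = False

    def params(self) -> list[Tensor]:
        ps = []
        for w, b, se in zip(self.conv_w, self.conv_b, self.se):
            ps += [w, b]
            if self.cfg.use_se:
                ps += se.params()
        ps += self.pool.params()
        ps += [self.cls_w, self.cls_b]
        return ps

    @staticmethod
    def _normalise(x: np.ndarray) -> np.ndarray:
        # per-sample standardisation of the log-mel values
        mu = x.mean(axis=(1, 2), keepdims=True)
        sd = x.std(axis=(1, 2), keepdims=True) + 1e-6
        return (x - mu) / sd

    def forward(
        self, batch: np.ndarray, train: bool = False, rng: np.random.Generator | None = None
    ) -> Tensor:
        """batch: (B, frames, n_mels) log-mel values -> logits Tensor (B,)."""
        x = self._normalise(np.asarray(batch, dtype=np.float64))
        h = Tensor(x[:, None, :, :])  # (B, 1, F, M)
        for w, b, se in zip(self.conv_w, self.conv_b, self.se):
            h = conv2d(h, w, b, pad=self.cfg.kernel // 2).relu()
            if self.cfg.use_se:
                h = se(h)
            h = maxpool2d(h, self.cfg.pool)
        if h.shape[2] < 1 or h.shape[3] < 1:
            raise ValueError("input spectrogram too small for the conv stack")
        frames = h.mean(axis=3).transpose(0, 2, 1)  # (B, T, C)
        if train and self.cfg.dropout > 0:
            if rng is None:
                rng = np.random.default_rng(self.cfg.seed)
            keep = 1.0 - self.cfg.dropout
            mask = (rng.random(frames.shape) < keep) / keep
            frames = frames * Tensor(mask)
        ctx = self.pool(frames)  # (B, C)
        logits = ctx @ self.cls_w + self.cls_b  # (B, 1)
        return logits.reshape(-1)

    def confidence(self, batch: np.ndarray) -> np.ndarray:
        """Scalar confidence in [0, 1] per spectrogram."""
        z = self.forward(batch, train=False).data
        return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))

    # ---- persistence (runtime artefacts; npz + json sidecar) --------------
    def save(self, path: str) -> None:
        arrays = {f"p{i}": p.data for i, p in enumerate(self.params())}
        np.savez(path, **arrays)
        with open(str(path) + ".json", "w") as fh:
            json.dump({"config": asdict(self.cfg), "trained": self.trained}, fh)

    @classmethod
    def load(cls, path: str) -> "WhinnyDetector":
        with open(str(path) + ".json") as fh:
            meta = json.load(fh)
        cfg_d = meta["config"]
        cfg_d["conv_channels"] = tuple(cfg_d["conv_channels"])
        model = cls(DetectorConfig(**cfg_d))
        data = np.load(path if str(path).endswith(".npz") else str(path) + ".npz")
        for i, p in enumerate(model.params()):
            p.data = data[f"p{i}"]
        model.trained = meta["trained"]
        return model

    def state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.params()]

    def load_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.params(), state):
            p.data = s.copy()


def build_model(cfg: DetectorConfig | None = None) -> WhinnyDetector:
    return WhinnyDetector(cfg or DetectorConfig())
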