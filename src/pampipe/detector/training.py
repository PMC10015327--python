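"""Site-independent splits, training loop, thresholded inference."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ..audio.frontend import MelConfig, AnalysisWindow, logmel
from ..audio.synth import LabelledClip
from .autodiff import Adam, bce_with_logits
from .model import DetectorConfig, WhinnyDetector
from .metrics import evaluate

__all__ = ["Detection", "split_site_independent", "train", "predict", "predict_clips"]


@dataclass
class Detection:
    site_id: str
    file: str
    start: float
    end: float
    confidence: float
    review_status: str = "unreviewed"
    detection_id: str = ""


def split_site_independent(
    clips: Sequence[LabelledClip],
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> tuple[list[LabelledClip], list[LabelledClip], list[LabelledClip]]:
    """Partition clips so no site id spans two partitions.

    Fractions apply to whole sites (each partition gets at least one site).
    """
    sites = sorted({c.site_id for c in clips})
    if len(sites) < 3:
        raise ValueError("need >= 3 distinct sites for three site-independent partitions")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(sites))
    n = len(sites)
    n_val = max(1, round(fractions[1] * n))
    n_test = max(1, round(fractions[2] * n))
    if n_val + n_test >= n:
        n_val = n_test = 1
    test_sites = set(order[:n_test])
    val_sites = set(order[n_test : n_test + n_val])
    train_sites = set(order[n_test + n_val :])
    part = lambda ss: [c for c in clips if c.site_id in ss]
    return part(train_sites), part(val_sites), part(test_sites)


def _featurise(clips: Sequence[LabelledClip], mel: MelConfig) -> tuple[np.ndarray, np.ndarray]:
    xs = [logmel(c.waveform, mel).values for c in clips]
    ys = np.array([1 if c.label == "positive" else 0 for c in clips])
    return np.stack(xs), ys


def train(
    model: WhinnyDetector,
    train_clips: Sequence[LabelledClip],
    val_clips: Sequence[LabelledClip],
    cfg: DetectorConfig | None = None,
    mel: MelConfig | None = None,
) -> tuple[WhinnyDetector, pd.DataFrame]:
    """Train with Adam on binary cross-entropy; keep the best-val-UAR checkpoint.

    Ties in validation UAR are broken towards the earlier epoch. With
    ``epochs=0`` the untrained model is returned (flagged ``trained=False``).
    """
    cfg = cfg or model.cfg
    mel = mel or MelConfig()
    if not train_clips or not val_clips:
        raise ValueError("train and validation partitions must be non-empty")
    Xtr, ytr = _featurise(train_clips, mel)
    if len(np.unique(ytr)) < 2:
        raise ValueError("training set must contain both classes")
    Xva, yva = _featurise(val_clips, mel)

    log_rows = []
    if cfg.epochs == 0:
        model.trained = False
        return model, pd.DataFrame(log_rows, columns=["epoch", "train_loss", "val_uar", "best"])

    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.params(), lr=cfg.lr)
    best_uar, best_state, best_epoch = -1.0, model.state(), -1
    n = len(train_clips)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for s in range(0, n, cfg.batch_size):
            idx = order[s : s + cfg.batch_size]
            logits = model.forward(Xtr[idx], train=True, rng=rng)
            loss = bce_with_logits(logits, ytr[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        conf = model.confidence(Xva)
        uar = evaluate(conf, yva, threshold=0.5).uar
        improved = uar > best_uar
        if improved:
            best_uar, best_state, best_epoch = uar, model.state(), epoch
        log_rows.append(
            {"epoch": epoch, "train_loss": float(np.mean(losses)), "val_uar": uar, "best": improved}
        )
    model.load_state(best_state)
    model.trained = True
    log = pd.DataFrame(log_rows)
    log.attrs["best_epoch"] = best_epoch
    log.attrs["best_val_uar"] = best_uar
    return model, log


def predict(
    model: WhinnyDetector,
    windows: Iterable[AnalysisWindow],
    threshold: float = 0.5,
    site_id: str = "",
) -> list[Detection]:
    """Emit a Detection for every window whose confidence >= threshold."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must be in [0, 1]")
    windows = list(windows)
    if not windows:
        return []
    batch = np.stack([w.spectrogram.values for w in windows])
    conf = model.confidence(batch)
    out = []
    for i, (w, c) in enumerate(zip(windows, conf)):
        if c >= threshold:
            out.append(
                Detection(
                    site_id=site_id,
                    file=w.source,
                    start=w.start,
                    end=w.end,
                    confidence=float(c),
                    detection_id=f"{site_id}:{w.source}:{i}",
                )
            )
    return out


def predict_clips(model: WhinnyDetector, clips: Sequence[LabelledClip], mel: MelConfig | None = None) -> np.ndarray:
    """Confidence per labelled clip (for evaluation)."""
    mel = mel or MelConfig()
    X, _ = _featurise(clips, mel)
    return model.confidence(X)
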