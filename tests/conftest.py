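import numpy as np
import pytest

from pampipe.audio.frontend import MelConfig
from pampipe.audio.synth import make_clipset
from pampipe.detector.model import DetectorConfig, build_model
from pampipe.detector.training import split_site_independent, train

#: 8 kHz clips keep the suite fast; fmax below Nyquist
RATE = 8000
CLIP_LEN = 2.0
MEL = MelConfig(win_s=0.032, hop_s=0.032, n_mels=32, fmin=100.0, fmax=3900.0)


@pytest.fixture(scope="session")
def easy_clipset():
    """Separable clipset: high SNR, no hard negatives (the detector's
    solvability surface)."""
    return make_clipset(
        n_pos=48, n_neg=48, hard_negative_fraction=0.0, n_sites=6,
        clip_length=CLIP_LEN, rate=RATE, snr_range=(20.0, 25.0), seed=11,
    )


@pytest.fixture(scope="session")
def mel_config():
    return MEL


@pytest.fixture(scope="session")
def trained_detector(easy_clipset):
    """One desk-scale training run shared across tests (seeded)."""
    cfg = DetectorConfig(epochs=8, seed=0, lr=2e-3)
    tr, va, te = split_site_independent(easy_clipset, seed=0)
    model = build_model(cfg)
    model, log = train(model, tr, va, cfg, MEL)
    return {"model": model, "log": log, "train": tr, "val": va, "test": te}
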