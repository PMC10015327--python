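"""Export verified-review inputs: positives CSV plus clipped WAV files."""

from __future__ import annotations

import os
from typing import Sequence

import pandas as pd

from ..audio.synth import Waveform
from .training import Detection

__all__ = ["export_positives", "DETECTIONS_COLUMNS"]

DETECTIONS_COLUMNS = ["detection_id", "site_id", "file", "start_s", "end_s", "confidence", "review_status"]


def export_positives(
    detections: Sequence[Detection], audio_dir: str, out_dir: str
) -> pd.DataFrame:
    """Write one CSV row and one clipped WAV per detection.

    Clip filenames are bijective with CSV rows (named by detection index);
    each clip's duration equals the analysis window. Missing source audio
    raises an IOError naming the file.
    """
    os.makedirs(out_dir, exist_ok=True)
    clips_dir = os.path.join(out_dir, "clips")
    os.makedirs(clips_dir, exist_ok=True)
    cache: dict[str, Waveform] = {}
    rows = []
    for i, d in enumerate(detections):
        src = os.path.join(audio_dir, d.file)
        if not os.path.exists(src):
            raise IOError(f"missing source audio: {src}")
        if d.file not in cache:
            cache[d.file] = Waveform.read(src)
        w = cache[d.file]
        s, e = int(round(d.start * w.rate)), int(round(d.end * w.rate))
        seg = w.samples[s:e]
        clip_name = f"det{i:06d}.wav"
        Waveform(samples=seg, rate=w.rate).write(os.path.join(clips_dir, clip_name))
        rows.append(
            {
                "detection_id": d.detection_id or f"det{i:06d}",
                "site_id": d.site_id,
                "file": d.file,
                "start_s": d.start,
                "end_s": d.end,
                "confidence": d.confidence,
                "review_status": d.review_status,
                "clip": clip_name,
            }
        )
    df = pd.DataFrame(rows, columns=DETECTIONS_COLUMNS + ["clip"])
    df.to_csv(os.path.join(out_dir, "positives.csv"), index=False)
    return df
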