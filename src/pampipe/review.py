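"""Semi-automated review bookkeeping and detection-history coding.

Every emitted detection gets exactly one human (or simulated) verdict; the
verified true positives are tallied per site per day, coded into 7-day binary
detection histories, and collapsed into per-site occurrence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .detector.training import Detection

__all__ = [
    "ReviewDecision",
    "DetectionHistory",
    "SiteOccurrence",
    "apply_reviews",
    "simulate_reviews",
    "code_history",
    "site_occurrence",
    "naive_occupancy",
    "N_DAYS",
]

N_DAYS = 7


class WorkflowError(RuntimeError):
    """A detection reached history coding without a review verdict."""


@dataclass(frozen=True)
class ReviewDecision:
    detection_id: str
    verdict: str  # {"true_positive", "false_positive"}
    reviewer: str = "reviewer"
    timestamp: str = ""

    def __post_init__(self):
        if self.verdict not in ("true_positive", "false_positive"):
            raise ValueError(f"invalid verdict {self.verdict!r}")


@dataclass(frozen=True)
class DetectionHistory:
    site_id: str
    days: tuple

    def __post_init__(self):
        if len(self.days) != N_DAYS:
            raise ValueError(f"detection history must have exactly {N_DAYS} days")
        if any(d not in (0, 1) for d in self.days):
            raise ValueError("history entries must be binary")


@dataclass(frozen=True)
class SiteOccurrence:
    site_id: str
    occurrence: int


def apply_reviews(
    detections: Sequence[Detection],
    decisions: Iterable[ReviewDecision],
    day_of: Mapping[str, int] | None = None,
) -> tuple[list[Detection], dict[str, dict[int, int]]]:
    """Apply verdicts and tally true positives per (site, day).

    ``day_of`` maps a detection's file name to its recording day index; by
    default the day is parsed from the ``_day<k>_`` token in the file name.
    Raises :class:`WorkflowError` if any detection lacks a verdict.
    """
    by_id = {d.detection_id: d for d in decisions}
    verified: list[Detection] = []
    counts: dict[str, dict[int, int]] = {}
    for det in detections:
        dec = by_id.get(det.detection_id)
        if dec is None:
            raise WorkflowError(f"detection {det.detection_id} is unreviewed")
        det.review_status = dec.verdict
        verified.append(det)
        if dec.verdict != "true_positive":
            continue
        if day_of is not None:
            day = day_of[det.file]
        else:
            day = _parse_day(det.file)
        site = counts.setdefault(det.site_id, {})
        site[day] = site.get(day, 0) + 1
    return verified, counts


def _parse_day(filename: str) -> int:
    for token in filename.replace(".wav", "").split("_"):
        if token.startswith("day") and token[3:].isdigit():
            return int(token[3:])
    raise ValueError(f"cannot parse recording day from file name {filename!r}")


def simulate_reviews(
    detections: Sequence[Detection],
    manifest: pd.DataFrame,
    reviewer: str = "simulated",
) -> list[ReviewDecision]:
    """Verdict from the synthetic event manifest: a detection is a true
    positive iff its window overlaps a whinny event in the same file."""
    events = manifest[manifest["kind"] == "whinny"]
    decisions = []
    for det in detections:
        evs = events[events["file"] == det.file]
        hit = np.any(
            (evs["onset_s"].to_numpy() < det.end)
            & (evs["onset_s"].to_numpy() + evs["duration_s"].to_numpy() > det.start)
        )
        decisions.append(
            ReviewDecision(
                detection_id=det.detection_id,
                verdict="true_positive" if hit else "false_positive",
                reviewer=reviewer,
            )
        )
    return decisions


def code_history(daily_counts: Mapping[int, int] | Sequence[int], site_id: str) -> DetectionHistory:
    """Code per-day true-positive counts into a 7-day binary history.

    ``daily_counts`` is either a full 7-vector or a mapping day->count over
    exactly the days 0..6; sites with data for fewer than 7 days are excluded
    (ValueError), mirroring the malfunctioning-recorder rule.
    """
    if isinstance(daily_counts, Mapping):
        days_present = set(daily_counts)
        if not days_present.issubset(set(range(N_DAYS))):
            raise ValueError("day indices must be within 0..6")
        counts = [daily_counts.get(d, 0) for d in range(N_DAYS)]
    else:
        counts = list(daily_counts)
        if len(counts) < N_DAYS:
            raise ValueError(
                f"site {site_id} excluded: only {len(counts)} recording days (< {N_DAYS})"
            )
        if len(counts) > N_DAYS:
            raise ValueError(f"site {site_id}: more than {N_DAYS} recording days")
    return DetectionHistory(site_id=site_id, days=tuple(1 if c > 0 else 0 for c in counts))


def site_occurrence(h: DetectionHistory) -> SiteOccurrence:
    """Logical OR over the 7 days."""
    return SiteOccurrence(site_id=h.site_id, occurrence=int(max(h.days)))


def naive_occupancy(occurrences: Sequence[int] | Sequence[SiteOccurrence]) -> float:
    """Proportion of sites with >= 1 detection (uncorrected for detectability)."""
    vals = [o.occurrence if isinstance(o, SiteOccurrence) else int(o) for o in occurrences]
    if len(vals) == 0:
        raise ValueError("no sites")
    return float(np.mean(vals))


def histories_to_frame(histories: Sequence[DetectionHistory]) -> pd.DataFrame:
    rows = []
    for h in histories:
        row = {"site_id": h.site_id}
        row.update({f"d{i + 1}": v for i, v in enumerate(h.days)})
        row["occurrence"] = site_occurrence(h).occurrence
        rows.append(row)
    return pd.DataFrame(rows)
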