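"""Daily contact timelines, three-period segmentation and kernel activity curves.

The laboratory trials were inspected daily for about a month and each arm
scored on a two-level contact scale: ``none`` (no termites visible on the
wooden block) or ``full`` (termites visible on at least one side).  Foraging
unfolds in three periods — joint exploration of both arms, feeding on the
unloaded wood, then feeding on the loaded wood accompanied by construction
of load-bearing clay walls.  :func:`segment_periods` reduces the verbal
period definitions to deterministic per-replicate first-passage events:

* period 1 (exploration) starts on the first day with any full contact;
* period 2 (unloaded feeding) starts on the first day where the unloaded
  arm is in full contact while the loaded arm is not;
* period 3 (loaded feeding) starts on the first day at or after the period-2
  onset where the loaded arm is in full contact or building is observed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CONTACT_NONE",
    "CONTACT_FULL",
    "DayRecord",
    "ActivityTimeline",
    "PeriodSegmentation",
    "segment_periods",
    "summarize_onsets",
    "contact_histogram",
    "kernel_activity_estimate",
    "read_timelines",
    "write_timelines",
]

CONTACT_NONE = "none"
CONTACT_FULL = "full"
_CONTACT_LEVELS = (CONTACT_NONE, CONTACT_FULL)


@dataclass(frozen=True)
class DayRecord:
    """Contact state of both arms on one observation day."""

    day: int
    contact_unloaded: str
    contact_loaded: str
    building: bool = False

    def __post_init__(self) -> None:
        if self.contact_unloaded not in _CONTACT_LEVELS:
            raise ValueError(f"unknown contact level {self.contact_unloaded!r}")
        if self.contact_loaded not in _CONTACT_LEVELS:
            raise ValueError(f"unknown contact level {self.contact_loaded!r}")


@dataclass(frozen=True)
class ActivityTimeline:
    """Daily contact record for one replicate; days strictly increasing from 1."""

    replicate_id: str
    days: tuple[DayRecord, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "days", tuple(self.days))
        idx = [d.day for d in self.days]
        if not idx or idx[0] != 1 or any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError(
                f"timeline {self.replicate_id}: day indices must be strictly "
                f"increasing and start at 1"
            )

    def __len__(self) -> int:
        return len(self.days)


@dataclass(frozen=True)
class PeriodSegmentation:
    """Per-replicate onset days of the three activity periods.

    Any onset may be ``None`` when the corresponding behavioural transition
    never occurred (``complete`` is then False and the replicate should be
    flagged rather than averaged).
    """

    onset_exploration: int | None
    onset_noload_feeding: int | None
    onset_load_feeding: int | None

    def __post_init__(self) -> None:
        t1, t2, t3 = (
            self.onset_exploration,
            self.onset_noload_feeding,
            self.onset_load_feeding,
        )
        if t1 is not None and t2 is not None and t1 > t2:
            raise ValueError(f"exploration onset {t1} after unloaded-feeding onset {t2}")
        if t2 is not None and t3 is not None and t2 >= t3:
            raise ValueError(f"unloaded-feeding onset {t2} not before loaded-feeding onset {t3}")

    @property
    def complete(self) -> bool:
        return None not in (
            self.onset_exploration,
            self.onset_noload_feeding,
            self.onset_load_feeding,
        )


def segment_periods(timeline: ActivityTimeline) -> PeriodSegmentation:
    """Detect the three period onsets in one replicate's timeline.

    Requires at least three observation days.  A replicate in which the
    loaded arm is never contacted gets ``onset_load_feeding=None``.
    """
    if len(timeline) < 3:
        raise ValueError("timeline must cover at least 3 days")

    t1 = t2 = t3 = None
    for rec in timeline.days:
        if t1 is None and (
            rec.contact_unloaded == CONTACT_FULL or rec.contact_loaded == CONTACT_FULL
        ):
            t1 = rec.day
        if t2 is None and rec.contact_unloaded == CONTACT_FULL and rec.contact_loaded == CONTACT_NONE:
            t2 = rec.day
        if (
            t3 is None
            and t2 is not None
            and rec.day >= t2
            and (rec.contact_loaded == CONTACT_FULL or rec.building)
        ):
            t3 = rec.day
    return PeriodSegmentation(t1, t2, t3)


def summarize_onsets(segmentations: Sequence[PeriodSegmentation]) -> dict:
    """Aggregate onset means and ranges over replicates, skipping flagged ones."""
    out: dict = {"n": len(segmentations), "n_incomplete": 0}
    names = ("exploration", "noload_feeding", "load_feeding")
    cols = {name: [] for name in names}
    for seg in segmentations:
        if not seg.complete:
            out["n_incomplete"] += 1
            continue
        cols["exploration"].append(seg.onset_exploration)
        cols["noload_feeding"].append(seg.onset_noload_feeding)
        cols["load_feeding"].append(seg.onset_load_feeding)
    for name in names:
        vals = np.asarray(cols[name], dtype=float)
        out[name] = {
            "mean": float(vals.mean()) if vals.size else None,
            "min": float(vals.min()) if vals.size else None,
            "max": float(vals.max()) if vals.size else None,
        }
    return out


def contact_histogram(
    timelines: Sequence[ActivityTimeline], arm: str
) -> tuple[np.ndarray, np.ndarray]:
    """Per-day fraction of replicates in full contact on the given arm.

    All timelines must share the same day range.  Returns ``(days, freq)``
    with ``freq`` in [0, 1]; day indices double as linearly interpolated
    bin centres for plotting.
    """
    if arm not in ("unloaded", "loaded"):
        raise ValueError(f"arm must be 'unloaded' or 'loaded', got {arm!r}")
    if not timelines:
        raise ValueError("need at least one timeline")
    days = [d.day for d in timelines[0].days]
    for t in timelines[1:]:
        if [d.day for d in t.days] != days:
            raise ValueError("timelines must share the same day range")
    attr = "contact_unloaded" if arm == "unloaded" else "contact_loaded"
    counts = np.zeros(len(days))
    for t in timelines:
        counts += [getattr(d, attr) == CONTACT_FULL for d in t.days]
    return np.asarray(days, dtype=float), counts / len(timelines)


def kernel_activity_estimate(
    days: np.ndarray,
    freqs: np.ndarray,
    *,
    bandwidth: float | None = None,
    grid_size: int = 512,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-kernel density of contact activity over days.

    ``freqs`` are per-day contact frequencies used as kernel weights;
    bandwidth defaults to Silverman's rule on the weighted sample.  The
    returned grid extends four bandwidths past the observed days so the
    density integrates to 1 within 1e-3 (trapezoidal rule).

    Raises ``ValueError`` on an all-zero histogram.
    """
    days = np.asarray(days, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    if days.shape != freqs.shape or days.ndim != 1:
        raise ValueError("days and freqs must be 1-d arrays of equal length")
    if np.any(freqs < 0):
        raise ValueError("frequencies must be nonnegative")
    total = freqs.sum()
    if total <= 0:
        raise ValueError("all-zero histogram: no contact mass to smooth")
    w = freqs / total

    mean = float(np.sum(w * days))
    var = float(np.sum(w * (days - mean) ** 2))
    if var <= 1e-12:
        # Single-day mass: an explicit Gaussian kernel around that day.
        h = bandwidth if bandwidth is not None else 1.0
        grid = np.linspace(mean - 5 * h, mean + 5 * h, grid_size)
        return grid, stats.norm.pdf(grid, loc=mean, scale=h)

    if bandwidth is None:
        neff = 1.0 / float(np.sum(w**2))
        h = np.sqrt(var) * (4.0 / (3.0 * neff)) ** 0.2  # Silverman, d=1
    else:
        h = float(bandwidth)
    kde = stats.gaussian_kde(days, weights=w, bw_method=h / np.sqrt(var))
    grid = np.linspace(days.min() - 4 * h, days.max() + 4 * h, grid_size)
    return grid, kde(grid)


# ---------------------------------------------------------------------------
# Timeline CSV I/O: replicate_id, day, arm, contact in {none, full}, building 0/1
# ---------------------------------------------------------------------------

TIMELINE_COLUMNS = ["replicate_id", "day", "arm", "contact", "building"]


def write_timelines(timelines: Sequence[ActivityTimeline], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(TIMELINE_COLUMNS)
        for t in timelines:
            for rec in t.days:
                writer.writerow([t.replicate_id, rec.day, "unloaded", rec.contact_unloaded, 0])
                writer.writerow(
                    [t.replicate_id, rec.day, "loaded", rec.contact_loaded, int(rec.building)]
                )


def read_timelines(path: str | Path) -> list[ActivityTimeline]:
    per_rep: dict[str, dict[int, dict]] = {}
    order: list[str] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = [c for c in TIMELINE_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise ValueError(f"{path}: missing timeline column(s) {missing}")
        for row in reader:
            rid = row["replicate_id"]
            if rid not in per_rep:
                per_rep[rid] = {}
                order.append(rid)
            day = int(row["day"])
            slot = per_rep[rid].setdefault(day, {"building": False})
            slot[row["arm"]] = row["contact"]
            if int(row["building"]):
                slot["building"] = True
    timelines = []
    for rid in order:
        days = tuple(
            DayRecord(
                day=day,
                contact_unloaded=slot["unloaded"],
                contact_loaded=slot["loaded"],
                building=slot["building"],
            )
            for day, slot in sorted(per_rep[rid].items())
        )
        timelines.append(ActivityTimeline(replicate_id=rid, days=days))
    return timelines
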