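"""State labeling and sliding-window extraction around annotated seizures.

Timeline convention: seconds from the start of the recording, 0-based,
half-open intervals ``[start, end)``.  For a retained seizure with onset
``t0`` the prediction horizon occupies ``[t0 - SPH, t0)`` and the preictal
state occupies the ``preictal_min`` minutes before that; everything not
claimed by a seizure's zones, its postictal guard, or a dropped seizure's
contaminated lead-in is interictal.
"""
from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "SegmentationConfig",
    "StateIntervals",
    "Window",
    "WindowSet",
    "merge_lead_seizures",
    "label_states",
    "extract_windows",
    "balance_interictal",
]

LABELS = ("interictal", "preictal", "sph", "ictal", "unusable")


@dataclass(frozen=True)
class SegmentationConfig:
    """Windowing and state-scheme parameters (times in minutes / seconds)."""

    sph_min: float = 5.0
    preictal_min: float = 30.0
    window_s: float = 30.0
    step_s: float = 15.0
    cluster_gap_min: Optional[float] = None  # default: preictal_min + sph_min
    postictal_guard_min: float = 30.0

    def __post_init__(self) -> None:
        if self.window_s <= 0:
            raise ValueError("window_s must be positive")
        if not 0 < self.step_s <= self.window_s:
            raise ValueError("need 0 < step_s <= window_s")
        if self.sph_min <= 0 or self.preictal_min <= 0:
            raise ValueError("sph_min and preictal_min must be positive")
        if self.postictal_guard_min < 0:
            raise ValueError("postictal_guard_min must be non-negative")

    @property
    def sph_s(self) -> float:
        return 60.0 * self.sph_min

    @property
    def preictal_s(self) -> float:
        return 60.0 * self.preictal_min

    @property
    def cluster_gap_s(self) -> float:
        gap = self.cluster_gap_min
        if gap is None:
            gap = self.preictal_min + self.sph_min
        return 60.0 * gap


@dataclass
class StateIntervals:
    """Disjoint, sorted labeled intervals partitioning ``[0, duration)``.

    ``intervals`` entries are ``(start_s, end_s, label, seizure_id)`` where
    ``seizure_id`` is the index of the owning seizure for
    preictal/sph/ictal intervals and ``None`` otherwise.  ``dropped`` logs
    seizures excluded from classification as ``(seizure_id, onset, reason)``.
    """

    intervals: list[tuple[float, float, str, Optional[int]]]
    duration: float
    dropped: list[tuple[int, float, str]] = field(default_factory=list)
    retained: list[int] = field(default_factory=list)


@dataclass(frozen=True)
class Window:
    start_s: float
    label: str
    seizure_id: Optional[int]


@dataclass
class WindowSet:
    windows: list[Window]
    window_s: float

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self):
        return iter(self.windows)


def merge_lead_seizures(
    events: Sequence[tuple[float, float]], cluster_gap_min: float
) -> list[tuple[float, float]]:
    """Merge seizures that start soon after the previous one into its lead event.

    A seizure whose onset falls less than ``cluster_gap_min`` minutes after
    the previous (merged) event's offset is absorbed: the lead seizure is
    retained and its offset extended.  Idempotent; empty input yields [].
    """
    gap_s = 60.0 * cluster_gap_min
    merged: list[list[float]] = []
    for onset, offset in sorted((float(a), float(b)) for a, b in events):
        if merged and onset - merged[-1][1] < gap_s:
            merged[-1][1] = max(merged[-1][1], offset)
        else:
            merged.append([onset, offset])
    return [(a, b) for a, b in merged]


def label_states(
    duration_s: float,
    events: Sequence[tuple[float, float]],
    config: SegmentationConfig,
) -> StateIntervals:
    """Label the timeline of one recording from its merged seizure events.

    Per retained seizure with onset ``t0``: ``sph = [t0 - SPH, t0)`` and
    ``preictal = [t0 - SPH - preictal, t0 - SPH)``.  A seizure whose full
    lead-in would start before the record or overlap the previous event is
    dropped (logged); its lead-in is marked unusable rather than interictal.
    Postictal guards of ``postictal_guard_min`` minutes are unusable unless
    claimed by a later seizure's zones.  Intervals are clipped to
    ``[0, duration_s)``.
    """
    events = sorted((float(a), float(b)) for a, b in events)
    dropped: list[tuple[int, float, str]] = []
    retained: list[int] = []
    for i, (t0, t1) in enumerate(events):
        lead_start = t0 - config.sph_s - config.preictal_s
        prev_offset = events[i - 1][1] if i > 0 else None
        if lead_start < 0:
            reason = "insufficient lead-in before start of record"
        elif prev_offset is not None and lead_start < prev_offset:
            reason = "lead-in overlaps previous seizure"
        else:
            retained.append(i)
            continue
        dropped.append((i, t0, reason))
        logger.info("seizure %d at %.1f s dropped: %s", i, t0, reason)

    # paint operations, later entries override earlier ones
    paints: list[tuple[float, float, str, Optional[int]]] = [
        (0.0, duration_s, "interictal", None)
    ]
    guard = 60.0 * config.postictal_guard_min
    for t0, t1 in events:
        paints.append((t1, t1 + guard, "unusable", None))
    for i, (t0, t1) in enumerate(events):
        lead_start = t0 - config.sph_s - config.preictal_s
        if i in retained:
            paints.append((lead_start, t0 - config.sph_s, "preictal", i))
            paints.append((t0 - config.sph_s, t0, "sph", i))
        else:
            paints.append((max(lead_start, 0.0), t0, "unusable", None))
    for i, (t0, t1) in enumerate(events):
        paints.append((t0, t1, "ictal", i))

    edges = sorted(
        {0.0, duration_s}
        | {min(max(v, 0.0), duration_s) for a, b, _, _ in paints for v in (a, b)}
    )
    intervals: list[tuple[float, float, str, Optional[int]]] = []
    for a, b in zip(edges, edges[1:]):
        label, sid = "interictal", None
        for pa, pb, plabel, psid in paints:
            if pa <= a and b <= pb:
                label, sid = plabel, psid
        if intervals and intervals[-1][2] == label and intervals[-1][3] == sid:
            prev = intervals.pop()
            intervals.append((prev[0], b, label, sid))
        else:
            intervals.append((a, b, label, sid))
    return StateIntervals(
        intervals=intervals, duration=duration_s, dropped=dropped, retained=retained
    )


def extract_windows(
    states: StateIntervals,
    config: SegmentationConfig,
    labels: Iterable[str] = ("interictal", "preictal"),
) -> WindowSet:
    """Slide fixed-length windows inside each labeled interval.

    An interval of length ``L >= window_s`` yields
    ``floor((L - window_s) / step_s) + 1`` windows; windows never cross
    interval boundaries.  Only intervals whose label is in *labels* are
    windowed (SPH, ictal and unusable stretches are excluded from
    classification by default).
    """
    wanted = set(labels)
    out: list[Window] = []
    for start, end, label, sid in states.intervals:
        if label not in wanted:
            continue
        length = end - start
        if length < config.window_s - 1e-9:
            continue
        count = int(math.floor((length - config.window_s) / config.step_s + 1e-9)) + 1
        for k in range(count):
            out.append(Window(start + k * config.step_s, label, sid))
    return WindowSet(windows=out, window_s=config.window_s)


def balance_interictal(windows: WindowSet, seed: int = 0) -> WindowSet:
    """Subsample interictal windows to match each seizure's preictal count.

    For each seizure with ``n`` preictal windows, ``n`` interictal windows
    are drawn (seeded, without replacement) from the unassigned interictal
    pool and tagged with that seizure's id, so grouped cross-validation
    keeps a seizure's preictal windows and its paired interictal sample in
    one fold.  Warns and uses the whole pool if it is too small.
    """
    preictal = [w for w in windows if w.label == "preictal"]
    pool = [w for w in windows if w.label == "interictal"]
    other = [w for w in windows if w.label not in ("interictal", "preictal")]
    per_seizure: dict[int, int] = {}
    for w in preictal:
        per_seizure[w.seizure_id] = per_seizure.get(w.seizure_id, 0) + 1
    needed = sum(per_seizure.values())
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pool))
    if needed > len(pool):
        warnings.warn(
            f"interictal pool ({len(pool)}) smaller than preictal count ({needed}); "
            "using every interictal window"
        )
    picked: list[Window] = []
    cursor = 0
    for sid in sorted(per_seizure):
        take = per_seizure[sid]
        chosen = order[cursor : cursor + take]
        cursor += take
        for idx in chosen:
            w = pool[idx]
            picked.append(Window(w.start_s, w.label, sid))
    out = sorted(preictal + picked + other, key=lambda w: w.start_s)
    return WindowSet(windows=out, window_s=windows.window_s)
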