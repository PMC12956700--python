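"""Critical-event segmentation from triaxial acceleration and 3-min slicing.

A critical event segment is a flight phase containing a run of five or more
suprathreshold acceleration peaks (multi-roll manoeuvring, labelled high
stress); peak-free stretches of level flight become non-critical segments
(low stress).  Segments are cut into exactly-180-s physiological slices,
completing a sub-length remainder by right-aligning one final window on the
segment end (backward sampling).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional

import numpy as np
import pandas as pd
from scipy import signal as sps

if TYPE_CHECKING:  # pragma: no cover
    from .synth import PhysioRecord

logger = logging.getLogger("aerostress")

CRITICAL = "critical"
NON_CRITICAL = "non_critical"

#: Minimum run length of suprathreshold peaks that defines a critical event.
MIN_CRITICAL_PEAKS = 5

#: Slice duration (s); ≥2 min of beats is needed for reliable HRV analysis.
SLICE_S = 180.0


@dataclass
class EventSegment:
    """A half-open interval [start_s, end_s) labelled by stress condition."""

    start_s: float
    end_s: float
    label: str
    n_peaks: Optional[int] = None
    source: str = "detected"

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError("segment must have positive duration")
        if self.label not in (CRITICAL, NON_CRITICAL):
            raise ValueError(f"unknown label {self.label!r}")
        if self.label == CRITICAL and self.source == "detected":
            if self.n_peaks is None or self.n_peaks < MIN_CRITICAL_PEAKS:
                raise ValueError(
                    f"critical segments require >= {MIN_CRITICAL_PEAKS} peaks"
                )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def to_dict(self) -> dict:
        return {
            "start_s": self.start_s,
            "end_s": self.end_s,
            "label": self.label,
            "n_peaks": self.n_peaks,
            "source": self.source,
        }


@dataclass
class Slice:
    """Exactly 180 s of ECG + respiration inheriting its segment's label."""

    sortie_id: str
    start_s: float
    end_s: float
    label: str
    ecg: np.ndarray
    ecg_rate_hz: float
    resp: np.ndarray
    resp_rate_hz: float
    segment_ref: EventSegment = field(repr=False, default=None)  # type: ignore

    def __post_init__(self) -> None:
        if abs((self.end_s - self.start_s) - SLICE_S) > 1e-6:
            raise ValueError(f"slice must span exactly {SLICE_S} s")

    @property
    def slice_id(self) -> str:
        return f"{self.sortie_id}:{self.start_s:.0f}-{self.end_s:.0f}"


def detect_accel_peaks(
    accel_xyz: np.ndarray,
    rate_hz: float,
    threshold_k: float = 6.0,
    min_separation_s: float = 1.0,
    baseline_window_s: float = 30.0,
) -> np.ndarray:
    """Find manoeuvre peaks as robust-SD excursions from a rolling baseline.

    Each axis is referenced to its 30-s rolling median; deviations are
    scaled by the axis MAD so the threshold ``threshold_k`` is unit-free.
    Peaks closer than ``min_separation_s`` keep the larger excursion.

    Returns sorted peak times in seconds.
    """
    accel = np.atleast_2d(np.asarray(accel_xyz, dtype=float))
    n = accel.shape[1]
    win = int(round(baseline_window_s * rate_hz))
    if n <= win:
        raise ValueError("acceleration trace shorter than the baseline window")
    score = np.zeros(n)
    any_spread = False
    for axis in accel:
        baseline = (
            pd.Series(axis).rolling(win, center=True, min_periods=1).median().to_numpy()
        )
        dev = axis - baseline
        mad = 1.4826 * np.median(np.abs(dev))
        if mad == 0.0:
            continue
        any_spread = True
        score = np.maximum(score, np.abs(dev) / mad)
    if not any_spread:
        logger.warning("flat acceleration signal: no peaks detectable")
        return np.empty(0)
    idx, _ = sps.find_peaks(
        score, height=threshold_k, distance=max(int(min_separation_s * rate_hz), 1)
    )
    return idx / rate_hz


def extract_critical_segments(
    peak_times_s: np.ndarray,
    min_peaks: int = MIN_CRITICAL_PEAKS,
    max_gap_s: float = 30.0,
    pad_s: float = 10.0,
    duration_s: Optional[float] = None,
) -> list[EventSegment]:
    """Group peaks into runs and keep runs of ``min_peaks`` or more.

    Consecutive peaks belong to one run while their gap is at most
    ``max_gap_s``.  A qualifying run spans [first - pad, last + pad),
    clipped to the sortie.
    """
    peaks = np.asarray(peak_times_s, dtype=float)
    if peaks.size == 0:
        return []
    if np.any(np.diff(peaks) < 0):
        raise ValueError("peak times must be sorted")
    breaks = np.flatnonzero(np.diff(peaks) > max_gap_s)
    runs = np.split(peaks, breaks + 1)
    segments = []
    for run in runs:
        if run.size < min_peaks:
            continue
        start = max(run[0] - pad_s, 0.0)
        end = run[-1] + pad_s
        if duration_s is not None:
            end = min(end, duration_s)
        segments.append(
            EventSegment(start, end, CRITICAL, n_peaks=int(run.size))
        )
    return segments


def extract_noncritical_segments(
    peak_times_s: np.ndarray,
    duration_s: float,
    min_len_s: float = SLICE_S,
    guard_s: float = 10.0,
    match_count: Optional[int] = None,
) -> list[EventSegment]:
    """Peak-free intervals, shrunk by a guard band, as low-stress segments.

    ``match_count`` subsamples longest-first to balance the critical count.
    """
    peaks = np.sort(np.asarray(peak_times_s, dtype=float))
    bounds = np.concatenate(([0.0], peaks, [duration_s]))
    segments = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        start, end = lo + guard_s if lo > 0 else lo, hi - guard_s if hi < duration_s else hi
        if end - start >= min_len_s:
            segments.append(EventSegment(start, end, NON_CRITICAL))
    if match_count is not None and len(segments) > match_count:
        segments = sorted(segments, key=lambda s: -s.duration_s)[:match_count]
        segments = sorted(segments, key=lambda s: s.start_s)
    return segments


def _window(series: np.ndarray, rate_hz: float, start_s: float, name: str) -> np.ndarray:
    i0 = int(round(start_s * rate_hz))
    i1 = i0 + int(round(SLICE_S * rate_hz))
    if i0 < 0 or i1 > series.size:
        raise ValueError(
            f"signal coverage missing for channel {name!r} in "
            f"[{start_s:.1f}, {start_s + SLICE_S:.1f}) s"
        )
    return series[i0:i1]


def slice_segment(
    segment: EventSegment,
    record: "PhysioRecord",
    slice_s: float = SLICE_S,
) -> list[Slice]:
    """Cut a segment into non-overlapping 3-min slices plus one
    right-aligned remainder slice (backward sampling).

    A 450-s segment yields [0,180), [180,360) and [270,450) relative
    windows.  Segments shorter than one slice yield no slices.
    """
    dur = segment.duration_s
    if dur < slice_s - 1e-9:
        logger.warning(
            "segment [%.1f, %.1f) shorter than %.0f s: no slices",
            segment.start_s, segment.end_s, slice_s,
        )
        return []
    starts = []
    k = int(np.floor(dur / slice_s + 1e-9))
    for i in range(k):
        starts.append(segment.start_s + i * slice_s)
    remainder = dur - k * slice_s
    if remainder > 1e-9:
        starts.append(segment.end_s - slice_s)
    slices = []
    for s0 in starts:
        slices.append(
            Slice(
                sortie_id=record.sortie_id,
                start_s=s0,
                end_s=s0 + slice_s,
                label=segment.label,
                ecg=_window(record.ecg, record.ecg_rate_hz, s0, "ecg"),
                ecg_rate_hz=record.ecg_rate_hz,
                resp=_window(record.resp, record.resp_rate_hz, s0, "resp"),
                resp_rate_hz=record.resp_rate_hz,
                segment_ref=segment,
            )
        )
    return slices


def segment_record(
    record: "PhysioRecord",
    threshold_k: float = 6.0,
    min_separation_s: float = 1.0,
    baseline_window_s: float = 30.0,
    min_peaks: int = MIN_CRITICAL_PEAKS,
    max_gap_s: float = 30.0,
    pad_s: float = 10.0,
    guard_s: float = 10.0,
    match_count: bool = True,
) -> list[EventSegment]:
    """Detect critical and non-critical segments for one sortie.

    With ``match_count`` the non-critical list is subsampled longest-first
    to the number of critical segments, emulating a balanced design.
    """
    duration = record.ecg.size / record.ecg_rate_hz
    peaks = detect_accel_peaks(
        record.accel_xyz,
        record.accel_rate_hz,
        threshold_k=threshold_k,
        min_separation_s=min_separation_s,
        baseline_window_s=baseline_window_s,
    )
    critical = extract_critical_segments(
        peaks, min_peaks=min_peaks, max_gap_s=max_gap_s, pad_s=pad_s,
        duration_s=duration,
    )
    noncritical = extract_noncritical_segments(
        peaks, duration, guard_s=guard_s,
        match_count=len(critical) if (match_count and critical) else None,
    )
    return critical + noncritical
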