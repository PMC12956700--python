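"""ECG and respiration cleaning and beat-series extraction.

Cleaning targets the artefacts that matter for short-slice HRV analysis:
baseline wander (high-pass), 50 Hz mains pickup (notch) and high-frequency
interference (low-pass) for ECG; slow drift and out-of-band noise for the
chest-belt respiration channel. R-peaks are detected with a derivative/energy
detector and converted to an RR-interval series in milliseconds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

logger = logging.getLogger("aerostress")

#: Plausible human RR-interval range (ms); intervals outside are artefacts.
RR_PLAUSIBLE_MS = (300.0, 2000.0)


@dataclass
class RRSeries:
    """Ordered R-peak times and derived RR intervals for one slice.

    ``rr_ms`` is the series of successive peak-time differences in
    milliseconds.  After artefact filtering it may be shorter than
    ``n_beats - 1``; for clean series the two agree exactly.
    """

    peak_times_s: np.ndarray
    rr_ms: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.peak_times_s = np.asarray(self.peak_times_s, dtype=float)
        if self.rr_ms is None:
            self.rr_ms = np.diff(self.peak_times_s) * 1000.0
        self.rr_ms = np.asarray(self.rr_ms, dtype=float)
        if self.peak_times_s.size and np.any(np.diff(self.peak_times_s) <= 0):
            raise ValueError("peak times must be strictly increasing")
        if np.any(self.rr_ms <= 0):
            raise ValueError("RR intervals must be positive")
        if self.rr_ms.size > max(self.n_beats - 1, 0):
            raise ValueError("more RR intervals than beat pairs")

    @property
    def n_beats(self) -> int:
        return int(self.peak_times_s.size)

    @property
    def duration_s(self) -> float:
        if self.n_beats < 2:
            return 0.0
        return float(self.peak_times_s[-1] - self.peak_times_s[0])

    @classmethod
    def from_peak_times(cls, times_s: np.ndarray) -> "RRSeries":
        return cls(peak_times_s=np.asarray(times_s, dtype=float))


def clean_ecg(
    ecg: np.ndarray,
    rate_hz: float,
    highpass_hz: float = 0.5,
    lowpass_hz: float = 40.0,
    notch_hz: float = 50.0,
    notch_q: float = 30.0,
) -> np.ndarray:
    """Remove baseline drift, mains interference and HF noise from an ECG.

    Band-pass 0.5-40 Hz (zero-phase Butterworth, steep corners so the
    passband is flat and cleaning is near-idempotent) plus a 50 Hz notch.
    Output has the same length and sampling rate as the input.
    """
    ecg = np.asarray(ecg, dtype=float)
    if rate_hz <= 2.0 * lowpass_hz:
        raise ValueError(
            f"sampling rate {rate_hz} Hz must exceed twice the "
            f"low-pass corner ({lowpass_hz} Hz)"
        )
    if ecg.size < 10 * rate_hz:
        raise ValueError("need at least 10 s of ECG signal")
    sos_hp = sps.butter(4, highpass_hz, btype="highpass", fs=rate_hz, output="sos")
    out = sps.sosfiltfilt(sos_hp, ecg)
    if notch_hz < rate_hz / 2.0:
        b, a = sps.iirnotch(notch_hz, notch_q, fs=rate_hz)
        out = sps.filtfilt(b, a, out)
    sos_lp = sps.butter(10, lowpass_hz, btype="lowpass", fs=rate_hz, output="sos")
    return sps.sosfiltfilt(sos_lp, out)


def detect_r_peaks(
    ecg: np.ndarray,
    rate_hz: float,
    min_rr_s: float = RR_PLAUSIBLE_MS[0] / 1000.0,
    max_rr_s: float = RR_PLAUSIBLE_MS[1] / 1000.0,
) -> RRSeries:
    """Locate R-peaks in a cleaned ECG and return the RR series.

    Derivative-energy detection: the squared derivative is smoothed with a
    moving window, candidate beats are maxima of that envelope above an
    adaptive threshold, and each candidate is refined to the local maximum
    of the ECG itself.  Intervals outside the plausible range are removed
    and counted.
    """
    ecg = np.asarray(ecg, dtype=float)
    if ecg.size < 2 or float(np.ptp(ecg)) == 0.0:
        raise ValueError("insufficient beats: flat or empty ECG")
    deriv = np.gradient(ecg) * rate_hz
    energy = deriv**2
    win = max(int(round(0.10 * rate_hz)), 1)
    envelope = sps.convolve(energy, np.ones(win) / win, mode="same")
    threshold = 0.25 * np.percentile(envelope, 99)
    if threshold <= 0:
        raise ValueError("insufficient beats: no QRS energy above threshold")
    cand, _ = sps.find_peaks(
        envelope, height=threshold, distance=max(int(min_rr_s * rate_hz), 1)
    )
    # refine each candidate to the true R-wave apex
    half = max(int(round(0.05 * rate_hz)), 1)
    refined = []
    for c in cand:
        lo, hi = max(c - half, 0), min(c + half + 1, ecg.size)
        refined.append(lo + int(np.argmax(ecg[lo:hi])))
    peaks = np.unique(np.asarray(refined, dtype=int))
    # merge residual double detections closer than the plausible minimum
    if peaks.size > 1:
        keep = [peaks[0]]
        for p in peaks[1:]:
            if (p - keep[-1]) / rate_hz < min_rr_s:
                if ecg[p] > ecg[keep[-1]]:
                    keep[-1] = p
            else:
                keep.append(p)
        peaks = np.asarray(keep)
    if peaks.size < 2:
        raise ValueError("insufficient beats: fewer than 2 R-peaks detected")
    times = peaks / rate_hz
    rr = np.diff(times) * 1000.0
    plausible = (rr >= min_rr_s * 1000.0) & (rr <= max_rr_s * 1000.0)
    n_removed = int(np.sum(~plausible))
    if n_removed:
        logger.warning("removed %d implausible RR interval(s)", n_removed)
    return RRSeries(peak_times_s=times, rr_ms=rr[plausible])


def clean_resp(
    resp: np.ndarray,
    rate_hz: float,
    lowpass_hz: float = 1.0,
) -> np.ndarray:
    """Detrend and band-limit a respiration trace to [0, 1] Hz."""
    resp = np.asarray(resp, dtype=float)
    if resp.size < 30 * rate_hz:
        raise ValueError("need at least 30 s of respiration signal")
    if rate_hz <= 2.0 * lowpass_hz:
        raise ValueError(
            f"sampling rate {rate_hz} Hz too low for a {lowpass_hz} Hz low-pass"
        )
    out = sps.detrend(resp, type="linear")
    sos = sps.butter(4, lowpass_hz, btype="lowpass", fs=rate_hz, output="sos")
    return sps.sosfiltfilt(sos, out)
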