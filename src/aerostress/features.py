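"""The 21 ECG and respiratory stress-sensitivity indicators.

16 ECG indicators (time-domain, Welch-spectral and Poincaré) computed from
the RR-interval series of a 3-min slice, and 5 respiratory indicators
(mean breathing rate and four 0.1 Hz-wide spectral band powers) from the
cleaned chest-belt signal.  All definitions are implemented from first
principles with the population (1/n) variance convention, under which
SD1 = SDSD/√2 holds exactly.
"""

from __future__ import annotations

import math
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.interpolate import interp1d

from .preprocess import RRSeries, clean_ecg, clean_resp, detect_r_peaks
from .segmentation import Slice

#: Canonical indicator order used in every table this package writes.
ECG_INDICATORS = [
    "mean_hr", "mean_rr", "sdnn", "sdsd", "rmssd", "pnn20", "pnn50",
    "lf", "hf", "lfn", "hfn", "lf_hf", "sd1", "sd2", "sd1_sd2", "s",
]
RESP_INDICATORS = ["mean_rsp", "eb1", "eb2", "eb3", "eb4"]
INDICATORS = ECG_INDICATORS + RESP_INDICATORS

LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.4)
RESP_BANDS = [(0.0, 0.1), (0.1, 0.2), (0.2, 0.3), (0.3, 0.4)]


def time_domain(rr: RRSeries) -> dict:
    """Time-domain HRV indicators.

    mean_hr is the mean of instantaneous rates 60000/RR_i (not
    60000/mean RR; the two differ by Jensen's inequality).  pNNx counts
    successive differences strictly exceeding x ms.
    """
    x = np.asarray(rr.rr_ms, dtype=float)
    if x.size < 2:
        raise ValueError("too few beats for time-domain indicators")
    d = np.diff(x)
    return {
        "mean_rr": float(np.mean(x)),
        "mean_hr": float(np.mean(60000.0 / x)),
        "sdnn": float(np.std(x)),
        "sdsd": float(np.std(d)),
        "rmssd": float(np.sqrt(np.mean(d**2))),
        "pnn20": float(100.0 * np.mean(np.abs(d) > 20.0)),
        "pnn50": float(100.0 * np.mean(np.abs(d) > 50.0)),
    }


def frequency_domain(
    rr: RRSeries,
    grid_hz: float = 4.0,
    welch_window_s: float = 120.0,
    lf_band: tuple = LF_BAND,
    hf_band: tuple = HF_BAND,
) -> dict:
    """Spectral HRV indicators from the evenly resampled RR tachogram.

    The tachogram (RR_i at the closing beat time of each interval) is
    cubic-interpolated onto a 4 Hz grid and analysed with a Welch
    periodogram (120-s Hann window, 50% overlap, mean detrend); band
    powers are trapezoid-integrated over [0.04, 0.15) and [0.15, 0.4) Hz.
    LFn and HFn are normalized by LF+HF, so they sum to one.
    """
    if rr.duration_s < 120.0:
        raise ValueError("need at least 120 s of beats for spectral indicators")
    t = rr.peak_times_s[1:]
    x = rr.rr_ms
    if x.size != t.size:  # artefact-filtered series: fall back to valid pairs
        t = rr.peak_times_s[1 : x.size + 1]
    grid = np.arange(t[0], t[-1], 1.0 / grid_hz)
    xi = interp1d(t, x, kind="cubic", assume_sorted=True)(grid)
    nperseg = min(int(welch_window_s * grid_hz), xi.size)
    f, pxx = sps.welch(
        xi, fs=grid_hz, window="hann", nperseg=nperseg,
        noverlap=nperseg // 2, detrend="constant",
    )
    lf = _band_power(f, pxx, lf_band)
    hf = _band_power(f, pxx, hf_band)
    total = lf + hf
    return {
        "lf": lf,
        "hf": hf,
        "lfn": lf / total if total > 0 else math.nan,
        "hfn": hf / total if total > 0 else math.nan,
        "lf_hf": lf / hf if hf > 0 else math.nan,
    }


def _band_power(f: np.ndarray, pxx: np.ndarray, band: tuple) -> float:
    mask = (f >= band[0]) & (f < band[1])
    if mask.sum() < 2:
        return 0.0
    return float(np.trapezoid(pxx[mask], f[mask]))


def poincare(rr: RRSeries) -> dict:
    """Poincaré-plot descriptors of the RR scatter RR_{i+1} vs RR_i.

    SD1 (width across the identity line) indexes short-term variability;
    SD2 (spread along it) long-term variability; S = π·SD1·SD2 is the
    fitted ellipse area.
    """
    x = np.asarray(rr.rr_ms, dtype=float)
    if x.size < 2:
        raise ValueError("too few beats for Poincaré indicators")
    d = np.diff(x)
    var_d = float(np.var(d))
    var_x = float(np.var(x))
    sd1 = math.sqrt(var_d / 2.0)
    sd2 = math.sqrt(max(2.0 * var_x - var_d / 2.0, 0.0))
    return {
        "sd1": sd1,
        "sd2": sd2,
        "sd1_sd2": sd1 / sd2 if sd2 > 0 else math.nan,
        "s": math.pi * sd1 * sd2,
    }


def respiratory(
    resp_clean: np.ndarray,
    rate_hz: float,
    min_breath_sep_s: float = 1.0,
) -> dict:
    """Mean breathing rate and the four 0.1 Hz respiratory band powers.

    Breaths are counted as prominent signal peaks at least 1 s apart;
    band powers come from a Welch periodogram of the cleaned signal,
    trapezoid-integrated over [0.1(k−1), 0.1k) Hz for k = 1..4.
    """
    x = np.asarray(resp_clean, dtype=float)
    duration = x.size / rate_hz
    sd = float(np.std(x))
    if sd > 0:
        peaks, _ = sps.find_peaks(
            x, distance=max(int(min_breath_sep_s * rate_hz), 1), prominence=0.25 * sd
        )
        n_breaths = int(peaks.size)
    else:
        n_breaths = 0
    mean_rsp = 60.0 * n_breaths / duration if n_breaths >= 2 else math.nan
    nperseg = min(int(120.0 * rate_hz), x.size)
    f, pxx = sps.welch(
        x, fs=rate_hz, window="hann", nperseg=nperseg,
        noverlap=nperseg // 2, detrend="constant",
    )
    out = {"mean_rsp": mean_rsp}
    for k, band in enumerate(RESP_BANDS, start=1):
        out[f"eb{k}"] = _band_power(f, pxx, band)
    return out


def extract_features(slc: Slice) -> dict:
    """All 21 indicators plus the stress label for one slice."""
    try:
        ecg = clean_ecg(slc.ecg, slc.ecg_rate_hz)
        rr = detect_r_peaks(ecg, slc.ecg_rate_hz)
        out = {}
        out.update(time_domain(rr))
        out.update(frequency_domain(rr))
        out.update(poincare(rr))
        resp = clean_resp(slc.resp, slc.resp_rate_hz)
        out.update(respiratory(resp, slc.resp_rate_hz))
    except ValueError as exc:
        raise ValueError(f"slice {slc.slice_id}: {exc}") from exc
    # critical manoeuvre segments carry the high-stress condition
    out["label"] = "high" if slc.label == "critical" else "low"
    return out


def build_feature_table(slices: Iterable[Slice]) -> pd.DataFrame:
    """Feature table: one row per slice, canonical indicator columns."""
    rows = []
    for slc in slices:
        feats = extract_features(slc)
        rows.append(
            {"sortie_id": slc.sortie_id, "slice_id": slc.slice_id}
            | {k: feats[k] for k in INDICATORS}
            | {"label": feats["label"]}
        )
    return pd.DataFrame(rows)
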