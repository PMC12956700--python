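"""Synthetic flight-sortie generator with ground-truth stress labels.

Emulates a study of fighter-pilot sorties recorded with a chest-worn
monitor (single-lead ECG, belt respiration, triaxial body acceleration).
Manoeuvre bursts (multi-roll segments) carry a high-stress autonomic
profile — faster heart rate, reduced respiratory-coupled RR oscillation,
raised LF/HF balance, slower and shallower breathing — while level flight
carries the paired low-stress profile.

The RR model is additive sinusoids plus Gaussian jitter: a low-frequency
(Mayer-wave band, 0.04-0.15 Hz) oscillation and a respiratory-coupled
high-frequency (0.15-0.4 Hz) oscillation around the mean interval.  It is
not an integral-pulse model; its virtue is that the LF/HF spectral
structure of the tachogram is analytically controllable.

Sortie-level and slow within-sortie multiplicative modulation of the
profile parameters provides between-slice physiological variability, so
group differences have moderate, realistic effect sizes rather than being
trivially separable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .preprocess import RRSeries
from .segmentation import CRITICAL, NON_CRITICAL, EventSegment

#: Bands (Hz) that the RR oscillation frequencies must respect.
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.4)

#: Default sampling rates (Hz); device rates are unpublished, so these are
#: package choices sized for the analysis (ECG well above QRS bandwidth).
ECG_RATE_HZ = 250.0
RESP_RATE_HZ = 25.0
ACCEL_RATE_HZ = 25.0

#: Modulated breathing frequency is truncated to the interior of the
#: 0.2-0.3 Hz band so the respiratory band contrast stays amplitude-driven.
RESP_F_CLIP_HZ = (0.205, 0.295)


@dataclass(frozen=True)
class StressProfile:
    """Autonomic parameter set for one stress condition.

    mean_rr_ms     expected RR interval (ms)
    lf_amp_ms      amplitude of the LF (Mayer-wave) RR oscillation (ms)
    hf_amp_ms      amplitude of the respiratory-coupled RR oscillation (ms)
    resp_rate_bpm  breathing rate (breaths/min); /60 must lie in (0.15, 0.4) Hz
    resp_amp       respiration signal amplitude (a.u.)
    rr_noise_ms    white RR jitter SD (ms)
    """

    mean_rr_ms: float
    lf_amp_ms: float
    hf_amp_ms: float
    resp_rate_bpm: float
    resp_amp: float
    rr_noise_ms: float

    def __post_init__(self) -> None:
        if self.mean_rr_ms <= 0 or self.resp_rate_bpm <= 0 or self.resp_amp < 0:
            raise ValueError("profile rates/means must be positive")
        if min(self.lf_amp_ms, self.hf_amp_ms, self.rr_noise_ms) < 0:
            raise ValueError("amplitudes and noise SD must be non-negative")

    @property
    def f_resp_hz(self) -> float:
        return self.resp_rate_bpm / 60.0


#: Default paired condition profiles.  High stress: shorter mean RR (faster
#: heart rate), weaker respiratory-coupled oscillation, higher LF/HF ratio,
#: slower and shallower breathing — the sign pattern the screening stage is
#: expected to recover.
LOW_STRESS = StressProfile(
    mean_rr_ms=860.0, lf_amp_ms=25.0, hf_amp_ms=40.0,
    resp_rate_bpm=15.0, resp_amp=1.0, rr_noise_ms=15.0,
)
HIGH_STRESS = StressProfile(
    mean_rr_ms=750.0, lf_amp_ms=26.0, hf_amp_ms=32.0,
    resp_rate_bpm=14.2, resp_amp=0.75, rr_noise_ms=15.0,
)


def validate_profile_pair(low: StressProfile, high: StressProfile) -> None:
    """Check the directional pairing the analysis assumes."""
    ok = (
        high.mean_rr_ms < low.mean_rr_ms
        and high.hf_amp_ms < low.hf_amp_ms
        and high.lf_amp_ms / high.hf_amp_ms > low.lf_amp_ms / low.hf_amp_ms
        and high.resp_rate_bpm < low.resp_rate_bpm
        and high.resp_amp < low.resp_amp
    )
    if not ok:
        raise ValueError(
            "inconsistent profile pair: high-stress profile must have lower "
            "mean RR, HF amplitude, respiratory rate and amplitude, and a "
            "higher LF/HF amplitude ratio than the low-stress profile"
        )


@dataclass(frozen=True)
class SortiePlan:
    """Manoeuvre schedule for one sortie."""

    duration_s: float
    critical_windows: tuple  # of (start_s, end_s, n_peaks)
    seed: int

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")
        prev_end = 0.0
        for start, end, n_peaks in self.critical_windows:
            if start < prev_end or end <= start or end > self.duration_s:
                raise ValueError("windows must be disjoint, ordered, in-range")
            if n_peaks < 1:
                raise ValueError("each window needs at least one peak")
            prev_end = end


@dataclass
class PhysioRecord:
    """One sortie's synchronized ECG, respiration and acceleration."""

    sortie_id: str
    ecg: np.ndarray
    ecg_rate_hz: float
    resp: np.ndarray
    resp_rate_hz: float
    accel_xyz: np.ndarray  # shape (3, n)
    accel_rate_hz: float

    def __post_init__(self) -> None:
        if min(self.ecg_rate_hz, self.resp_rate_hz, self.accel_rate_hz) <= 0:
            raise ValueError("sampling rates must be positive")
        if self.ecg.size == 0 or self.resp.size == 0 or self.accel_xyz.size == 0:
            raise ValueError("all channels must be non-empty")
        durations = [
            self.ecg.size / self.ecg_rate_hz,
            self.resp.size / self.resp_rate_hz,
            self.accel_xyz.shape[-1] / self.accel_rate_hz,
        ]
        tol = 1.0 / min(self.ecg_rate_hz, self.resp_rate_hz, self.accel_rate_hz)
        if max(durations) - min(durations) > tol + 1e-9:
            raise ValueError("channel durations disagree by more than one sample")

    @property
    def duration_s(self) -> float:
        return self.ecg.size / self.ecg_rate_hz


# ---------------------------------------------------------------------------
# RR-interval generation
# ---------------------------------------------------------------------------

def _check_profile(profile: StressProfile, f_lf_hz: float) -> None:
    if not (LF_BAND[0] < f_lf_hz < LF_BAND[1]):
        raise ValueError(f"f_LF {f_lf_hz} Hz outside the LF band {LF_BAND}")
    if not (HF_BAND[0] < profile.f_resp_hz < HF_BAND[1]):
        raise ValueError(
            f"respiratory frequency {profile.f_resp_hz:.3f} Hz outside the "
            f"HF band {HF_BAND}"
        )


def generate_rr_series(
    profile: StressProfile,
    duration_s: float,
    seed: int,
    f_lf_hz: float = 0.1,
) -> RRSeries:
    """Generate beat times with the additive-sinusoid RR model.

    RR_i = mean + lf_amp sin(2π f_LF t_i) + hf_amp sin(2π f_resp t_i) + ε_i,
    ε_i ~ N(0, rr_noise²) clipped at ±mean/2 so intervals stay positive.
    Beat times accumulate until they cover ``duration_s``.
    """
    if duration_s < 60:
        raise ValueError("need at least 60 s of beats")
    _check_profile(profile, f_lf_hz)
    rng = np.random.default_rng(seed)
    clip = profile.mean_rr_ms / 2.0
    times = []
    t = 0.0
    while t <= duration_s:
        times.append(t)
        eps = float(np.clip(rng.normal(0.0, profile.rr_noise_ms or 1e-12), -clip, clip))
        rr = (
            profile.mean_rr_ms
            + profile.lf_amp_ms * np.sin(2 * np.pi * f_lf_hz * t)
            + profile.hf_amp_ms * np.sin(2 * np.pi * profile.f_resp_hz * t)
            + eps
        )
        t += rr / 1000.0
    times.append(t)  # final beat crosses duration_s so the series covers it
    return RRSeries.from_peak_times(np.asarray(times))


def jittered_profile(
    profile: StressProfile,
    rng: np.random.Generator,
    sd: float = 0.15,
    resp_rate_scale: float = 0.3,
) -> StressProfile:
    """Draw a between-slice modulated copy of a profile.

    Each parameter is scaled by an independent lognormal factor exp(N(0, sd));
    the breathing rate uses a reduced spread and is truncated so its
    frequency stays inside the 0.2-0.3 Hz band.  Used both to emulate
    slice-to-slice physiological variability and to build proper null
    studies in which both groups share one generating distribution.
    """
    fac = {p: float(np.exp(rng.normal(0.0, sd))) for p in (
        "mean_rr_ms", "lf_amp_ms", "hf_amp_ms", "rr_noise_ms", "resp_amp")}
    resp_fac = float(np.exp(rng.normal(0.0, resp_rate_scale * sd)))
    rate = float(np.clip(
        profile.resp_rate_bpm * resp_fac,
        RESP_F_CLIP_HZ[0] * 60.0, RESP_F_CLIP_HZ[1] * 60.0,
    ))
    return StressProfile(
        mean_rr_ms=profile.mean_rr_ms * fac["mean_rr_ms"],
        lf_amp_ms=profile.lf_amp_ms * fac["lf_amp_ms"],
        hf_amp_ms=profile.hf_amp_ms * fac["hf_amp_ms"],
        resp_rate_bpm=rate,
        resp_amp=profile.resp_amp * fac["resp_amp"],
        rr_noise_ms=profile.rr_noise_ms * fac["rr_noise_ms"],
    )


# ---------------------------------------------------------------------------
# Waveform synthesis
# ---------------------------------------------------------------------------

def synthesize_ecg(
    rr: RRSeries,
    rate_hz: float,
    r_amp: float = 1.0,
    qrs_sigma_s: float = 0.012,
    drift_amp: float = 0.0,
    drift_freq_hz: float = 0.08,
    mains_amp: float = 0.0,
    mains_hz: float = 50.0,
    duration_s: Optional[float] = None,
) -> np.ndarray:
    """Template-superposition ECG: one Gaussian QRS-like deflection per beat.

    Optional additive baseline drift (slow sinusoid) and mains interference
    exercise the cleaning stage.
    """
    if rate_hz < 100:
        raise ValueError("ECG sampling rate must be at least 100 Hz")
    if rr.n_beats == 0:
        raise ValueError("empty RR series")
    total = duration_s if duration_s is not None else float(rr.peak_times_s[-1])
    n = int(round(total * rate_hz)) + 1
    t = np.arange(n) / rate_hz
    out = np.zeros(n)
    half = int(np.ceil(4 * qrs_sigma_s * rate_hz))
    for tb in rr.peak_times_s:
        c = int(round(tb * rate_hz))
        lo, hi = max(c - half, 0), min(c + half + 1, n)
        if lo >= hi:
            continue
        out[lo:hi] += r_amp * np.exp(-((t[lo:hi] - tb) ** 2) / (2 * qrs_sigma_s**2))
    if drift_amp:
        out += drift_amp * np.sin(2 * np.pi * drift_freq_hz * t)
    if mains_amp:
        out += mains_amp * np.sin(2 * np.pi * mains_hz * t)
    return out


def generate_respiration(
    profile: StressProfile,
    duration_s: float,
    rate_hz: float,
    seed: int,
    rel_noise: float = 0.15,
) -> np.ndarray:
    """Quasi-sinusoidal chest-excursion signal at the profile's breath rate.

    Broadband noise scales with the breathing amplitude, so a shallower
    (high-stress) breather has uniformly lower spectral band powers.
    """
    if rate_hz < 10:
        raise ValueError("respiration sampling rate must be at least 10 Hz")
    _check_profile(profile, f_lf_hz=0.1)
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * rate_hz)) + 1
    t = np.arange(n) / rate_hz
    clean = profile.resp_amp * np.sin(2 * np.pi * profile.f_resp_hz * t)
    noise = rng.normal(0.0, rel_noise * profile.resp_amp or 0.0, size=n)
    return clean + noise


def generate_acceleration(
    plan: SortiePlan,
    rate_hz: float,
    seed: Optional[int] = None,
    baseline_sd: float = 0.05,
    peak_amp: float = 2.0,
    peak_sigma_s: float = 0.15,
    min_spacing_s: float = 1.5,
    max_spacing_s: float = 25.0,
) -> np.ndarray:
    """Triaxial acceleration: quiet baseline plus manoeuvre peak bursts.

    Inside each planned window exactly ``n_peaks`` suprathreshold Gaussian
    bumps are injected on rotating axes, spaced well below the segmentation
    gap parameter so the burst reads as one run of consecutive peaks.
    """
    rng = np.random.default_rng(plan.seed if seed is None else seed)
    n = int(round(plan.duration_s * rate_hz)) + 1
    t = np.arange(n) / rate_hz
    accel = rng.normal(0.0, baseline_sd, size=(3, n))
    half = int(np.ceil(4 * peak_sigma_s * rate_hz))
    for start, end, n_peaks in plan.critical_windows:
        margin = min_spacing_s / 2.0
        usable = (end - start) - 2 * margin
        if n_peaks * min_spacing_s > (end - start):
            raise ValueError(
                f"window [{start}, {end}) too short for {n_peaks} peaks at "
                f"{min_spacing_s} s spacing"
            )
        if n_peaks == 1:
            peak_times = np.array([start + (end - start) / 2.0])
        else:
            spacing = min(max_spacing_s, usable / (n_peaks - 1))
            spacing = max(spacing, min_spacing_s)
            span = spacing * (n_peaks - 1)
            first = start + margin + (usable - span) / 2.0
            peak_times = first + spacing * np.arange(n_peaks)
        for i, tp in enumerate(peak_times):
            axis = int(rng.integers(0, 3))
            amp = peak_amp * rng.uniform(0.8, 1.2)
            sign = 1.0 if rng.random() < 0.5 else -1.0
            c = int(round(tp * rate_hz))
            lo, hi = max(c - half, 0), min(c + half + 1, n)
            accel[axis, lo:hi] += sign * amp * np.exp(
                -((t[lo:hi] - tp) ** 2) / (2 * peak_sigma_s**2)
            )
    return accel


# ---------------------------------------------------------------------------
# Full-study generation
# ---------------------------------------------------------------------------

def _in_windows(t: float, windows: Sequence[tuple]) -> bool:
    return any(start <= t < end for start, end, *_ in windows)


@dataclass
class _Modulation:
    """Per-sortie multiplicative parameter modulation with slow drift."""

    factors: dict
    drift_amp: float
    drift_period_s: dict
    drift_phase: dict

    #: breathing-rate modulation is scaled down so the respiratory
    #: fundamental stays inside its nominal 0.2-0.3 Hz spectral band
    RESP_RATE_SCALE = 0.3
    PARAMS = [
        "mean_rr_ms", "lf_amp_ms", "hf_amp_ms", "rr_noise_ms",
        "resp_rate_bpm", "resp_amp",
    ]

    @classmethod
    def draw(cls, rng: np.random.Generator, sortie_sd: float, drift_sd: float):
        def scale(p):
            return cls.RESP_RATE_SCALE if p == "resp_rate_bpm" else 1.0

        return cls(
            factors={
                p: float(np.exp(rng.normal(0.0, scale(p) * sortie_sd)))
                for p in cls.PARAMS
            },
            drift_amp=drift_sd * np.sqrt(2.0),
            drift_period_s={p: float(rng.uniform(400.0, 900.0)) for p in cls.PARAMS},
            drift_phase={p: float(rng.uniform(0.0, 2 * np.pi)) for p in cls.PARAMS},
        )

    def value(self, base, param: str, t):
        amp = self.drift_amp
        if param == "resp_rate_bpm":
            amp *= self.RESP_RATE_SCALE
        drift = amp * np.sin(
            2 * np.pi * t / self.drift_period_s[param] + self.drift_phase[param]
        )
        return base * self.factors[param] * (1.0 + drift)


def _modulated_rr_times(
    low: StressProfile,
    high: StressProfile,
    windows: Sequence[tuple],
    duration_s: float,
    mod: _Modulation,
    rng: np.random.Generator,
    f_lf_hz: float = 0.1,
) -> RRSeries:
    """Beat times under a time-varying profile, phase-continuous in both
    oscillators across the low/high condition switches."""
    times = []
    t, phase_lf, phase_hf = 0.0, 0.0, 0.0
    while t <= duration_s:
        p = high if _in_windows(t, windows) else low
        mean_rr = mod.value(p.mean_rr_ms, "mean_rr_ms", t)
        lf_amp = mod.value(p.lf_amp_ms, "lf_amp_ms", t)
        hf_amp = mod.value(p.hf_amp_ms, "hf_amp_ms", t)
        f_resp = np.clip(
            mod.value(p.resp_rate_bpm, "resp_rate_bpm", t) / 60.0, *RESP_F_CLIP_HZ
        )
        noise_sd = mod.value(p.rr_noise_ms, "rr_noise_ms", t)
        times.append(t)
        eps = float(np.clip(rng.normal(0.0, noise_sd), -mean_rr / 2, mean_rr / 2))
        rr = mean_rr + lf_amp * np.sin(phase_lf) + hf_amp * np.sin(phase_hf) + eps
        rr = max(rr, mean_rr / 4.0)
        dt = rr / 1000.0
        phase_lf += 2 * np.pi * f_lf_hz * dt
        phase_hf += 2 * np.pi * f_resp * dt
        t += dt
    times.append(t)  # final beat crosses duration_s
    return RRSeries.from_peak_times(np.asarray(times))


def _modulated_respiration(
    low: StressProfile,
    high: StressProfile,
    windows: Sequence[tuple],
    duration_s: float,
    rate_hz: float,
    mod: _Modulation,
    rng: np.random.Generator,
    rel_noise: float = 0.15,
) -> np.ndarray:
    n = int(round(duration_s * rate_hz)) + 1
    t = np.arange(n) / rate_hz
    in_win = np.zeros(n, dtype=bool)
    for start, end, *_ in windows:
        in_win |= (t >= start) & (t < end)
    rate_bpm = np.where(
        in_win,
        mod.value(high.resp_rate_bpm, "resp_rate_bpm", t),
        mod.value(low.resp_rate_bpm, "resp_rate_bpm", t),
    )
    amp = np.where(
        in_win,
        mod.value(high.resp_amp, "resp_amp", t),
        mod.value(low.resp_amp, "resp_amp", t),
    )
    f_hz = np.clip(rate_bpm / 60.0, *RESP_F_CLIP_HZ)
    phase = 2 * np.pi * np.cumsum(f_hz) / rate_hz
    return amp * np.sin(phase) + rng.normal(0.0, 1.0, size=n) * rel_noise * amp


@dataclass
class StudyData:
    """Synthetic study: per-sortie records plus ground-truth segments."""

    records: list
    ground_truth: dict  # sortie_id -> list[EventSegment]

    def summary(self) -> dict:
        n_crit = sum(
            sum(1 for s in segs if s.label == CRITICAL)
            for segs in self.ground_truth.values()
        )
        n_non = sum(
            sum(1 for s in segs if s.label == NON_CRITICAL)
            for segs in self.ground_truth.values()
        )
        return {
            "n_sorties": len(self.records),
            "n_critical_truth": n_crit,
            "n_noncritical_truth": n_non,
        }


def generate_study(
    n_sorties: int = 32,
    low: StressProfile = LOW_STRESS,
    high: StressProfile = HIGH_STRESS,
    duration_s: float = 1320.0,
    n_windows: int = 2,
    window_len_s: float = 200.0,
    peaks_range: tuple = (8, 11),
    ecg_rate_hz: float = ECG_RATE_HZ,
    resp_rate_hz: float = RESP_RATE_HZ,
    accel_rate_hz: float = ACCEL_RATE_HZ,
    sortie_sd: float = 0.15,
    drift_sd: float = 0.07,
    ecg_drift_amp: float = 0.1,
    ecg_mains_amp: float = 0.05,
    seed: int = 0,
) -> StudyData:
    """Generate a seed-reproducible multi-sortie study.

    Each sortie contains ``n_windows`` manoeuvre windows placed with jitter
    in equal blocks of the timeline, leaving level-flight gaps long enough
    to host at least one 3-min slice.  Ground truth holds the manoeuvre
    windows (critical) and the remaining level-flight intervals of at least
    180 s (non-critical).
    """
    if n_sorties < 1:
        raise ValueError("need at least one sortie")
    validate_profile_pair(low, high)
    block = duration_s / max(n_windows, 1)
    if n_windows and window_len_s > block - 2 * 220.0:
        # keep >=220 s of level flight around every window
        max_len = block - 2 * 220.0
        if max_len <= 0:
            raise ValueError("sortie too short for the requested windows")
        window_len_s = max_len
    root = np.random.SeedSequence(seed)
    records, truth = [], {}
    for i, ss in enumerate(root.spawn(n_sorties)):
        rng = np.random.default_rng(ss)
        sortie_id = f"sortie_{i:03d}"
        windows = []
        for w in range(n_windows):
            center = (w + 0.5) * block + rng.uniform(-20.0, 20.0)
            start = center - window_len_s / 2.0
            n_peaks = int(rng.integers(peaks_range[0], peaks_range[1]))
            windows.append((start, start + window_len_s, n_peaks))
        plan = SortiePlan(
            duration_s=duration_s,
            critical_windows=tuple(windows),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        mod = _Modulation.draw(rng, sortie_sd, drift_sd)
        rr = _modulated_rr_times(low, high, windows, duration_s, mod, rng)
        ecg = synthesize_ecg(
            rr, ecg_rate_hz,
            drift_amp=ecg_drift_amp, mains_amp=ecg_mains_amp,
            duration_s=duration_s,
        )
        resp = _modulated_respiration(
            low, high, windows, duration_s, resp_rate_hz, mod, rng
        )
        accel = generate_acceleration(plan, accel_rate_hz)
        records.append(
            PhysioRecord(
                sortie_id=sortie_id,
                ecg=ecg, ecg_rate_hz=ecg_rate_hz,
                resp=resp, resp_rate_hz=resp_rate_hz,
                accel_xyz=accel, accel_rate_hz=accel_rate_hz,
            )
        )
        segs = [
            EventSegment(s, e, CRITICAL, n_peaks=k, source="ground_truth")
            for s, e, k in windows
        ]
        bounds = [0.0] + [b for w in windows for b in (w[0], w[1])] + [duration_s]
        for lo_b, hi_b in zip(bounds[::2], bounds[1::2]):
            if hi_b - lo_b >= 180.0:
                segs.append(
                    EventSegment(lo_b, hi_b, NON_CRITICAL, source="ground_truth")
                )
        truth[sortie_id] = sorted(segs, key=lambda s: s.start_s)
    return StudyData(records=records, ground_truth=truth)


# ---------------------------------------------------------------------------
# Serialization (columnar CSV per channel + JSON sidecar, truth as JSON)
# ---------------------------------------------------------------------------

def write_sortie(record: PhysioRecord, out_dir) -> None:
    out = Path(out_dir) / record.sortie_id
    out.mkdir(parents=True, exist_ok=True)
    channels = {
        "ecg": (np.atleast_2d(record.ecg), record.ecg_rate_hz, ["value"]),
        "resp": (np.atleast_2d(record.resp), record.resp_rate_hz, ["value"]),
        "accel": (record.accel_xyz, record.accel_rate_hz, ["x", "y", "z"]),
    }
    for name, (data, rate, cols) in channels.items():
        t = np.arange(data.shape[1]) / rate
        df = pd.DataFrame({"t_s": t} | {c: data[j] for j, c in enumerate(cols)})
        df.to_csv(out / f"{name}.csv", index=False, float_format="%.6f")
        sidecar = {"sortie_id": record.sortie_id, "channel": name, "rate_hz": rate}
        (out / f"{name}.json").write_text(json.dumps(sidecar, indent=1))


def read_sortie(sortie_dir) -> PhysioRecord:
    d = Path(sortie_dir)
    meta = {
        name: json.loads((d / f"{name}.json").read_text())
        for name in ("ecg", "resp", "accel")
    }
    ecg = pd.read_csv(d / "ecg.csv")["value"].to_numpy()
    resp = pd.read_csv(d / "resp.csv")["value"].to_numpy()
    acc = pd.read_csv(d / "accel.csv")
    return PhysioRecord(
        sortie_id=meta["ecg"]["sortie_id"],
        ecg=ecg, ecg_rate_hz=meta["ecg"]["rate_hz"],
        resp=resp, resp_rate_hz=meta["resp"]["rate_hz"],
        accel_xyz=acc[["x", "y", "z"]].to_numpy().T,
        accel_rate_hz=meta["accel"]["rate_hz"],
    )


def write_ground_truth(truth: dict, path) -> None:
    payload = {
        sid: [s.to_dict() for s in segs] for sid, segs in truth.items()
    }
    Path(path).write_text(json.dumps(payload, indent=1))
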