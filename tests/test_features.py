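import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal as sps
from scipy.interpolate import CubicSpline

import aerostress as a
from aerostress.features import (
    frequency_domain, poincare, respiratory, time_domain,
)
from tests.conftest import random_rr_series


# ---------------------------------------------------------------------------
# Naive definitional oracles (plain loops / independent FFT path)
# ---------------------------------------------------------------------------

def naive_time_domain(rr_ms):
    rr = [float(v) for v in rr_ms]
    n = len(rr)
    mean_rr = sum(rr) / n
    mean_hr = sum(60000.0 / v for v in rr) / n
    sdnn = math.sqrt(sum((v - mean_rr) ** 2 for v in rr) / n)
    d = [rr[i + 1] - rr[i] for i in range(n - 1)]
    mean_d = sum(d) / len(d)
    sdsd = math.sqrt(sum((v - mean_d) ** 2 for v in d) / len(d))
    rmssd = math.sqrt(sum(v * v for v in d) / len(d))
    pnn20 = 100.0 * sum(1 for v in d if abs(v) > 20.0) / len(d)
    pnn50 = 100.0 * sum(1 for v in d if abs(v) > 50.0) / len(d)
    return dict(mean_rr=mean_rr, mean_hr=mean_hr, sdnn=sdnn, sdsd=sdsd,
                rmssd=rmssd, pnn20=pnn20, pnn50=pnn50)


def naive_poincare(rr_ms):
    rr = [float(v) for v in rr_ms]
    d = [rr[i + 1] - rr[i] for i in range(len(rr) - 1)]
    mean_d = sum(d) / len(d)
    var_d = sum((v - mean_d) ** 2 for v in d) / len(d)
    mean_rr = sum(rr) / len(rr)
    var_rr = sum((v - mean_rr) ** 2 for v in rr) / len(rr)
    sd1 = math.sqrt(var_d / 2.0)
    sd2 = math.sqrt(max(2.0 * var_rr - var_d / 2.0, 0.0))
    return dict(sd1=sd1, sd2=sd2,
                sd1_sd2=sd1 / sd2 if sd2 > 0 else math.nan,
                s=math.pi * sd1 * sd2)


def naive_welch(x, fs, nperseg, noverlap):
    """Hann-window Welch periodogram by direct FFT, mean-detrended."""
    x = np.asarray(x, float)
    step = nperseg - noverlap
    win = sps.get_window("hann", nperseg)
    scale = 1.0 / (fs * np.sum(win**2))
    n_seg = (x.size - nperseg) // step + 1
    psd = np.zeros(nperseg // 2 + 1)
    for k in range(n_seg):
        seg = x[k * step : k * step + nperseg]
        seg = seg - seg.mean()
        X = np.fft.rfft(seg * win)
        p = (X * np.conj(X)).real * scale
        p[1:] *= 2
        if nperseg % 2 == 0:
            p[-1] /= 2
        psd += p
    return np.fft.rfftfreq(nperseg, 1 / fs), psd / n_seg


def naive_band(f, p, lo, hi):
    m = (f >= lo) & (f < hi)
    return float(np.trapezoid(p[m], f[m])) if m.sum() >= 2 else 0.0


def naive_frequency_domain(rr):
    t = rr.peak_times_s[1:]
    grid = np.arange(t[0], t[-1], 0.25)
    xi = CubicSpline(t, rr.rr_ms)(grid)
    nperseg = min(480, xi.size)
    f, p = naive_welch(xi, 4.0, nperseg, nperseg // 2)
    lf = naive_band(f, p, 0.04, 0.15)
    hf = naive_band(f, p, 0.15, 0.4)
    return dict(lf=lf, hf=hf, lfn=lf / (lf + hf), hfn=hf / (lf + hf),
                lf_hf=lf / hf if hf > 0 else math.nan)


def close(x, y):
    if math.isnan(x) and math.isnan(y):
        return True
    return abs(x - y) <= 1e-9 * max(1.0, abs(x), abs(y))


# ---------------------------------------------------------------------------
# Oracle-equivalence and worked examples
# ---------------------------------------------------------------------------

class TestOracleEquivalence:
    def test_ecg_indicators_match_naive_recomputation(self):
        """All 16 ECG indicators agree with an independent definitional
        recomputation on 100 random RR series."""
        rng = np.random.default_rng(123)
        for _ in range(100):
            rr = random_rr_series(rng, n_min=160, n_max=260)
            ours = {}
            ours.update(time_domain(rr))
            ours.update(poincare(rr))
            ours.update(frequency_domain(rr))
            oracle = {}
            oracle.update(naive_time_domain(rr.rr_ms))
            oracle.update(naive_poincare(rr.rr_ms))
            oracle.update(naive_frequency_domain(rr))
            for key in a.ECG_INDICATORS:
                assert close(ours[key], oracle[key]), key

    def test_respiratory_bands_match_naive_welch(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            prof = a.jittered_profile(a.LOW_STRESS, rng)
            x = a.generate_respiration(
                prof, 180.0, 10.0, seed=int(rng.integers(2**31))
            )
            ours = respiratory(x, 10.0)
            nperseg = min(1200, x.size)
            f, p = naive_welch(x, 10.0, nperseg, nperseg // 2)
            for k, (lo, hi) in enumerate(
                [(0.0, 0.1), (0.1, 0.2), (0.2, 0.3), (0.3, 0.4)], start=1
            ):
                assert close(ours[f"eb{k}"], naive_band(f, p, lo, hi))

    def test_breath_rate_matches_construction(self):
        # known cycle count: f * duration cycles in the slice
        x = a.generate_respiration(
            a.StressProfile(800, 0, 0, 15.0, 1.0, 0), 180.0, 25.0,
            seed=0, rel_noise=0.0,
        )
        assert respiratory(x, 25.0)["mean_rsp"] == pytest.approx(15.0, abs=0.5)


class TestTimeDomain:
    def test_constant_series(self):
        rr = a.RRSeries(np.arange(5) * 0.8, np.full(4, 800.0))
        out = time_domain(rr)
        assert out["mean_rr"] == 800.0
        assert out["mean_hr"] == pytest.approx(75.0)
        for k in ("sdnn", "rmssd", "sdsd", "pnn20", "pnn50"):
            assert out[k] == 0.0

    def test_alternating_series_boundary_of_exceeding(self):
        # differences are exactly +-50 ms: strict ">" keeps pNN50 at zero
        rr_ms = np.array([800.0, 850, 800, 850, 800])
        rr = a.RRSeries(np.concatenate(([0], np.cumsum(rr_ms))) / 1000.0, rr_ms)
        out = time_domain(rr)
        assert out["rmssd"] == pytest.approx(50.0)
        assert out["pnn50"] == 0.0
        assert out["pnn20"] == 100.0

    def test_too_few_beats(self):
        with pytest.raises(ValueError, match="too few"):
            time_domain(a.RRSeries(np.array([0.0, 0.8]), np.array([800.0])))

    @settings(max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(min_value=350.0, max_value=1800.0), min_size=4,
                 max_size=60),
        st.floats(min_value=-200.0, max_value=200.0),
    )
    def test_shift_invariance(self, rr_list, c):
        """Adding a constant to all RR shifts mean RR and leaves the
        dispersion indices unchanged."""
        rr_ms = np.asarray(rr_list)
        times = np.concatenate(([0.0], np.cumsum(rr_ms))) / 1000.0
        base = time_domain(a.RRSeries(times, rr_ms)) | poincare(
            a.RRSeries(times, rr_ms)
        )
        shifted_ms = rr_ms + c
        times2 = np.concatenate(([0.0], np.cumsum(shifted_ms))) / 1000.0
        shifted = time_domain(a.RRSeries(times2, shifted_ms)) | poincare(
            a.RRSeries(times2, shifted_ms)
        )
        assert shifted["mean_rr"] == pytest.approx(base["mean_rr"] + c)
        for k in ("sdnn", "rmssd", "sdsd", "sd1", "sd2"):
            assert shifted[k] == pytest.approx(base[k], abs=1e-8)


class TestFrequencyDomain:
    def tone_series(self, f_tone, amp=30.0):
        prof = a.StressProfile(
            mean_rr_ms=800.0,
            lf_amp_ms=amp if f_tone < 0.15 else 0.0,
            hf_amp_ms=amp if f_tone >= 0.15 else 0.0,
            resp_rate_bpm=max(f_tone * 60.0, 15.0),
            resp_amp=1.0, rr_noise_ms=0.0,
        )
        return a.generate_rr_series(prof, 300.0, seed=0, f_lf_hz=min(f_tone, 0.1))

    def test_lf_tone_dominates(self):
        out = frequency_domain(self.tone_series(0.1))
        assert out["lfn"] >= 0.9

    def test_hf_tone_dominates(self):
        out = frequency_domain(self.tone_series(0.25))
        assert out["hfn"] >= 0.9
        assert out["lf_hf"] <= 0.12

    def test_normalization_identity(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            out = frequency_domain(random_rr_series(rng, 180, 250))
            assert out["lfn"] + out["hfn"] == pytest.approx(1.0, abs=1e-12)

    def test_short_coverage_rejected(self):
        rr = a.RRSeries(np.arange(50) * 0.8, np.full(49, 800.0))
        with pytest.raises(ValueError, match="120 s"):
            frequency_domain(rr)


class TestPoincare:
    def test_constant_series_degenerate(self):
        rr = a.RRSeries(np.arange(5) * 0.8, np.full(4, 800.0))
        out = poincare(rr)
        assert out["sd1"] == 0.0 and out["sd2"] == 0.0 and out["s"] == 0.0
        assert math.isnan(out["sd1_sd2"])

    def test_sd1_is_sdsd_over_sqrt2(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            rr = random_rr_series(rng)
            p, t = poincare(rr), time_domain(rr)
            assert p["sd1"] == pytest.approx(t["sdsd"] / math.sqrt(2), rel=1e-9)
            assert p["s"] == pytest.approx(math.pi * p["sd1"] * p["sd2"], rel=1e-12)


class TestRespiratory:
    def test_single_tone_band_dominance(self):
        t = np.arange(0, 180, 0.1)
        x = np.sin(2 * np.pi * 0.25 * t)
        out = respiratory(x, 10.0)
        assert out["mean_rsp"] == pytest.approx(15.0, abs=0.5)
        for k in ("eb1", "eb2", "eb4"):
            assert out["eb3"] > 10 * out[k]

    def test_zero_signal(self):
        out = respiratory(np.zeros(1800), 10.0)
        assert math.isnan(out["mean_rsp"])
        for k in ("eb1", "eb2", "eb3", "eb4"):
            assert out[k] == pytest.approx(0.0, abs=1e-15)

    def test_two_tone_parseval_split(self):
        t = np.arange(0, 360, 0.1)
        x = np.sin(2 * np.pi * 0.05 * t) + np.sin(2 * np.pi * 0.35 * t)
        out = respiratory(x, 10.0)
        assert out["eb1"] == pytest.approx(out["eb4"], rel=0.1)
        assert out["eb2"] < 0.1 * out["eb1"]
        assert out["eb3"] < 0.1 * out["eb1"]

    def test_band_additivity(self):
        rng = np.random.default_rng(4)
        t = np.arange(0, 360, 0.1)
        x = sum(
            np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
            for f in (0.05, 0.15, 0.22, 0.33)
        )
        out = respiratory(x, 10.0)
        nperseg = min(1200, x.size)
        f_, p = naive_welch(x, 10.0, nperseg, nperseg // 2)
        total = naive_band(f_, p, 0.0, 0.4)
        assert out["eb1"] + out["eb2"] + out["eb3"] + out["eb4"] == pytest.approx(
            total, rel=0.05
        )


class TestExtractFeatures:
    def test_feature_table_shape(self, small_slices):
        table = a.build_feature_table(small_slices[:10])
        assert len(table) == 10
        assert list(table.columns) == ["sortie_id", "slice_id", *a.INDICATORS,
                                       "label"]
        assert set(table["label"]) <= {"high", "low"}

    def test_deterministic(self, small_slices):
        v1 = a.extract_features(small_slices[0])
        v2 = a.extract_features(small_slices[0])
        assert v1 == v2
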