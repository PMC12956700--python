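import logging

import numpy as np
import pandas as pd
import pytest

import aerostress as a


@pytest.fixture(autouse=True)
def _quiet_logs(caplog):
    logging.getLogger("aerostress").setLevel(logging.INFO)


@pytest.fixture(scope="session")
def small_study():
    """Six synthetic sorties at default conditions (fixed seed)."""
    return a.generate_study(n_sorties=6, seed=42)


@pytest.fixture(scope="session")
def small_slices(small_study):
    slices = []
    for rec in small_study.records:
        for seg in a.segment_record(rec):
            slices.extend(a.slice_segment(seg, rec))
    return slices


@pytest.fixture(scope="session")
def small_features(small_slices):
    return a.build_feature_table(small_slices)


@pytest.fixture(scope="session")
def constant_rr_record():
    """One synthetic sortie-like record with a constant 800-ms RR train."""
    profile = a.StressProfile(
        mean_rr_ms=800.0, lf_amp_ms=0.0, hf_amp_ms=0.0,
        resp_rate_bpm=15.0, resp_amp=1.0, rr_noise_ms=0.0,
    )
    rr = a.generate_rr_series(profile, 600.0, seed=0)
    ecg = a.synthesize_ecg(rr, 250.0, duration_s=600.0)
    resp = a.generate_respiration(profile, 600.0, 25.0, seed=0)
    plan = a.SortiePlan(duration_s=600.0, critical_windows=(), seed=0)
    accel = a.generate_acceleration(plan, 25.0)
    return a.PhysioRecord(
        sortie_id="fixture_const",
        ecg=ecg, ecg_rate_hz=250.0,
        resp=resp, resp_rate_hz=25.0,
        accel_xyz=accel, accel_rate_hz=25.0,
    )


def random_rr_series(rng, n_min=30, n_max=240):
    """A random plausible RR series (ms) with its beat times."""
    n = int(rng.integers(n_min, n_max))
    rr = rng.uniform(400.0, 1500.0, size=n)
    times = np.concatenate(([0.0], np.cumsum(rr) / 1000.0))
    return a.RRSeries.from_peak_times(times)
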