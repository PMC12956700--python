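"""Configuration and end-to-end pipeline orchestration.

Stage order: simulate -> segment -> extract -> screen -> train -> report.
A single master seed deterministically derives one sub-seed per stage (via
a per-stage ``SeedSequence``), so any stage can be rerun in isolation and
(config, seed) fully determine every artifact.
"""

from __future__ import annotations

import json
import logging
import platform
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .features import INDICATORS, build_feature_table
from .model import evaluate_structures, reports_table
from .screening import run_screening, screening_table, select_features
from .segmentation import segment_record, slice_segment
from .synth import (
    StressProfile, StudyData, generate_study, read_sortie,
    validate_profile_pair, write_ground_truth, write_sortie,
)

logger = logging.getLogger("aerostress")

#: Stage indices used for sub-seed derivation.
STAGES = ["simulate", "segment", "extract", "screen", "train"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "synth": {
        "n_sorties": 32,
        "duration_s": 1320.0,
        "n_windows": 2,
        "window_len_s": 200.0,
        "ecg_rate_hz": 250.0,
        "resp_rate_hz": 25.0,
        "accel_rate_hz": 25.0,
        "sortie_sd": 0.15,
        "drift_sd": 0.07,
        "profiles": {
            "low": {
                "mean_rr_ms": 860.0, "lf_amp_ms": 25.0, "hf_amp_ms": 40.0,
                "resp_rate_bpm": 15.0, "resp_amp": 1.0, "rr_noise_ms": 15.0,
            },
            "high": {
                "mean_rr_ms": 750.0, "lf_amp_ms": 26.0, "hf_amp_ms": 32.0,
                "resp_rate_bpm": 14.2, "resp_amp": 0.75, "rr_noise_ms": 15.0,
            },
        },
    },
    "segmentation": {
        "threshold_k": 6.0,
        "min_separation_s": 1.0,
        "baseline_window_s": 30.0,
        "min_peaks": 5,
        "max_gap_s": 30.0,
        "pad_s": 10.0,
        "guard_s": 10.0,
        "match_count": True,
    },
    "screening": {"alpha": 0.05},
    "outputs": {"write_signals": True},
    "model": {
        "structures": ["decision_tree", "random_forest", "xgboost", "stacking"],
        "folds": 5,
    },
}


def _merge(defaults: dict, override: dict, path: str = "") -> dict:
    out = dict(defaults)
    for key, value in override.items():
        if key not in defaults:
            raise ValueError(f"unknown configuration key {path + key!r}")
        if isinstance(defaults[key], dict):
            if not isinstance(value, dict):
                raise ValueError(f"section {path + key!r} must be a mapping")
            out[key] = _merge(defaults[key], value, path=f"{path}{key}.")
        else:
            out[key] = value
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Defaults, optionally overridden by a YAML file; unknown keys rejected."""
    config = DEFAULT_CONFIG
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        config = _merge(config, loaded)
    if overrides:
        config = _merge(config, overrides)
    # validate eagerly: profile pairing and ranges fail at load, not mid-run
    low, high = profiles(config)
    validate_profile_pair(low, high)
    if config["model"]["folds"] < 2:
        raise ValueError("folds must be at least 2")
    return config


def profiles(config: dict) -> tuple[StressProfile, StressProfile]:
    p = config["synth"]["profiles"]
    return StressProfile(**p["low"]), StressProfile(**p["high"])


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage sub-seed (< 2^31) from the master seed."""
    idx = STAGES.index(stage)
    return int(np.random.SeedSequence([master, idx]).generate_state(1)[0] % 2**31)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def run_simulate(config: dict, out_dir: Path) -> StudyData:
    low, high = profiles(config)
    s = config["synth"]
    study = generate_study(
        n_sorties=s["n_sorties"], low=low, high=high,
        duration_s=s["duration_s"], n_windows=s["n_windows"],
        window_len_s=s["window_len_s"],
        ecg_rate_hz=s["ecg_rate_hz"], resp_rate_hz=s["resp_rate_hz"],
        accel_rate_hz=s["accel_rate_hz"],
        sortie_sd=s["sortie_sd"], drift_sd=s["drift_sd"],
        seed=stage_seed(config["seed"], "simulate"),
    )
    if config.get("outputs", {}).get("write_signals", True):
        sortie_dir = out_dir / "sorties"
        for rec in study.records:
            write_sortie(rec, sortie_dir)
    write_ground_truth(study.ground_truth, out_dir / "ground_truth.json")
    logger.info("simulate: %s", study.summary())
    return study


def run_segment(config: dict, study: StudyData, out_dir: Path) -> dict:
    """Detect segments per sortie and emit slice metadata."""
    seg = config["segmentation"]
    all_segments, all_slices = {}, []
    for rec in study.records:
        segments = segment_record(rec, **seg)
        all_segments[rec.sortie_id] = segments
        for segment in segments:
            all_slices.extend(slice_segment(segment, rec))
    payload = {
        sid: [s.to_dict() for s in segs] for sid, segs in all_segments.items()
    }
    (out_dir / "segments.json").write_text(json.dumps(payload, indent=1))
    meta = [
        {"sortie_id": s.sortie_id, "start_s": s.start_s, "end_s": s.end_s,
         "label": s.label}
        for s in all_slices
    ]
    (out_dir / "slices.json").write_text(json.dumps(meta, indent=1))
    logger.info(
        "segment: %d segments, %d slices",
        sum(len(v) for v in all_segments.values()), len(all_slices),
    )
    return {"segments": all_segments, "slices": all_slices}


def run_extract(slices: list, out_dir: Path) -> pd.DataFrame:
    features = build_feature_table(slices)
    features.to_csv(out_dir / "features.csv", index=False, float_format="%.10g")
    logger.info("extract: %d rows x %d indicators", len(features), len(INDICATORS))
    return features


def run_screen(config: dict, features: pd.DataFrame, out_dir: Path):
    records = run_screening(features, alpha=config["screening"]["alpha"])
    selected = select_features(records)
    screening_table(records).to_csv(
        out_dir / "screening.csv", index=False, float_format="%.6g"
    )
    (out_dir / "selected_indicators.json").write_text(json.dumps(selected, indent=1))
    logger.info("screen: selected %d of %d indicators", len(selected), len(records))
    return records, selected


def run_train(config: dict, features: pd.DataFrame, selected, out_dir: Path) -> dict:
    reports = evaluate_structures(
        features, selected,
        structures=config["model"]["structures"],
        k=config["model"]["folds"],
        seed=stage_seed(config["seed"], "train"),
    )
    payload = {name: rep.to_dict() for name, rep in reports.items()}
    (out_dir / "cv_reports.json").write_text(json.dumps(payload, indent=1))
    reports_table(reports).to_csv(
        out_dir / "cv_metrics.csv", index=False, float_format="%.4f"
    )
    for name, rep in reports.items():
        logger.info("train: %s %s", name, rep.metrics)
    return reports


def run_pipeline(config: dict, out_dir) -> dict:
    """Execute every stage, write all artifacts, return the run report."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "config.yaml").write_text(yaml.safe_dump(config, sort_keys=True))
    study = run_simulate(config, out_dir)
    seg = run_segment(config, study, out_dir)
    features = run_extract(seg["slices"], out_dir)
    records, selected = run_screen(config, features, out_dir)
    reports = run_train(config, features, selected, out_dir)
    report = {
        "version": __version__,
        "python": platform.python_version(),
        "seed": config["seed"],
        "counts": {
            **study.summary(),
            "n_segments_detected": sum(len(v) for v in seg["segments"].values()),
            "n_slices": len(seg["slices"]),
            "n_slices_high": int((features["label"] == "high").sum()),
            "n_slices_low": int((features["label"] == "low").sum()),
        },
        "selected_indicators": selected,
        "cv_metrics": {name: rep.metrics for name, rep in reports.items()},
    }
    (out_dir / "run_report.json").write_text(json.dumps(report, indent=1))
    return report


ARTIFACTS = [
    "config.yaml", "ground_truth.json", "segments.json", "slices.json",
    "features.csv", "screening.csv", "selected_indicators.json",
    "cv_reports.json", "cv_metrics.csv", "run_report.json",
]


def make_report(run_dir) -> str:
    """Render a human-readable summary from stored artifacts only."""
    run_dir = Path(run_dir)
    missing = [name for name in ARTIFACTS if not (run_dir / name).exists()]
    if missing:
        raise FileNotFoundError(
            "missing run artifacts: " + ", ".join(sorted(missing))
        )
    report = json.loads((run_dir / "run_report.json").read_text())
    screening = pd.read_csv(run_dir / "screening.csv")
    metrics = pd.read_csv(run_dir / "cv_metrics.csv")
    lines = [
        f"aerostress run report (seed {report['seed']})",
        "",
        "counts: " + json.dumps(report["counts"]),
        "",
        "indicator screening (t-test, Cohen's d):",
        screening[
            ["indicator", "test_used", "t_stat", "p_value", "cohens_d", "verdict"]
        ].to_string(index=False),
        "",
        "selected indicators: " + ", ".join(report["selected_indicators"]),
        "",
        "five-fold cross-validation (percent):",
        metrics.to_string(index=False),
        "",
    ]
    return "\n".join(lines)
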