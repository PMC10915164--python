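"""Readers, writers, run configuration and the end-to-end pipeline driver.

Event tables (plain CSV) are the interchange unit between stages, so the
classification cascade can run without trace-level data. Traces round-trip
through two-column CSV (time_s, current_pA) or a compact ``.npz`` container;
Axon ABF files are readable when the optional ``pyabf`` dependency is
installed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
import yaml

from .classify import ClassifierModel
from .detect import Trace, detect_events, estimate_baseline, filter_events
from .features import FEATURE_COLUMNS, FeatureMatrix, extract_all, spectrum_summary
from .quantify import quantify
from .screen import (
    SCREENING_PRESETS,
    NoveltyModel,
    ScreeningParams,
    screen_sample,
)

__all__ = [
    "read_trace",
    "write_trace",
    "write_events_csv",
    "read_feature_csv",
    "write_feature_csv",
    "save_model",
    "load_model",
    "RunConfig",
    "run_pipeline",
]

logger = logging.getLogger(__name__)


def read_trace(path, format: str | None = None, sampling_rate: float | None = None) -> Trace:
    """Read a trace from CSV, the npz container or (optionally) ABF.

    CSV needs columns time_s,current_pA (sampling rate inferred from the
    time column unless given); the npz container stores samples, rate and
    metadata. ABF requires the optional pyabf package.
    """
    path = Path(path)
    fmt = format or {".csv": "csv", ".npz": "npz", ".abf": "abf"}.get(path.suffix.lower())
    if fmt == "csv":
        df = pd.read_csv(path, float_precision="round_trip")
        if not {"time_s", "current_pA"} <= set(df.columns):
            raise ValueError(f"{path}: expected columns time_s,current_pA")
        if sampling_rate is None:
            dt = np.diff(df["time_s"].to_numpy())
            if dt.size == 0 or dt.min() <= 0:
                raise ValueError(f"{path}: cannot infer sampling rate from time column")
            sampling_rate = 1.0 / float(np.median(dt))
        return Trace(df["current_pA"].to_numpy(dtype=float), sampling_rate)
    if fmt == "npz":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["metadata_json"])) if "metadata_json" in z else {}
            return Trace(z["samples"], float(z["sampling_rate"]), metadata=meta)
    if fmt == "abf":
        try:
            import pyabf  # type: ignore
        except ImportError as exc:
            raise ImportError(
                "reading Axon ABF files requires the optional 'pyabf' package "
                "(pip install porescreen[abf])"
            ) from exc
        abf = pyabf.ABF(str(path))
        abf.setSweep(0)
        return Trace(np.asarray(abf.sweepY, dtype=float), float(abf.dataRate))
    raise ValueError(f"unsupported trace format: {format or path.suffix}")


def write_trace(trace: Trace, path, format: str | None = None) -> Path:
    """Write a trace as CSV (time_s,current_pA) or the npz container."""
    path = Path(path)
    fmt = format or {".csv": "csv", ".npz": "npz"}.get(path.suffix.lower())
    if fmt == "csv":
        t = np.arange(trace.n_samples) / trace.sampling_rate + trace.start_time
        # %.17g round-trips float64 exactly
        pd.DataFrame({"time_s": t, "current_pA": trace.samples}).to_csv(
            path, index=False, float_format="%.17g"
        )
    elif fmt == "npz":
        np.savez_compressed(
            path,
            samples=trace.samples,
            sampling_rate=trace.sampling_rate,
            metadata_json=json.dumps(trace.metadata, default=str),
        )
    else:
        raise ValueError(f"unsupported trace format: {format or path.suffix}")
    return path


def write_events_csv(events, sampling_rate: float, path) -> Path:
    rows = [
        {
            "start_ms": ev.start_index / sampling_rate * 1e3,
            "end_ms": ev.end_index / sampling_rate * 1e3,
            "dwell_ms": ev.dwell_ms(sampling_rate),
            "direction": ev.direction,
        }
        for ev in events
    ]
    pd.DataFrame(rows, columns=["start_ms", "end_ms", "dwell_ms", "direction"]).to_csv(
        path, index=False
    )
    return Path(path)


def write_feature_csv(matrix: FeatureMatrix, path) -> Path:
    matrix.to_frame().to_csv(path, index_label="event_id")
    return Path(path)


def read_feature_csv(path, label_column: str = "label", column_map: dict | None = None) -> FeatureMatrix:
    """Generic labeled-event-CSV importer with an optional column mapping
    (external column name -> canonical feature name)."""
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    labels = df[label_column].to_numpy(dtype=object) if label_column in df.columns else None
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing feature columns {missing}")
    return FeatureMatrix(df[FEATURE_COLUMNS], labels, {"source": str(path)})


def save_model(model, path) -> Path:
    joblib.dump(model, path)
    return Path(path)


def load_model(path):
    return joblib.load(path)


@dataclass
class RunConfig:
    """End-to-end pipeline settings; flags override the config file."""

    seed: int = 0
    out_dir: str = "porescreen_out"
    threshold_sd: float = 4.0
    hysteresis: float = 0.5
    min_dwell_ms: float = 10.0
    baseline_window_ms: float = 500.0
    preset: str = "fresh_juice"
    screening: ScreeningParams | None = None
    classifier_path: str | None = None
    novelty_path: str | None = None
    calibration: dict[str, float] = field(default_factory=dict)  # analyte -> k

    def __post_init__(self) -> None:
        if self.screening is None:
            if self.preset not in SCREENING_PRESETS:
                raise ValueError(f"unknown screening preset {self.preset!r}")
            self.screening = SCREENING_PRESETS[self.preset]

    @staticmethod
    def from_yaml(path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        screening = raw.pop("screening", None)
        cfg = RunConfig(**raw)
        if screening:
            cfg.screening = ScreeningParams(**screening)
        return cfg

    def digest(self) -> str:
        payload = {k: str(v) for k, v in sorted(self.__dict__.items())}
        return hashlib.sha256(json.dumps(payload).encode()).hexdigest()[:12]


def run_pipeline(
    config: RunConfig,
    trace: Trace,
    classifier: ClassifierModel | None = None,
    novelty: NoveltyModel | None = None,
):
    """detect -> features -> screen -> quantify, writing all artifacts.

    Models can be passed directly or loaded from the configured paths.
    Writes the event CSV, feature CSV, spectrum summary, result JSON and a
    run log (seed, parameters, config hash) into ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if classifier is None:
        if not config.classifier_path:
            raise ValueError("no classifier: pass one or set classifier_path")
        classifier = load_model(config.classifier_path)
    if novelty is None:
        if not config.novelty_path:
            raise ValueError("no novelty model: pass one or set novelty_path")
        novelty = load_model(config.novelty_path)

    stage = "detect"
    try:
        baseline = estimate_baseline(trace, config.baseline_window_ms)
        events = filter_events(
            detect_events(trace, baseline, config.threshold_sd, config.hysteresis),
            trace.sampling_rate,
            config.min_dwell_ms,
        )
        write_events_csv(events, trace.sampling_rate, out / "events.csv")

        stage = "features"
        fm = extract_all(trace, events, baseline, provenance={"config": config.digest()})
        write_feature_csv(fm, out / "features.csv")

        stage = "screen"
        result = screen_sample(fm, classifier, novelty, config.screening)
        labeled = fm.subset(result.inlier_mask)
        labeled.labels = result.inlier_labels
        if len(labeled) and len(set(result.inlier_labels)) >= 1:
            try:
                spectrum_summary(labeled).to_csv(out / "spectrum.csv")
            except ValueError:
                logger.warning("spectrum summary skipped (class with n < 2)")

        stage = "quantify"
        t_ms = trace.duration_ms
        concentrations = {}
        counts: dict[str, int] = {}
        for lab in result.inlier_labels:
            counts[str(lab)] = counts.get(str(lab), 0) + 1
        for analyte, k in config.calibration.items():
            if analyte in counts and k > 0:
                concentrations[analyte] = quantify(counts[analyte], k, t_ms)

        payload = {
            "seed": config.seed,
            "config_hash": config.digest(),
            "n_input": int(result.n_input),
            "n_noise": int(result.noise_mask.sum()),
            "n_inliers": int(result.inlier_mask.sum()),
            "n_outliers": int(result.outlier_mask.sum()),
            "proportions": result.proportions,
            "unknown_clusters": {k: len(v) for k, v in result.unknown_registry.items()},
            "event_counts": counts,
            "concentrations_mM": concentrations,
            "recording_time_ms": t_ms,
            "params": {
                "threshold_sd": config.threshold_sd,
                "min_dwell_ms": config.min_dwell_ms,
                "dbscan_eps": config.screening.dbscan_eps,
                "dbscan_min_samples": config.screening.dbscan_min_samples,
                "ocsvm_nu": config.screening.ocsvm_nu,
            },
        }
        with open(out / "result.json", "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
        return result, payload
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
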