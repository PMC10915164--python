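"""Event feature extraction.

Each idealized blockade is summarised by the descriptors used throughout the
analysis: open-pore current I0, residual current Ib, blockage amplitude
dI = Ib - I0, blockage ratio dI/I0, interior standard deviation (pA),
skewness, kurtosis (Pearson convention: Gaussian = 3), dwell time (ms) and
median current. The machine-learning feature vector is the five-tuple
(blockage ratio, std, kurt, skew, dwell); the median is stored but not part
of the vector.

Moments are bias-uncorrected central moments: std = sqrt(m2) with
denominator n, skew = m3 / m2^1.5, kurt = m4 / m2^2. std is computed on
current in pA (not on normalized current).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .detect import BaselineModel, RawEvent, Trace

__all__ = [
    "FEATURE_COLUMNS",
    "EventRecord",
    "FeatureMatrix",
    "compute_event_features",
    "extract_all",
    "spectrum_summary",
]

logger = logging.getLogger(__name__)

#: canonical ML feature order
FEATURE_COLUMNS = ["ratio", "std", "kurt", "skew", "dwell"]


@dataclass(frozen=True)
class EventRecord:
    """Full descriptor set for one event."""

    I0_local: float      # pA
    Ib: float            # pA
    delta_I: float       # pA, Ib - I0_local
    blockage_ratio: float
    std: float           # pA
    kurt: float
    skew: float
    dwell: float         # ms
    med: float           # pA
    start_ms: float = float("nan")

    def feature_vector(self) -> np.ndarray:
        return np.array([self.blockage_ratio, self.std, self.kurt, self.skew, self.dwell])


@dataclass
class FeatureMatrix:
    """Labeled n x 5 event-feature table.

    ``data`` holds the five feature columns in canonical order; ``labels``
    is an optional per-row class label array; ``provenance`` records where
    the rows came from (trace id, detection parameters, generator seed...).
    """

    data: pd.DataFrame
    labels: Optional[np.ndarray] = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in FEATURE_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"feature matrix missing columns {missing}")
        self.data = self.data.reset_index(drop=True)
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
            if self.labels.size != len(self.data):
                raise ValueError("labels length does not match rows")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def values(self) -> np.ndarray:
        """n x 5 array in canonical feature order."""
        return self.data[FEATURE_COLUMNS].to_numpy(dtype=float)

    @property
    def classes(self) -> list[str]:
        if self.labels is None:
            return []
        return sorted(set(self.labels))

    def subset(self, mask: np.ndarray) -> "FeatureMatrix":
        mask = np.asarray(mask)
        if mask.dtype != bool:
            idx = mask
        else:
            idx = np.flatnonzero(mask)
        return FeatureMatrix(
            self.data.iloc[idx],
            None if self.labels is None else self.labels[idx],
            dict(self.provenance),
        )

    @staticmethod
    def concat(parts: list["FeatureMatrix"]) -> "FeatureMatrix":
        data = pd.concat([p.data for p in parts], ignore_index=True)
        if all(p.labels is not None for p in parts):
            labels = np.concatenate([p.labels for p in parts])
        else:
            labels = None
        return FeatureMatrix(data, labels)

    def to_frame(self) -> pd.DataFrame:
        df = self.data.copy()
        if self.labels is not None:
            df["label"] = self.labels
        return df


def _central_moments(x: np.ndarray) -> tuple[float, float, float, float]:
    mean = x.mean()
    d = x - mean
    m2 = np.mean(d ** 2)
    m3 = np.mean(d ** 3)
    m4 = np.mean(d ** 4)
    return mean, m2, m3, m4


def compute_event_features(
    trace: Trace,
    event: RawEvent,
    baseline: BaselineModel,
    edge_exclusion_ms: float = 2.0,
    pre_window_ms: float = 50.0,
) -> EventRecord:
    """Compute the descriptor set for one (dwell-filtered) event.

    The first/last ``edge_exclusion_ms`` of the event are excluded from the
    interior statistics. The default (2 ms) covers the full settle of a
    zero-phase 1 kHz low-pass edge *plus* the detector opening early on the
    transition: higher moments, kurtosis especially, are exquisitely
    sensitive to any leftover edge transient. ``I0_local`` is the baseline level averaged over a
    ``pre_window_ms`` window preceding the event, which tolerates slow drift
    of the open-pore current.
    """
    fs = trace.sampling_rate
    edge = int(round(edge_exclusion_ms * fs / 1e3))
    lo, hi = event.start_index + edge, event.end_index - edge
    interior = trace.samples[lo:hi]
    if interior.size < 3:
        raise ValueError(
            f"event interior has {interior.size} samples after edge exclusion; need >= 3"
        )
    pre = int(round(pre_window_ms * fs / 1e3))
    w0 = max(0, event.start_index - pre)
    window = baseline.level[w0:event.start_index]
    I0_local = float(window.mean()) if window.size else float(baseline.level[event.start_index])

    Ib, m2, m3, m4 = _central_moments(interior)
    std = float(np.sqrt(m2))
    if m2 <= 0.0:
        logger.warning("degenerate event interior (zero variance); skew := 0, kurt := 3")
        skew, kurt = 0.0, 3.0
    else:
        skew = float(m3 / m2 ** 1.5)
        kurt = float(m4 / m2 ** 2)
    delta_I = float(Ib - I0_local)
    return EventRecord(
        I0_local=I0_local,
        Ib=float(Ib),
        delta_I=delta_I,
        blockage_ratio=delta_I / I0_local,
        std=std,
        kurt=kurt,
        skew=skew,
        dwell=event.dwell_ms(fs),
        med=float(np.median(interior)),
        start_ms=event.start_index / fs * 1e3,
    )


def extract_all(
    trace: Trace,
    events: list[RawEvent],
    baseline: BaselineModel,
    edge_exclusion_ms: float = 2.0,
    provenance: dict | None = None,
) -> FeatureMatrix:
    """One feature row per event, order preserved; failing events are skipped
    with a warning."""
    rows = []
    for i, ev in enumerate(events):
        try:
            rec = compute_event_features(trace, ev, baseline, edge_exclusion_ms)
        except ValueError as exc:
            logger.warning("skipping event %d: %s", i, exc)
            continue
        rows.append(
            {
                "ratio": rec.blockage_ratio,
                "std": rec.std,
                "kurt": rec.kurt,
                "skew": rec.skew,
                "dwell": rec.dwell,
                "I0_pA": rec.I0_local,
                "Ib_pA": rec.Ib,
                "med": rec.med,
                "start_ms": rec.start_ms,
            }
        )
    cols = FEATURE_COLUMNS + ["I0_pA", "Ib_pA", "med", "start_ms"]
    df = pd.DataFrame(rows, columns=cols)
    prov = {"n_events_in": len(events), "edge_exclusion_ms": edge_exclusion_ms}
    prov.update(provenance or {})
    return FeatureMatrix(df, None, prov)


def spectrum_summary(matrix: FeatureMatrix) -> pd.DataFrame:
    """Per-class (mean, sd) of the five features — the multi-feature spectrum.

    Returns a DataFrame indexed by (class, feature) with columns mean / sd,
    classes in lexicographic order. Every class needs n >= 2.
    """
    if matrix.labels is None:
        raise ValueError("spectrum_summary requires a labeled matrix")
    df = matrix.data[FEATURE_COLUMNS].copy()
    df["label"] = matrix.labels
    counts = df.groupby("label").size()
    small = counts[counts < 2]
    if len(small):
        raise ValueError(f"classes with fewer than 2 events: {list(small.index)}")
    g = df.groupby("label")[FEATURE_COLUMNS]
    out = pd.concat({"mean": g.mean(), "sd": g.std(ddof=1)}, axis=1)
    out = out.swaplevel(axis=1).sort_index(axis=1).sort_index()
    stacked = out.stack(level=0, future_stack=True)
    stacked.index.names = ["class", "feature"]
    # preserve canonical feature order inside each class
    stacked = stacked.reindex(
        pd.MultiIndex.from_product([sorted(counts.index), FEATURE_COLUMNS]),
    )
    stacked.index.names = ["class", "feature"]
    return stacked[["mean", "sd"]]
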