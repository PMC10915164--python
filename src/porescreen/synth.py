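"""Synthetic single-channel recordings and feature-space event samples.

The generator emulates the statistical structure of reversible single-site
capture by an engineered nanopore carrying one boronic-acid adapter:

* exclusive occupancy — one analyte bound at a time, so events never overlap;
  capture is a renewal process with exponential open intervals at total rate
  lambda = sum_i k_i * C_i (per ms) and exponential dwell times;
* class-specific blockage-ratio sign: alpha-hydroxy acids report
  positive-going events (their charge enhances the pore current), while
  1,2-diphenols, alditols and saccharides are negative-going;
* a single event type per class except the saccharides, which carry two or
  more sub-states (pyranose/furanose interconversion in solution);
* event features independent of concentration — only the event rate scales
  with C, which is what makes count-based quantification possible;
* non-clustered background noise events with a uniform blockage ratio and
  log-uniform dwell.

Intra-event noise is a centred sinh-arcsinh transformed Gaussian, giving
independent analytic control of the std / skew / kurt signature of each
class (see :mod:`porescreen.sas`). Fixture constants are designed for sign,
multi-state structure and class separability; they are not quantitative
reproductions of any measured analyte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .detect import Trace
from .features import FEATURE_COLUMNS, FeatureMatrix
from .sas import sas_sample, sas_stats

__all__ = [
    "SubState",
    "AnalyteModel",
    "MixtureSpec",
    "TraceSpec",
    "GroundTruthRecord",
    "GroundTruth",
    "make_default_panel",
    "panel_by_name",
    "simulate_trace",
    "expected_event_count",
    "simulate_features",
    "BACKGROUND",
]

CATEGORIES = {
    "diphenol",
    "alditol",
    "alpha_hydroxy_acid",
    "saccharide",
    "unknown",
    "background_noise",
}

#: reserved label for non-clustered background noise events
BACKGROUND = "background_noise"

#: documented sampling jitter of the blockage-ratio feature (pore-to-pore and
#: baseline-estimation variation), dimensionless
RATIO_JITTER_SD = 0.004

#: nominal samples per ms used to size the feature-jitter SEs (25 kHz)
SAMPLES_PER_MS = 25.0

#: background-event dwell range (ms), log-uniform
BG_DWELL_RANGE = (5.0, 500.0)
#: background-event blockage-ratio range, uniform
BG_RATIO_RANGE = (-0.9, 0.9)
#: background-event intra-event Gaussian noise scale (pA)
BG_NOISE_SD = 2.5


@dataclass(frozen=True)
class SubState:
    """One event sub-state: occupancy weight, blockage-ratio mean and the
    sinh-arcsinh noise shape (scale pA, skew parameter, tail parameter)."""

    weight: float
    ratio_mean: float
    noise_scale: float   # pA
    skew_param: float
    tail_param: float

    def __post_init__(self) -> None:
        if not (-1.0 < self.ratio_mean < 1.0):
            raise ValueError(f"blockage ratio mean must lie in (-1, 1), got {self.ratio_mean}")
        if self.tail_param <= 0:
            raise ValueError("tail parameter must be > 0")
        if self.noise_scale <= 0:
            raise ValueError("noise scale must be > 0")


@dataclass(frozen=True)
class AnalyteModel:
    """Generative law for one analyte class."""

    name: str
    category: str
    sub_states: tuple[SubState, ...]
    mean_dwell: float            # ms
    calibration_k: float         # events / (mM * ms)

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.mean_dwell <= 0:
            raise ValueError("mean dwell must be > 0")
        if self.calibration_k < 0:
            raise ValueError("calibration coefficient must be >= 0")
        if self.category == BACKGROUND:
            return
        if not self.sub_states:
            raise ValueError("analyte needs at least one sub-state")
        total = sum(s.weight for s in self.sub_states)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"sub-state weights must sum to 1, got {total}")
        if self.category == "alpha_hydroxy_acid":
            if any(s.ratio_mean <= 0 for s in self.sub_states):
                raise ValueError("alpha-hydroxy acids must be positive-going (r > 0)")
        elif self.category in {"diphenol", "alditol", "saccharide"}:
            if any(s.ratio_mean >= 0 for s in self.sub_states):
                raise ValueError(f"{self.category} must be negative-going (r < 0)")
        if self.category in {"diphenol", "alditol", "alpha_hydroxy_acid"}:
            if len(self.sub_states) != 1:
                raise ValueError(f"{self.category} must have exactly one sub-state")
        if self.category == "saccharide" and len(self.sub_states) < 2:
            raise ValueError("saccharides must have >= 2 sub-states")


@dataclass(frozen=True)
class MixtureSpec:
    """(analyte, concentration mM) pairs plus a background event rate."""

    entries: tuple[tuple[str, float], ...]
    background_noise_rate: float = 0.0   # events / ms

    def __post_init__(self) -> None:
        names = [n for n, _ in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("duplicate analyte names in mixture")
        if any(c < 0 for _, c in self.entries):
            raise ValueError("concentrations must be >= 0")
        if self.background_noise_rate < 0:
            raise ValueError("background noise rate must be >= 0")


@dataclass(frozen=True)
class TraceSpec:
    """Acquisition settings of a simulated recording."""

    duration_s: float
    sampling_rate: float = 25_000.0   # Hz
    lowpass_corner: float = 1_000.0   # Hz
    open_pore_current: float = 220.0  # pA
    baseline_noise_sd: float = 2.0    # pA
    bias_mV: float = 160.0            # metadata only

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration must be > 0")
        if self.open_pore_current <= 0:
            raise ValueError("open-pore current must be > 0")
        if self.sampling_rate <= 2.0 * self.lowpass_corner:
            raise ValueError("sampling rate must exceed twice the low-pass corner")


@dataclass(frozen=True)
class GroundTruthRecord:
    start_ms: float
    end_ms: float
    label: str
    sub_state: int

    def __post_init__(self) -> None:
        if self.end_ms <= self.start_ms:
            raise ValueError("event end must exceed start")


@dataclass
class GroundTruth:
    """Time-ordered, non-overlapping list of generated events."""

    records: list[GroundTruthRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        prev_end = -math.inf
        for r in self.records:
            if r.start_ms < prev_end:
                raise ValueError("ground-truth events overlap")
            prev_end = r.end_ms

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.start_ms, r.end_ms, r.label, r.sub_state) for r in self.records],
            columns=["start_ms", "end_ms", "label", "sub_state"],
        )


# ---------------------------------------------------------------------------
# Default fixture panel
#
# Blockage-ratio means are spaced by >= 0.06 against a ratio jitter sd of
# 0.004, i.e. adjacent class means sit >= 4 pooled sd apart in the ratio
# feature alone; skew/tail parameters vary so the moment features differ too.
# name: (category, [(weight, r, sigma_e pA, eps_s, delta_t)], tau ms, k)
# ---------------------------------------------------------------------------
_PANEL_TABLE: dict[str, tuple[str, list[tuple[float, float, float, float, float]], float, float]] = {
    "CAT":   ("diphenol",          [(1.0, -0.20, 2.5,  0.3, 1.0)], 40.0, 0.0004),
    "3-CQA": ("diphenol",          [(1.0, -0.27, 3.0, -0.4, 1.2)], 35.0, 0.0005),
    "D-SOR": ("alditol",           [(1.0, -0.34, 2.2,  0.5, 0.8)], 30.0, 0.0005),
    "XYL":   ("alditol",           [(1.0, -0.41, 2.8, -0.6, 1.4)], 25.0, 0.0005),
    "L-MA":  ("alpha_hydroxy_acid", [(1.0, 0.18, 2.0,  0.4, 1.0)], 30.0, 0.0008),
    "D-MA":  ("alpha_hydroxy_acid", [(1.0, 0.24, 2.0, -0.4, 1.0)], 30.0, 0.0008),
    "L-TA":  ("alpha_hydroxy_acid", [(1.0, 0.31, 2.6,  0.6, 1.2)], 35.0, 0.0008),
    "CA":    ("alpha_hydroxy_acid", [(1.0, 0.38, 3.2, -0.3, 0.9)], 45.0, 0.0002),
    "ICIT":  ("alpha_hydroxy_acid", [(1.0, 0.45, 2.4,  0.2, 1.1)], 40.0, 0.0004),
    "D-GLC": ("saccharide", [(0.6, -0.52, 2.6, 0.3, 1.0), (0.4, -0.60, 3.0, -0.5, 1.3)], 50.0, 0.00012),
    "D-FRU": ("saccharide", [(0.5, -0.68, 2.4, 0.5, 0.9), (0.5, -0.76, 2.9, -0.2, 1.2)], 45.0, 0.00025),
}

_UNKNOWN_TABLE: dict[str, tuple[str, list[tuple[float, float, float, float, float]], float, float]] = {
    "sucrose": ("unknown", [(1.0, -0.85, 2.5,  0.2, 1.0)], 40.0, 0.0005),
    "U1":      ("unknown", [(1.0,  0.60, 2.3, -0.3, 1.1)], 35.0, 0.0005),
    "U2":      ("unknown", [(1.0, -0.92, 2.6,  0.4, 1.0)], 30.0, 0.0005),
    "U3":      ("unknown", [(1.0,  0.72, 2.7,  0.3, 0.9)], 35.0, 0.0005),
}

#: the 11-analyte target roster (enantiomer pair included)
TARGET_CLASSES = list(_PANEL_TABLE)


def _build(name: str, row) -> AnalyteModel:
    category, subs, tau, k = row
    return AnalyteModel(
        name=name,
        category=category,
        sub_states=tuple(SubState(*s) for s in subs),
        mean_dwell=tau,
        calibration_k=k,
    )


def make_default_panel(include_unknowns: bool = False, seed: int = 0) -> list[AnalyteModel]:
    """The default analyte panel: 11 target classes; with ``include_unknowns``
    also sucrose, U1, U2, U3 and a background-noise pseudo-class.

    The panel is a fixed documented fixture; ``seed`` is accepted for
    interface symmetry with the samplers but does not alter the constants.
    """
    models = [_build(n, r) for n, r in _PANEL_TABLE.items()]
    if include_unknowns:
        models += [_build(n, r) for n, r in _UNKNOWN_TABLE.items()]
        bg_tau = (BG_DWELL_RANGE[1] - BG_DWELL_RANGE[0]) / math.log(
            BG_DWELL_RANGE[1] / BG_DWELL_RANGE[0]
        )
        models.append(
            AnalyteModel(BACKGROUND, BACKGROUND, (), mean_dwell=bg_tau, calibration_k=0.0)
        )
    return models


def panel_by_name(panel: list[AnalyteModel]) -> dict[str, AnalyteModel]:
    return {m.name: m for m in panel}


def _bg_mean_dwell() -> float:
    lo, hi = BG_DWELL_RANGE
    return (hi - lo) / math.log(hi / lo)


def _rates(panel: list[AnalyteModel], mixture: MixtureSpec) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Per-stream names, capture rates (per ms) and mean dwells (ms),
    background stream appended last when active."""
    models = panel_by_name(panel)
    names, lam, tau = [], [], []
    for name, conc in mixture.entries:
        if name not in models:
            raise KeyError(f"analyte {name!r} not in panel")
        m = models[name]
        names.append(name)
        lam.append(m.calibration_k * conc)
        tau.append(m.mean_dwell)
    if mixture.background_noise_rate > 0:
        names.append(BACKGROUND)
        lam.append(mixture.background_noise_rate)
        tau.append(_bg_mean_dwell())
    return names, np.asarray(lam, dtype=float), np.asarray(tau, dtype=float)


def expected_event_count(
    panel: list[AnalyteModel], mixture: MixtureSpec, duration_ms: float
) -> dict[str, float]:
    """Expected event counts of the renewal process over ``duration_ms``.

    total = duration / (1/lambda_total + tau_bar) with tau_bar the
    rate-weighted mean dwell; class i receives share p_i = lambda_i /
    lambda_total. The dict includes a ``"total"`` entry. All-zero rates give
    all-zero counts.
    """
    if duration_ms <= 0:
        raise ValueError("duration must be > 0")
    names, lam, tau = _rates(panel, mixture)
    lam_total = lam.sum()
    if lam_total == 0:
        return {**{n: 0.0 for n in names}, "total": 0.0}
    p = lam / lam_total
    tau_bar = float(np.dot(p, tau))
    total = duration_ms / (1.0 / lam_total + tau_bar)
    out = {n: float(pi * total) for n, pi in zip(names, p)}
    out["total"] = float(total)
    return out


def _draw_event_times(
    rng: np.random.Generator,
    names: list[str],
    lam: np.ndarray,
    panel: dict[str, AnalyteModel],
    duration_ms: float,
) -> list[GroundTruthRecord]:
    lam_total = lam.sum()
    if lam_total == 0:
        return []
    p = lam / lam_total
    records: list[GroundTruthRecord] = []
    t = 0.0
    while True:
        t += rng.exponential(1.0 / lam_total)
        if t >= duration_ms:
            break
        idx = rng.choice(len(names), p=p)
        name = names[idx]
        if name == BACKGROUND:
            sub = -1
            lo, hi = BG_DWELL_RANGE
            dwell = math.exp(rng.uniform(math.log(lo), math.log(hi)))
        else:
            model = panel[name]
            weights = np.array([s.weight for s in model.sub_states])
            sub = int(rng.choice(len(weights), p=weights / weights.sum()))
            dwell = rng.exponential(model.mean_dwell)
        end = min(t + dwell, duration_ms)
        if end > t:
            records.append(GroundTruthRecord(t, end, name, sub))
        t = end
    return records


def simulate_trace(
    panel: list[AnalyteModel],
    mixture: MixtureSpec,
    spec: TraceSpec,
    seed: int,
    apply_filter: bool = True,
) -> tuple[Trace, GroundTruth]:
    """Simulate one single-channel recording of an analyte mixture.

    Open intervals are exponential at the total capture rate, the event class
    is drawn proportionally to k_i * C_i, the sub-state by weight, and the
    dwell is exponential with the class mean. Within an event the current is
    I0 * (1 + r) plus centred sinh-arcsinh noise; open-pore samples are
    I0 plus Gaussian baseline noise. With ``apply_filter`` the trace is
    low-pass filtered at the spec corner with a zero-phase 4-pole Bessel
    filter. Same seed => bit-identical output.
    """
    rng = np.random.default_rng(seed)
    models = panel_by_name(panel)
    duration_ms = spec.duration_s * 1e3
    names, lam, _ = _rates(panel, mixture)
    records = _draw_event_times(rng, names, lam, models, duration_ms)

    fs = spec.sampling_rate
    n = int(round(spec.duration_s * fs))
    current = spec.open_pore_current + rng.normal(0.0, spec.baseline_noise_sd, n)
    I0 = spec.open_pore_current
    for r in records:
        i0 = max(0, int(round(r.start_ms / 1e3 * fs)))
        i1 = min(n, int(round(r.end_ms / 1e3 * fs)))
        if i1 <= i0:
            continue
        m = i1 - i0
        if r.label == BACKGROUND:
            ratio = rng.uniform(*BG_RATIO_RANGE)
            noise = rng.normal(0.0, BG_NOISE_SD, m)
        else:
            sub = models[r.label].sub_states[r.sub_state]
            ratio = sub.ratio_mean
            noise = sub.noise_scale * sas_sample(rng, sub.skew_param, sub.tail_param, m)
        current[i0:i1] = I0 * (1.0 + ratio) + noise

    if apply_filter and spec.lowpass_corner:
        sos = signal.bessel(4, spec.lowpass_corner, fs=fs, output="sos")
        current = signal.sosfiltfilt(sos, current)

    trace = Trace(
        samples=current,
        sampling_rate=fs,
        metadata={
            "seed": seed,
            "bias_mV": spec.bias_mV,
            "open_pore_pA": I0,
            "lowpass_corner_hz": spec.lowpass_corner if apply_filter else None,
        },
    )
    return trace, GroundTruth(records)


def _truncated_exp_dwell(rng: np.random.Generator, tau: float, size: int, floor: float = 10.0) -> np.ndarray:
    # memorylessness: Exp(tau) conditioned on > floor  ==  floor + Exp(tau)
    return floor + rng.exponential(tau, size)


def simulate_features(
    panel: list[AnalyteModel],
    counts_per_class: dict[str, int],
    seed: int,
) -> FeatureMatrix:
    """Fast feature-space sampler emulating a labeled training deposit.

    Per event: blockage ratio ~ Normal(r, 0.004); std/skew/kurt are the
    analytic sinh-arcsinh moments of the drawn sub-state plus Gaussian
    sampling jitter with the classical large-sample standard errors at the
    effective sample count implied by the dwell; dwell ~ Exponential(tau)
    truncated to > 10 ms. Deterministic under seed.
    """
    rng = np.random.default_rng(seed)
    models = panel_by_name(panel)
    frames = []
    labels = []
    for name in counts_per_class:
        if name != BACKGROUND and name not in models:
            raise KeyError(f"unknown class {name!r}")
    for name, count in counts_per_class.items():
        if count < 0:
            raise ValueError("counts must be >= 0")
        if count == 0:
            continue
        if name == BACKGROUND:
            lo, hi = 10.5, 800.0
            df = pd.DataFrame(
                {
                    "ratio": rng.uniform(*BG_RATIO_RANGE, count),
                    "std": rng.uniform(1.0, 6.0, count),
                    "kurt": rng.uniform(1.8, 6.0, count),
                    "skew": rng.uniform(-1.5, 1.5, count),
                    "dwell": np.exp(rng.uniform(math.log(lo), math.log(hi), count)),
                }
            )
        else:
            model = models[name]
            weights = np.array([s.weight for s in model.sub_states])
            sub_idx = rng.choice(len(weights), size=count, p=weights / weights.sum())
            dwell = _truncated_exp_dwell(rng, model.mean_dwell, count)
            n_eff = np.maximum(10.0, (dwell - 2.0) * SAMPLES_PER_MS)
            ratio = np.empty(count)
            std = np.empty(count)
            skew = np.empty(count)
            kurt = np.empty(count)
            for j, sub in enumerate(model.sub_states):
                sel = sub_idx == j
                k = int(sel.sum())
                if k == 0:
                    continue
                _, sd_u, g1, g2 = sas_stats(sub.skew_param, sub.tail_param)
                s_pa = sub.noise_scale * sd_u
                ne = n_eff[sel]
                ratio[sel] = rng.normal(sub.ratio_mean, RATIO_JITTER_SD, k)
                std[sel] = s_pa * (1.0 + rng.normal(0.0, np.sqrt((g2 - 1.0) / (4.0 * ne))))
                skew[sel] = g1 + rng.normal(0.0, np.sqrt(6.0 / ne))
                kurt[sel] = g2 + rng.normal(0.0, np.sqrt(24.0 / ne))
            df = pd.DataFrame(
                {"ratio": ratio, "std": np.abs(std), "kurt": kurt, "skew": skew, "dwell": dwell}
            )
        frames.append(df[FEATURE_COLUMNS])
        labels.append(np.full(len(df), name, dtype=object))
    if frames:
        data = pd.concat(frames, ignore_index=True)
        lab = np.concatenate(labels)
    else:
        data = pd.DataFrame(columns=FEATURE_COLUMNS)
        lab = np.array([], dtype=object)
    return FeatureMatrix(data, lab, {"generator": "simulate_features", "seed": seed})
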