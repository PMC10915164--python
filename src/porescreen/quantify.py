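"""Concentration calibration and quantification.

With exclusive single-site capture, the event appearance rate of analyte i
is proportional to its concentration; the calibration coefficient k_i
(events per mM per ms) is the through-origin slope of rate E/t versus C,
and an unknown concentration follows from the event count by

    C_i = E_i / (k_i * t)

with t the total recording time in ms. Using total rather than open-pore
time biases counts low at high occupancy; keeping total occupancy below
~20 % bounds that bias at roughly 10 %, and because calibration and assay
share the counting pipeline the bias largely cancels in the round trip.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CalibrationCurve", "fit_calibration", "quantify", "proportions"]


@dataclass
class CalibrationCurve:
    """Fitted through-origin rate-vs-concentration line for one analyte."""

    analyte: str
    points: pd.DataFrame   # columns C_mM, E_events, t_ms
    k: float               # events / (mM * ms)
    residual_sd: float     # sd of rate residuals, events/ms


def fit_calibration(points, analyte: str = "") -> CalibrationCurve:
    """Least-squares slope through the origin of rate E/t versus C.

    ``points`` is an iterable of (C_mM, E_events, t_ms) or a DataFrame with
    those columns. k = sum(C r) / sum(C^2) with r = E/t. Needs at least two
    points with distinct positive concentrations.
    """
    if isinstance(points, pd.DataFrame):
        df = points[["C_mM", "E_events", "t_ms"]].astype(float).copy()
    else:
        df = pd.DataFrame(list(points), columns=["C_mM", "E_events", "t_ms"], dtype=float)
    if (df["t_ms"] <= 0).any():
        raise ValueError("recording times must be > 0")
    if (df["C_mM"] < 0).any():
        raise ValueError("concentrations must be >= 0")
    pos = df[df["C_mM"] > 0]
    if pos["C_mM"].nunique() < 2:
        raise ValueError("need >= 2 points with distinct positive concentrations")
    rate = df["E_events"] / df["t_ms"]
    c = df["C_mM"]
    k = float((c * rate).sum() / (c ** 2).sum())
    resid = rate - k * c
    return CalibrationCurve(
        analyte=analyte,
        points=df,
        k=k,
        residual_sd=float(resid.std(ddof=1)) if len(df) > 1 else 0.0,
    )


def quantify(E: float, curve: CalibrationCurve | float, t_ms: float) -> float:
    """Concentration (mM) from an event count: C = E / (k * t)."""
    k = curve.k if isinstance(curve, CalibrationCurve) else float(curve)
    if t_ms <= 0:
        raise ValueError("recording time must be > 0")
    if k <= 0:
        raise ValueError("calibration coefficient k must be > 0 to quantify")
    if E < 0:
        raise ValueError("event count must be >= 0")
    return E / (k * t_ms)


def proportions(labels, roster: list[str] | None = None) -> dict[str, float]:
    """Per-class event fractions, summing to 1.

    Classes ordered by ``roster`` when given (extra observed labels appended
    in sorted order), otherwise sorted.
    """
    labels = np.asarray(list(labels), dtype=object)
    if labels.size == 0:
        raise ValueError("empty label vector")
    values, counts = np.unique(labels, return_counts=True)
    frac = {str(v): c / labels.size for v, c in zip(values, counts)}
    if roster is None:
        order = sorted(frac)
    else:
        order = [c for c in roster if c in frac] + sorted(set(frac) - set(roster))
    return {c: frac[c] for c in order}
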