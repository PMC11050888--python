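"""Pulp thermal-injury threshold analysis.

A pulp temperature rise of 5.5 C over the 37 C baseline — i.e. 42.5 C —
is the classical threshold for irreversible pulp damage (Zach-Cohen).  The
sensor traces produced by the solver (or exported by any transient thermal
package) are piecewise-linearly interpolated: on the first sample interval
[t1, t2] whose temperatures bracket the critical value, the line

    T = a + b t,    b = (T2 - T1) / (t2 - t1),    a = T1 - b t1

is fitted exactly through the two samples and inverted at the threshold,

    t_crit = (T_crit - a) / b,

giving the threshold-crossing time.  The comparative summary tabulates, for
the four cavity designs, the composite volume, the crossing time, the peak
pulp temperature, and a recommended safe dry-finishing duration (the
crossing time minus a configurable safety margin, rounded down to whole
seconds).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import (
    DegenerateWindowError,
    IncompleteInputError,
    InsufficientDataError,
    InvalidParameterError,
)
from .geometry import DESIGN_KINDS
from .solver import SensorSeries

__all__ = [
    "CRITICAL_TEMPERATURE_C",
    "SensorSeries",
    "LineFit",
    "ThresholdResult",
    "DesignResult",
    "ComparativeSummary",
    "fit_segment",
    "time_to_threshold",
    "max_temperature",
    "comparative_summary",
]

#: Zach-Cohen irreversible-damage threshold: 37 C baseline + 5.5 C rise.
CRITICAL_TEMPERATURE_C = 42.5


@dataclass(frozen=True)
class LineFit:
    """Exact line through two samples: T = a + b*t."""

    a: float  # intercept, C
    b: float  # slope, C/s
    fit_window: tuple[tuple[float, float], tuple[float, float]]

    def predict(self, t: float) -> float:
        return self.a + self.b * t


@dataclass(frozen=True)
class ThresholdResult:
    """Outcome of a threshold-crossing search.

    ``t_cross`` is ``None`` when the trace never reaches ``T_crit`` within
    its span (``reached`` is then False).  ``fit`` is the line fit of the
    bracketing segment when one was used.
    """

    T_crit: float
    t_cross: float | None
    reached: bool
    fit: LineFit | None = None


def fit_segment(
    p1: tuple[float, float], p2: tuple[float, float]
) -> LineFit:
    """Fit T = a + b*t exactly through two (time, temperature) samples.

    ``b = (T2 - T1)/(t2 - t1)`` and ``a = T1 - b*t1``; requires ``t2 > t1``.
    """
    (t1, T1), (t2, T2) = p1, p2
    if t2 == t1:
        raise DegenerateWindowError(f"degenerate fit window: t1 == t2 == {t1}")
    if t2 < t1:
        raise DegenerateWindowError(
            f"fit window reversed: t1={t1} > t2={t2}"
        )
    b = (T2 - T1) / (t2 - t1)
    a = T1 - b * t1
    return LineFit(a=a, b=b, fit_window=((t1, T1), (t2, T2)))


def time_to_threshold(
    series: SensorSeries, T_crit: float = CRITICAL_TEMPERATURE_C
) -> ThresholdResult:
    """First time the trace reaches ``T_crit``, by segment-wise line fit.

    Scans for the first (earliest) sample interval with
    ``T_i <= T_crit < T_{i+1}`` — an upward crossing — fits the line
    through its endpoints and inverts it at ``T_crit``.  If the very first
    sample already meets or exceeds the threshold its time is returned
    directly; if the trace never reaches the threshold the result carries
    ``reached=False``.
    """
    if not np.isfinite(T_crit):
        raise InvalidParameterError(f"T_crit must be finite, got {T_crit!r}")
    t = series.times
    T = series.temperatures
    if len(t) == 0:
        raise InsufficientDataError("empty sensor series")
    if T[0] >= T_crit:
        return ThresholdResult(T_crit=T_crit, t_cross=float(t[0]), reached=True)
    if len(t) < 2:
        raise InsufficientDataError(
            "series has a single sample below the threshold; "
            "at least two samples are needed to bracket a crossing"
        )
    below = T[:-1] <= T_crit
    above = T[1:] > T_crit
    crossings = np.flatnonzero(below & above)
    if len(crossings) == 0:
        return ThresholdResult(T_crit=T_crit, t_cross=None, reached=False)
    i = int(crossings[0])
    fit = fit_segment((float(t[i]), float(T[i])), (float(t[i + 1]), float(T[i + 1])))
    t_cross = (T_crit - fit.a) / fit.b
    return ThresholdResult(
        T_crit=T_crit, t_cross=float(t_cross), reached=True, fit=fit
    )


def max_temperature(series: SensorSeries) -> tuple[float, float]:
    """Maximum temperature of the trace and its earliest occurrence time."""
    if len(series) == 0:
        raise InsufficientDataError("empty sensor series")
    i = int(np.argmax(series.temperatures))
    return float(series.temperatures[i]), float(series.times[i])


@dataclass(frozen=True)
class DesignResult:
    """Per-design inputs to the comparative summary."""

    design: str
    composite_volume_mm3: float
    pulp_series: SensorSeries


@dataclass
class ComparativeSummary:
    """Four-design comparison table.

    ``table`` has one row per design with columns composite_volume_mm3,
    t_cross_s (NaN when the threshold is not reached), T_max_pulp_C,
    t_max_s and safe_duration_s.
    """

    table: pd.DataFrame
    T_crit: float
    safety_margin_s: float

    def to_json_dict(self) -> dict:
        recs = self.table.reset_index().to_dict(orient="records")
        return {
            "T_crit_C": self.T_crit,
            "safety_margin_s": self.safety_margin_s,
            "designs": recs,
        }


def comparative_summary(
    results: Mapping[str, DesignResult],
    T_crit: float = CRITICAL_TEMPERATURE_C,
    safety_margin_s: float = 0.0,
) -> ComparativeSummary:
    """Tabulate volume, crossing time, peak pulp temperature and a safe
    dry-finishing duration for the four cavity designs.

    The recommended safe duration is ``floor(t_cross - safety_margin)``
    seconds (never negative); a trace that never reaches the threshold gets
    the full trace span as its safe duration.
    """
    missing = [k for k in DESIGN_KINDS if k not in results]
    if missing:
        raise IncompleteInputError(
            f"comparative summary needs all four designs; missing: {missing}"
        )
    rows = []
    for kind in DESIGN_KINDS:
        res = results[kind]
        thr = time_to_threshold(res.pulp_series, T_crit)
        T_max, t_max = max_temperature(res.pulp_series)
        if thr.reached:
            t_cross = thr.t_cross
            safe = max(0.0, math.floor(t_cross - safety_margin_s))
        else:
            t_cross = float("nan")
            safe = float(res.pulp_series.times[-1])
        rows.append(
            {
                "design": kind,
                "composite_volume_mm3": res.composite_volume_mm3,
                "t_cross_s": t_cross,
                "T_max_pulp_C": T_max,
                "t_max_s": t_max,
                "safe_duration_s": safe,
            }
        )
    table = pd.DataFrame(rows).set_index("design")
    return ComparativeSummary(
        table=table, T_crit=T_crit, safety_margin_s=safety_margin_s
    )
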