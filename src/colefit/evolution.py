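"""Analysis of fitted-parameter time series over an ischemia period.

During cold ischemia, extracellular resistance R0 and membrane
capacitance rise over the first hours (extracellular-space compression
and cellular edema) and then decay toward a stationary value as cell
membranes rupture; alpha and R∞ decrease monotonically. The end of the
R0 increase phase is a proposed marker of irreversible tissue damage
("point of no return"); this module operationalizes it as the maximum
of the (optionally smoothed) parameter trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict

import numpy as np
import pandas as pd

__all__ = [
    "EvolutionSeries",
    "EndOfRise",
    "ParameterSummary",
    "detect_end_of_rise",
    "summarize_evolution",
]

#: Minimum record count that satisfies the long-term study protocol.
PROTOCOL_MIN_POINTS = 15


@dataclass
class EvolutionSeries:
    """Time-stamped parameter estimates for one organ.

    `times_hours` are hours since excision, strictly increasing;
    `params` holds one row per time point, one column per parameter.
    """

    times_hours: np.ndarray
    params: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times_hours = np.asarray(self.times_hours, dtype=float)
        if self.times_hours.ndim != 1 or self.times_hours.size < 2:
            raise ValueError("an evolution series needs at least 2 time points")
        if np.any(np.diff(self.times_hours) <= 0.0):
            raise ValueError("timestamps must be strictly increasing")
        if not isinstance(self.params, pd.DataFrame):
            self.params = pd.DataFrame(self.params)
        if len(self.params) != self.times_hours.size:
            raise ValueError("params must have one row per time point")

    @property
    def protocol_ok(self) -> bool:
        return self.times_hours.size >= PROTOCOL_MIN_POINTS

    def __len__(self) -> int:
        return self.times_hours.size


@dataclass
class EndOfRise:
    """Location of the end of a parameter's increase phase."""

    time_hours: float
    index: int
    monotone_flag: bool


@dataclass
class ParameterSummary:
    initial: float
    peak: float
    peak_time: float
    final: float
    net_direction: str  # 'rise-fall' | 'monotone-up' | 'monotone-down' | 'flat'


def _smooth(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with an odd window; edges use the
    symmetric sub-window that fits."""
    if window < 1 or window % 2 == 0:
        raise ValueError("smoothing window must be a positive odd integer")
    if window == 1 or values.size < 3:
        return values.astype(float)
    half = window // 2
    out = np.empty_like(values, dtype=float)
    for i in range(values.size):
        k = min(half, i, values.size - 1 - i)
        out[i] = values[i - k : i + k + 1].mean()
    return out


def _get_column(series: EvolutionSeries, parameter: str) -> np.ndarray:
    if parameter not in series.params.columns:
        raise ValueError(
            f"unknown parameter {parameter!r}; available: "
            f"{list(series.params.columns)}"
        )
    return series.params[parameter].to_numpy(dtype=float)


def detect_end_of_rise(
    series: EvolutionSeries, parameter: str = "r0", smoothing_window: int = 3
) -> EndOfRise:
    """Time at which a parameter's increase phase concludes.

    Returns the time of the maximum of the smoothed trajectory; ties are
    resolved to the earliest time (conservative for viability). When the
    maximum sits on the series boundary — a still-rising or only-falling
    trajectory with no interior maximum — `monotone_flag` is set and the
    boundary time returned.
    """
    if len(series) < 3:
        raise ValueError("end-of-rise detection needs at least 3 time points")
    values = _get_column(series, parameter)
    smoothed = _smooth(values, smoothing_window)
    idx = int(np.argmax(smoothed))  # argmax takes the earliest tie
    return EndOfRise(
        time_hours=float(series.times_hours[idx]),
        index=idx,
        monotone_flag=idx in (0, len(series) - 1),
    )


def _classify(smoothed: np.ndarray, prominence: float) -> str:
    rng = float(np.max(smoothed) - np.min(smoothed))
    scale = max(abs(float(np.max(smoothed))), abs(float(np.min(smoothed))), 1.0)
    if rng <= 1e-12 * scale:
        return "flat"
    idx = int(np.argmax(smoothed))
    rise = smoothed[idx] - smoothed[0]
    fall = smoothed[idx] - smoothed[-1]
    thr = prominence * rng
    if rise <= thr:
        return "monotone-down"
    if fall <= thr:
        return "monotone-up"
    return "rise-fall"


def summarize_evolution(
    series: EvolutionSeries,
    smoothing_window: int = 3,
    prominence: float = 0.2,
) -> Dict[str, ParameterSummary]:
    """Descriptive per-parameter summary of an evolution series.

    `net_direction` is classified on the smoothed trajectory: 'rise-fall'
    requires the peak to stand above both endpoints by more than
    `prominence` × (trajectory range), which keeps estimation noise from
    turning a monotone trajectory into a spurious peak.
    """
    out: Dict[str, ParameterSummary] = {}
    for col in series.params.columns:
        values = series.params[col].to_numpy(dtype=float)
        smoothed = _smooth(values, smoothing_window)
        idx = int(np.argmax(smoothed))
        out[col] = ParameterSummary(
            initial=float(values[0]),
            peak=float(values[idx]),
            peak_time=float(series.times_hours[idx]),
            final=float(values[-1]),
            net_direction=_classify(smoothed, prominence),
        )
    return out
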