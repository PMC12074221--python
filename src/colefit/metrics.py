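"""Accuracy and repeatability statistics for bioimpedance measurements.

Three evaluation tools:

* `relative_error` — per-frequency Euclidean distance in the complex
  impedance plane, normalized by the expected modulus, in percent.
* `residual_sd` — ohm-scale summaries of fit residual magnitudes.
* `reverse_repeatability` — 100 × SD(short-term consecutive estimates) /
  SD(long-term evolution study), per model parameter. Smaller means more
  repeatable: short-term scatter is judged against the full range the
  parameter traverses during an ischemia study, so a small value means
  the device can resolve the temporal evolution.

Standard deviations use the population (÷N) convention throughout;
since reverse repeatability is a ratio of SDs the convention cancels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .fitting import FitResult
from .models import ImpedanceSpectrum

__all__ = [
    "RelativeError",
    "RepeatabilityInput",
    "RepeatabilityReport",
    "relative_error",
    "residual_sd",
    "reverse_repeatability",
    "compare_model_errors",
    "Z0_REPORT_PARAMS",
    "Z2_REPORT_PARAMS",
]

#: Default parameter subsets for repeatability reports.
Z0_REPORT_PARAMS = ("r0", "rinf", "cm", "alpha")
#: The parameters of Z2 most stable in their ischemia dynamics.
Z2_REPORT_PARAMS = ("r0", "cm_lf")


def _as_z(x) -> np.ndarray:
    if isinstance(x, ImpedanceSpectrum):
        return x.z
    return np.asarray(x, dtype=complex).ravel()


@dataclass
class RelativeError:
    """Per-frequency relative error (%) with max/mean aggregates."""

    per_frequency: np.ndarray

    @property
    def max(self) -> float:
        return float(np.max(self.per_frequency))

    @property
    def mean(self) -> float:
        return float(np.mean(self.per_frequency))


def relative_error(measured, reference) -> RelativeError:
    """Complex-plane relative error, percent, per frequency.

    ``100 · |Z_meas(fᵢ) − Z_ref(fᵢ)| / |Z_ref(fᵢ)|``. Inputs are complex
    arrays (or `ImpedanceSpectrum`) on the same grid.
    """
    zm = _as_z(measured)
    zr = _as_z(reference)
    if zm.size != zr.size or zm.size == 0:
        raise ValueError("measured and reference must be non-empty and equal-length")
    mod = np.abs(zr)
    if np.any(mod == 0.0):
        raise ValueError("reference modulus must be non-zero at every frequency")
    return RelativeError(per_frequency=100.0 * np.abs(zm - zr) / mod)


def residual_sd(fit) -> Dict[str, float]:
    """Ohm-scale residual summaries for a fit.

    Accepts a `FitResult` or a residual array; returns the population
    standard deviation, mean and max of the residual magnitudes.
    """
    res = fit.residuals if isinstance(fit, FitResult) else np.asarray(fit)
    res = np.asarray(res).ravel()
    if res.size == 0:
        raise ValueError("residuals are empty")
    mags = np.abs(res)
    return {
        "sd_ohm": float(np.std(mags)),
        "mean_abs_residual_ohm": float(np.mean(mags)),
        "max_abs_residual_ohm": float(np.max(mags)),
    }


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return pd.DataFrame([r.as_dict() if hasattr(r, "as_dict") else dict(r) for r in records])


@dataclass
class RepeatabilityInput:
    """Parameter-estimate records from the two-timescale protocol.

    `short_term`: ≥3 records taken consecutively within a ≤5-minute
    window (probe re-placed between measurements). `long_term`: records
    spanning an evolution study; ≥15 satisfies the study protocol
    (`protocol_ok`), ≥2 is the computational minimum.
    """

    short_term: pd.DataFrame
    long_term: pd.DataFrame

    def __post_init__(self) -> None:
        self.short_term = _as_frame(self.short_term)
        self.long_term = _as_frame(self.long_term)
        if len(self.short_term) < 3:
            raise ValueError("short-term repeatability requires at least 3 records")
        if len(self.long_term) < 2:
            raise ValueError("long-term comparison requires at least 2 records")

    @property
    def protocol_ok(self) -> bool:
        return len(self.short_term) >= 3 and len(self.long_term) >= 15


@dataclass
class RepeatabilityReport:
    """Per-parameter reverse repeatability, percent.

    `values[p]` is NaN when flagged in `undefined` (zero long-term SD).
    `aggregate` is the mean over defined parameters. Values are
    scale-invariant: rescaling a parameter's units rescales both SDs.
    """

    values: Dict[str, float]
    undefined: tuple
    parameters: tuple
    method: str = "population_sd"

    @property
    def aggregate(self) -> float:
        ok = [v for p, v in self.values.items() if p not in self.undefined]
        return float(np.mean(ok)) if ok else math.nan

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": list(self.values),
                "reverse_repeatability_percent": list(self.values.values()),
                "undefined": [p in self.undefined for p in self.values],
            }
        )


def reverse_repeatability(
    inp: RepeatabilityInput, parameters: Sequence[str] | None = None
) -> RepeatabilityReport:
    """Reverse repeatability per parameter: 100·SD_short / SD_long.

    A parameter whose long-term SD is zero is flagged `undefined` (NaN)
    rather than reported as infinity.
    """
    if parameters is None:
        parameters = [
            c for c in inp.short_term.columns if c in inp.long_term.columns
        ]
    missing = [
        p for p in parameters
        if p not in inp.short_term.columns or p not in inp.long_term.columns
    ]
    if missing:
        raise ValueError(f"unknown parameter(s): {missing}")
    values: Dict[str, float] = {}
    undefined = []
    for p in parameters:
        sd_short = float(np.std(inp.short_term[p].to_numpy(dtype=float)))
        sd_long = float(np.std(inp.long_term[p].to_numpy(dtype=float)))
        if sd_long == 0.0:
            values[p] = math.nan
            undefined.append(p)
        else:
            values[p] = 100.0 * sd_short / sd_long
    return RepeatabilityReport(
        values=values, undefined=tuple(undefined), parameters=tuple(parameters)
    )


def compare_model_errors(errors_a, errors_b) -> Dict[str, float]:
    """Paired comparison of per-spectrum error values of two models.

    Returns the mean reduction of b relative to a,
    ``100·(mean(a) − mean(b))/mean(a)``, and the two-sided paired t-test
    p-value on the differences. With zero-variance differences the
    p-value is undefined and flagged (`p_defined` False, p NaN) instead
    of fabricated.
    """
    a = np.asarray(errors_a, dtype=float).ravel()
    b = np.asarray(errors_b, dtype=float).ravel()
    if a.size != b.size or a.size < 2:
        raise ValueError("paired error vectors of equal length >= 2 required")
    reduction = 100.0 * (np.mean(a) - np.mean(b)) / np.mean(a)
    d = a - b
    if np.std(d) == 0.0:
        return {
            "mean_reduction_percent": float(reduction),
            "p_value": math.nan,
            "p_defined": False,
        }
    t = stats.ttest_rel(a, b)
    return {
        "mean_reduction_percent": float(reduction),
        "p_value": float(t.pvalue),
        "p_defined": True,
    }
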