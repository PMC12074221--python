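"""Forward Cole-family impedance models.

Three single-dispersion models of tissue impedance are provided:

``Z0``
    The classic Cole model with a phase-delay correction,
    ``Z0 = [R∞ + (R0 − R∞) / (1 + (jωτ)^α)] · e^(−jωTD)`` with
    ``τ = (RE + RI)·Cm``, ``RE = R0`` and ``RI = R∞R0/(R0 − R∞)``.
``Z1``
    Z0 with a parasitic shunt capacitance CP in parallel with the tissue,
    modelling stray capacitance of probes, cables and ground coupling.
``Z2``
    A Cole variant in which the effective membrane capacitance grows
    linearly with frequency, ``Cm(f) = Cm,LF + A·f``.

All models use the electrical-engineering sign convention (capacitive
reactance has negative imaginary part) and the principal branch for the
fractional power, ``(jωτ)^α = (ωτ)^α · e^(jαπ/2)``, which keeps the
impedance locus on the depressed semicircular arc between R0 and R∞ in
the lower half of the complex plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Union

import numpy as np

__all__ = [
    "FrequencyGrid",
    "ImpedanceSpectrum",
    "ColeParams",
    "Z1Params",
    "Z2Params",
    "ModelParams",
    "derived_ri",
    "impedance_zc",
    "impedance_z0",
    "impedance_z1",
    "impedance_z2",
    "impedance",
    "spectrum",
]

#: Default measurement band: 22 log-spaced frequencies, 5 kHz to 1 MHz.
DEFAULT_F_MIN_HZ = 5_000.0
DEFAULT_F_MAX_HZ = 1_000_000.0
DEFAULT_N_FREQUENCIES = 22


class FrequencyGrid:
    """Ordered set of measurement frequencies in Hz.

    Frequencies must be finite, strictly increasing and positive. The
    default grid is the 22-point logarithmic grid from 5 kHz to 1 MHz
    (inclusive endpoints) used throughout the package.
    """

    __slots__ = ("_f",)

    def __init__(self, frequencies) -> None:
        f = np.asarray(frequencies, dtype=float)
        if f.ndim != 1 or f.size == 0:
            raise ValueError("frequency grid must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(f)):
            raise ValueError("frequency grid contains non-finite values")
        if f[0] <= 0.0:
            raise ValueError("frequencies must be strictly positive")
        if np.any(np.diff(f) <= 0.0):
            raise ValueError("frequencies must be strictly increasing")
        self._f = f
        self._f.setflags(write=False)

    @classmethod
    def default(cls) -> "FrequencyGrid":
        return cls(
            np.geomspace(DEFAULT_F_MIN_HZ, DEFAULT_F_MAX_HZ, DEFAULT_N_FREQUENCIES)
        )

    @property
    def frequencies(self) -> np.ndarray:
        return self._f

    def __len__(self) -> int:
        return self._f.size

    def __iter__(self) -> Iterator[float]:
        return iter(self._f)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FrequencyGrid):
            return NotImplemented
        return self._f.shape == other._f.shape and bool(np.all(self._f == other._f))

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"FrequencyGrid(n={len(self)}, "
            f"{self._f[0]:g}..{self._f[-1]:g} Hz)"
        )


@dataclass
class ImpedanceSpectrum:
    """Complex impedance per frequency, with optional session metadata."""

    frequencies: np.ndarray
    z: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.z = np.asarray(self.z, dtype=complex)
        if self.frequencies.shape != self.z.shape or self.frequencies.ndim != 1:
            raise ValueError("frequencies and z must be 1-D arrays of equal length")

    @property
    def grid(self) -> FrequencyGrid:
        return FrequencyGrid(self.frequencies)

    def __len__(self) -> int:
        return self.frequencies.size


def derived_ri(r0: float, rinf: float) -> float:
    """Intracellular resistance implied by the zero/infinite-frequency limits.

    ``RI = R∞·R0 / (R0 − R∞)``; requires R0 > R∞ > 0.
    """
    if not (rinf > 0.0):
        raise ValueError("model requires R∞ > 0")
    if not (r0 > rinf):
        raise ValueError("model requires R0 > R∞")
    return rinf * r0 / (r0 - rinf)


@dataclass(frozen=True)
class ColeParams:
    """Parameters of the Z0 (Cole) model.

    r0, rinf in ohm; cm in farad; alpha dimensionless in (0, 1];
    td (phase delay) in seconds.
    """

    r0: float
    rinf: float
    cm: float
    alpha: float
    td: float = 0.0

    def __post_init__(self) -> None:
        if not (self.rinf > 0.0 and self.r0 > self.rinf):
            raise ValueError("model requires R0 > R∞ > 0")
        if not (self.cm > 0.0):
            raise ValueError("membrane capacitance must be positive")
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError("alpha must lie in (0, 1]")
        if self.td < 0.0:
            raise ValueError("phase delay TD must be non-negative")

    @property
    def ri(self) -> float:
        return derived_ri(self.r0, self.rinf)

    def as_dict(self) -> dict:
        return {
            "r0": self.r0,
            "rinf": self.rinf,
            "cm": self.cm,
            "alpha": self.alpha,
            "td": self.td,
        }


@dataclass(frozen=True)
class Z1Params:
    """Z0 plus a parasitic shunt capacitance cp (farad); cp = 0 means no shunt."""

    cole: ColeParams
    cp: float = 0.0

    def __post_init__(self) -> None:
        if self.cp < 0.0:
            raise ValueError("parasitic capacitance CP must be non-negative")

    def as_dict(self) -> dict:
        d = self.cole.as_dict()
        d["cp"] = self.cp
        return d


@dataclass(frozen=True)
class Z2Params:
    """Parameters of the frequency-dependent-capacitance model Z2.

    The effective membrane capacitance is ``cm_lf + a·f`` and must stay
    positive over the working band (a may be negative).
    """

    r0: float
    rinf: float
    cm_lf: float
    a: float
    alpha: float
    td: float = 0.0

    def __post_init__(self) -> None:
        if not (self.rinf > 0.0 and self.r0 > self.rinf):
            raise ValueError("model requires R0 > R∞ > 0")
        if not (self.cm_lf > 0.0):
            raise ValueError("low-frequency membrane capacitance must be positive")
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError("alpha must lie in (0, 1]")
        if self.td < 0.0:
            raise ValueError("phase delay TD must be non-negative")

    @property
    def ri(self) -> float:
        return derived_ri(self.r0, self.rinf)

    def effective_cm(self, f) -> np.ndarray:
        return self.cm_lf + self.a * np.asarray(f, dtype=float)

    def as_dict(self) -> dict:
        return {
            "r0": self.r0,
            "rinf": self.rinf,
            "cm_lf": self.cm_lf,
            "a": self.a,
            "alpha": self.alpha,
            "td": self.td,
        }


ModelParams = Union[ColeParams, Z1Params, Z2Params]


def _check_frequency(f: np.ndarray) -> np.ndarray:
    f = np.asarray(f, dtype=float)
    if np.any(f < 0.0):
        raise ValueError("frequency must be non-negative")
    return f


def _cole_core(r0, rinf, cm_eff, alpha, f):
    """Depressed-arc dispersion term, broadcastable over arrays.

    ``R∞ + (R0 − R∞)/(1 + (ω·(RE+RI)·Cm)^α · e^(jαπ/2))`` with
    RE + RI = R0²/(R0 − R∞) recomputed from (R0, R∞) on every call.
    """
    re_plus_ri = r0 * r0 / (r0 - rinf)
    wt = 2.0 * np.pi * f * re_plus_ri * cm_eff
    jwta = np.power(wt, alpha) * np.exp(1j * alpha * np.pi / 2.0)
    return rinf + (r0 - rinf) / (1.0 + jwta)


def impedance_zc(params: ColeParams, f) -> np.ndarray:
    """Cole dispersion ZC (no phase delay) at frequency f (Hz, scalar or array)."""
    f = _check_frequency(f)
    return _cole_core(params.r0, params.rinf, params.cm, params.alpha, f)


def impedance_z0(params: ColeParams, f) -> np.ndarray:
    """Z0 = ZC rotated by the phase delay, e^(−j2πf·TD)."""
    f = _check_frequency(f)
    zc = _cole_core(params.r0, params.rinf, params.cm, params.alpha, f)
    return zc * np.exp(-2j * np.pi * f * params.td)


def impedance_z1(params: Z1Params, f) -> np.ndarray:
    """Z1: ZC in parallel with the shunt ZP = 1/(jωCP), then TD rotation.

    The parallel combination is evaluated as ``ZC / (1 + jωCP·ZC)``, which
    is the analytic limit at CP = 0 (no shunt) and at f = 0 (shunt open),
    so neither case divides by zero.
    """
    f = _check_frequency(f)
    c = params.cole
    zc = _cole_core(c.r0, c.rinf, c.cm, c.alpha, f)
    z = zc / (1.0 + 2j * np.pi * f * params.cp * zc)
    return z * np.exp(-2j * np.pi * f * c.td)


def impedance_z2(params: Z2Params, f) -> np.ndarray:
    """Z2: Cole dispersion with Cm(f) = Cm,LF + A·f, then TD rotation."""
    f = _check_frequency(f)
    cm_eff = params.cm_lf + params.a * f
    if np.any(cm_eff <= 0.0):
        raise ValueError(
            "effective membrane capacitance A·f + Cm,LF must stay positive"
        )
    zm = _cole_core(params.r0, params.rinf, cm_eff, params.alpha, f)
    return zm * np.exp(-2j * np.pi * f * params.td)


def impedance(params: ModelParams, f) -> np.ndarray:
    """Evaluate whichever model `params` belongs to at frequency f."""
    if isinstance(params, ColeParams):
        return impedance_z0(params, f)
    if isinstance(params, Z1Params):
        return impedance_z1(params, f)
    if isinstance(params, Z2Params):
        return impedance_z2(params, f)
    raise TypeError(f"unsupported parameter type: {type(params).__name__}")


def spectrum(
    params: ModelParams,
    grid: FrequencyGrid | None = None,
    metadata: Mapping | None = None,
) -> ImpedanceSpectrum:
    """Vectorized forward evaluation of a model on a frequency grid."""
    if grid is None:
        grid = FrequencyGrid.default()
    z = impedance(params, grid.frequencies)
    return ImpedanceSpectrum(
        frequencies=grid.frequencies.copy(),
        z=z,
        metadata=dict(metadata or {}),
    )


def model_kind_of(params: ModelParams) -> str:
    """Short tag ('Z0' | 'Z1' | 'Z2') for a parameter object."""
    return {"ColeParams": "Z0", "Z1Params": "Z1", "Z2Params": "Z2"}[
        type(params).__name__
    ]
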