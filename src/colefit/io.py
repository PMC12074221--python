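"""Spectrum CSV files and session manifests.

Spectra travel as small human-readable CSV files with the columns
``frequency_hz, z_real_ohm, z_imag_ohm`` and, optionally,
``z_mod_ohm, z_phase_rad``. Lines starting with ``#`` are provenance
comments (seed, config hash); round trips preserve full float
precision. Polar columns, when present, must agree with the cartesian
ones to 1e-9 relative or the file is rejected.
"""

from __future__ import annotations

import cmath
import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .models import ImpedanceSpectrum

__all__ = [
    "SessionManifest",
    "SpectrumParseError",
    "read_spectrum",
    "write_spectrum",
    "config_hash",
]

_REQUIRED_COLUMNS = ("frequency_hz", "z_real_ohm", "z_imag_ohm")
_POLAR_COLUMNS = ("z_mod_ohm", "z_phase_rad")
_POLAR_RTOL = 1e-9


class SpectrumParseError(ValueError):
    """Raised when a spectrum CSV is malformed; names the offending row."""


@dataclass(frozen=True)
class SessionManifest:
    """Measurement-session metadata.

    `graft_id` is the unique numeric organ identifier, `laterality`
    'left' or 'right', `measurement_number` a 1-based ordinal within the
    graft's session sequence, `timestamp` ISO-8601 UTC.
    """

    graft_id: int
    laterality: str
    measurement_number: int
    timestamp: str

    def __post_init__(self) -> None:
        if self.laterality not in ("left", "right"):
            raise ValueError("laterality must be 'left' or 'right'")
        if self.measurement_number < 1:
            raise ValueError("measurement_number must be >= 1")
        if not self.timestamp:
            raise ValueError("timestamp is required on every record")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path) -> "SessionManifest":
        return cls(**json.loads(Path(path).read_text()))


def config_hash(obj) -> str:
    """Short deterministic hash of a JSON-serializable configuration."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def write_spectrum(
    spectrum: ImpedanceSpectrum,
    path,
    include_polar: bool = False,
    provenance: dict | None = None,
) -> None:
    """Write a spectrum as CSV; provenance entries become '#' comments."""
    path = Path(path)
    lines = []
    meta = dict(spectrum.metadata)
    if provenance:
        meta.update(provenance)
    for key in sorted(meta):
        lines.append(f"# {key}={meta[key]}")
    cols = list(_REQUIRED_COLUMNS) + (list(_POLAR_COLUMNS) if include_polar else [])
    lines.append(",".join(cols))
    for f, z in zip(spectrum.frequencies, spectrum.z):
        row = [repr(float(f)), repr(float(z.real)), repr(float(z.imag))]
        if include_polar:
            row += [repr(float(abs(z))), repr(float(cmath.phase(z)))]
        lines.append(",".join(row))
    path.write_text("\n".join(lines) + "\n")


def read_spectrum(path) -> ImpedanceSpectrum:
    """Read a spectrum CSV, validating grid order and polar consistency."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, comment="#", float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise SpectrumParseError(f"{path}: empty spectrum file") from None
    except pd.errors.ParserError as exc:
        raise SpectrumParseError(f"{path}: {exc}") from None
    for col in _REQUIRED_COLUMNS:
        if col not in frame.columns:
            raise SpectrumParseError(f"{path}: missing column {col!r}")
    if len(frame) == 0:
        raise SpectrumParseError(f"{path}: no data rows")
    for col in frame.columns:
        numeric = pd.to_numeric(frame[col], errors="coerce")
        if numeric.isna().any():
            row = int(numeric.isna().idxmax()) + 2  # 1-based + header line
            raise SpectrumParseError(f"{path}: malformed value in row {row}")
        frame[col] = numeric

    f = frame["frequency_hz"].to_numpy(dtype=float)
    diffs = np.diff(f)
    if np.any(diffs == 0.0):
        row = int(np.flatnonzero(diffs == 0.0)[0]) + 3
        raise SpectrumParseError(f"{path}: duplicated frequency at row {row}")
    if np.any(diffs < 0.0):
        row = int(np.flatnonzero(diffs < 0.0)[0]) + 3
        raise SpectrumParseError(f"{path}: descending frequency at row {row}")

    z = frame["z_real_ohm"].to_numpy(float) + 1j * frame["z_imag_ohm"].to_numpy(float)
    if all(c in frame.columns for c in _POLAR_COLUMNS):
        mod = frame["z_mod_ohm"].to_numpy(float)
        phase = frame["z_phase_rad"].to_numpy(float)
        zp = mod * np.exp(1j * phase)
        scale = np.maximum(np.abs(z), 1e-300)
        bad = np.abs(zp - z) / scale > _POLAR_RTOL
        if np.any(bad):
            row = int(np.flatnonzero(bad)[0]) + 2
            raise SpectrumParseError(
                f"{path}: polar columns inconsistent with cartesian at row {row}"
            )
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
    return ImpedanceSpectrum(frequencies=f, z=z, metadata=meta)
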