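"""Sweep container and on-disk format.

A sweep is one stimulus epoch: injected current and recorded (or simulated)
membrane voltage on a common time base.  In memory everything is SI (amperes,
volts, seconds); on disk a sweep is a two-column CSV (current, voltage) with
a JSON sidecar (``<name>.json`` next to ``<name>.csv``) declaring the
sampling rate, units, and any epoch annotations.  Declared units such as
pA/mV are converted to SI on read.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Sweep", "SweepFormatError", "write_sweep", "read_sweep", "read_sweep_set"]

CURRENT_UNITS = {"A": 1.0, "mA": 1e-3, "uA": 1e-6, "nA": 1e-9, "pA": 1e-12}
VOLTAGE_UNITS = {"V": 1.0, "mV": 1e-3, "uV": 1e-6}


class SweepFormatError(ValueError):
    """Raised for malformed sweep files (missing header fields, bad lengths)."""


@dataclass
class Sweep:
    fs: float  # Hz
    current: np.ndarray  # amperes
    voltage: np.ndarray  # volts
    t0: float = 0.0
    name: str = "sweep"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.current = np.asarray(self.current, dtype=float)
        self.voltage = np.asarray(self.voltage, dtype=float)
        if self.fs <= 0:
            raise SweepFormatError("fs must be positive")
        if self.current.shape != self.voltage.shape:
            raise SweepFormatError("current and voltage must have equal length")

    @property
    def n_samples(self) -> int:
        return int(self.current.size)

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def time(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs


def write_sweep(
    sweep: Sweep,
    path: str | Path,
    current_unit: str = "pA",
    voltage_unit: str = "mV",
) -> Path:
    """Write ``<path>.csv`` plus ``<path>.json`` sidecar; returns the CSV path."""
    path = Path(path)
    if path.suffix == ".csv":
        path = path.with_suffix("")
    csv_path = path.with_suffix(".csv")
    data = np.column_stack(
        [sweep.current / CURRENT_UNITS[current_unit], sweep.voltage / VOLTAGE_UNITS[voltage_unit]]
    )
    np.savetxt(csv_path, data, delimiter=",", header="current,voltage", comments="")
    sidecar = {
        "fs_hz": sweep.fs,
        "t0_s": sweep.t0,
        "name": sweep.name,
        "units": {"current": current_unit, "voltage": voltage_unit},
        "annotations": _jsonable(sweep.meta),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return csv_path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def read_sweep(path: str | Path) -> Sweep:
    """Read one sweep (CSV + JSON sidecar) and convert to SI units."""
    csv_path = Path(path).with_suffix(".csv")
    side_path = Path(path).with_suffix(".json")
    if not csv_path.exists():
        raise FileNotFoundError(csv_path)
    if not side_path.exists():
        raise SweepFormatError(f"missing sidecar {side_path.name} declaring fs and units")
    sidecar = json.loads(side_path.read_text())
    if "fs_hz" not in sidecar:
        raise SweepFormatError("sidecar missing required field 'fs_hz'")
    if "units" not in sidecar:
        raise SweepFormatError("sidecar missing required field 'units'")
    units = sidecar["units"]
    try:
        cu = CURRENT_UNITS[units["current"]]
        vu = VOLTAGE_UNITS[units["voltage"]]
    except KeyError as exc:
        raise SweepFormatError(f"unknown unit in sidecar: {exc}") from exc
    data = np.loadtxt(csv_path, delimiter=",", skiprows=1, ndmin=2)
    if data.shape[1] != 2:
        raise SweepFormatError("sweep CSV must have exactly two columns")
    return Sweep(
        fs=float(sidecar["fs_hz"]),
        current=data[:, 0] * cu,
        voltage=data[:, 1] * vu,
        t0=float(sidecar.get("t0_s", 0.0)),
        name=sidecar.get("name", csv_path.stem),
        meta=sidecar.get("annotations", {}),
    )


def read_sweep_set(path: str | Path) -> list[Sweep]:
    """Read a directory of sweeps (or a single sweep file) into a list."""
    path = Path(path)
    if path.is_dir():
        return [read_sweep(p) for p in sorted(path.glob("*.csv"))]
    return [read_sweep(path)]
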