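"""Electrode-position data model and polar/Cartesian coordinate transforms.

Cochlear-implant electrode positions are reported in a polar coordinate system
whose origin is the mid-modiolar axis (the central axis of the cochlear
spiral): the electrode-to-modiolar-axis distance EMD (mm) is the radius and
the angular depth of insertion aDOI (degrees, 0 deg at the round window) is
the angle. Because an inserted array can pass a full cochlear turn, aDOI is a
*multi-turn* angle and may exceed 360 deg; converting Cartesian coordinates
back to polar therefore needs an unwrapping step that restores the turn count
from the basal-to-apical ordering of the electrodes.

All public interfaces use degrees; radians are used only inside the
trigonometric calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DegeneratePositionError, InvalidMeasurementError

__all__ = [
    "AxisShift",
    "ElectrodeArrayMeasurement",
    "CartesianElectrodes",
    "to_cartesian",
    "apply_shift",
    "to_polar",
    "unwrap_angles",
    "transform_measurement",
    "read_measurements_csv",
    "write_measurements_csv",
    "MEASUREMENT_CSV_COLUMNS",
]

#: Column schema of the measurement CSV (one row per array/method/electrode).
MEASUREMENT_CSV_COLUMNS = ("array_id", "method", "electrode", "emd_mm", "adoi_deg")


@dataclass(frozen=True)
class AxisShift:
    """Uniform 2-D translation of electrode coordinates (mm).

    Represents a candidate displacement between two selections of the
    mid-modiolar axis. Shifting every electrode of one measurement set by the
    same vector is equivalent to re-measuring that set from a differently
    chosen axis; the round-window 0 deg reference direction is held fixed.
    """

    shift_x: float
    shift_y: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.shift_x) and np.isfinite(self.shift_y)):
            raise InvalidMeasurementError("axis shift components must be finite")

    @property
    def norm(self) -> float:
        return float(np.hypot(self.shift_x, self.shift_y))


def _as_float_array(values: Iterable[float], name: str) -> np.ndarray:
    arr = np.asarray(list(values) if not isinstance(values, np.ndarray) else values,
                     dtype=float)
    if arr.ndim != 1:
        raise InvalidMeasurementError(f"{name} must be one-dimensional")
    return arr


@dataclass(frozen=True)
class ElectrodeArrayMeasurement:
    """One method's polar measurements for the electrodes of one array.

    Electrodes are ordered basal to apical (ascending electrode number for a
    22-contact perimodiolar array, E22 most apical). Only a subset of the 22
    contacts is typically measured (E1 and the even electrodes E2-E22).

    Invariants enforced at construction: unique, strictly increasing electrode
    numbers; EMD finite and > 0; aDOI finite, >= 0 and < 720 deg.
    """

    array_id: str
    method_label: str
    electrode_numbers: tuple[int, ...]
    emd: np.ndarray = field(repr=False)
    adoi: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        numbers = tuple(int(e) for e in self.electrode_numbers)
        object.__setattr__(self, "electrode_numbers", numbers)
        emd = _as_float_array(self.emd, "emd")
        adoi = _as_float_array(self.adoi, "adoi")
        emd.setflags(write=False)
        adoi.setflags(write=False)
        object.__setattr__(self, "emd", emd)
        object.__setattr__(self, "adoi", adoi)

        n = len(numbers)
        if n == 0:
            raise InvalidMeasurementError("measurement has no electrodes")
        if len(emd) != n or len(adoi) != n:
            raise InvalidMeasurementError("emd/adoi length mismatch with electrodes")
        if len(set(numbers)) != n:
            raise InvalidMeasurementError("duplicate electrode numbers")
        if any(b <= a for a, b in zip(numbers, numbers[1:])):
            raise InvalidMeasurementError(
                "records must be ordered by increasing electrode number")
        if not all(1 <= e <= 22 for e in numbers):
            raise InvalidMeasurementError("electrode numbers must lie in 1..22")
        if not np.all(np.isfinite(emd)) or np.any(emd <= 0):
            raise InvalidMeasurementError("emd must be finite and > 0 (mm)")
        if not np.all(np.isfinite(adoi)) or np.any(adoi < 0) or np.any(adoi >= 720):
            raise InvalidMeasurementError("adoi must be finite, >= 0 and < 720 deg")

    def __len__(self) -> int:
        return len(self.electrode_numbers)

    def with_values(self, emd: np.ndarray, adoi: np.ndarray,
                    method_label: str | None = None) -> "ElectrodeArrayMeasurement":
        """Copy with replaced EMD/aDOI values (same array and electrodes)."""
        return ElectrodeArrayMeasurement(
            array_id=self.array_id,
            method_label=self.method_label if method_label is None else method_label,
            electrode_numbers=self.electrode_numbers,
            emd=np.asarray(emd, dtype=float),
            adoi=np.asarray(adoi, dtype=float),
        )


@dataclass(frozen=True)
class CartesianElectrodes:
    """Planar electrode coordinates relative to a candidate mid-modiolar axis.

    The origin is the axis; +x points toward the round-window reference
    direction (aDOI = 0 deg). Units are millimetres.
    """

    array_id: str
    electrode_numbers: tuple[int, ...]
    x: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)
    method_label: str = ""

    def __post_init__(self) -> None:
        numbers = tuple(int(e) for e in self.electrode_numbers)
        object.__setattr__(self, "electrode_numbers", numbers)
        x = _as_float_array(self.x, "x")
        y = _as_float_array(self.y, "y")
        x.setflags(write=False)
        y.setflags(write=False)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if len(x) != len(numbers) or len(y) != len(numbers):
            raise InvalidMeasurementError("x/y length mismatch with electrodes")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise InvalidMeasurementError("coordinates must be finite")

    def __len__(self) -> int:
        return len(self.electrode_numbers)


def to_cartesian(meas: ElectrodeArrayMeasurement) -> CartesianElectrodes:
    """Convert polar measurements to planar coordinates.

    x_i = EMD_i * cos(aDOI_i), y_i = EMD_i * sin(aDOI_i), with aDOI converted
    from degrees to radians. Multi-turn angles wrap naturally through the
    periodicity of cos/sin; electrode order is preserved.
    """
    theta = np.deg2rad(meas.adoi)
    return CartesianElectrodes(
        array_id=meas.array_id,
        electrode_numbers=meas.electrode_numbers,
        x=meas.emd * np.cos(theta),
        y=meas.emd * np.sin(theta),
        method_label=meas.method_label,
    )


def apply_shift(cart: CartesianElectrodes, shift: AxisShift) -> CartesianElectrodes:
    """Translate every electrode by the same (shift_x, shift_y) vector."""
    return CartesianElectrodes(
        array_id=cart.array_id,
        electrode_numbers=cart.electrode_numbers,
        x=cart.x + shift.shift_x,
        y=cart.y + shift.shift_y,
        method_label=cart.method_label,
    )


def unwrap_angles(raw_adoi: Sequence[float] | np.ndarray, *,
                  basal_to_apical: bool = True) -> np.ndarray:
    """Restore multi-turn insertion angles from wrapped per-electrode angles.

    The input is one angle per electrode, ordered from the most basal to the
    most apical electrode (set ``basal_to_apical=False`` for the reverse
    ordering). Two steps:

    1. every angle is reduced modulo 360 deg into [0, 360);
    2. a *wrap event* is a consecutive pair whose first angle lies in
       [270, 360] deg and whose second lies in [0, 90] deg — the signature of
       the trajectory passing the round-window direction into the next turn.
       Each electrode gains 360 deg for every wrap event that precedes it.

    For electrode arrays spanning less than ~540 deg (one wrap event at most)
    this equals the simpler rule of adding 360 deg once to everything after
    the first wrap. Non-monotone pathological sequences are passed through
    with the literal rule applied, not rejected.
    """
    raw = np.asarray(raw_adoi, dtype=float)
    if raw.ndim != 1:
        raise InvalidMeasurementError("raw_adoi must be one-dimensional")
    if not np.all(np.isfinite(raw)):
        raise InvalidMeasurementError("raw_adoi must be finite")
    if not basal_to_apical:
        return unwrap_angles(raw[::-1])[::-1]
    wrapped = np.mod(raw, 360.0)
    if len(wrapped) == 1:
        return wrapped
    events = (wrapped[:-1] >= 270.0) & (wrapped[1:] <= 90.0)
    turns = np.concatenate(([0.0], np.cumsum(events, dtype=float)))
    return wrapped + 360.0 * turns


def to_polar(cart: CartesianElectrodes, *,
             basal_to_apical: bool = True) -> ElectrodeArrayMeasurement:
    """Convert planar coordinates back to polar (EMD, multi-turn aDOI).

    EMD_i = sqrt(x_i^2 + y_i^2); the raw angle is atan2(y_i, x_i), then
    :func:`unwrap_angles` restores the turn count. Raises
    :class:`DegeneratePositionError` if any electrode sits exactly on the axis
    (x = y = 0), where the angle is undefined.
    """
    emd, adoi = _polar_arrays(cart.x, cart.y, basal_to_apical=basal_to_apical)
    return ElectrodeArrayMeasurement(
        array_id=cart.array_id,
        method_label=cart.method_label,
        electrode_numbers=cart.electrode_numbers,
        emd=emd,
        adoi=adoi,
    )


def _polar_arrays(x: np.ndarray, y: np.ndarray, *,
                  basal_to_apical: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """EMD/unwrapped-aDOI arrays from coordinates; no data-model validation."""
    emd = np.hypot(x, y)
    if np.any(emd == 0.0):
        raise DegeneratePositionError(
            "electrode coincides with the candidate axis; angle undefined")
    raw = np.rad2deg(np.arctan2(y, x))
    return emd, unwrap_angles(raw, basal_to_apical=basal_to_apical)


def transform_measurement(meas: ElectrodeArrayMeasurement, shift: AxisShift, *,
                          basal_to_apical: bool = True) -> ElectrodeArrayMeasurement:
    """Re-express a measurement after translating its axis-relative coordinates.

    Shorthand for ``to_polar(apply_shift(to_cartesian(meas), shift))``; this is
    the "uniform alteration" applied by the collocation algorithm.
    """
    return to_polar(apply_shift(to_cartesian(meas), shift),
                    basal_to_apical=basal_to_apical)


# ---------------------------------------------------------------------------
# CSV interface


def measurements_to_frame(
        measurements: Iterable[ElectrodeArrayMeasurement]) -> pd.DataFrame:
    """Long-format table with one row per (array, method, electrode)."""
    rows = []
    for m in measurements:
        for e, emd, adoi in zip(m.electrode_numbers, m.emd, m.adoi):
            rows.append((m.array_id, m.method_label, e, emd, adoi))
    return pd.DataFrame(rows, columns=list(MEASUREMENT_CSV_COLUMNS))


def frame_to_measurements(frame: pd.DataFrame) -> list[ElectrodeArrayMeasurement]:
    """Parse a long-format table into per-(array, method) measurements.

    Rows are grouped by (array_id, method) in first-appearance order and
    sorted by electrode number within each group.
    """
    missing = set(MEASUREMENT_CSV_COLUMNS) - set(frame.columns)
    if missing:
        raise InvalidMeasurementError(f"missing columns: {sorted(missing)}")
    out: list[ElectrodeArrayMeasurement] = []
    for (array_id, method), grp in frame.groupby(["array_id", "method"], sort=False):
        grp = grp.sort_values("electrode")
        out.append(ElectrodeArrayMeasurement(
            array_id=str(array_id),
            method_label=str(method),
            electrode_numbers=tuple(int(e) for e in grp["electrode"]),
            emd=grp["emd_mm"].to_numpy(dtype=float),
            adoi=grp["adoi_deg"].to_numpy(dtype=float),
        ))
    return out


def read_measurements_csv(path) -> list[ElectrodeArrayMeasurement]:
    """Read the measurement CSV (header mandatory, UTF-8, decimal point)."""
    return frame_to_measurements(pd.read_csv(path, encoding="utf-8"))


def write_measurements_csv(measurements: Iterable[ElectrodeArrayMeasurement],
                           path) -> None:
    measurements_to_frame(measurements).to_csv(path, index=False, encoding="utf-8")
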