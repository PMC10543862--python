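"""Synthetic cochlear-spiral measurement cohorts.

Generates paired per-electrode measurement sets with the structure the
analysis assumes, so every pipeline stage is testable without patient data:

* a planar log-spiral electrode trajectory ``r(theta) = r0 * exp(-decay *
  theta)`` spanning more than a full cochlear turn, sampled at the measured
  electrode subset (E1 plus the even electrodes of a 22-contact perimodiolar
  array);
* a hidden 2-D offset between the mid-modiolar axes used by the two
  measurement methods (folded-normal magnitude, uniform direction), which
  produces the characteristic partial periodic difference pattern;
* independent Gaussian measurement noise per electrode and parameter,
  calibrated so that two noise-only replicates reproduce the interrater
  precision of +/-0.2 mm (EMD) and +/-10 deg (aDOI) through
  LoA = 1.96 * sqrt(2) * sigma.

Everything is reproducible from the cohort seed; hidden axis offsets are
returned as ground truth for parameter-recovery checks.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DegeneratePositionError
from .measurement import (
    AxisShift,
    CartesianElectrodes,
    ElectrodeArrayMeasurement,
    _polar_arrays,
)

__all__ = [
    "SpiralCohortConfig",
    "Cohort",
    "generate_true_positions",
    "measure_with_axis",
    "generate_cohort",
    "generate_interrater_pair",
    "write_cohort",
    "DEFAULT_ELECTRODES",
]

logger = logging.getLogger(__name__)

#: E1 and the even-numbered electrodes of a 22-contact array: the subset at
#: which EMD/aDOI are measured (12 electrodes).
DEFAULT_ELECTRODES: tuple[int, ...] = (1,) + tuple(range(2, 23, 2))

# noise SDs whose two-replicate limits of agreement (1.96*sqrt(2)*sigma)
# equal the interrater precision of +/-0.2 mm and +/-10 deg
DEFAULT_SIGMA_EMD_MM = 0.0722
DEFAULT_SIGMA_ADOI_DEG = 3.61

EMD_FLOOR_MM = 1e-3


@dataclass(frozen=True)
class SpiralCohortConfig:
    """Generative parameters of a synthetic cohort.

    Defaults emulate the reference study conditions: 50 arrays, 12 measured
    electrodes spanning 20-420 deg of insertion, EMD magnitudes of a
    perimodiolar array (~1.8-2.8 mm), inter-method axis offsets of mean
    0.3 mm, and noise calibrated to the manual interrater precision.
    """

    n_arrays: int = 50
    electrode_numbers: tuple[int, ...] = DEFAULT_ELECTRODES
    adoi_start_deg: float = 20.0
    adoi_end_deg: float = 420.0
    r0_mm: float = 2.8
    decay_per_degree: float = 0.0011046  # r(400 deg) ~= 1.8 mm
    offset_mean_mm: float = 0.3
    offset_sd_mm: float = 0.1
    sigma_emd_mm: float = DEFAULT_SIGMA_EMD_MM
    sigma_adoi_deg: float = DEFAULT_SIGMA_ADOI_DEG
    array_jitter: bool = True  # small per-array variation of span and size
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_arrays < 1:
            raise ConfigError("n_arrays must be >= 1")
        if len(self.electrode_numbers) < 3:
            raise ConfigError("need at least 3 electrodes")
        if not all(1 <= e <= 22 for e in self.electrode_numbers):
            raise ConfigError("electrode numbers must lie in 1..22")
        if list(self.electrode_numbers) != sorted(set(self.electrode_numbers)):
            raise ConfigError("electrode numbers must be strictly increasing")
        if self.r0_mm <= 0:
            raise ConfigError("spiral radius r0 must be > 0")
        if not (0 <= self.adoi_start_deg < self.adoi_end_deg):
            raise ConfigError("need 0 <= adoi_start < adoi_end")
        if self.adoi_end_deg - self.adoi_start_deg >= 540:
            raise ConfigError("array span must be < 540 deg (single wrap event)")
        if self.sigma_emd_mm < 0 or self.sigma_adoi_deg < 0:
            raise ConfigError("noise SDs must be >= 0")
        if self.offset_mean_mm < 0 or self.offset_sd_mm < 0:
            raise ConfigError("offset distribution parameters must be >= 0")
        # exponential law is positive whenever r0 > 0; guard absurd decay that
        # would shrink the spiral below the EMD floor inside the span
        r_end = self.r0_mm * math.exp(-self.decay_per_degree * self.adoi_end_deg)
        if r_end <= EMD_FLOOR_MM:
            raise ConfigError("spiral radius collapses within the aDOI range")

    def radius_at(self, adoi_deg: np.ndarray | float) -> np.ndarray | float:
        return self.r0_mm * np.exp(-self.decay_per_degree * np.asarray(adoi_deg))


def _rng(config: SpiralCohortConfig, array_index: int, stream: int):
    return np.random.default_rng([config.seed, array_index, stream])


def _array_id(array_index: int) -> str:
    return f"array_{array_index + 1:02d}"


def generate_true_positions(config: SpiralCohortConfig,
                            array_index: int) -> CartesianElectrodes:
    """True planar electrode positions of one array, relative to the true axis.

    Electrode angles are evenly spaced over the configured aDOI range at the
    measured electrode subset and radii follow the log-spiral law. With
    ``array_jitter`` enabled, the insertion depth and spiral size vary
    slightly between arrays (deterministically from the seed) so cohort
    arrays are not identical clones.
    """
    n = len(config.electrode_numbers)
    start, end, r0 = config.adoi_start_deg, config.adoi_end_deg, config.r0_mm
    if config.array_jitter:
        rng = _rng(config, array_index, 0)
        end = end + rng.uniform(-15.0, 15.0)
        r0 = r0 * rng.uniform(0.95, 1.05)
    adoi = np.linspace(start, end, n)
    r = r0 * np.exp(-config.decay_per_degree * adoi)
    if np.any(r <= 0):
        raise ConfigError("spiral radius non-positive inside the aDOI range")
    theta = np.deg2rad(adoi)
    return CartesianElectrodes(
        array_id=_array_id(array_index),
        electrode_numbers=config.electrode_numbers,
        x=r * np.cos(theta),
        y=r * np.sin(theta),
    )


def measure_with_axis(true_positions: CartesianElectrodes,
                      axis_offset: AxisShift,
                      sigma_emd_mm: float,
                      sigma_adoi_deg: float,
                      rng: np.random.Generator | int | None,
                      method_label: str) -> ElectrodeArrayMeasurement:
    """Measure an array's polar coordinates from a (possibly offset) axis.

    The candidate axis sits at ``axis_offset`` in the true frame, so
    axis-relative coordinates are the true coordinates minus the offset;
    polar conversion (with angle unwrapping) then yields the noise-free
    measurement, to which independent Gaussian noise is added per electrode.
    EMD is floored at a small positive value and aDOI at zero; clips are
    counted in the log (they only occur under extreme noise settings).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    x = true_positions.x - axis_offset.shift_x
    y = true_positions.y - axis_offset.shift_y
    if np.any(np.hypot(x, y) == 0.0):
        raise DegeneratePositionError("candidate axis coincides with an electrode")
    emd, adoi = _polar_arrays(x, y)
    emd = emd + rng.normal(0.0, sigma_emd_mm, size=emd.shape)
    adoi = adoi + rng.normal(0.0, sigma_adoi_deg, size=adoi.shape)
    n_clip = int(np.sum(emd < EMD_FLOOR_MM) + np.sum(adoi < 0.0))
    if n_clip:
        logger.warning("array %s: clipped %d noisy values at the physical floor",
                       true_positions.array_id, n_clip)
    emd = np.maximum(emd, EMD_FLOOR_MM)
    adoi = np.maximum(adoi, 0.0)
    return ElectrodeArrayMeasurement(
        array_id=true_positions.array_id,
        method_label=method_label,
        electrode_numbers=true_positions.electrode_numbers,
        emd=emd,
        adoi=adoi,
    )


@dataclass(frozen=True)
class Cohort:
    """Paired synthetic measurement sets plus the hidden ground truth."""

    config: SpiralCohortConfig
    manual: tuple[ElectrodeArrayMeasurement, ...]
    auto: tuple[ElectrodeArrayMeasurement, ...]
    truth: pd.DataFrame = field(repr=False)  # array_id, true offsets, seed


def _draw_offset(config: SpiralCohortConfig, array_index: int) -> AxisShift:
    rng = _rng(config, array_index, 1)
    magnitude = abs(rng.normal(config.offset_mean_mm, config.offset_sd_mm))
    direction = rng.uniform(0.0, 2.0 * math.pi)
    return AxisShift(magnitude * math.cos(direction),
                     magnitude * math.sin(direction))


def generate_cohort(config: SpiralCohortConfig) -> Cohort:
    """Simulate the full two-method cohort.

    Per array, the "manual" set is measured from the true axis and the "auto"
    set from an axis displaced by a hidden draw from the offset distribution;
    both sets carry independent measurement noise. Ground-truth offsets are
    returned in the ``truth`` table (the sidecar of the CSV export).
    """
    manual, auto, rows = [], [], []
    for i in range(config.n_arrays):
        true = generate_true_positions(config, i)
        offset = _draw_offset(config, i)
        manual.append(measure_with_axis(
            true, AxisShift(0.0, 0.0), config.sigma_emd_mm,
            config.sigma_adoi_deg, _rng(config, i, 2), "manual"))
        auto.append(measure_with_axis(
            true, offset, config.sigma_emd_mm,
            config.sigma_adoi_deg, _rng(config, i, 3), "auto"))
        rows.append({"array_id": true.array_id,
                     "true_offset_x_mm": offset.shift_x,
                     "true_offset_y_mm": offset.shift_y,
                     "seed": config.seed})
    return Cohort(config=config, manual=tuple(manual), auto=tuple(auto),
                  truth=pd.DataFrame(rows))


def generate_interrater_pair(
        config: SpiralCohortConfig,
        labels: tuple[str, str] = ("manual_rater1", "manual_rater2"),
) -> tuple[list[ElectrodeArrayMeasurement], list[ElectrodeArrayMeasurement]]:
    """Two rater-style replicate sets: same true axis, independent noise only.

    Emulates the interrater study used to set the a-priori agreement criteria;
    the Bland-Altman limits of their differences converge to
    1.96 * sqrt(2) * sigma for each parameter.
    """
    rater_a, rater_b = [], []
    for i in range(config.n_arrays):
        true = generate_true_positions(config, i)
        zero = AxisShift(0.0, 0.0)
        rater_a.append(measure_with_axis(
            true, zero, config.sigma_emd_mm, config.sigma_adoi_deg,
            _rng(config, i, 4), labels[0]))
        rater_b.append(measure_with_axis(
            true, zero, config.sigma_emd_mm, config.sigma_adoi_deg,
            _rng(config, i, 5), labels[1]))
    return rater_a, rater_b


def write_cohort(cohort: Cohort, outdir) -> tuple[str, str]:
    """Write measurements.csv (both methods) and the truth.json sidecar."""
    from pathlib import Path
    from .measurement import write_measurements_csv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    csv_path = outdir / "measurements.csv"
    truth_path = outdir / "truth.json"
    write_measurements_csv(list(cohort.manual) + list(cohort.auto), csv_path)
    with open(truth_path, "w", encoding="utf-8") as fh:
        json.dump({"config": asdict(cohort.config),
                   "arrays": cohort.truth.to_dict(orient="records")},
                  fh, indent=2)
    return str(csv_path), str(truth_path)
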