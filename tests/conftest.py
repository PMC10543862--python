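import numpy as np
import pytest

from modioloc import (
    AxisShift,
    ElectrodeArrayMeasurement,
    SpiralCohortConfig,
    generate_true_positions,
    measure_with_axis,
)


def random_spiral_measurement(rng: np.random.Generator,
                              n_electrodes: int = 12) -> ElectrodeArrayMeasurement:
    """Random valid measurement: monotone multi-turn angles, step < 90 deg.

    Starting angle in [0, 300) with increments in (2, 35) deg keeps the total
    span under 720 deg while frequently crossing 360 deg, so multi-turn
    unwrapping is exercised.
    """
    start = rng.uniform(0.0, 300.0)
    increments = rng.uniform(2.0, 35.0, size=n_electrodes - 1)
    adoi = start + np.concatenate(([0.0], np.cumsum(increments)))
    emd = rng.uniform(1.0, 3.0, size=n_electrodes)
    electrodes = (1,) + tuple(range(2, 2 * n_electrodes, 2))
    return ElectrodeArrayMeasurement(
        array_id="rand", method_label="m", electrode_numbers=electrodes,
        emd=emd, adoi=adoi)


def displaced_pair(offset: AxisShift, seed: int = 0,
                   sigma_emd: float = 0.0, sigma_adoi: float = 0.0):
    """(set1, set2): same true electrodes measured from a displaced axis
    (set1) and the true axis (set2); shifting set1 by +offset restores
    collocation exactly in the noise-free case."""
    config = SpiralCohortConfig(seed=seed, n_arrays=1)
    true = generate_true_positions(config, 0)
    set1 = measure_with_axis(true, offset, sigma_emd, sigma_adoi,
                             np.random.default_rng([seed, 10]), "auto")
    set2 = measure_with_axis(true, AxisShift(0.0, 0.0), sigma_emd, sigma_adoi,
                             np.random.default_rng([seed, 11]), "manual")
    return set1, set2


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
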