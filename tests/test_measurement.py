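"""Coordinate transforms, angle unwrapping and the measurement data model."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from modioloc import (
    AxisShift,
    CartesianElectrodes,
    ElectrodeArrayMeasurement,
    InvalidMeasurementError,
    DegeneratePositionError,
    apply_shift,
    to_cartesian,
    to_polar,
    transform_measurement,
    unwrap_angles,
    read_measurements_csv,
    write_measurements_csv,
)
from conftest import random_spiral_measurement


def meas(emd, adoi, electrodes=None):
    emd = np.atleast_1d(np.asarray(emd, dtype=float))
    if electrodes is None:
        electrodes = tuple(range(1, len(emd) + 1))
    return ElectrodeArrayMeasurement(
        array_id="t", method_label="m", electrode_numbers=electrodes,
        emd=emd, adoi=np.atleast_1d(np.asarray(adoi, dtype=float)))


class TestToCartesian:
    @pytest.mark.parametrize("emd, adoi, x, y", [
        (2.0, 0.0, 2.0, 0.0),
        (1.0, 90.0, 0.0, 1.0),
        (2.0, 450.0, 0.0, 2.0),  # periodicity: 450 deg = 90 deg
        (1.0, 180.0, -1.0, 0.0),
    ])
    def test_known_angles(self, emd, adoi, x, y):
        cart = to_cartesian(meas([emd], [adoi]))
        assert cart.x[0] == pytest.approx(x, abs=1e-12)
        assert cart.y[0] == pytest.approx(y, abs=1e-12)

    def test_rejects_nonpositive_emd(self):
        with pytest.raises(InvalidMeasurementError):
            meas([0.0], [10.0])
        with pytest.raises(InvalidMeasurementError):
            meas([-1.0], [10.0])

    def test_rejects_nonfinite(self):
        with pytest.raises(InvalidMeasurementError):
            meas([np.nan], [10.0])
        with pytest.raises(InvalidMeasurementError):
            meas([1.0], [np.inf])


class TestApplyShift:
    def test_identity_shift(self):
        cart = to_cartesian(meas([1.0, 2.0], [10.0, 50.0]))
        shifted = apply_shift(cart, AxisShift(0.0, 0.0))
        np.testing.assert_array_equal(shifted.x, cart.x)
        np.testing.assert_array_equal(shifted.y, cart.y)

    def test_componentwise_addition(self):
        cart = CartesianElectrodes("t", (1, 2), np.array([1.0, 2.0]),
                                   np.array([3.0, 4.0]))
        out = apply_shift(cart, AxisShift(0.5, -0.5))
        np.testing.assert_allclose(out.x, [1.5, 2.5])
        np.testing.assert_allclose(out.y, [2.5, 3.5])

    def test_shift_to_origin(self):
        cart = CartesianElectrodes("t", (1,), np.array([1.0]), np.array([0.0]))
        out = apply_shift(cart, AxisShift(-1.0, 0.0))
        assert out.x[0] == 0.0 and out.y[0] == 0.0


class TestToPolar:
    @pytest.mark.parametrize("x, y, emd, adoi", [
        (0.0, 1.0, 1.0, 90.0),
        (-1.0, 0.0, 1.0, 180.0),
        (0.0, -2.0, 2.0, 270.0),
    ])
    def test_known_points(self, x, y, emd, adoi):
        cart = CartesianElectrodes("t", (1,), np.array([x]), np.array([y]))
        out = to_polar(cart)
        assert out.emd[0] == pytest.approx(emd, abs=1e-12)
        assert out.adoi[0] == pytest.approx(adoi, abs=1e-12)

    def test_origin_is_degenerate(self):
        cart = CartesianElectrodes("t", (1,), np.array([0.0]), np.array([0.0]))
        with pytest.raises(DegeneratePositionError):
            to_polar(cart)


class TestUnwrapAngles:
    @pytest.mark.parametrize("raw, expected", [
        ([-10.0, 10.0], [350.0, 370.0]),
        ([30.0, 170.0, 300.0], [30.0, 170.0, 300.0]),
        ([200.0, 350.0, 20.0, 80.0], [200.0, 350.0, 380.0, 440.0]),
    ])
    def test_hand_worked_examples(self, raw, expected):
        np.testing.assert_allclose(unwrap_angles(raw), expected)

    def test_full_turn_shift_invariance(self, rng):
        raw = rng.uniform(-180.0, 180.0, size=12)
        np.testing.assert_allclose(unwrap_angles(raw + 360.0),
                                   unwrap_angles(raw), atol=1e-9)

    def test_reverse_ordering_flag(self):
        raw = [80.0, 20.0, 350.0, 200.0]  # apical -> basal
        np.testing.assert_allclose(
            unwrap_angles(raw, basal_to_apical=False),
            [440.0, 380.0, 350.0, 200.0])

    def test_single_element(self):
        np.testing.assert_allclose(unwrap_angles([-45.0]), [315.0])


@settings(max_examples=200, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_round_trip_identity(seed):
    """to_polar(apply_shift(to_cartesian(m), 0)) == m, multi-turn included."""
    m = random_spiral_measurement(np.random.default_rng(seed))
    back = transform_measurement(m, AxisShift(0.0, 0.0))
    np.testing.assert_allclose(back.emd, m.emd, atol=1e-9)
    np.testing.assert_allclose(back.adoi, m.adoi, atol=1e-9)


@settings(max_examples=50, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1),
       st.floats(min_value=-80.0, max_value=80.0))
def test_rotation_acts_only_on_angle(seed, rotation):
    """Rotating the frame leaves EMD unchanged and shifts aDOI by the angle.

    Checked on wrap-free sequences (all angles stay inside one turn after the
    rotation), where the unwrapped angle is the plain polar angle.
    """
    rng = np.random.default_rng(seed)
    adoi = np.sort(rng.uniform(100.0, 260.0, size=8))
    emd = rng.uniform(1.0, 3.0, size=8)
    m = meas(emd, adoi, electrodes=tuple(range(1, 9)))
    rotated = meas(emd, adoi + rotation, electrodes=tuple(range(1, 9)))
    a = transform_measurement(m, AxisShift(0.0, 0.0))
    b = transform_measurement(rotated, AxisShift(0.0, 0.0))
    np.testing.assert_allclose(b.emd, a.emd, atol=1e-9)
    np.testing.assert_allclose(b.adoi - a.adoi, rotation, atol=1e-9)


class TestDataModel:
    def test_duplicate_electrodes_rejected(self):
        with pytest.raises(InvalidMeasurementError):
            meas([1.0, 1.0], [10.0, 20.0], electrodes=(3, 3))

    def test_ordering_enforced(self):
        with pytest.raises(InvalidMeasurementError):
            meas([1.0, 1.0], [10.0, 20.0], electrodes=(4, 2))

    def test_adoi_bounds(self):
        with pytest.raises(InvalidMeasurementError):
            meas([1.0], [-5.0])
        with pytest.raises(InvalidMeasurementError):
            meas([1.0], [720.0])

    def test_csv_round_trip(self, tmp_path, rng):
        measurements = [random_spiral_measurement(rng) for _ in range(3)]
        measurements = [
            ElectrodeArrayMeasurement(f"a{i}", "manual", m.electrode_numbers,
                                      m.emd, m.adoi)
            for i, m in enumerate(measurements)]
        path = tmp_path / "meas.csv"
        write_measurements_csv(measurements, path)
        back = read_measurements_csv(path)
        assert len(back) == 3
        for orig, rt in zip(measurements, back):
            assert rt.array_id == orig.array_id
            assert rt.electrode_numbers == orig.electrode_numbers
            np.testing.assert_allclose(rt.emd, orig.emd, atol=1e-12)
            np.testing.assert_allclose(rt.adoi, orig.adoi, atol=1e-12)
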