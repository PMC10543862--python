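"""Polar <-> Cartesian electrode coordinates and multi-turn angle unwrapping.

Builds a small five-electrode measurement whose insertion angles pass 360 deg,
converts it to planar coordinates relative to the mid-modiolar axis and back,
and shows that the unwrapping step restores the multi-turn angles exactly.
"""

import numpy as np

from modioloc import (
    AxisShift,
    ElectrodeArrayMeasurement,
    to_cartesian,
    to_polar,
    apply_shift,
    unwrap_angles,
)

meas = ElectrodeArrayMeasurement(
    array_id="demo",
    method_label="manual",
    electrode_numbers=(1, 2, 4, 6, 8),
    emd=np.array([2.7, 2.5, 2.3, 2.1, 1.9]),   # mm, shrinking toward the apex
    adoi=np.array([20.0, 130.0, 240.0, 350.0, 430.0]),  # deg, past one turn
)

cart = to_cartesian(meas)
print("x (mm):", np.round(cart.x, 3))
print("y (mm):", np.round(cart.y, 3))

back = to_polar(apply_shift(cart, AxisShift(0.0, 0.0)))
print("round-trip EMD  :", np.round(back.emd, 6))
print("round-trip aDOI :", np.round(back.adoi, 6))
# The 430 deg electrode survives the trip: atan2 alone would report 70 deg,
# the wrap event between 350 and 430 deg restores the extra turn.

print("unwrap [-10, 10]        ->", unwrap_angles([-10.0, 10.0]))
print("unwrap [200,350,20,80]  ->", unwrap_angles([200.0, 350.0, 20.0, 80.0]))
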