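"""Recovering a hidden mid-modiolar axis offset by collocation.

Simulates one array measured twice: once from the true axis ("manual") and
once from an axis displaced by 0.4 mm ("auto"), noise-free. The correlation
cost is zero exactly at the restoring shift, and both the simplex optimiser
and the brute-force grid oracle find it.
"""

import numpy as np

from modioloc import (
    AxisShift,
    SpiralCohortConfig,
    collocation_cost,
    generate_true_positions,
    grid_search_shift,
    measure_with_axis,
    optimize_shift,
)

truth = AxisShift(0.32, -0.24)  # hidden inter-method axis offset (mm)
config = SpiralCohortConfig(seed=7, n_arrays=1)
positions = generate_true_positions(config, 0)
auto = measure_with_axis(positions, truth, 0.0, 0.0, 0, "auto")
manual = measure_with_axis(positions, AxisShift(0.0, 0.0), 0.0, 0.0, 1,
                           "manual")

print("cost at zero shift   :", collocation_cost(auto, manual,
                                                 AxisShift(0.0, 0.0)))
print("cost at true offset  :", collocation_cost(auto, manual, truth))

est = optimize_shift(auto, manual)
print(f"optimiser: shift = ({est.shift.shift_x:+.4f}, "
      f"{est.shift.shift_y:+.4f}) mm, cost = {est.cost:.2e}, "
      f"{est.n_evaluations} evaluations")

grid = grid_search_shift(auto, manual, search_bound=1.0, grid_step=0.05)
print(f"grid oracle: nearest node = ({grid.shift.shift_x:+.2f}, "
      f"{grid.shift.shift_y:+.2f}) mm, cost = {grid.cost:.2e}")

err = np.hypot(est.shift.shift_x - truth.shift_x,
               est.shift.shift_y - truth.shift_y)
print(f"recovery error: {err * 1000:.3f} um")
# The optimiser lands on the hidden offset to micrometre precision; the grid
# search agrees to within one 0.05 mm cell.
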