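"""Derive clinical/biomechanical measurements from tracked points.

Pair distances model cardiac wall measurements (IVS thickness, LV internal
diameter, LVPW thickness); normalised deformation (D - D0)/D0 models muscle
cross-section change; the fascicle construction computes fascicle length and
pennation angle from five tracked points.
"""

import numpy as np

import sonopoint as sp

# -- cardiac-style pair distance + deformation ------------------------------
n = 100
t = np.arange(n) / 50.0
# two points on either side of a "wall" whose thickness oscillates like a
# cardiac cycle (1 Hz), 40 px baseline, +/-6 px excursion
top = sp.Trajectory(0, np.column_stack([np.full(n, 60.0), 40.0 - 3.0 * np.sin(2 * np.pi * t)]))
bottom = sp.Trajectory(1, np.column_stack([np.full(n, 60.0), 80.0 + 3.0 * np.sin(2 * np.pi * t)]))

thickness = sp.pair_distance_series(top, bottom, pitch=75.0, name="wall_thickness")
print(f"wall thickness: {thickness.values.min():.0f}-{thickness.values.max():.0f} um "
      f"({thickness.units}) over {n/50.0:.0f} s")

deform = sp.deformation_series(thickness, reference_frame=0)
print(f"deformation (D-D0)/D0 range: [{deform.values.min():+.3f}, {deform.values.max():+.3f}]")
# 40 px at 75 um/px = 3000 um baseline; +/-6 px excursion is +/-15% deformation.

# -- fascicle length and pennation angle ------------------------------------
theta = 20.0  # true pennation, degrees
d1 = np.array([100.0, 100.0])
fd = d1 + 10.0 * np.array([np.cos(np.radians(theta)), -np.sin(np.radians(theta))])
trajs = {
    0: sp.Trajectory(0, np.array([[50.0, 40.0]])),   # superficial aponeurosis
    1: sp.Trajectory(1, np.array([[150.0, 40.0]])),
    2: sp.Trajectory(2, np.array([d1])),             # deep aponeurosis (fascicle insertion)
    3: sp.Trajectory(3, np.array([[150.0, 100.0]])),
    4: sp.Trajectory(4, np.array([fd])),             # second point along the fascicle
}
spec = sp.MeasurementSpec(
    kind="fascicle",
    roles={"sup_apo_1": 0, "sup_apo_2": 1, "deep_apo_1": 2, "deep_apo_2": 3,
           "fascicle_dir": 4},
)
length, penn = sp.fascicle_metrics(trajs, spec)
print(f"fascicle length: {length.values[0]:.1f} px "
      f"(closed form 60/sin20deg = {60/np.sin(np.radians(20)):.1f})")
print(f"pennation angle: {penn.values[0]:.1f} degrees")
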