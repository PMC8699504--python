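"""Dose-volume histogram metrics for a two-gland geometry.

Builds per-gland DVHs from voxel doses, combines them by volume
weighting, reads off D_mean and V65, and interpolates between a baseline
and a mid-treatment DVH.
"""

import numpy as np

from xerpred.dosimetry import (
    combine_dvhs, d_mean, dvh_from_doses, interpolate_dvh, v_dose,
)

rng = np.random.default_rng(3)
# ipsilateral gland: hot (some voxels above 65 Gy); contralateral: spared
left = dvh_from_doses(
    np.concatenate([rng.normal(40, 5, 900), rng.normal(68, 2, 100)]),
    structure_id="parotid_L", absolute_volume=28.0,
)
right = dvh_from_doses(
    rng.normal(26, 4, 1000), structure_id="parotid_R", absolute_volume=24.0,
)

both = combine_dvhs(left, right)
print(f"left : D_mean {d_mean(left):5.1f} Gy   V65 {v_dose(left, 65):5.1f}%")
print(f"right: D_mean {d_mean(right):5.1f} Gy   V65 {v_dose(right, 65):5.1f}%")
print(f"combined ({both.absolute_volume:.0f} cm^3): "
      f"D_mean {d_mean(both):5.1f} Gy   V65 {v_dose(both, 65):5.1f}%")

# re-planned DVH at the 10th of 35 fractions, slightly hotter
replan = dvh_from_doses(
    np.concatenate([rng.normal(43, 5, 900), rng.normal(69, 2, 110)]),
    structure_id="parotid_L", absolute_volume=27.0,
)
mid = interpolate_dvh(left, replan, f_a=0, f_b=12, f_target=10)
print(f"interpolated at fraction 10: D_mean {d_mean(mid):5.1f} Gy")
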