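"""Define a contralateral ROI from a statistic map and mirror it.

A synthetic group t-map with a hot blob near the left hand-knob landmark
is smoothed at 10 mm FWHM (for definition only); the 70 top-statistic
voxels around the peak nearest the landmark form the contralateral ROI,
and reversing the sign of the world x coordinate yields its ipsilateral
mirror.
"""

import numpy as np

from harold import roi

shape = (32, 32, 32)
affine = np.diag([3.0, 3.0, 3.0, 1.0])
affine[:3, 3] = -3.0 * 16

# blob near the left hand knob (about x=-38, y=-22, z=54 in MNI mm; here
# a symmetric toy frame)
idx = np.indices(shape).reshape(3, -1).T
world = idx @ affine[:3, :3].T + affine[:3, 3]
center = np.array([-36.0, -21.0, 12.0])
rng = np.random.default_rng(0)
tmap = (8 * np.exp(-((world - center) ** 2).sum(1) / (2 * 9.0**2))
        ).reshape(shape) + 0.3 * rng.standard_normal(shape)

smoothed = roi.smooth_map(tmap, affine, fwhm_mm=10.0)
contra = roi.select_roi(smoothed, affine, landmark_mm=center, k=70,
                        hemisphere="left")
ipsi = roi.mirror_roi(contra)

print(f"contralateral ROI: {contra.k} voxels, hemisphere={contra.hemisphere},"
      f" centroid x = {contra.world_coords()[:, 0].mean():.1f} mm")
print(f"ipsilateral ROI:   {ipsi.k} voxels, hemisphere={ipsi.hemisphere},"
      f" centroid x = {ipsi.world_coords()[:, 0].mean():.1f} mm")
print(f"combined (bilateral) model size: {contra.k + ipsi.k} voxels")

beta_map = 0.5 + 0.1 * rng.standard_normal(shape)
print(f"\nexample ROI-mean activation: {roi.roi_mean(beta_map, ipsi):.3f} "
      "(unweighted mean over mask voxels of an unsmoothed beta map)")
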