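"""Suppress per-frame detector jitter with the transposed sliding-window
filter, and compare against zero-phase low-pass baselines.

Per-frame keypoint models jitter by a few pixels frame-to-frame.  The filter
anchors short LK-RSTC tracklets at the noisy estimates and averages all
tracklets covering each frame — using the video's actual motion, which a
pure time-series filter cannot do.
"""

import numpy as np

import sonopoint as sp

scene = sp.make_scene(
    "sinusoid", seed=11, n_frames=300, amplitude=4.0, frequency=3.0,
    track_points=np.array([[128.0, 64.0]]),
)
truth = scene.truth[0]
anchors = sp.simulate_anchor_noise(scene.truth, sigma=2.0, seed=12)

filtered = sp.filter_trajectories(scene.clip, anchors, sp.RSTCFilterConfig())[0]
lp10 = sp.butterworth_filter(anchors[0], 10.0, "lowpass")
lp5 = sp.butterworth_filter(anchors[0], 5.0, "lowpass")

print(f"RMSE vs truth (px):")
print(f"  raw anchors (sigma=2 px jitter): {sp.rmse(truth, anchors[0]):.3f}")
print(f"  10 Hz low-pass baseline:         {sp.rmse(truth, lp10):.3f}")
print(f"  5 Hz low-pass baseline:          {sp.rmse(truth, lp5):.3f}")
print(f"  tracklet filter:                 {sp.rmse(truth, filtered):.3f}")
# The tracklet filter beats both baselines: the 10 Hz cutoff passes too much
# jitter, the 5 Hz cutoff attenuates the genuine 3 Hz motion's harmonics,
# while tracklet averaging removes jitter without touching real motion.

res_raw = anchors[0].with_positions(anchors[0].positions - truth.positions)
res_filt = filtered.with_positions(filtered.positions - truth.positions)
print(f">2 Hz error power: raw {sp.band_power(res_raw, 2.0):.3f} px^2, "
      f"filtered {sp.band_power(res_filt, 2.0):.4f} px^2")
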