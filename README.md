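# sonopoint

Semi-automated point tracking for B-mode ultrasound video.

Tracking arbitrary anatomical points through ultrasound video underlies a
wide range of clinical and biomechanical measurements — cardiac wall
thickness over the heart cycle, muscle cross-section deformation during
movement, fascicle length and pennation angle in pennate muscle.  Two error
modes dominate in practice: sequential optical-flow trackers accumulate
low-frequency **drift**, while per-frame keypoint detectors (CNNs) are
drift-free but produce high-frequency frame-to-frame **jitter**.  This
package combines the two: per-frame estimates serve as trusted anchors, and
short bidirectional optical-flow segments between anchors remove the jitter
while preserving genuine fast tissue motion.

It is a library first (importable API plus `examples/` scripts), with a thin
`sonopoint` command-line interface for the common operations.

## The core algorithm

**LK-RSTC** (Lucas-Kanade with reverse sigmoid tracking correction).  Given
a point's position at two anchor frames, pyramidal Lucas-Kanade optical flow
tracks it forward from the start anchor and in reverse from the end anchor.
At each of the N intermediate frames i = 1..N the two paths are fused with a
logistic weight that trusts the nearer anchor's path:

    fused(i) = (1 − w_i)·P_fwd(i) + w_i·P_rev(i),
    w_i = σ(k·(i/(N+1) − ½)),   σ(z) = 1/(1+e^(−z)),  k = 10 by default.

Because LK drifts little over short horizons and both ends are pinned to
anchors, the fused "tracklet" is accurate everywhere in the window.

**Transposed sliding-window filter.**  To de-jitter a per-frame trajectory,
a window of W = round(0.5 s × fps) frames slides along it frame by frame;
each window position yields one tracklet anchored at the trajectory's values
at the window's end frames.  The final position at any frame is the average
over all tracklets covering that frame — averaging across overlapping
windows (hence "transposed"), not across time.  Interior frames are covered
by W − 2 tracklets, so anchor jitter averages away, while each tracklet
follows the actual image motion, so real high-frequency motion survives —
unlike with a low-pass filter.

The same LK-RSTC primitive densifies sparse manual annotations (one window
per gap between consecutive labels), and plane geometry turns the tracked
points into measurements: pairwise distances, normalised deformation
(D − D₀)/D₀, and fascicle length / pennation angle from line intersections.

A built-in speckle **phantom** renders synthetic B-mode-like videos under
closed-form motion (translation, sinusoid, shear) with exact ground-truth
trajectories and a noisy-anchor simulator, so everything is testable without
any ultrasound data.

## Worked example

```python
import numpy as np
import sonopoint as sp

scene = sp.make_scene("sinusoid", seed=11, n_frames=300, amplitude=4.0,
                      frequency=3.0, track_points=np.array([[128.0, 64.0]]))
truth = scene.truth[0]
anchors = sp.simulate_anchor_noise(scene.truth, sigma=2.0, seed=12)

filtered = sp.filter_trajectories(scene.clip, anchors, sp.RSTCFilterConfig())[0]
print(sp.rmse(truth, anchors[0]), sp.rmse(truth, filtered))
```

Running `python examples/03_filter_jittery_anchors.py` (which adds the
low-pass baselines) prints:

```
RMSE vs truth (px):
  raw anchors (sigma=2 px jitter): 2.780
  10 Hz low-pass baseline:         1.723
  5 Hz low-pass baseline:          1.130
  tracklet filter:                 0.618
>2 Hz error power: raw 3.997 px^2, filtered 0.0102 px^2
```

The simulated detector jitter (σ = 2 px per axis → RMSE ≈ 2.8 px) is cut to
0.62 px by the tracklet filter, beating both zero-phase Butterworth
baselines: the 10 Hz cutoff passes too much jitter, and the 5 Hz cutoff
attenuates real motion.  The >2 Hz error power drops by a factor of ~400.
The other `examples/` scripts cover phantom generation, label densification,
geometry measurements, and the evaluation/statistics tools.

## Command line

```sh
sonopoint simulate --motion sinusoid --frequency 3 --frames 500 --seed 7 --out scene/
sonopoint filter --video scene/scene.npz --anchors scene/anchors.json --out filtered.json
sonopoint augment --video v.npz --layer manual.json --out dense.json
sonopoint evaluate --truth scene/truth.json --candidates filtered.json --pitch 75
sonopoint preftest --a 127 --b 109 --ties 152
sonopoint info / convert / measure / pipeline ...
```

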