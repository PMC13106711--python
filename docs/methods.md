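# Methods

## Problem setting

B-mode ultrasound shows tissue as a speckle pattern — coherent interference
texture that is noise to the eye but a trackable signature to optical flow.
Point tracking in such video suffers two complementary error modes: *drift*
(low-frequency error accumulating along sequential trackers such as
Lucas-Kanade chains) and *jitter* (high-frequency frame-to-frame noise from
per-frame detectors that localise each frame independently).  sonopoint's
premise is that per-frame estimates and short-horizon optical flow cancel
each other's weaknesses: per-frame anchors eliminate drift, optical-flow
tracklets between anchors eliminate jitter.

## LK-RSTC

Given anchors at frames a and b (b ≥ a + 2), the point is tracked with
pyramidal Lucas-Kanade forward from the anchor at a and in reverse from the
anchor at b.  With N = b − a − 1 intermediate frames, frame i ∈ 1..N is
estimated as

    fused(i) = (1 − w_i)·P_fwd(i) + w_i·P_rev(i),
    w_i = σ(k·(i/(N+1) − ½)),  σ(z) = 1/(1+e^(−z)).

Properties honoured by this parameterisation: the weights are strictly
increasing, lie in (0, 1), and are symmetric (w_i + w_{N+1−i} = 1); near the
window start the forward path dominates (w_1 < 0.01 for k = 10, N = 28) and
near the end the reverse path dominates.  The steepness k (default 10,
dimensionless) controls how quickly trust transfers between the paths; the
logistic-on-normalised-position form is this package's choice — any sigmoid
with these boundary properties would serve.

If exactly one path is invalid at a frame, the valid path's estimate is
used; if both are invalid the frame's status flag drops.  This retains as
much data as possible.  The reverse path seeds exactly at the end anchor
(not at the forward path's terminus).

### The Lucas-Kanade solver

The solver is a standard translational pyramidal LK implementation written
on numpy/scipy: a Gaussian image pyramid (σ = 1 blur, decimation by 2,
default 3 levels), per-level Newton iterations minimising the SSD between
the template patch around the point and the target frame, coarse-to-fine
propagation of the displacement, and sub-pixel sampling via bilinear
`map_coordinates`.  Defaults: 21 px patch (spans several speckle grains at
typical B-mode pitch), 30 iterations max, convergence at 0.01 px.  A point
is flagged invalid when it starts or lands outside the image or the patch
structure tensor is near-singular (aperture problem); reaching the
iteration cap with the point still in bounds is treated as valid, which is
common LK practice.  Image pyramids are memoised per clip because the
sliding window revisits every frame ~2W times.

## Transposed sliding-window filter

The filter converts a per-frame (jittery) trajectory into a de-jittered
one.  Window length W = round(window_seconds × fps), default 0.5 s (25
frames at 50 Hz; a 0.6 s window at 50 Hz is 30 frames with 28 intermediate
estimates per tracklet).  Windows start at every `stride` frames (default
1); each window position contributes one LK-RSTC tracklet anchored at the
input trajectory's values at the window's end frames.  The output at frame
t is the arithmetic mean of all valid tracklet estimates covering t;
interior frames are covered by W − 2 tracklets at stride 1.  Frames with no
covering estimate — always the first and last frame, others only on LK
failure — pass the anchor value through.  Invalid estimates are excluded
from the mean rather than imputed; anchors are trusted exactly (tracklet
endpoints pinned).

Tracklets are mutually independent, so any evaluation schedule (including a
parallel one) that reduces contributions in canonical window order yields
bit-identical output; this is tested.

Why it works: anchor jitter at the two ends of each window enters each
tracklet only through its anchors, and averaging W − 2 tracklets with
distinct anchor pairs shrinks that noise roughly as 1/√(W−2); meanwhile
each tracklet follows the actual image motion, so genuine high-frequency
tissue motion is not attenuated the way a low-pass filter would attenuate
it.  The measured behaviour on the phantom (3 Hz, 4 px sinusoid, 50 fps,
500 frames, anchor σ = 2 px): RMSE to truth drops from ≈2.8 px (raw
anchors) to ≈0.6 px, below both the 10 Hz (≈1.7 px) and 5 Hz (≈1.2 px)
zero-phase Butterworth baselines, with >98% of the oscillation amplitude
retained; an 8 Hz motion component at 50 fps survives the filter at full
amplitude while a 5 Hz low-pass removes it almost entirely.

## Label densification

Sparse manual labels (typically ~25 across ~500 frames) are densified by
running one independent LK-RSTC window per gap between consecutive
annotated frames, anchored at the two manual labels.  Manual labels pass
through bit-exactly; nothing is extrapolated before a label's first or
after its last annotation (two anchors are required).  A one-frame gap is a
3-frame window; adjacent annotations need no interpolation.  If LK fails at
some frame inside a gap, that frame falls back to linear interpolation
between the anchors so the output stays dense.  Densification is idempotent.

## Measurements

All geometry treats annotated lines as infinite lines.  Pair distances are
per-frame Euclidean distances (micrometres when a pixel pitch in μm/px is
supplied, e.g. ~75 μm/px for typical B-mode; else pixels).  Deformation is
(D − D₀)/D₀ with D₀ at a user-chosen reference frame (default: the series'
first frame).  For fascicle architecture, five tracked points define three
lines — superficial aponeurosis (2 points), deep aponeurosis (2 points, one
of which is the fascicle's insertion), and the fascicle (insertion point
plus a second point along it).  Fascicle length is the distance between the
fascicle line's intersections with the two aponeurosis lines (closed form
h/sin θ for parallel horizontal aponeuroses h apart and pennation θ);
pennation is the acute angle (degrees, (0, 90]) between the fascicle and
the deep aponeurosis line.  Parallel/degenerate geometry at a frame flags
that frame NaN and processing continues.  Lines are 2-point lines, not
local tangents; intersections may fall outside the annotated segments.

## Synthetic phantom

The phantom emulates what matters for optical-flow tracking — a
band-limited granular texture under smooth sub-pixel motion — and nothing
else.  Textures are seeded white Gaussian noise blurred at the grain scale
(default 2 px) and contrast-stretched over ±3σ to mid-gray 8-bit images
(mean ≈ 128, std ≈ 42).  Motion models (static, constant-velocity
translation, sinusoid of given amplitude/frequency below Nyquist, linear
shear about the image centre) are applied by bicubic inverse warping;
bicubic rather than bilinear because bilinear resampling blurs speckle
enough to bias LK at sub-pixel shifts.  Ground truth is always the motion
model's closed form, never re-estimated from pixels, and rendering is
independently verified by phase correlation between consecutive frames.
Default scene: 128×256 px, 50 Hz, 500 frames — matching common B-mode
capture rates and realistic annotation spans.

The anchor-noise simulator adds i.i.d. Gaussian noise (default σ = 2 px per
frame and axis — a plausible magnitude for per-frame CNN jitter, treated as
a calibration knob, not a claim) and optional linear drift along a seeded
random direction.

What the phantom does *not* emulate: out-of-plane decorrelation, spatially
varying point-spread functions, attenuation/shadowing, nonlinear tissue
deformation, and probe-pressure artifacts.  Passing tests on the phantom
therefore demonstrate the algorithmic properties (jitter suppression,
drift-free interpolation, geometric correctness), not clinical-grade
accuracy on real ultrasound.

A note on the annotation-density experiment: on a *noiseless* phantom LK is
essentially exact regardless of label spacing (errors ~0.01 px), so the
expected error-vs-density relationship does not manifest.  Drift along an
LK chain is driven by frame noise, so that experiment runs with additive
per-frame pixel noise (σ = 10 gray levels on speckle of std ≈ 42) — the
realistic condition — where densification error falls monotonically as
manual labels increase 5 → 15 → 30 over 500 frames.

## Evaluation tools

RMSE is Euclidean-displacement RMSE, sqrt(mean ‖Δ‖²) over frames (not
per-axis).  Trajectory PSD is a Welch estimate per axis (Hann window,
segment length min(256, n), 50% overlap, mean removed), averaged over x and
y; its integral matches the per-axis-mean variance within windowing
tolerance (Parseval).  Low/high-pass baselines are zero-phase
(forward-backward) Butterworth filters of order 4; the forward-backward
pass squares the magnitude response, so a single-pass −3 dB cutoff becomes
amplitude ×½.  Classical smoother baselines (causal constant-velocity
Kalman, its Rauch-Tung-Striebel two-pass smoother, exponential moving
average, Savitzky-Golay) are implemented per axis; these operate on the
time series alone and serve as comparators for the video-aware filter.  The
preference test is the exact two-sided binomial test against 0.5 with ties
excluded and an exact (Clopper-Pearson) 95% CI; counts of 127 vs 109 with
152 ties give proportion 0.538, p = 0.268, CI (0.472, 0.603).

## Design choices where the design was open

* Frame indexing is 0-based with half-open ranges; image coordinates are
  (x right, y down), origin at the top-left pixel centre, sub-pixel
  positions as floats.
* Frames are 8-bit grayscale; higher bit depths would need an explicit
  normalisation policy.
* The lossless interchange container is a frame stack (multipage TIFF or
  NPZ) because codec round-trips are not bit-stable; MP4/AVI are read-only
  and require an imageio codec plugin.
* The annotation JSON schema is
  `{"name", "fps", "labels": {"<frame>": [[label_id, x, y], ...]}}` with
  decimal-string frame keys — human-readable and diff-friendly.  Layer fps
  is stored optionally.
* "Trim" keeps complete frames only: frames carrying every label_id that
  appears anywhere in the layer.
* Keypoint tables use the 3-header-row CSV dialect (scorer / bodyparts /
  coords) with empty cells for missing labels on export and NaN-or-empty
  accepted on import; likelihood columns are read and ignored.
* The per-frame detector stage is a pluggable anchor source (imported
  keypoint table, noisy-anchor simulator, or densified labels); model
  training is out of scope.

## Problem sizes and runtime

The validation experiments use 500-frame 128×256 scenes at 50 Hz with one
tracked point — large enough for ~475 overlapping windows and stable
spectral estimates, small enough that the full test suite runs in ~1.5 min
and the acceptance script in ~35 s on one CPU.  Filtering throughput is
roughly 25–30 frames/s per point at these sizes (pyramid memoisation is
what makes the sliding window affordable).

## Known limitations

* Jitter suppression degrades at low frame rates: fewer frames per window
  means fewer tracklets to average and larger inter-frame displacements for
  LK.
* The filter trusts anchors exactly at window endpoints; systematically
  biased anchors (drift) are *not* corrected, only jitter is.
* Translational LK only: no affine/illumination-robust or M-estimator
  variants; strong rotation or deformation within the patch biases
  estimates.
* Phantom realism limits are listed above; clinical validation on real data
  is outside the package's test scope.
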