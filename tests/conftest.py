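"""Shared fixtures: phantom scenes and derived tracking runs.

The expensive scenes (500-frame sinusoid with the full jitter-filter run,
static scene, densification experiment) are session-scoped so the unit tests
and the acceptance tests share one computation.  All randomness is
seed-pinned; the suite is bit-reproducible.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import sonopoint as sp

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")

#: study conditions for the jitter-suppression experiment: 3 Hz, 4 px
#: sinusoid at 50 fps over 500 frames, anchor jitter sigma = 2 px
SINUSOID_AMPLITUDE = 4.0
SINUSOID_FREQ = 3.0
N_FRAMES = 500
ANCHOR_SIGMA = 2.0
TRACK_POINT = np.array([[128.0, 64.0]])


@pytest.fixture(scope="session")
def sinusoid_scene() -> sp.PhantomScene:
    return sp.make_scene(
        "sinusoid", seed=11, n_frames=N_FRAMES, amplitude=SINUSOID_AMPLITUDE,
        frequency=SINUSOID_FREQ, track_points=TRACK_POINT,
    )


@pytest.fixture(scope="session")
def sinusoid_anchors(sinusoid_scene) -> list[sp.Trajectory]:
    return sp.simulate_anchor_noise(sinusoid_scene.truth, sigma=ANCHOR_SIGMA, seed=12)


@pytest.fixture(scope="session")
def sinusoid_filtered(sinusoid_scene, sinusoid_anchors) -> list[sp.Trajectory]:
    return sp.filter_trajectories(
        sinusoid_scene.clip, sinusoid_anchors, sp.RSTCFilterConfig()
    )


@pytest.fixture(scope="session")
def static_scene() -> sp.PhantomScene:
    return sp.make_scene("static", seed=21, n_frames=150, track_points=TRACK_POINT)


@pytest.fixture(scope="session")
def static_anchors(static_scene) -> list[sp.Trajectory]:
    return sp.simulate_anchor_noise(static_scene.truth, sigma=ANCHOR_SIGMA, seed=22)


@pytest.fixture(scope="session")
def static_filtered(static_scene, static_anchors) -> list[sp.Trajectory]:
    return sp.filter_trajectories(static_scene.clip, static_anchors, sp.RSTCFilterConfig())


@pytest.fixture(scope="session")
def noisy_frame_scene() -> sp.PhantomScene:
    """Sinusoid phantom with per-frame imaging noise: the densification
    test bed (frame noise is what makes long LK chains drift)."""
    return sp.make_scene(
        "sinusoid", seed=31, n_frames=N_FRAMES, amplitude=SINUSOID_AMPLITUDE,
        frequency=SINUSOID_FREQ, track_points=TRACK_POINT, pixel_noise_sigma=10.0,
    )


def sparse_layer_from_truth(truth: sp.Trajectory, n_labels: int) -> sp.AnnotationLayer:
    """Evenly spaced manual annotations sampled from ground truth."""
    frames = np.unique(
        np.round(np.linspace(truth.first_frame, truth.last_frame, n_labels)).astype(int)
    )
    layer = sp.AnnotationLayer(name=f"sparse_{n_labels}", fps=truth.fps)
    for f in frames:
        x, y = truth.at(int(f))
        layer.add(int(f), sp.PointLabel(truth.label_id, float(x), float(y)))
    return layer


@pytest.fixture(scope="session")
def densify_error_curve(noisy_frame_scene) -> dict[int, float]:
    """RMSE of densified labels vs truth for 5, 15 and 30 manual labels."""
    truth = noisy_frame_scene.truth[0]
    out = {}
    for n_labels in (5, 15, 30):
        layer = sparse_layer_from_truth(truth, n_labels)
        dense = sp.densify_layer(noisy_frame_scene.clip, layer)
        traj = sp.trajectories_from_layer(dense, fps=truth.fps)[0]
        out[n_labels] = sp.rmse(truth, traj)
    return out


@pytest.fixture()
def tiny_clip() -> sp.VideoClip:
    """A small translating speckle clip for fast LK tests."""
    tex = sp.make_texture(5, height=64, width=96)
    motion = sp.MotionModel("translation", velocity=(0.5, 0.0))
    scene = sp.render_scene(tex, motion, 12, np.array([[40.0, 30.0]]))
    return scene.clip
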