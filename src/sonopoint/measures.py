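"""Clinical and biomechanical measurements from tracked points.

Tracked trajectories become scalar time series through plane geometry:

* pair distances — e.g. interventricular septum (IVS) thickness, left
  ventricular internal diameter, and posterior wall (LVPW) thickness from
  point pairs straddling each cardiac structure;
* normalised deformation — (D - D0) / D0 relative to a reference frame,
  dimensionless strain-like measure of muscle cross-section change;
* fascicle geometry — in a pennate muscle imaged longitudinally, two points
  on each aponeurosis define the superficial and deep aponeurosis lines, and
  a point on a fascicle (at its deep-aponeurosis insertion) plus a second
  point along the fascicle define the fascicle line.  Fascicle length is the
  distance between the fascicle line's intersections with the two
  aponeurosis lines; pennation is the acute angle between the fascicle and
  the deep aponeurosis, in degrees.

All lines are treated as infinite lines, so intersections may fall outside
the annotated segments.  Frames with degenerate geometry (parallel lines)
are flagged NaN and processing continues.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trajectory import Trajectory

__all__ = [
    "MeasurementSpec",
    "ScalarSeries",
    "DegenerateGeometry",
    "pair_distance_series",
    "deformation_series",
    "line_intersection",
    "fascicle_metrics",
]

#: parallelism threshold on |sin(angle between lines)|
_PARALLEL_TOL = 1e-9

#: role names a fascicle measurement must bind (deep_apo_1 is the
#: fascicle/deep-aponeurosis intersection point)
FASCICLE_ROLES = ("sup_apo_1", "sup_apo_2", "deep_apo_1", "deep_apo_2", "fascicle_dir")


class DegenerateGeometry(ValueError):
    """Raised when lines are parallel or defined by coincident points."""


@dataclass(frozen=True)
class MeasurementSpec:
    """Binds measurement roles to tracked label_ids.

    kind
        ``pair_distance`` (roles a, b), ``deformation`` (roles a, b plus a
        reference frame), or ``fascicle`` (the five FASCICLE_ROLES).
    """

    kind: str
    roles: dict[str, int] = field(default_factory=dict)
    reference_frame: int = 0
    name: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("pair_distance", "deformation", "fascicle"):
            raise ValueError(f"unknown measurement kind {self.kind!r}")
        required = FASCICLE_ROLES if self.kind == "fascicle" else ("a", "b")
        missing = [r for r in required if r not in self.roles]
        if missing:
            raise ValueError(f"{self.kind} spec missing roles {missing}")
        ids = [self.roles[r] for r in required]
        if len(set(ids)) != len(ids):
            raise ValueError("measurement roles must bind distinct label_ids")


@dataclass
class ScalarSeries:
    """A named per-frame scalar with units."""

    name: str
    values: np.ndarray
    units: str = "px"
    fps: float = 50.0
    first_frame: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)

    def __len__(self) -> int:
        return int(self.values.shape[0])

    @property
    def times(self) -> np.ndarray:
        return (np.arange(len(self)) + self.first_frame) / self.fps


def _require_same_range(a: Trajectory, b: Trajectory) -> None:
    if not a.same_range(b):
        raise ValueError(
            f"trajectories cover different frame ranges: "
            f"[{a.first_frame}, {a.last_frame}] vs [{b.first_frame}, {b.last_frame}]"
        )


def pair_distance_series(
    traj_a: Trajectory, traj_b: Trajectory, pitch: float | None = None, name: str = "distance"
) -> ScalarSeries:
    """Per-frame Euclidean distance between two tracked points.

    Reported in micrometres when ``pitch`` (um/px) is given, else pixels.
    """
    _require_same_range(traj_a, traj_b)
    d = np.linalg.norm(traj_a.positions - traj_b.positions, axis=1)
    if pitch is not None:
        d = d * pitch
    return ScalarSeries(
        name=name, values=d, units="um" if pitch is not None else "px",
        fps=traj_a.fps, first_frame=traj_a.first_frame,
    )


def deformation_series(dist: ScalarSeries, reference_frame: int | None = None) -> ScalarSeries:
    """Normalised deformation (D - D0) / D0.

    D0 is the distance at ``reference_frame`` (absolute index; defaults to
    the series' first frame — "the start of the task").
    """
    ref = dist.first_frame if reference_frame is None else reference_frame
    idx = ref - dist.first_frame
    if not 0 <= idx < len(dist):
        raise ValueError(f"reference frame {ref} outside the series range")
    d0 = dist.values[idx]
    if not d0 > 0:
        raise ValueError(f"reference distance at frame {ref} is {d0}; must be positive")
    return ScalarSeries(
        name=f"{dist.name}_deformation",
        values=(dist.values - d0) / d0,
        units="dimensionless",
        fps=dist.fps,
        first_frame=dist.first_frame,
    )


def line_intersection(p1, p2, q1, q2) -> np.ndarray:
    """Intersection of the infinite lines (p1,p2) and (q1,q2).

    Raises :class:`DegenerateGeometry` when either line is defined by
    coincident points or the lines are parallel (|sin angle| <= 1e-9).
    """
    p1, p2, q1, q2 = (np.asarray(v, dtype=np.float64) for v in (p1, p2, q1, q2))
    u = p2 - p1
    v = q2 - q1
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise DegenerateGeometry("line defined by coincident points")
    cross = u[0] * v[1] - u[1] * v[0]
    if abs(cross) / (nu * nv) <= _PARALLEL_TOL:
        raise DegenerateGeometry("lines are parallel")
    t = ((q1[0] - p1[0]) * v[1] - (q1[1] - p1[1]) * v[0]) / cross
    return p1 + t * u


def _acute_angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise DegenerateGeometry("zero-length direction")
    c = abs(float(u @ v)) / (nu * nv)
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def fascicle_metrics(
    trajectories: dict[int, Trajectory] | list[Trajectory],
    spec: MeasurementSpec,
    pitch: float | None = None,
) -> tuple[ScalarSeries, ScalarSeries]:
    """Fascicle length and pennation angle per frame.

    Per frame the superficial and deep aponeurosis lines come from their two
    tracked points each, the fascicle line from ``deep_apo_1`` through
    ``fascicle_dir``; length is the distance between the fascicle line's
    intersections with the two aponeurosis lines (um if ``pitch`` given,
    else px) and pennation the acute angle (degrees, 0-90] between fascicle
    and deep aponeurosis.  Frames with degenerate geometry yield NaN.
    """
    if spec.kind != "fascicle":
        raise ValueError(f"spec kind must be 'fascicle', got {spec.kind!r}")
    by_id = (
        trajectories
        if isinstance(trajectories, dict)
        else {t.label_id: t for t in trajectories}
    )
    try:
        trajs = {role: by_id[spec.roles[role]] for role in FASCICLE_ROLES}
    except KeyError as exc:
        raise ValueError(f"no trajectory for label_id {exc}") from exc
    base = trajs["sup_apo_1"]
    for t in trajs.values():
        _require_same_range(base, t)

    n = len(base)
    length = np.full(n, np.nan)
    pennation = np.full(n, np.nan)
    for i in range(n):
        s1 = trajs["sup_apo_1"].positions[i]
        s2 = trajs["sup_apo_2"].positions[i]
        d1 = trajs["deep_apo_1"].positions[i]
        d2 = trajs["deep_apo_2"].positions[i]
        fd = trajs["fascicle_dir"].positions[i]
        try:
            top = line_intersection(d1, fd, s1, s2)
            bottom = line_intersection(d1, fd, d1, d2)
            length[i] = np.linalg.norm(top - bottom)
            pennation[i] = _acute_angle_deg(fd - d1, d2 - d1)
        except DegenerateGeometry:
            continue  # frame flagged NaN, processing continues

    if pitch is not None:
        length = length * pitch
    name = spec.name or "fascicle"
    return (
        ScalarSeries(
            name=f"{name}_length", values=length,
            units="um" if pitch is not None else "px",
            fps=base.fps, first_frame=base.first_frame,
        ),
        ScalarSeries(
            name=f"{name}_pennation", values=pennation, units="degrees",
            fps=base.fps, first_frame=base.first_frame,
        ),
    )
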