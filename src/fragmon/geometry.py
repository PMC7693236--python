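"""Room-frame conventions, detector pose, and point-of-closest-approach geometry.

All coordinates are in millimetres in a right-handed room frame whose origin is
the treatment-room isocenter and whose +z axis points along the beam direction
of the active field.  Each field is analysed in its own frame; the field angle
only matters when combining per-field reports.

A reconstructed fragment track is a straight line: a point (conventionally at
the detector front face) plus a unit direction oriented from the detector
toward the patient.  The fragment emission-point estimate is the Point of
Closest Approach (PCA) between that line and the nominal pencil-beam axis: the
midpoint of the mutual-perpendicular segment joining the two lines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Vec3",
    "Track",
    "BeamAxis",
    "DetectorPose",
    "PcaPoint",
    "transform_track",
    "compute_pca",
    "compute_pca_batch",
]

#: parallel-line degeneracy threshold on |d1 x d2|
DEGENERACY_EPS = 1e-9

Vec3 = np.ndarray  # shape (3,), float64, mm


def _as_vec3(v) -> np.ndarray:
    a = np.asarray(v, dtype=float)
    if a.shape != (3,):
        raise ValueError(f"expected a 3-vector, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError("vector components must be finite")
    return a


def _check_unit(d: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    n = float(np.linalg.norm(d))
    if n == 0.0:
        raise ValueError("zero-length direction")
    if abs(n - 1.0) > tol:
        raise ValueError(f"direction is not unit (|d| = {n!r})")
    return d


@dataclass(frozen=True)
class Track:
    """A reconstructed fragment trajectory (straight line) in the room frame."""

    point: Vec3
    direction: Vec3
    t: float = 0.0
    pb_id: int = -1
    fraction_id: int = -1

    def __post_init__(self):
        object.__setattr__(self, "point", _as_vec3(self.point))
        object.__setattr__(self, "direction", _check_unit(_as_vec3(self.direction)))
        if self.t < 0:
            raise ValueError("track time must be >= 0")


@dataclass(frozen=True)
class BeamAxis:
    """Nominal pencil-beam axis: spot position at the isocenter plane, +z direction."""

    origin: Vec3
    direction: Vec3 = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self):
        object.__setattr__(self, "origin", _as_vec3(self.origin))
        object.__setattr__(self, "direction", _check_unit(_as_vec3(self.direction)))

    @classmethod
    def from_spot(cls, x_mm: float, y_mm: float) -> "BeamAxis":
        return cls(origin=np.array([x_mm, y_mm, 0.0]))


@dataclass(frozen=True)
class DetectorPose:
    """Rigid pose of the tracker in the room frame plus its placement uncertainty.

    ``rotation`` maps detector-local coordinates into the room frame and
    ``translation`` is the position of the detector face center.  ``sigma_xyz``
    is the per-axis 1-sigma positioning reproducibility of the cart (nominally
    1-1.5 mm per axis from the laser-tracker survey).
    """

    rotation: np.ndarray
    translation: Vec3
    sigma_xyz: Vec3 = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        r = np.asarray(self.rotation, dtype=float)
        if r.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(r.T @ r, np.eye(3), atol=1e-9):
            raise ValueError("rotation matrix is not orthonormal")
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", _as_vec3(self.translation))
        s = _as_vec3(self.sigma_xyz)
        if np.any(s < 0):
            raise ValueError("sigma_xyz components must be >= 0")
        object.__setattr__(self, "sigma_xyz", s)

    @classmethod
    def identity(cls) -> "DetectorPose":
        return cls(rotation=np.eye(3), translation=np.zeros(3))

    @classmethod
    def nominal(
        cls,
        distance_mm: float = 500.0,
        tilt_deg: float = 60.0,
        elevation_deg: float = 30.0,
        sigma_xyz=(1.2, 1.2, 1.2),
    ) -> "DetectorPose":
        """Nominal clinical pose: face center ``distance_mm`` from the isocenter,
        tilted ``tilt_deg`` from the beam axis in the horizontal plane and raised
        ``elevation_deg`` upwards, face normal looking back at the isocenter."""
        tilt = np.radians(tilt_deg)
        elev = np.radians(elevation_deg)
        n = np.array(
            [np.cos(elev) * np.sin(tilt), np.sin(elev), np.cos(elev) * np.cos(tilt)]
        )
        center = distance_mm * n
        # detector-local axes: w = outward normal (from isocenter through face),
        # u = horizontal in-face axis, v completes the right-handed triad.
        w = n
        u = np.cross(np.array([0.0, 1.0, 0.0]), w)
        u /= np.linalg.norm(u)
        v = np.cross(w, u)
        rot = np.column_stack([u, v, w])
        return cls(rotation=rot, translation=center, sigma_xyz=np.asarray(sigma_xyz, float))

    @property
    def face_axes(self) -> tuple[np.ndarray, np.ndarray]:
        """In-face unit vectors (detector-local x and y) in the room frame."""
        return self.rotation[:, 0].copy(), self.rotation[:, 1].copy()


@dataclass(frozen=True)
class PcaPoint:
    """Point of closest approach between a track line and a beam axis."""

    position: Vec3
    miss_distance: float
    s_beam: float
    degenerate: bool = False


def transform_track(track_local: Track, pose: DetectorPose) -> Track:
    """Map a detector-local track into the room frame through ``pose``."""
    p = pose.rotation @ track_local.point + pose.translation
    d = pose.rotation @ track_local.direction
    d = d / np.linalg.norm(d)
    return Track(point=p, direction=d, t=track_local.t,
                 pb_id=track_local.pb_id, fraction_id=track_local.fraction_id)


def compute_pca(track: Track | BeamAxis, axis: BeamAxis | Track) -> PcaPoint:
    """Closed-form PCA between two lines via the mutual-perpendicular construction.

    Returns the midpoint of the shortest segment joining the lines, the line-line
    distance, and the signed arc length of the perpendicular foot along the second
    line (the beam axis) measured from its origin.  Near-parallel pairs
    (|d1 x d2| < 1e-9) are flagged ``degenerate`` and the PCA is reported at the
    perpendicular foot of the track point.
    """
    p1, d1 = track.point if isinstance(track, Track) else track.origin, track.direction
    p2, d2 = (axis.origin if isinstance(axis, BeamAxis) else axis.point), axis.direction

    w0 = p1 - p2
    b = float(d1 @ d2)
    d = float(w0 @ d1)
    e = float(w0 @ d2)
    denom = 1.0 - b * b  # == |d1 x d2|^2 for unit directions

    if denom < DEGENERACY_EPS**2:
        # parallel lines: foot of the track point on the axis
        u = e
        q2 = p2 + u * d2
        miss = float(np.linalg.norm(p1 - q2 - (float((p1 - q2) @ d2)) * d2))
        mid = 0.5 * (p1 + q2)
        return PcaPoint(position=mid, miss_distance=miss, s_beam=float(u), degenerate=True)

    s = (b * e - d) / denom
    u = (e - b * d) / denom
    q1 = p1 + s * d1
    q2 = p2 + u * d2
    mid = 0.5 * (q1 + q2)
    return PcaPoint(
        position=mid,
        miss_distance=float(np.linalg.norm(q1 - q2)),
        s_beam=float(u),
        degenerate=False,
    )


def compute_pca_batch(
    points: np.ndarray,
    directions: np.ndarray,
    axis_origins: np.ndarray,
    axis_direction: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised PCA of N track lines against per-track beam axes.

    Parameters
    ----------
    points, directions : (N, 3) arrays — track line point and unit direction.
    axis_origins : (N, 3) array — spot position of each track's pencil beam.
    axis_direction : (3,) common axis direction; defaults to +z.

    Returns
    -------
    positions : (N, 3) PCA midpoints
    miss : (N,) line-line distances
    s_beam : (N,) arc length of the axis foot from the axis origin
    degenerate : (N,) bool
    """
    p1 = np.asarray(points, float)
    d1 = np.asarray(directions, float)
    p2 = np.asarray(axis_origins, float)
    d2 = np.array([0.0, 0.0, 1.0]) if axis_direction is None else np.asarray(axis_direction, float)

    w0 = p1 - p2
    b = d1 @ d2
    d = np.einsum("ij,ij->i", w0, d1)
    e = w0 @ d2
    denom = 1.0 - b * b
    degen = denom < DEGENERACY_EPS**2
    denom_safe = np.where(degen, 1.0, denom)

    s = (b * e - d) / denom_safe
    u = (e - b * d) / denom_safe
    u = np.where(degen, e, u)
    q2 = p2 + u[:, None] * d2
    q1 = np.where(degen[:, None], p1, p1 + s[:, None] * d1)
    if np.any(degen):
        # parallel: transverse offset of the track point from the axis
        off = p1 - q2
        off = off - (off @ d2)[:, None] * d2
        miss_deg = np.linalg.norm(off, axis=1)
    mid = 0.5 * (q1 + q2)
    miss = np.linalg.norm(q1 - q2, axis=1)
    if np.any(degen):
        miss = np.where(degen, miss_deg, miss)
    return mid, miss, u, degen
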