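"""Coordinate-free geometric primitives shared by all version estimators.

All 3-D quantities live in a single LPS-like anatomical frame
(x = patient-left / medial(+), y = posterior(+), z = superior(+)), with
lengths in millimetres.  The primitives here are deliberately dumb: plane
fitting from exactly three points, vector angles, orthonormal in-plane
frames and orthogonal projection.  Anatomical orientation semantics (which
way a normal should face) are applied by the method layer, not here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DegenerateGeometryError",
    "OrientationAmbiguityError",
    "Plane",
    "ResliceFrame",
    "as_point3",
    "as_point2",
    "fit_plane",
    "angle_deg",
    "project_to_frame",
    "embed_from_frame",
    "rotation_from_euler_deg",
]

#: triangles thinner than this (mm^2) are treated as collinear input
DEGENERATE_AREA_MM2 = 1e-9

#: vectors shorter than this (mm) are treated as zero
ZERO_LENGTH_MM = 1e-12


class DegenerateGeometryError(ValueError):
    """Raised when landmarks are coincident/collinear or a vector has no length."""


class OrientationAmbiguityError(ValueError):
    """Raised when an orientation reference is perpendicular to the normal it should orient."""


def as_point3(p, name: str = "point") -> np.ndarray:
    """Coerce to a finite float (3,) array, in mm."""
    a = np.asarray(p, dtype=float)
    if a.shape != (3,):
        raise ValueError(f"{name} must be a 3-vector, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} has non-finite components: {a}")
    return a


def as_point2(p, name: str = "point") -> np.ndarray:
    """Coerce to a finite float (2,) array, in mm."""
    a = np.asarray(p, dtype=float)
    if a.shape != (2,):
        raise ValueError(f"{name} must be a 2-vector, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} has non-finite components: {a}")
    return a


def _unit(v: np.ndarray, name: str = "vector") -> np.ndarray:
    n = float(np.linalg.norm(v))
    if n < ZERO_LENGTH_MM:
        raise DegenerateGeometryError(f"{name} has (near-)zero length")
    return v / n


@dataclass(frozen=True)
class Plane:
    """An infinite plane: a point on it and a unit normal."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "point", as_point3(self.point, "plane point"))
        n = as_point3(self.normal, "plane normal")
        if abs(np.linalg.norm(n) - 1.0) > 1e-9:
            raise ValueError("plane normal must be unit length")
        object.__setattr__(self, "normal", n)

    def signed_distance(self, p) -> float:
        return float(np.dot(as_point3(p) - self.point, self.normal))

    def flipped(self) -> "Plane":
        return Plane(self.point, -self.normal)


@dataclass(frozen=True)
class ResliceFrame:
    """An in-plane 2-D coordinate frame: origin plus two orthonormal axes.

    The implied plane normal is ``axis_u x axis_v`` (right-handed).
    """

    origin: np.ndarray
    axis_u: np.ndarray
    axis_v: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "origin", as_point3(self.origin, "frame origin"))
        u = as_point3(self.axis_u, "axis_u")
        v = as_point3(self.axis_v, "axis_v")
        if abs(np.linalg.norm(u) - 1.0) > 1e-12 or abs(np.linalg.norm(v) - 1.0) > 1e-12:
            raise ValueError("frame axes must be unit length")
        if abs(float(np.dot(u, v))) > 1e-12:
            raise ValueError("frame axes must be orthogonal")
        object.__setattr__(self, "axis_u", u)
        object.__setattr__(self, "axis_v", v)

    @property
    def normal(self) -> np.ndarray:
        return np.cross(self.axis_u, self.axis_v)

    @property
    def plane(self) -> Plane:
        return Plane(self.origin, self.normal)


def fit_plane(p1, p2, p3, names=("p1", "p2", "p3")) -> Plane:
    """Plane through three non-collinear points.

    The normal is ``normalize((p2-p1) x (p3-p1))`` — deterministic in the
    argument order (right-hand rule); no anatomical canonicalisation is done.
    """
    a = as_point3(p1, names[0])
    b = as_point3(p2, names[1])
    c = as_point3(p3, names[2])
    cross = np.cross(b - a, c - a)
    area = 0.5 * float(np.linalg.norm(cross))
    if area < DEGENERATE_AREA_MM2:
        raise DegenerateGeometryError(
            f"landmarks {names[0]}, {names[1]}, {names[2]} are collinear or coincident "
            f"(triangle area {area:.3g} mm^2)"
        )
    return Plane(point=a, normal=cross / np.linalg.norm(cross))


def angle_deg(u, v) -> float:
    """Unsigned angle between two nonzero vectors, in degrees in [0, 180].

    Works for 2-D and 3-D vectors.  Computed as atan2(|u x v|, u . v), which
    is equivalent to the clamped-arccos of the normalised dot product but
    stays well-conditioned near 0 and 180 degrees.
    """
    ua = np.asarray(u, dtype=float)
    va = np.asarray(v, dtype=float)
    nu = float(np.linalg.norm(ua))
    nv = float(np.linalg.norm(va))
    if nu < ZERO_LENGTH_MM or nv < ZERO_LENGTH_MM:
        raise DegenerateGeometryError("angle of a zero vector is undefined")
    if ua.shape == (2,):
        cross_mag = abs(ua[0] * va[1] - ua[1] * va[0])
    else:
        cross_mag = np.linalg.norm(np.cross(ua, va))
    return float(np.degrees(np.arctan2(cross_mag, np.dot(ua, va))))


def project_to_frame(frame: ResliceFrame, p) -> np.ndarray:
    """Orthogonal projection of a 3-D point into a frame's (u, v) coordinates.

    The out-of-plane component is discarded.
    """
    d = as_point3(p) - frame.origin
    return np.array([float(np.dot(d, frame.axis_u)), float(np.dot(d, frame.axis_v))])


def embed_from_frame(frame: ResliceFrame, uv) -> np.ndarray:
    """Map in-plane (u, v) coordinates back to the 3-D point on the frame's plane."""
    q = as_point2(uv, "uv")
    return frame.origin + q[0] * frame.axis_u + q[1] * frame.axis_v


def rotation_from_euler_deg(rx: float = 0.0, ry: float = 0.0, rz: float = 0.0) -> np.ndarray:
    """Rotation matrix from extrinsic x-y-z Euler angles in degrees (R = Rz @ Ry @ Rx)."""
    from scipy.spatial.transform import Rotation

    return Rotation.from_euler("xyz", [rx, ry, rz], degrees=True).as_matrix()
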