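"""Parametric virtual-scapula landmark generator with known true version.

Patient CT data cannot be redistributed, so validation rests on a synthetic
landmark constellation whose true version angle, landmark noise and patient
pose are all controlled.  The canonical (neutral-pose) frame puts the glenoid
centre at the origin, the scapular plane in the y = 0 plane (containing the
medial border and inferior angle), and a neutral (version 0) glenoid fossa in
the x = 0 plane, so that a retroverted fossa faces posteriorly (+y).

Construction of the fossa rim for a true version v (degrees):

* glenoid fossa line direction ``g = normalize(sin v, cos v, eps*sin v)``
  with ``eps = (|M| - Mx) / Mz`` for medial border offset ``M`` (0 when
  ``Mz = 0``).  The small out-of-axial-plane term makes the line subtend the
  angle v against the transverse scapular axis *both* in the axial plane and
  in the corrected transverse plane, so every estimator sees the same ground
  truth even when the medial border does not lie at the glenoid's superior
  level.  The anterior/posterior rim points sit at the lower third of the
  rim, at ``(0,0,-r sin30) -/+ r cos30 * g``.
* fossa plane normal ``n_F = (-cos v, sin v, 0)`` — the lateral normal tilted
  posteriorly by v, giving the two-plane method the same truth; the superior
  rim pole is placed in that plane above the glenoid centre.

Gaussian landmark noise (annotation error) is added in the canonical frame,
then a rigid patient-pose transform (acquisition orientation) is applied to
every point.  Generation is deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Tuple

import numpy as np

from .geometry import rotation_from_euler_deg
from .io import LandmarkSet
from .methods import AxialLandmarks
from .reslice import ImageVolume

__all__ = [
    "PoseTransform",
    "SyntheticParams",
    "SyntheticCase",
    "generate_case",
    "generate_batch",
    "axial_project",
    "make_affine_volume",
]

#: generation order; fixed so the noise stream is reproducible
_LANDMARK_ORDER = (
    "glenoid_center",
    "glenoid_superior",
    "glenoid_anterior",
    "glenoid_posterior",
    "medial_border",
    "inferior_angle",
    "vault_tip",
)


@dataclass(frozen=True)
class PoseTransform:
    """Rigid patient-pose transform: rotation then translation."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        r = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if r.shape != (3, 3) or not np.allclose(r.T @ r, np.eye(3), atol=1e-12):
            raise ValueError("rotation must be orthonormal")
        if np.linalg.det(r) < 0:
            raise ValueError("rotation must be proper (det +1)")
        if t.shape != (3,):
            raise ValueError("translation must be a 3-vector")
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)

    @classmethod
    def from_euler_deg(cls, rx=0.0, ry=0.0, rz=0.0, translation=(0.0, 0.0, 0.0)):
        return cls(rotation=rotation_from_euler_deg(rx, ry, rz),
                   translation=np.asarray(translation, dtype=float))

    @classmethod
    def identity(cls) -> "PoseTransform":
        return cls()

    def apply(self, p: np.ndarray) -> np.ndarray:
        return self.rotation @ np.asarray(p, dtype=float) + self.translation


@dataclass(frozen=True)
class SyntheticParams:
    """Generator parameters; defaults are loosely scaled to an adult scapula.

    Offsets are from the glenoid centre in the canonical frame (mm); they are
    conventions, not anatomical claims — only angle recovery is asserted.
    """

    true_version_deg: float = 0.0
    rim_radius: float = 15.0
    medial_offset: Tuple[float, float, float] = (100.0, 0.0, 10.0)
    inferior_offset: Tuple[float, float, float] = (80.0, 0.0, -120.0)
    vault_offset: Tuple[float, float, float] = (30.0, 0.0, 0.0)
    noise_sd: float = 0.0
    pose: PoseTransform = field(default_factory=PoseTransform)
    seed: int = 0

    def __post_init__(self):
        if self.rim_radius <= 0:
            raise ValueError("rim_radius must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for name in ("medial_offset", "inferior_offset", "vault_offset"):
            v = tuple(float(x) for x in getattr(self, name))
            object.__setattr__(self, name, v)
            if abs(v[1]) > 1e-12:
                raise ValueError(f"{name} must lie in the scapular plane (y = 0)")
        if self.medial_offset[0] <= 0:
            raise ValueError("medial_offset must point medially (x > 0)")


@dataclass(frozen=True)
class SyntheticCase:
    """Generated landmarks plus the ground truth that built them."""

    landmarks: LandmarkSet
    true_version_deg: float
    pose: PoseTransform
    params: SyntheticParams

    @property
    def axial_landmarks(self) -> AxialLandmarks:
        return axial_project(self, reference="medial_border")


def _canonical_landmarks(p: SyntheticParams) -> Dict[str, np.ndarray]:
    v = math.radians(p.true_version_deg)
    r = p.rim_radius
    a = r * math.cos(math.radians(30.0))  # half-length of the fossa line
    b = r * math.sin(math.radians(30.0))  # depth of the lower-third rim points
    medial = np.asarray(p.medial_offset)
    mx, _, mz = medial
    norm_m = float(np.linalg.norm(medial))
    eps = (norm_m - mx) / mz if abs(mz) > 1e-12 else 0.0

    g = np.array([math.sin(v), math.cos(v), eps * math.sin(v)])
    g /= np.linalg.norm(g)
    n_fossa = np.array([-math.cos(v), math.sin(v), 0.0])
    s_dir = np.cross(g, n_fossa)
    s_dir /= np.linalg.norm(s_dir)

    mid = np.array([0.0, 0.0, -b])
    return {
        "glenoid_center": np.zeros(3),
        "glenoid_superior": mid + (r + b) * s_dir,
        "glenoid_anterior": mid - a * g,
        "glenoid_posterior": mid + a * g,
        "medial_border": medial.copy(),
        "inferior_angle": np.asarray(p.inferior_offset, dtype=float),
        "vault_tip": np.asarray(p.vault_offset, dtype=float),
    }


def generate_case(params: SyntheticParams, case_id: str = "synthetic") -> SyntheticCase:
    """Generate one landmark constellation.

    Noise (i.i.d. Gaussian per coordinate, annotation error) is applied in
    the canonical frame *before* the pose, which models acquisition
    orientation.  Deterministic given ``params.seed``.
    """
    canon = _canonical_landmarks(params)
    rng = np.random.default_rng(params.seed)
    points = []
    for name in _LANDMARK_ORDER:
        pt = canon[name]
        if params.noise_sd > 0:
            pt = pt + rng.normal(0.0, params.noise_sd, size=3)
        points.append((name, params.pose.apply(pt)))
    return SyntheticCase(
        landmarks=LandmarkSet(case_id=case_id, points=points, source_frame="LPS"),
        true_version_deg=float(params.true_version_deg),
        pose=params.pose,
        params=params,
    )


def generate_batch(n: int, params: SyntheticParams, case_prefix: str = "case"):
    """Generate ``n`` cases with per-case seeds derived from ``params.seed``."""
    seeds = np.random.default_rng(params.seed).integers(0, 2**31 - 1, size=max(n, 1))
    return [
        generate_case(replace(params, seed=int(seeds[k])), case_id=f"{case_prefix}{k:03d}")
        for k in range(n)
    ]


def axial_project(case: SyntheticCase, reference: str = "medial_border") -> AxialLandmarks:
    """Project the (post-pose) landmarks onto the image axial plane.

    Emulates picking the 2-D points on an axial slice of the scanner volume:
    the superior (z) coordinate is dropped, so any pose tilt leaks into the
    2-D constellation exactly as it does in a real tilted acquisition.
    """
    ls = case.landmarks
    if reference not in ("medial_border", "vault_tip"):
        raise ValueError("reference must be 'medial_border' or 'vault_tip'")
    return AxialLandmarks(
        glenoid_anterior=ls.get("glenoid_anterior")[:2],
        glenoid_posterior=ls.get("glenoid_posterior")[:2],
        medial_reference=ls.get(reference)[:2],
        method_tag="friedman" if reference == "medial_border" else "vault",
    )


def make_affine_volume(
    shape=(16, 16, 16),
    spacing=(1.0, 1.0, 1.0),
    coeffs=(0.0, 1.0, 0.0, 0.0),
    origin=(0.0, 0.0, 0.0),
) -> ImageVolume:
    """Volume whose voxel values are ``a + b*x + c*y + d*z`` at voxel-centre
    world coordinates — trilinear interpolation reproduces an affine field
    exactly, making this the reslicing oracle fixture."""
    shape = tuple(int(s) for s in shape)
    if any(s < 1 for s in shape):
        raise ValueError("shape components must be >= 1")
    sp = np.asarray(spacing, dtype=float)
    if np.any(sp <= 0):
        raise ValueError("spacing must be positive")
    a0, bx, cy, dz = (float(c) for c in coeffs)
    o = np.asarray(origin, dtype=float)
    ix, iy, iz = np.meshgrid(*(np.arange(s, dtype=float) for s in shape), indexing="ij")
    x = o[0] + ix * sp[0]
    y = o[1] + iy * sp[1]
    z = o[2] + iz * sp[2]
    return ImageVolume(values=a0 + bx * x + cy * y + dz * z, spacing=sp, origin=o)
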