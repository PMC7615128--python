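"""The four glenoid version estimators.

Glenoid version is the axial-plane orientation of the glenoid articular
surface relative to the long axis of the scapula.  All estimators return a
signed angle in degrees with the clinical convention *retroversion positive*
(glenoid facing posteriorly), anteversion negative.

Two 3-D methods operate on landmarks in the anatomical frame:

* **two-plane** — the angle between the glenoid fossa plane (three rim
  points) and the scapular plane (glenoid centre, medial border, inferior
  angle), reported as 90° minus the dihedral angle of the oriented normals
  so that perpendicular planes read 0°.
* **corrected Friedman** — the conventional Friedman measurement taken in a
  corrected transverse plane that is perpendicular to the scapular plane and
  contains the transverse scapular axis, which removes patient-positioning
  error.

Two 2-D methods operate on points picked on a single axial slice:

* **Friedman** — angle between the glenoid fossa line (anterior to posterior
  rim) and the line from the medial scapular border to the glenoid midpoint.
* **vault** — same, with the tip of the scapular vault as the medial
  reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .geometry import (
    DegenerateGeometryError,
    OrientationAmbiguityError,
    ResliceFrame,
    angle_deg,
    as_point2,
    as_point3,
    fit_plane,
    project_to_frame,
)

__all__ = [
    "METHOD_NAMES",
    "TwoPlaneLandmarks",
    "AxialLandmarks",
    "CorrectedLandmarks",
    "VersionResult",
    "two_plane_version",
    "line_version_2d",
    "friedman_version",
    "vault_version",
    "corrected_transverse_frame",
    "corrected_friedman_version",
    "corrected_friedman_version_2d",
]

METHOD_NAMES = ("two_plane", "friedman", "vault", "corrected_friedman")


@dataclass(frozen=True)
class TwoPlaneLandmarks:
    """Six points: three on the glenoid fossa rim, three on the scapular plane.

    The fossa triple is one point at the superior pole of the glenoid and two
    on the lower third of the rim, anteriorly and posteriorly.  The scapular
    triple is the glenoid centre, the medial border where the scapular spine
    meets the scapular body, and the inferior scapular angle.
    """

    glenoid_superior: np.ndarray
    glenoid_anterior: np.ndarray
    glenoid_posterior: np.ndarray
    glenoid_center: np.ndarray
    medial_border: np.ndarray
    inferior_angle: np.ndarray

    def __post_init__(self):
        for name in self.__dataclass_fields__:
            object.__setattr__(self, name, as_point3(getattr(self, name), name))


@dataclass(frozen=True)
class AxialLandmarks:
    """Three points on one axial slice: the glenoid rim pair plus a medial
    reference (scapular medial border for Friedman, vault tip for vault)."""

    glenoid_anterior: np.ndarray
    glenoid_posterior: np.ndarray
    medial_reference: np.ndarray
    method_tag: str = "friedman"

    def __post_init__(self):
        object.__setattr__(self, "glenoid_anterior", as_point2(self.glenoid_anterior, "glenoid_anterior"))
        object.__setattr__(self, "glenoid_posterior", as_point2(self.glenoid_posterior, "glenoid_posterior"))
        object.__setattr__(self, "medial_reference", as_point2(self.medial_reference, "medial_reference"))
        if self.method_tag not in ("friedman", "vault"):
            raise ValueError(f"method_tag must be 'friedman' or 'vault', got {self.method_tag!r}")


@dataclass(frozen=True)
class CorrectedLandmarks:
    """3-D landmarks for the corrected Friedman method.

    ``medial_axis_point`` is the medial end of the Friedman line; it defaults
    to the medial border landmark of the scapular plane triple.
    """

    glenoid_center: np.ndarray
    medial_border: np.ndarray
    inferior_angle: np.ndarray
    glenoid_anterior: np.ndarray
    glenoid_posterior: np.ndarray
    medial_axis_point: Optional[np.ndarray] = None

    def __post_init__(self):
        for name in ("glenoid_center", "medial_border", "inferior_angle",
                     "glenoid_anterior", "glenoid_posterior"):
            object.__setattr__(self, name, as_point3(getattr(self, name), name))
        m = self.medial_axis_point
        object.__setattr__(
            self, "medial_axis_point",
            self.medial_border if m is None else as_point3(m, "medial_axis_point"),
        )


@dataclass(frozen=True)
class VersionResult:
    """A signed version measurement: positive = retroversion, negative = anteversion."""

    method: str
    version_deg: float
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        v = float(self.version_deg)
        if not np.isfinite(v) or not (-90.0 <= v <= 90.0):
            raise ValueError(
                f"version of {v}° is outside [-90, 90]; landmarks are likely mislabelled"
            )
        object.__setattr__(self, "version_deg", v)


def _oriented(normal: np.ndarray, reference: np.ndarray, what: str) -> np.ndarray:
    """Flip ``normal`` so its dot product with ``reference`` is non-negative."""
    ref_norm = float(np.linalg.norm(reference))
    if ref_norm < 1e-12:
        raise DegenerateGeometryError(f"{what}: orientation reference has zero length")
    d = float(np.dot(normal, reference)) / ref_norm
    if abs(d) < 1e-12:
        raise OrientationAmbiguityError(
            f"{what}: orientation reference is perpendicular to the normal; "
            "cannot decide which way the plane faces"
        )
    return -normal if d < 0 else normal


def two_plane_version(lm: TwoPlaneLandmarks) -> VersionResult:
    """Version as 90° minus the dihedral angle between fossa and scapular planes.

    The fossa normal is oriented laterally (away from the medial border) and
    the scapular normal posteriorly (toward the posterior rim point), so that
    perpendicular planes give 0° and a posteriorly tilted fossa gives a
    positive (retroverted) angle.
    """
    fossa = fit_plane(
        lm.glenoid_superior, lm.glenoid_anterior, lm.glenoid_posterior,
        names=("glenoid_superior", "glenoid_anterior", "glenoid_posterior"),
    )
    scapula = fit_plane(
        lm.glenoid_center, lm.medial_border, lm.inferior_angle,
        names=("glenoid_center", "medial_border", "inferior_angle"),
    )
    n_fossa = _oriented(fossa.normal, lm.glenoid_center - lm.medial_border, "fossa plane")
    n_scap = _oriented(
        scapula.normal, lm.glenoid_posterior - lm.glenoid_anterior, "scapular plane"
    )
    version = 90.0 - angle_deg(n_fossa, n_scap)
    return VersionResult(
        method="two_plane",
        version_deg=version,
        diagnostics={"fossa_normal": n_fossa, "scapular_normal": n_scap},
    )


def line_version_2d(anterior, posterior, medial_reference) -> float:
    """Signed 2-D version: 90° minus the angle between the glenoid fossa line
    and the medial reference line.

    ``g = posterior - anterior`` and ``m = medial_reference - midpoint``; when
    g has a component toward the medial reference the fossa faces posteriorly
    and the returned value is positive (retroversion).  Invariant to rigid 2-D
    motion and uniform scaling of the three points.
    """
    a = as_point2(anterior, "anterior")
    p = as_point2(posterior, "posterior")
    ref = as_point2(medial_reference, "medial_reference")
    g = p - a
    midpoint = 0.5 * (a + p)
    m = ref - midpoint
    if np.linalg.norm(g) < 1e-12:
        raise DegenerateGeometryError("glenoid fossa line has zero length")
    if np.linalg.norm(m) < 1e-12:
        raise DegenerateGeometryError(
            "medial reference coincides with the glenoid midpoint"
        )
    return 90.0 - angle_deg(g, m)


def friedman_version(lm: AxialLandmarks) -> VersionResult:
    """Friedman method: medial reference is the medial scapular border."""
    version = line_version_2d(lm.glenoid_anterior, lm.glenoid_posterior, lm.medial_reference)
    return VersionResult(method="friedman", version_deg=version)


def vault_version(lm: AxialLandmarks) -> VersionResult:
    """Vault method: medial reference is the tip of the scapular vault."""
    version = line_version_2d(lm.glenoid_anterior, lm.glenoid_posterior, lm.medial_reference)
    return VersionResult(method="vault", version_deg=version)


def corrected_transverse_frame(
    center, medial_border, inferior_angle, orient_hint=None
) -> ResliceFrame:
    """In-plane frame of the corrected transverse scapular plane.

    The corrected plane is perpendicular to the scapular plane and contains
    the transverse scapular axis (glenoid centre to medial border).
    ``axis_u`` points medially along that axis; ``axis_v`` is the scapular
    plane normal oriented posteriorly — via ``orient_hint`` (typically the
    anterior-to-posterior rim vector) when given, otherwise toward the +y
    hemisphere of the anatomical frame.
    """
    c = as_point3(center, "glenoid_center")
    m = as_point3(medial_border, "medial_border")
    scapula = fit_plane(
        c, m, inferior_angle, names=("glenoid_center", "medial_border", "inferior_angle")
    )
    u = m - c
    u = u / np.linalg.norm(u)
    n = scapula.normal - float(np.dot(scapula.normal, u)) * u  # guard fp drift
    n = n / np.linalg.norm(n)
    if orient_hint is not None:
        n = _oriented(n, as_point3(orient_hint, "orient_hint"), "corrected frame")
    else:
        n = _oriented(n, np.array([0.0, 1.0, 0.0]), "corrected frame")
    return ResliceFrame(origin=c, axis_u=u, axis_v=n)


def corrected_friedman_version(lm: CorrectedLandmarks) -> VersionResult:
    """Friedman measurement taken in the corrected transverse plane.

    The 3-D rim and medial-axis landmarks are orthogonally projected into the
    corrected frame; because the frame is built from the (equally transformed)
    scapular landmarks, the result is invariant to patient pose.
    """
    frame = corrected_transverse_frame(
        lm.glenoid_center,
        lm.medial_border,
        lm.inferior_angle,
        orient_hint=lm.glenoid_posterior - lm.glenoid_anterior,
    )
    a2 = project_to_frame(frame, lm.glenoid_anterior)
    p2 = project_to_frame(frame, lm.glenoid_posterior)
    m2 = project_to_frame(frame, lm.medial_axis_point)
    version = line_version_2d(a2, p2, m2)
    return VersionResult(
        method="corrected_friedman",
        version_deg=version,
        diagnostics={"frame": frame},
    )


def corrected_friedman_version_2d(anterior, posterior, medial_reference) -> VersionResult:
    """Corrected Friedman from points picked directly on a resliced image.

    Alternative input path for the manual workflow: the annotator re-picks the
    Friedman landmarks on the 2-D slice generated along the corrected frame,
    bypassing the 3-D projection.
    """
    version = line_version_2d(anterior, posterior, medial_reference)
    return VersionResult(method="corrected_friedman", version_deg=version)
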