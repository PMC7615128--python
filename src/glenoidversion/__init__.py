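"""glenoidversion: landmark-based measurement of glenoid version.

Implements the four measurement methods most used in shoulder arthroplasty
planning — the 3-D two-plane and corrected-Friedman methods and the 2-D
Friedman and vault methods — together with 3DSlicer landmark I/O, oblique CT
reslicing along the corrected transverse scapular plane, a synthetic scapula
generator with known ground truth, and summary/agreement statistics.
"""

from .geometry import (
    DegenerateGeometryError,
    OrientationAmbiguityError,
    Plane,
    ResliceFrame,
    angle_deg,
    fit_plane,
    project_to_frame,
)
from .methods import (
    METHOD_NAMES,
    AxialLandmarks,
    CorrectedLandmarks,
    TwoPlaneLandmarks,
    VersionResult,
    corrected_friedman_version,
    corrected_friedman_version_2d,
    corrected_transverse_frame,
    friedman_version,
    line_version_2d,
    two_plane_version,
    vault_version,
)
from .io import (
    LandmarkSet,
    ResultsTable,
    RoleMap,
    read_fcsv,
    read_landmarks,
    read_markups_json,
    resolve_roles,
)
from .reslice import ImageVolume, Slice2D, load_nifti, reslice, sample_trilinear
from .synthetic import (
    PoseTransform,
    SyntheticCase,
    SyntheticParams,
    axial_project,
    generate_batch,
    generate_case,
    make_affine_volume,
)
from .evaluation import CorrelationResult, SummaryStats, pearson, summarize

__version__ = "0.1.0"

__all__ = [
    "DegenerateGeometryError", "OrientationAmbiguityError",
    "Plane", "ResliceFrame", "angle_deg", "fit_plane", "project_to_frame",
    "METHOD_NAMES", "AxialLandmarks", "CorrectedLandmarks", "TwoPlaneLandmarks",
    "VersionResult", "corrected_friedman_version", "corrected_friedman_version_2d",
    "corrected_transverse_frame", "friedman_version", "line_version_2d",
    "two_plane_version", "vault_version",
    "LandmarkSet", "ResultsTable", "RoleMap",
    "read_fcsv", "read_landmarks", "read_markups_json", "resolve_roles",
    "ImageVolume", "Slice2D", "load_nifti", "reslice", "sample_trilinear",
    "PoseTransform", "SyntheticCase", "SyntheticParams",
    "axial_project", "generate_batch", "generate_case", "make_affine_volume",
    "CorrelationResult", "SummaryStats", "pearson", "summarize",
    "measure_case",
]


def measure_case(landmarks, methods=METHOD_NAMES, role_map=None):
    """Run the requested methods on one landmark set; returns a dict of
    method name -> VersionResult."""
    from .io import resolve_roles as _resolve

    out = {}
    for method in methods:
        record, _ = _resolve(landmarks, method, role_map)
        if method == "two_plane":
            out[method] = two_plane_version(record)
        elif method == "friedman":
            out[method] = friedman_version(record)
        elif method == "vault":
            out[method] = vault_version(record)
        else:
            out[method] = corrected_friedman_version(record)
    return out
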