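"""Oblique 2-D slice extraction from 3-D scalar volumes.

Supports the corrected-Friedman image workflow: once the corrected transverse
scapular frame is known, a new 2-D image slice is resampled from the CT
volume along that frame so the Friedman landmarks can be re-picked on it.

The voxel model is node-centred: the volume origin is the world position of
the *centre* of voxel (0, 0, 0) and continuous index ``i`` runs over
``[0, n-1]`` along each axis (NIfTI convention).  Interpolation is trilinear;
points strictly outside the grid return a caller-supplied fill value
(default -1024, air in Hounsfield units).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .geometry import ResliceFrame, as_point3, embed_from_frame

__all__ = [
    "ImageVolume",
    "Slice2D",
    "sample_trilinear",
    "reslice",
    "load_nifti",
    "save_slice_csv",
    "save_slice_png",
]

DEFAULT_FILL_HU = -1024.0


@dataclass
class ImageVolume:
    """A 3-D scalar grid with geometry, in the internal LPS-like frame.

    ``values[i, j, k]`` is the sample at continuous index (i, j, k); world
    position of an index is ``origin + direction @ (index * spacing)``.
    """

    values: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"volume must be 3-D, got shape {self.values.shape}")
        self.spacing = np.asarray(self.spacing, dtype=float)
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise ValueError("spacing must be three positive values (mm)")
        self.origin = as_point3(self.origin, "origin")
        self.direction = np.asarray(self.direction, dtype=float)
        if self.direction.shape != (3, 3) or not np.allclose(
            self.direction.T @ self.direction, np.eye(3), atol=1e-9
        ):
            raise ValueError("direction must be a 3x3 orthonormal matrix")

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Map world points (N, 3) to continuous indices (N, 3)."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        return ((p - self.origin) @ self.direction) / self.spacing

    def index_to_world(self, indices: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return (idx * self.spacing) @ self.direction.T + self.origin


@dataclass
class Slice2D:
    """A resampled oblique slice carrying its 3-D frame.

    ``values[j, i]`` is the pixel at column ``i`` (along ``frame.axis_u``) and
    row ``j`` (along ``frame.axis_v``); the slice is centred on the frame
    origin.
    """

    values: np.ndarray
    frame: ResliceFrame
    pixel_spacing: float
    fill_value: float = DEFAULT_FILL_HU

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def height(self) -> int:
        return self.values.shape[0]

    def pixel_to_world(self, i, j) -> np.ndarray:
        """World position of pixel centre (i, j); exact round trip with the frame."""
        u = (np.asarray(i, dtype=float) - (self.width - 1) / 2.0) * self.pixel_spacing
        v = (np.asarray(j, dtype=float) - (self.height - 1) / 2.0) * self.pixel_spacing
        return embed_from_frame(self.frame, (float(u), float(v)))

    def pixel_to_plane_uv(self, i, j) -> np.ndarray:
        """In-plane (u, v) mm coordinates of pixel (i, j) in the slice frame."""
        return np.array([
            (float(i) - (self.width - 1) / 2.0) * self.pixel_spacing,
            (float(j) - (self.height - 1) / 2.0) * self.pixel_spacing,
        ])


def sample_trilinear(vol: ImageVolume, points, fill: float = DEFAULT_FILL_HU):
    """Trilinear interpolation of the volume at world points.

    ``points`` may be a single (3,) point or an (N, 3) array.  Points outside
    the index range [0, n-1] on any axis return ``fill``.
    """
    pts = np.asarray(points, dtype=float)
    single = pts.ndim == 1
    idx = vol.world_to_index(pts)
    inside = np.all(
        (idx >= 0.0) & (idx <= np.asarray(vol.shape, dtype=float) - 1.0), axis=1
    )
    out = np.full(idx.shape[0], float(fill))
    if np.any(inside):
        out[inside] = map_coordinates(
            vol.values, idx[inside].T, order=1, mode="nearest"
        )
    return float(out[0]) if single else out


def reslice(
    vol: ImageVolume,
    frame: ResliceFrame,
    width: int = 256,
    height: int = 256,
    pixel_spacing: float = 0.5,
    fill: float = DEFAULT_FILL_HU,
) -> Slice2D:
    """Resample a 2-D oblique slice along ``frame``, centred on its origin.

    Pixel (i, j) is sampled at
    ``origin + (i - (w-1)/2) s * axis_u + (j - (h-1)/2) s * axis_v``.
    """
    if width < 1 or height < 1:
        raise ValueError("width and height must be >= 1")
    if pixel_spacing <= 0:
        raise ValueError("pixel_spacing must be positive (mm)")
    i = np.arange(width, dtype=float) - (width - 1) / 2.0
    j = np.arange(height, dtype=float) - (height - 1) / 2.0
    jj, ii = np.meshgrid(j, i, indexing="ij")
    pts = (
        frame.origin[None, :]
        + (ii.ravel() * pixel_spacing)[:, None] * frame.axis_u[None, :]
        + (jj.ravel() * pixel_spacing)[:, None] * frame.axis_v[None, :]
    )
    values = sample_trilinear(vol, pts, fill=fill).reshape(height, width)
    return Slice2D(values=values, frame=frame, pixel_spacing=float(pixel_spacing), fill_value=float(fill))


def load_nifti(path) -> ImageVolume:
    """Read a NIfTI volume and express its geometry in the internal LPS frame.

    NIfTI affines are RAS; the first two world axes are negated on ingest.
    Requires an orthogonal voxel lattice (no shear).
    """
    import nibabel as nib

    img = nib.load(str(path))
    affine = np.asarray(img.affine, dtype=float)
    lps = np.diag([-1.0, -1.0, 1.0, 1.0]) @ affine
    linear = lps[:3, :3]
    spacing = np.linalg.norm(linear, axis=0)
    if np.any(spacing <= 0):
        raise ValueError(f"{path}: degenerate voxel spacing in affine")
    direction = linear / spacing
    if not np.allclose(direction.T @ direction, np.eye(3), atol=1e-6):
        raise ValueError(f"{path}: sheared affine; only orthogonal lattices are supported")
    # re-orthonormalise header float noise
    u_, _, vt_ = np.linalg.svd(direction)
    direction = u_ @ vt_
    return ImageVolume(
        values=np.asarray(img.get_fdata(), dtype=float),
        spacing=spacing,
        origin=lps[:3, 3],
        direction=direction,
    )


def save_slice_csv(sl: Slice2D, path) -> None:
    """Write the raw pixel grid as CSV (rows = v axis, columns = u axis)."""
    np.savetxt(str(path), sl.values, delimiter=",", fmt="%.10g")


def save_slice_png(sl: Slice2D, path, window=None) -> None:
    """Write an 8-bit windowed PNG of the slice.

    ``window`` is (low, high) in image units; defaults to the data range.
    """
    from PIL import Image

    lo, hi = window if window is not None else (float(sl.values.min()), float(sl.values.max()))
    if hi <= lo:
        hi = lo + 1.0
    scaled = np.clip((sl.values - lo) / (hi - lo), 0.0, 1.0)
    Image.fromarray((scaled * 255).astype(np.uint8), mode="L").save(str(path))
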