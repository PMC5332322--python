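"""Scanner geometry and image containers.

The scanner is modelled as a parallel-bin sinogram sampler: ``n_views``
azimuthal angles uniformly covering [0, pi) and ``n_radial`` radial bins
spanning the transaxial field of view.  A 3D acquisition is represented as
``n_planes`` independent, identical 2D planes ("stacked-2D"); there are no
oblique lines of response.  All lengths are millimetres and attenuation is
mm^-1 at 511 keV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ScannerGeometry", "ImageVolume", "MaskVolume"]


@dataclass(frozen=True)
class ScannerGeometry:
    """Parallel-beam LOR layout plus the reconstruction voxel grid.

    Parameters
    ----------
    n_views:
        Number of azimuthal projection angles over the half circle.
    n_radial:
        Number of radial bins per view; bin spacing is ``fov_mm / n_radial``.
    n_planes:
        Number of transversal planes (1 for a single 2D ring).
    fov_mm:
        Transaxial field-of-view diameter in mm.
    grid_shape:
        ``(nx, ny, nz)`` voxel counts of the image grid.
    voxel_mm:
        ``(dx, dy, dz)`` voxel spacing in mm.
    """

    n_views: int = 120
    n_radial: int = 128
    n_planes: int = 1
    fov_mm: float = 256.0
    grid_shape: tuple[int, int, int] = (128, 128, 1)
    voxel_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)

    def __post_init__(self) -> None:
        if self.n_views < 2 or self.n_radial < 2:
            raise ValueError("need n_views >= 2 and n_radial >= 2")
        if self.n_planes < 1:
            raise ValueError("n_planes must be >= 1")
        if len(self.grid_shape) != 3 or len(self.voxel_mm) != 3:
            raise ValueError("grid_shape and voxel_mm must be length-3 tuples")
        if self.grid_shape[2] != self.n_planes:
            raise ValueError(
                f"grid nz={self.grid_shape[2]} must equal n_planes={self.n_planes} "
                "(stacked-2D geometry)"
            )
        # full transaxial coverage: the radial bins must span the FOV
        if self.radial_spacing * self.n_radial < self.fov_mm - 1e-9:
            raise ValueError("radial bins do not cover the transaxial FOV")
        # grid must sit inside the FOV so every voxel is crossed by LORs
        nx, ny, _ = self.grid_shape
        dx, dy, _ = self.voxel_mm
        if nx * dx > self.fov_mm + 1e-9 or ny * dy > self.fov_mm + 1e-9:
            raise ValueError("image grid extends beyond the scanner FOV")

    # -- derived layout ----------------------------------------------------
    @property
    def mode(self) -> str:
        return "2D-ring" if self.n_planes == 1 else "stacked-2D"

    @property
    def radial_spacing(self) -> float:
        return self.fov_mm / self.n_radial

    @property
    def sino_shape(self) -> tuple[int, int, int]:
        """(n_views, n_radial, n_planes)."""
        return (self.n_views, self.n_radial, self.n_planes)

    @property
    def n_lors(self) -> int:
        return self.n_views * self.n_radial * self.n_planes

    def view_angles(self) -> np.ndarray:
        """Azimuthal angles in radians, uniform over [0, pi)."""
        return np.pi * np.arange(self.n_views) / self.n_views

    def radial_offsets(self) -> np.ndarray:
        """Signed radial offsets of the bin centres from the scanner axis, mm."""
        n = self.n_radial
        return (np.arange(n) - (n - 1) / 2.0) * self.radial_spacing

    def voxel_centers(self, axis: int) -> np.ndarray:
        """Voxel-centre coordinates along ``axis`` (0=x, 1=y, 2=z), mm,
        centred on the scanner axis."""
        n = self.grid_shape[axis]
        d = self.voxel_mm[axis]
        return (np.arange(n) - (n - 1) / 2.0) * d

    def coordinate_grids(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable (x, y, z) voxel-centre coordinate arrays in mm."""
        x = self.voxel_centers(0)[:, None, None]
        y = self.voxel_centers(1)[None, :, None]
        z = self.voxel_centers(2)[None, None, :]
        return x, y, z


@dataclass
class ImageVolume:
    """A voxel grid carrying activity (a.u.) or attenuation (mm^-1)."""

    values: np.ndarray
    voxel_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim == 2:  # allow single-plane 2D input
            self.values = self.values[:, :, None]
        if self.values.ndim != 3:
            raise ValueError("image values must be a 3D (nx, ny, nz) array")
        self.voxel_mm = tuple(float(v) for v in self.voxel_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def copy(self) -> "ImageVolume":
        return ImageVolume(self.values.copy(), self.voxel_mm)


@dataclass
class MaskVolume:
    """A binary voxel region with a declared role.

    Roles used throughout the package: ``body-outline`` (voxels belonging to
    the patient/phantom, where the attenuation update must never write),
    ``hardware-mask`` (region searched for flexible hardware) and
    ``evaluation-region`` (quantification ROI).
    """

    values: np.ndarray
    role: str = "evaluation-region"

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.dtype != np.bool_:
            uniq = np.unique(arr)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError("mask values must be binary (0/1)")
            arr = arr.astype(bool)
        if arr.ndim == 2:
            arr = arr[:, :, None]
        if arr.ndim != 3:
            raise ValueError("mask must be a 3D (nx, ny, nz) array")
        self.values = arr

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())


def as_image_array(image, geometry: ScannerGeometry | None = None) -> np.ndarray:
    """Coerce an ImageVolume or array to a float64 (nx, ny, nz) array,
    optionally checked against a geometry's grid."""
    if isinstance(image, ImageVolume):
        arr = image.values
    else:
        arr = np.asarray(image, dtype=np.float64)
        if arr.ndim == 2:
            arr = arr[:, :, None]
    if geometry is not None and arr.shape != geometry.grid_shape:
        raise ValueError(
            f"image shape {arr.shape} does not match geometry grid "
            f"{geometry.grid_shape}"
        )
    return np.asarray(arr, dtype=np.float64)
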