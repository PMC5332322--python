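"""Joseph-type single-beam forward and backprojection.

The system matrix element ``M_ij`` is the Joseph interpolation weight of
voxel ``i`` for LOR ``j`` multiplied by the step length along the ray, so a
forward projection of an image in mm^-1 yields a dimensionless line integral
and a forward projection of a 0/1 support yields chord lengths in mm.  The
same matrix therefore serves both as the emission system matrix and as the
intersection-length operator ``l_ij`` used by attenuation correction factors
and the attenuation update.

For each LOR the driving axis is the grid axis most aligned with the ray;
the ray is sampled once per voxel plane along that axis, with linear
interpolation between the two straddling voxels in the orthogonal in-plane
direction and a step length of (voxel spacing along the driving axis) /
(direction cosine).  The backprojector is the exact adjoint: it applies the
transpose of the same sparse matrix.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import scipy.sparse as sp

from .geometry import ImageVolume, ScannerGeometry, as_image_array

__all__ = ["system_matrix", "forward_project", "back_project", "path_lengths"]


def _joseph_entries_for_view(geom: ScannerGeometry, theta: float):
    """COO triplets (radial bin, voxel flat index, weight mm) for one view."""
    nx, ny, _ = geom.grid_shape
    dx, dy, _ = geom.voxel_mm
    s = geom.radial_offsets()  # (n_radial,)
    c, snt = np.cos(theta), np.sin(theta)

    rows, cols, vals = [], [], []
    if abs(c) >= abs(snt):
        # drive along x: y(x) = x * tan(theta) + s / cos(theta)
        step = dx / abs(c)
        xc = geom.voxel_centers(0)  # (nx,)
        y = xc[None, :] * (snt / c) + s[:, None] / c  # (n_radial, nx)
        fy = y / dy + (ny - 1) / 2.0  # fractional y index
        i0 = np.floor(fy).astype(np.int64)
        frac = fy - i0
        ix = np.broadcast_to(np.arange(nx)[None, :], fy.shape)
        rr = np.broadcast_to(np.arange(geom.n_radial)[:, None], fy.shape)
        for ii, ww in ((i0, 1.0 - frac), (i0 + 1, frac)):
            ok = (ii >= 0) & (ii < ny) & (ww > 0)
            rows.append(rr[ok])
            cols.append(ix[ok] * ny + ii[ok])
            vals.append(ww[ok] * step)
    else:
        # drive along y: x(y) = y * cot(theta) - s / sin(theta)
        step = dy / abs(snt)
        yc = geom.voxel_centers(1)  # (ny,)
        x = yc[None, :] * (c / snt) - s[:, None] / snt  # (n_radial, ny)
        fx = x / dx + (nx - 1) / 2.0
        i0 = np.floor(fx).astype(np.int64)
        frac = fx - i0
        iy = np.broadcast_to(np.arange(ny)[None, :], fx.shape)
        rr = np.broadcast_to(np.arange(geom.n_radial)[:, None], fx.shape)
        for ii, ww in ((i0, 1.0 - frac), (i0 + 1, frac)):
            ok = (ii >= 0) & (ii < nx) & (ww > 0)
            rows.append(rr[ok])
            cols.append(ii[ok] * ny + iy[ok])
            vals.append(ww[ok] * step)
    return (np.concatenate(rows), np.concatenate(cols), np.concatenate(vals))


@lru_cache(maxsize=8)
def system_matrix(geom: ScannerGeometry) -> sp.csr_matrix:
    """In-plane system matrix of shape (n_views * n_radial, nx * ny).

    Row index is ``view * n_radial + radial``; column index is the flattened
    (x, y) voxel index.  Entries are intersection weights in mm.  Cached per
    geometry; the 3D (stacked-2D) operator applies this matrix plane by
    plane.
    """
    all_rows, all_cols, all_vals = [], [], []
    for v, theta in enumerate(geom.view_angles()):
        r, c, w = _joseph_entries_for_view(geom, theta)
        all_rows.append(r + v * geom.n_radial)
        all_cols.append(c)
        all_vals.append(w)
    nx, ny, _ = geom.grid_shape
    mat = sp.coo_matrix(
        (np.concatenate(all_vals), (np.concatenate(all_rows), np.concatenate(all_cols))),
        shape=(geom.n_views * geom.n_radial, nx * ny),
    )
    return mat.tocsr()


def _check_sino(sino, geom: ScannerGeometry) -> np.ndarray:
    arr = np.asarray(sino, dtype=np.float64)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    if arr.shape != geom.sino_shape:
        raise ValueError(
            f"sinogram shape {arr.shape} does not match geometry {geom.sino_shape}"
        )
    return arr


def forward_project(image, geom: ScannerGeometry) -> np.ndarray:
    """Line integrals of ``image`` along every LOR.

    Returns an array of shape ``geom.sino_shape``; units are (image units)
    times mm.
    """
    arr = as_image_array(image, geom)
    nx, ny, nz = geom.grid_shape
    mat = system_matrix(geom)
    # (nx*ny, nz) -> (n_views*n_radial, nz)
    flat = arr.reshape(nx * ny, nz)
    out = mat @ flat
    return np.asarray(out).reshape(geom.sino_shape)


def back_project(sino, geom: ScannerGeometry) -> ImageVolume:
    """Adjoint of :func:`forward_project`."""
    arr = _check_sino(sino, geom)
    nx, ny, nz = geom.grid_shape
    mat = system_matrix(geom)
    flat = arr.reshape(geom.n_views * geom.n_radial, nz)
    out = mat.T @ flat
    return ImageVolume(np.asarray(out).reshape(nx, ny, nz), geom.voxel_mm)


def path_lengths(mu_support, geom: ScannerGeometry) -> np.ndarray:
    """Chord length (mm) of every LOR through a 0/1 support volume."""
    arr = as_image_array(mu_support, geom)
    uniq = np.unique(arr)
    if not np.all(np.isin(uniq, (0.0, 1.0))):
        raise ValueError("path_lengths expects a binary 0/1 indicator volume")
    return forward_project(arr, geom)
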