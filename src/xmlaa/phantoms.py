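"""Voxel phantoms, hardware masks and attenuation-map corruptions.

The generators emulate a PET/MR bed position with flexible hardware in the
field of view: a warm water-equivalent body (cylinder or ellipse) plus cold,
attenuating hardware (headphone earpads, a headband, an RF surface coil
shell).  A voxel belongs to a shape iff its centre lies inside the shape,
which makes every phantom bit-reproducible from its parameters alone.

Default attenuation values at 511 keV: water 0.0096 mm^-1, generic hardware
material 0.01 mm^-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple
import warnings

import numpy as np
from scipy import ndimage

from .geometry import ImageVolume, MaskVolume, ScannerGeometry, as_image_array

__all__ = [
    "PhantomSpec",
    "Phantom",
    "make_simulation_phantom",
    "make_hp_phantom",
    "make_rf_phantom",
    "derive_body_outline",
    "inject_air_cavity",
    "inject_fat_water_inversion",
]

MU_WATER = 0.0096  # mm^-1 at 511 keV
MU_HARDWARE = 0.01  # mm^-1, generic plastic/foam hardware material


class Phantom(NamedTuple):
    """Ground-truth volumes and masks for one phantom configuration."""

    mu_true: ImageVolume          # full attenuation map (body + hardware)
    mu_body: ImageVolume          # body-only attenuation map (xMLAA init)
    lambda_true: ImageVolume      # activity, arbitrary units
    body_mask: MaskVolume         # role body-outline
    hardware_mask: MaskVolume     # role hardware-mask
    evaluation_mask: MaskVolume   # role evaluation-region


@dataclass
class PhantomSpec:
    """Declarative description of the warm/cold earpad simulation phantom.

    All lengths in mm, attenuation in mm^-1, activity in a.u.
    """

    body_diameter: float = 150.0
    mu_body: float = 0.01
    lambda_body: float = 1.0
    # pad thickness (x semi-axis) calibrated so the ground-truth mean
    # hardware-only ACF over the hardware-mask sinogram support is ~1.10,
    # the magnitude measured for real headphones with CT-based templates
    earpad_semi_axes: tuple[float, float, float] = (10.0, 35.0, 45.0)
    earpad_gap: float = 0.0        # gap between body surface and pad
    mu_earpad: float = 0.01
    lambda_warm: float = 1.0
    warm_side: str = "left"        # which pad carries activity
    # hardware mask: annulus from just outside the body to just beyond the
    # pads' outer extent — the outer boundary should enclose the hardware as
    # tightly as the compensation margin allows
    mask_inner_margin: float = 2.0  # annulus inner gap to the body, mm
    mask_outer_radius: float = 106.0
    eval_half_width: float = 40.0   # evaluation box is 80 mm wide ...
    eval_half_height: float = 20.0  # ... and 40 mm tall
    axial_trim_planes: int = 0      # z-planes removed from each mask end


# --------------------------------------------------------------------------
# shape rasterizers (voxel centre in shape)
# --------------------------------------------------------------------------

def _cylinder(geom: ScannerGeometry, center_xy, radius) -> np.ndarray:
    x, y, z = geom.coordinate_grids()
    inside = (x - center_xy[0]) ** 2 + (y - center_xy[1]) ** 2 <= radius**2
    return np.broadcast_to(inside, geom.grid_shape).copy()

def _ellipse_cylinder(geom, center_xy, semi_xy) -> np.ndarray:
    x, y, z = geom.coordinate_grids()
    inside = ((x - center_xy[0]) / semi_xy[0]) ** 2 + (
        (y - center_xy[1]) / semi_xy[1]
    ) ** 2 <= 1.0
    return np.broadcast_to(inside, geom.grid_shape).copy()

def _ellipsoid(geom, center, semi_axes) -> np.ndarray:
    x, y, z = geom.coordinate_grids()
    q = (
        ((x - center[0]) / semi_axes[0]) ** 2
        + ((y - center[1]) / semi_axes[1]) ** 2
        + ((z - center[2]) / semi_axes[2]) ** 2
    )
    return q <= 1.0

def _sphere(geom, center, radius) -> np.ndarray:
    x, y, z = geom.coordinate_grids()
    q = (x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2
    return q <= radius**2

def _arc_shell(geom, center_xy, r_inner, r_outer, ang_center, ang_half) -> np.ndarray:
    """Annular arc in the transversal plane; angles in radians, measured from
    +x axis; ``ang_center`` is the arc midpoint, ``ang_half`` its half width."""
    x, y, z = geom.coordinate_grids()
    r2 = (x - center_xy[0]) ** 2 + (y - center_xy[1]) ** 2
    ang = np.arctan2(y - center_xy[1], x - center_xy[0])
    dang = np.angle(np.exp(1j * (ang - ang_center)))
    inside = (r2 >= r_inner**2) & (r2 <= r_outer**2) & (np.abs(dang) <= ang_half)
    return np.broadcast_to(inside, geom.grid_shape).copy()

def _box(geom, center, half_extent) -> np.ndarray:
    x, y, z = geom.coordinate_grids()
    inside = (
        (np.abs(x - center[0]) <= half_extent[0])
        & (np.abs(y - center[1]) <= half_extent[1])
        & (np.abs(z - center[2]) <= half_extent[2])
    )
    return np.broadcast_to(inside, geom.grid_shape).copy()


def _trim_axial(mask: np.ndarray, n_trim: int) -> np.ndarray:
    """Zero the outermost ``n_trim`` planes on each axial end (low detector
    sensitivity there makes emission-based attenuation estimates too noisy)."""
    if n_trim <= 0:
        return mask
    out = mask.copy()
    out[:, :, :n_trim] = False
    out[:, :, mask.shape[2] - n_trim:] = False
    return out


# --------------------------------------------------------------------------
# phantoms
# --------------------------------------------------------------------------

def make_simulation_phantom(
    geom: ScannerGeometry, spec: PhantomSpec | None = None
) -> Phantom:
    """Warm/cold two-earpad phantom.

    A 150 mm diameter cylindrical body (mu = 0.01 mm^-1, lambda = 1 a.u.)
    flanked left and right by two ellipsoidal earpads (mu = 0.01 mm^-1); one
    pad is warm (lambda = 1), the other cold (lambda = 0).  The hardware mask
    is an annulus around the body enclosing both pads; the evaluation region
    is a box inside the body between the pads' inner faces.
    """
    spec = spec or PhantomSpec()
    if spec.warm_side not in ("left", "right"):
        raise ValueError("warm_side must be 'left' or 'right'")
    r_body = spec.body_diameter / 2.0
    ax, ay, az = spec.earpad_semi_axes
    pad_center_x = r_body + spec.earpad_gap + ax
    if geom.fov_mm < 2 * (pad_center_x + ax) or geom.fov_mm < 220.0:
        raise ValueError("geometry FOV too small to contain body and both earpads")

    zc = geom.voxel_centers(2)
    z_mid = float(zc[(len(zc) - 1) // 2]) if len(zc) % 2 else 0.0

    body = _cylinder(geom, (0.0, 0.0), r_body)
    pad_left = _ellipsoid(geom, (-pad_center_x, 0.0, z_mid), (ax, ay, az))
    pad_right = _ellipsoid(geom, (pad_center_x, 0.0, z_mid), (ax, ay, az))
    if (body & (pad_left | pad_right)).any():
        raise ValueError("earpad ellipsoids collide with the body cylinder")

    mu = np.zeros(geom.grid_shape)
    mu[body] = spec.mu_body
    mu[pad_left | pad_right] = spec.mu_earpad
    mu_body = np.zeros(geom.grid_shape)
    mu_body[body] = spec.mu_body

    lam = np.zeros(geom.grid_shape)
    lam[body] = spec.lambda_body
    warm = pad_left if spec.warm_side == "left" else pad_right
    lam[warm] = spec.lambda_warm

    hw = _cylinder(geom, (0.0, 0.0), spec.mask_outer_radius) & ~_cylinder(
        geom, (0.0, 0.0), r_body + spec.mask_inner_margin
    )
    hw = _trim_axial(hw, spec.axial_trim_planes)

    # central evaluation box between the two pads, strictly inside the body
    h = spec.eval_half_height
    half_x = min(
        spec.eval_half_width,
        pad_center_x - ax - 2.0,
        np.sqrt(max(r_body**2 - h**2, 0.0)) - 2.0,
    )
    half_z = min(20.0, (geom.grid_shape[2] * geom.voxel_mm[2]) / 2.0)
    ev = _box(geom, (0.0, 0.0, z_mid), (half_x, h, half_z)) & body

    return Phantom(
        mu_true=ImageVolume(mu, geom.voxel_mm),
        mu_body=ImageVolume(mu_body, geom.voxel_mm),
        lambda_true=ImageVolume(lam, geom.voxel_mm),
        body_mask=MaskVolume(body, "body-outline"),
        hardware_mask=MaskVolume(hw, "hardware-mask"),
        evaluation_mask=MaskVolume(ev, "evaluation-region"),
    )


def make_hp_phantom(
    geom: ScannerGeometry,
    mu_body: float = MU_WATER,
    mu_hardware: float = MU_HARDWARE,
    mu_band: float = 0.005,
    axial_trim_planes: int = 0,
) -> Phantom:
    """Headphone experiment: a warm 150 mm water cylinder wearing cold
    headphones (two earpad ellipsoids joined by a thin headband arc; the
    strap is much lighter material than the dense earpad cups).

    The hardware mask is the annular interior of a head coil surrounding the
    phantom; the evaluation region is a centred box inside the body.
    """
    r_body = 75.0
    ax, ay, az = 10.0, 35.0, 45.0
    pad_x = r_body + ax
    zc = geom.voxel_centers(2)
    z_mid = float(zc[(len(zc) - 1) // 2]) if len(zc) % 2 else 0.0

    body = _cylinder(geom, (0.0, 0.0), r_body)
    pads = _ellipsoid(geom, (-pad_x, 0.0, z_mid), (ax, ay, az)) | _ellipsoid(
        geom, (pad_x, 0.0, z_mid), (ax, ay, az)
    )
    band = _arc_shell(geom, (0.0, 0.0), 104.0, 110.0, np.pi / 2.0, np.deg2rad(55.0))
    hardware = (pads | band) & ~body
    if (body & pads).any():
        raise ValueError("earpads collide with the body")

    mu_full = np.zeros(geom.grid_shape)
    mu_full[body] = mu_body
    mu_full[band & ~body] = mu_band
    mu_full[pads & ~body] = mu_hardware
    mu_b = np.zeros(geom.grid_shape)
    mu_b[body] = mu_body
    lam = np.zeros(geom.grid_shape)
    lam[body] = 1.0

    hw_mask = _cylinder(geom, (0.0, 0.0), 118.0) & ~_cylinder(geom, (0.0, 0.0), r_body + 4.0)
    hw_mask = _trim_axial(hw_mask, axial_trim_planes)
    ev = _box(geom, (0.0, 0.0, z_mid), (58.0, 20.0, 20.0)) & body

    return Phantom(
        ImageVolume(mu_full, geom.voxel_mm),
        ImageVolume(mu_b, geom.voxel_mm),
        ImageVolume(lam, geom.voxel_mm),
        MaskVolume(body, "body-outline"),
        MaskVolume(hw_mask, "hardware-mask"),
        MaskVolume(ev, "evaluation-region"),
    )


def make_rf_phantom(
    geom: ScannerGeometry,
    mu_body: float = MU_WATER,
    mu_shell: float = 0.006,
    mu_inclusion: float = 0.05,
    axial_trim_planes: int = 0,
) -> Phantom:
    """RF surface-coil experiment: a warm elliptical water phantom (pelvis
    analogue) with a cold coil shell draped on top.

    The shell is an arc of moderate attenuation carrying a few small highly
    attenuating inclusions (electronics); the hardware mask is an elliptical
    annulus enclosing the coil's physical outline.
    """
    a_body, b_body = 95.0, 60.0
    zc = geom.voxel_centers(2)
    z_mid = float(zc[(len(zc) - 1) // 2]) if len(zc) % 2 else 0.0

    body = _ellipse_cylinder(geom, (0.0, 0.0), (a_body, b_body))
    shell = _arc_shell(geom, (0.0, -20.0), 84.0, 94.0, np.pi / 2.0, np.deg2rad(60.0))
    shell &= ~body
    # small cylindrical inclusions along the shell midline
    incl = np.zeros(geom.grid_shape, dtype=bool)
    r_mid = 89.0
    for ang in np.deg2rad([55.0, 90.0, 125.0]):
        cx, cy = r_mid * np.cos(ang), -20.0 + r_mid * np.sin(ang)
        incl |= _cylinder(geom, (cx, cy), 5.0)
    incl &= shell

    mu_full = np.zeros(geom.grid_shape)
    mu_full[body] = mu_body
    mu_full[shell] = mu_shell
    mu_full[incl] = mu_inclusion
    mu_b = np.zeros(geom.grid_shape)
    mu_b[body] = mu_body
    lam = np.zeros(geom.grid_shape)
    lam[body] = 1.0

    hw_mask = _ellipse_cylinder(geom, (0.0, 0.0), (a_body + 25.0, b_body + 45.0))
    hw_mask &= ~_ellipse_cylinder(geom, (0.0, 0.0), (a_body + 4.0, b_body + 4.0))
    hw_mask = _trim_axial(hw_mask, axial_trim_planes)
    ev = _box(geom, (0.0, 0.0, z_mid), (70.0, 40.0, 20.0)) & body

    return Phantom(
        ImageVolume(mu_full, geom.voxel_mm),
        ImageVolume(mu_b, geom.voxel_mm),
        ImageVolume(lam, geom.voxel_mm),
        MaskVolume(body, "body-outline"),
        MaskVolume(hw_mask, "hardware-mask"),
        MaskVolume(ev, "evaluation-region"),
    )


# --------------------------------------------------------------------------
# masks and attenuation-map corruptions
# --------------------------------------------------------------------------

def derive_body_outline(
    mu_init, threshold: float = 0.005, dilation_vox: int = 0
) -> MaskVolume:
    """Body outline from an initial attenuation map: voxels above
    ``threshold`` (mm^-1), morphologically closed, then dilated."""
    arr = as_image_array(mu_init)
    if (arr < 0).any():
        raise ValueError("attenuation map must be non-negative")
    outline = arr > threshold
    if outline.any():
        # in-plane structuring element when the volume is a single plane
        nz = 3 if arr.shape[2] >= 3 else 1
        structure = np.ones((3, 3, nz), dtype=bool)
        outline = ndimage.binary_closing(outline, structure=structure)
        if dilation_vox > 0:
            outline = ndimage.binary_dilation(
                outline, structure=structure, iterations=dilation_vox
            )
    else:
        warnings.warn("empty body outline (air scan?)", stacklevel=2)
    return MaskVolume(outline, "body-outline")


def inject_air_cavity(mu, center_mm, diameter_mm: float, geom: ScannerGeometry) -> ImageVolume:
    """Zero the attenuation inside a sphere — emulates a segmentation error
    where an air cavity is wrongly carved into the attenuation map."""
    arr = as_image_array(mu, geom).copy()
    if diameter_mm > 0:
        r = diameter_mm / 2.0
        c = tuple(center_mm)
        for ax, n in enumerate(geom.grid_shape):
            if n == 1:  # single-plane axis: the sphere cuts it as a disc
                continue
            coords = geom.voxel_centers(ax)
            if c[ax] - r < coords[0] - geom.voxel_mm[ax] / 2 or c[ax] + r > coords[-1] + geom.voxel_mm[ax] / 2:
                raise ValueError("air-cavity sphere extends outside the grid")
        arr[_sphere(geom, c, r)] = 0.0
    return ImageVolume(arr, geom.voxel_mm)


def inject_fat_water_inversion(mu, body_mask: MaskVolume, factor: float) -> ImageVolume:
    """Scale body attenuation by ``factor`` — emulates a fat/water tissue
    inversion in MR-based attenuation maps (typical factor 0.85)."""
    if factor <= 0:
        raise ValueError("scale factor must be positive")
    arr = as_image_array(mu).copy()
    arr[body_mask.values] *= factor
    return ImageVolume(arr)
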