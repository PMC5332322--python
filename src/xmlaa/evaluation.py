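"""Quantitative evaluation: region errors, plane profiles and ACF statistics.

The central diagnostic of hardware attenuation estimation is not the voxel
map itself — the limited angular information means the estimated shape can
be wrong — but the hardware-only attenuation correction factors along the
LORs that actually matter: those crossing the emission support.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forward_model import compute_acf
from .geometry import MaskVolume, ScannerGeometry, as_image_array
from .projector import forward_project

__all__ = [
    "AcfStats",
    "region_mean_error",
    "planewise_means",
    "hardware_acf",
    "mask_sinogram_support",
    "emission_support",
]

_AXES = {"transversal": 2, "coronal": 1, "sagittal": 0}


@dataclass(frozen=True)
class AcfStats:
    """Summary of ACF values over a stated LOR subset."""

    mean: float
    sd: float
    min: float
    max: float
    n_lors: int

    @classmethod
    def from_acf(cls, acf: np.ndarray, support: np.ndarray) -> "AcfStats":
        vals = np.asarray(acf, dtype=np.float64)[np.asarray(support, dtype=bool)]
        if vals.size == 0:
            raise ValueError("empty LOR support")
        return cls(
            mean=float(vals.mean()),
            sd=float(vals.std()),
            min=float(vals.min()),
            max=float(vals.max()),
            n_lors=int(vals.size),
        )

    def as_dict(self) -> dict:
        return {
            "mean": self.mean,
            "sd": self.sd,
            "min": self.min,
            "max": self.max,
            "n_lors": self.n_lors,
        }


def region_mean_error(lambda_test, lambda_ref, region: MaskVolume) -> float:
    """Relative error (%) of the mean activity in ``region``:
    100 * (mean(test) - mean(ref)) / mean(ref)."""
    test = as_image_array(lambda_test)
    ref = as_image_array(lambda_ref)
    m = region.values
    if not m.any():
        raise ValueError("evaluation region is empty")
    ref_mean = ref[m].mean()
    if ref_mean == 0:
        raise ValueError("reference mean is zero in the evaluation region")
    return float(100.0 * (test[m].mean() - ref_mean) / ref_mean)


def planewise_means(lam, body_mask: MaskVolume, axis: str = "transversal"):
    """Mean activity inside the body, plane by plane along ``axis``.

    Returns ``(plane_indices, means)``; planes with no body voxels are
    omitted.  Plane numbering is 0-based from the first stored plane.
    """
    if axis not in _AXES:
        raise ValueError(f"axis must be one of {sorted(_AXES)}")
    a = _AXES[axis]
    arr = as_image_array(lam)
    mask = body_mask.values
    other = tuple(i for i in range(3) if i != a)
    counts = mask.sum(axis=other)
    sums = np.where(mask, arr, 0.0).sum(axis=other)
    keep = counts > 0
    idx = np.nonzero(keep)[0]
    return idx, sums[keep] / counts[keep]


def hardware_acf(mu_full, mu_body_only, geom: ScannerGeometry) -> np.ndarray:
    """ACFs of the hardware components only: acf(mu_full) / acf(mu_body).

    Equals the ACF of (mu_full - mu_body) since the line integral is linear;
    >= 1 elementwise when the hardware only adds attenuation.
    """
    return compute_acf(mu_full, geom) / compute_acf(mu_body_only, geom)


def mask_sinogram_support(mask: MaskVolume, geom: ScannerGeometry, threshold_mm: float = 0.0) -> np.ndarray:
    """Boolean LOR set whose forward projection of ``mask`` exceeds the
    threshold (default: any non-zero intersection)."""
    return forward_project(mask.values.astype(np.float64), geom) > threshold_mm


def emission_support(body, geom: ScannerGeometry, threshold_mm: float = 1.0) -> np.ndarray:
    """LORs crossing the emission region.

    ``body`` may be a mask volume or an activity image; the support is the
    set of LORs whose forward-projected path through it exceeds
    ``threshold_mm`` — an automated stand-in for a manually segmented
    emission sinogram support.  Only these LORs need accurate ACFs.
    """
    arr = body.values.astype(np.float64) if isinstance(body, MaskVolume) else as_image_array(body, geom)
    return forward_project(arr, geom) > threshold_mm
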