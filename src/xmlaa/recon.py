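"""Alternating activity/attenuation reconstruction (external MLAA).

One outer iteration is (i) an ordinary-Poisson MLEM activity update over the
whole FOV and (ii) a gradient-style attenuation update restricted to the
hardware mask — a voxel region strictly outside the body outline where
flexible hardware (headphones, RF coils) may sit.  The activity update is

    lam_i <- lam_i * [ sum_j M_ij p_j / (sum_k M_kj lam_k + a_j (s_j + r_j n_j)) ]
                   / [ sum_j M_ij / (a_j n_j) ]

and the attenuation update, with relaxation alpha, is

    mu_i <- mu_i + alpha * (N_i + d(L_S + L_I)/d mu_i) / (D_i + C_i),
    N_i = sum_j l_ij (phat_j - p_j) (phat_j - s_j/n_j - r_j) / phat_j,
    D_i = sum_j l_ij (phat_j - s_j/n_j - r_j)
                 (1 - p_j (s_j/n_j + r_j) / phat_j^2) sum_k l_kj,

where phat uses the just-updated activity (activity first), C_i is the
non-negative prior curvature surrogate and negative results are truncated to
zero.  No subsets are used in the joint loop; the final activity image is
produced by OSEM plus a Gaussian post-filter.

The "background trick" (forcing zero attenuation on LORs without counts) is
deliberately not applied: it would also erase the attenuation of cold
hardware, which is exactly what this algorithm must recover.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np
from scipy import ndimage

from .forward_model import EPS_FLOOR, SinogramSet, compute_acf, expected_counts, objective
from .geometry import ImageVolume, MaskVolume, ScannerGeometry, as_image_array
from .priors import PriorConfig, intensity_gradient, smoothing_gradient
from .projector import back_project, forward_project

__all__ = [
    "ReconConfig",
    "mlem_update",
    "attenuation_update",
    "run_xmlaa",
    "osem_reconstruct",
    "gaussian_postfilter",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReconConfig:
    """Iteration counts and numerical knobs of the reconstruction loop."""

    n_xmlaa_iters: int = 50
    alpha: float = 4.0          # attenuation-update relaxation
    n_osem_iters: int = 3
    n_subsets: int = 21         # final OSEM only; the joint loop uses all LORs
    postfilter_fwhm_mm: float = 5.0
    eps_floor: float = EPS_FLOOR
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.n_subsets < 1:
            raise ValueError("n_subsets must be >= 1")


def _view_subsets(n_views: int, n_subsets: int) -> list[np.ndarray]:
    """Interleaved view partition: view v belongs to subset v mod n_subsets."""
    if n_views % n_subsets != 0:
        raise ValueError(f"n_subsets={n_subsets} does not divide n_views={n_views}")
    return [np.arange(s, n_views, n_subsets) for s in range(n_subsets)]


def mlem_update(
    lam,
    acf,
    sino: SinogramSet,
    geom: ScannerGeometry,
    views: np.ndarray | None = None,
    eps: float = EPS_FLOOR,
) -> np.ndarray:
    """One ordinary-Poisson MLEM activity update (optionally on a view subset).

    Voxels with zero sensitivity (no LOR coverage in the subset) are frozen at
    their current value rather than divided by zero.
    """
    lam = as_image_array(lam, geom)
    acf = np.asarray(acf, dtype=np.float64)
    vmask = np.zeros(geom.sino_shape)
    if views is None:
        vmask[:] = 1.0
    else:
        vmask[views] = 1.0

    denom = forward_project(lam, geom) + acf * (sino.scatter + sino.randoms * sino.norm)
    ratio = np.where(sino.prompts > 0, sino.prompts / np.maximum(denom, eps), 0.0)
    num = back_project(ratio * vmask, geom).values
    sens = back_project(vmask / (acf * sino.norm), geom).values
    with np.errstate(invalid="ignore"):
        out = np.where(sens > 0, lam * num / np.where(sens > 0, sens, 1.0), lam)
    return out


def attenuation_update(
    mu,
    lam,
    sino: SinogramSet,
    hardware_mask: MaskVolume,
    priors: PriorConfig,
    config: ReconConfig,
    geom: ScannerGeometry,
    total_chord: np.ndarray | None = None,
) -> np.ndarray:
    """One relaxed gradient attenuation update inside the hardware mask.

    Voxels outside the mask are returned bit-identical; negative results are
    truncated to zero; voxels whose denominator is not safely positive skip
    this iteration.
    """
    mu = as_image_array(mu, geom)
    lam = as_image_array(lam, geom)
    mask = hardware_mask.values
    eps = config.eps_floor

    acf = compute_acf(mu, geom)
    phat = expected_counts(lam, acf, sino, geom)
    add = sino.additive_term()           # s/n + r
    trues = phat - add                   # unattenuated-model trues term
    phat_safe = np.maximum(phat, eps)

    num_sino = trues * (phat - sino.prompts) / phat_safe
    if total_chord is None:
        total_chord = forward_project(np.ones(geom.grid_shape), geom)
    den_sino = trues * (1.0 - sino.prompts * add / phat_safe**2) * total_chord

    numerator = back_project(num_sino, geom).values
    denominator = back_project(den_sino, geom).values

    gS, cS = smoothing_gradient(mu, mask, priors)
    gI, cI = intensity_gradient(mu, mask, priors)
    numerator = numerator + priors.beta_S * gS + priors.beta_I * gI
    denominator = denominator + priors.beta_S * cS + priors.beta_I * cI

    ok = mask & (denominator > eps)
    n_skipped = int(mask.sum() - ok.sum())
    if n_skipped:
        log.debug("attenuation update: %d mask voxels skipped (denominator <= eps)", n_skipped)
    out = mu.copy()
    out[ok] = np.maximum(mu[ok] + config.alpha * numerator[ok] / denominator[ok], 0.0)
    return out


def run_xmlaa(
    sino: SinogramSet,
    mu_init,
    hardware_mask: MaskVolume,
    priors: PriorConfig,
    config: ReconConfig,
    geom: ScannerGeometry,
    body_outline: MaskVolume | None = None,
):
    """Alternating joint estimation of activity and external attenuation.

    Runs ``config.n_xmlaa_iters`` iterations of (activity update, attenuation
    update) on the full data (no subsets).  ``mu_init`` must contain the body
    (and any stationary hardware) and zero inside the hardware mask.  If a
    body outline is supplied, any overlap with the hardware mask is rejected
    up front — the update must never touch the body.

    Returns ``(lambda_est, mu_est, trace)`` where ``trace`` maps
    ``Q, L, L_S, L_I`` to per-iteration lists.
    """
    mu = as_image_array(mu_init, geom).copy()
    if body_outline is not None and (hardware_mask.values & body_outline.values).any():
        raise ValueError("hardware mask overlaps the body outline")

    # uniform positive start inside the scanner FOV (zero outside: the
    # multiplicative update keeps it zero, and those voxels see no LORs)
    x, y, _ = geom.coordinate_grids()
    fov = (x**2 + y**2) <= (geom.fov_mm / 2.0) ** 2
    lam = np.where(np.broadcast_to(fov, geom.grid_shape), 1.0, 0.0)

    total_chord = forward_project(np.ones(geom.grid_shape), geom)
    trace: dict[str, list[float]] = {"Q": [], "L": [], "L_S": [], "L_I": []}
    for _ in range(config.n_xmlaa_iters):
        acf = compute_acf(mu, geom)
        lam = mlem_update(lam, acf, sino, geom, eps=config.eps_floor)
        mu = attenuation_update(
            mu, lam, sino, hardware_mask, priors, config, geom, total_chord
        )
        acf = compute_acf(mu, geom)
        phat = expected_counts(lam, acf, sino, geom)
        Q, L, LS, LI = objective(
            sino.prompts, phat, mu, priors, hardware_mask, eps=config.eps_floor
        )
        trace["Q"].append(Q)
        trace["L"].append(L)
        trace["L_S"].append(LS)
        trace["L_I"].append(LI)
    return (
        ImageVolume(lam, geom.voxel_mm),
        ImageVolume(mu, geom.voxel_mm),
        trace,
    )


def osem_reconstruct(
    sino: SinogramSet, acf, config: ReconConfig, geom: ScannerGeometry
) -> ImageVolume:
    """Ordered-subsets EM with interleaved view subsets.

    With ``n_subsets = 1`` this reduces exactly to plain MLEM.  The subset
    count must divide the number of views.
    """
    subsets = _view_subsets(geom.n_views, config.n_subsets)
    x, y, _ = geom.coordinate_grids()
    fov = (x**2 + y**2) <= (geom.fov_mm / 2.0) ** 2
    lam = np.where(np.broadcast_to(fov, geom.grid_shape), 1.0, 0.0)
    acf = np.asarray(acf, dtype=np.float64)
    for _ in range(config.n_osem_iters):
        for views in subsets:
            lam = mlem_update(lam, acf, sino, geom, views=views, eps=config.eps_floor)
    return ImageVolume(lam, geom.voxel_mm)


def gaussian_postfilter(image, fwhm_mm: float, geom: ScannerGeometry | None = None) -> ImageVolume:
    """Isotropic Gaussian smoothing specified by its FWHM in mm.

    Reflecting boundaries preserve the total image sum; FWHM = 0 is the
    identity.
    """
    if isinstance(image, ImageVolume):
        voxel = image.voxel_mm
        arr = image.values
    else:
        if geom is None:
            raise ValueError("need voxel spacing: pass an ImageVolume or a geometry")
        voxel = geom.voxel_mm
        arr = as_image_array(image, geom)
    if fwhm_mm < 0:
        raise ValueError("FWHM must be non-negative")
    if fwhm_mm == 0:
        return ImageVolume(arr.copy(), voxel)
    sigma_mm = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    sigma_vox = [sigma_mm / v if n > 1 else 0.0 for v, n in zip(voxel, arr.shape)]
    return ImageVolume(ndimage.gaussian_filter(arr, sigma=sigma_vox, mode="reflect"), voxel)
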