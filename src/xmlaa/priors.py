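"""Attenuation priors: Geman-McClure smoothing and bi-modal intensity pull.

Both priors are log-priors added to the Poisson log-likelihood, so their
gradients enter the attenuation-update numerator with a plus sign and their
(non-negative diagonal surrogate) curvatures enter the denominator.

Smoothing prior:  L_S(mu) = - sum over neighbour pairs w_ik psi(mu_i - mu_k)
with the Geman-McClure potential psi(t) = t^2 / (delta^2 + t^2).  The
potential is redescending: large steps (object edges) are penalized no more
than delta-scale steps, so hardware edges survive while speckle is smoothed.

Intensity prior: a bi-modal pull toward the expected attenuation of air
(mu_air +- sigma_air) and of hardware material (mu_hardware +- sigma_hardware).
Only the gradient is needed by the update, and it is defined directly as a
piecewise linear function: in each basin (split at the midpoint between the
modes) it is the Gaussian score -(mu - mode)/sigma^2, with the magnitude
clipped beyond ``clip_k`` standard deviations so far outliers feel a bounded,
constant pull.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PriorConfig",
    "smoothing_gradient",
    "intensity_gradient",
    "smoothing_log_prior",
    "intensity_log_prior",
]


@dataclass(frozen=True)
class PriorConfig:
    """Weights and shape constants of the attenuation priors.

    Defaults are the operating point used for all experiments: beta_S = 5.0,
    beta_I = 0.01, air mode 0.0 +- 0.0001 mm^-1, hardware mode
    0.01 +- 0.0020 mm^-1.  ``gm_delta`` is the Geman-McClure scale (the edge
    height, in mm^-1, above which smoothing lets go); ``neighborhood`` is the
    in-plane connectivity (4 or 8, inverse-distance weights; axial neighbours
    are not used in stacked-2D mode).
    """

    beta_S: float = 5.0
    beta_I: float = 0.01
    mu_air: float = 0.0
    sigma_air: float = 1e-4
    mu_hardware: float = 0.01
    sigma_hardware: float = 2e-3
    gm_delta: float = 0.005
    clip_k: float = 3.0
    neighborhood: int = 8

    def __post_init__(self) -> None:
        if self.sigma_air <= 0 or self.sigma_hardware <= 0 or self.gm_delta <= 0:
            raise ValueError("sigma_air, sigma_hardware and gm_delta must be > 0")
        if not self.mu_air < self.mu_hardware:
            raise ValueError("mu_air must be below mu_hardware")
        if self.beta_S < 0 or self.beta_I < 0:
            raise ValueError("prior weights must be non-negative")
        if self.neighborhood not in (4, 8):
            raise ValueError("neighborhood must be 4 or 8")


def _neighbor_offsets(config: PriorConfig):
    """In-plane neighbour offsets with inverse-distance weights."""
    offsets = [((1, 0), 1.0), ((0, 1), 1.0)]
    if config.neighborhood == 8:
        w = 1.0 / np.sqrt(2.0)
        offsets += [((1, 1), w), ((1, -1), w)]
    return offsets


def _pair_diffs(mu: np.ndarray, dx: int, dy: int):
    """Differences mu[i] - mu[i + (dx, dy)] for in-grid pairs.

    Returns (slice of i, slice of neighbour) index tuples and the diff array.
    """
    nx, ny = mu.shape[:2]
    sl_i = (slice(max(0, -dx), nx - max(0, dx)), slice(max(0, -dy), ny - max(0, dy)))
    sl_k = (slice(max(0, dx), nx - max(0, -dx)), slice(max(0, dy), ny - max(0, -dy)))
    return sl_i, sl_k


def _gm_psi(t: np.ndarray, delta: float) -> np.ndarray:
    return t * t / (delta * delta + t * t)


def _gm_psi_prime(t: np.ndarray, delta: float) -> np.ndarray:
    d2 = delta * delta
    return 2.0 * t * d2 / (d2 + t * t) ** 2




def smoothing_gradient(mu, mask, config: PriorConfig):
    """Gradient and curvature surrogate of L_S on ``mask`` voxels.

    grad_i = - sum_{k in N(i)} w_ik psi'(mu_i - mu_k); neighbours outside the
    grid are skipped, neighbours outside the mask still participate (they
    anchor the mask boundary).  The curvature surrogate is the diagonal
    upper bound sum_k w_ik * 2 / delta^2 (the maximum of psi'' over all
    arguments): it majorizes the true curvature everywhere, which keeps the
    update denominator well-signed and damps the poorly determined
    limited-angle modes of the external estimation problem.
    """
    mu = np.asarray(mu, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    grad = np.zeros_like(mu)
    wsum = np.zeros_like(mu)
    delta = config.gm_delta
    for z in range(mu.shape[2]):
        sl = mu[:, :, z]
        for (dx, dy), w in _neighbor_offsets(config):
            sl_i, sl_k = _pair_diffs(sl, dx, dy)
            t = sl[sl_i] - sl[sl_k]
            dpsi = w * _gm_psi_prime(t, delta)
            grad[:, :, z][sl_i] -= dpsi
            grad[:, :, z][sl_k] += dpsi
            wsum[:, :, z][sl_i] += w
            wsum[:, :, z][sl_k] += w
    curv = wsum * (2.0 / delta**2)
    grad[~mask] = 0.0
    curv[~mask] = 0.0
    return grad, curv


def smoothing_log_prior(mu, mask, config: PriorConfig) -> float:
    """L_S value: minus the weighted sum of pair potentials over pairs with
    at least one voxel in the mask (larger = smoother)."""
    mu = np.asarray(mu, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    total = 0.0
    for z in range(mu.shape[2]):
        sl = mu[:, :, z]
        mk = mask[:, :, z]
        for (dx, dy), w in _neighbor_offsets(config):
            sl_i, sl_k = _pair_diffs(sl, dx, dy)
            touch = mk[sl_i] | mk[sl_k]
            t = sl[sl_i] - sl[sl_k]
            total += float((w * _gm_psi(t, config.gm_delta))[touch].sum())
    return -total


def intensity_gradient(mu, mask, config: PriorConfig):
    """Piecewise-linear gradient and curvature surrogate of L_I on ``mask``.

    Voxels below the mid-point between the modes are pulled to ``mu_air``,
    voxels above it to ``mu_hardware``; the pull is -(mu - mode)/sigma^2 with
    magnitude clipped beyond ``clip_k`` sigma.  The gradient vanishes exactly
    at both modes.  The curvature surrogate is the Gaussian-score bound
    1/sigma^2 of the active basin (an upper bound on the negated gradient
    slope over the whole basin), applied basin-wide for stability.
    """
    mu = np.asarray(mu, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    mid = 0.5 * (config.mu_air + config.mu_hardware)
    air = mu <= mid

    grad = np.zeros_like(mu)
    curv = np.zeros_like(mu)
    for basin, mode, sigma in (
        (air, config.mu_air, config.sigma_air),
        (~air, config.mu_hardware, config.sigma_hardware),
    ):
        k = config.clip_k * sigma
        dev = np.clip(mu - mode, -k, k)
        grad[basin] = (-dev / sigma**2)[basin]
        curv[basin] = 1.0 / sigma**2
    grad[~mask] = 0.0
    curv[~mask] = 0.0
    return grad, curv


def intensity_log_prior(mu, mask, config: PriorConfig) -> float:
    """L_I value: the antiderivative of the piecewise-linear gradient
    (quadratic near each mode, linear beyond the clip point), summed over
    mask voxels.  Zero at the modes by construction of each branch."""
    mu = np.asarray(mu, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    mid = 0.5 * (config.mu_air + config.mu_hardware)
    air = mu <= mid
    val = np.zeros_like(mu)
    k = config.clip_k
    for basin, mode, sigma in (
        (air, config.mu_air, config.sigma_air),
        (~air, config.mu_hardware, config.sigma_hardware),
    ):
        t = np.abs(mu - mode)
        quad = -0.5 * t**2 / sigma**2
        lin = -0.5 * (k * sigma) ** 2 / sigma**2 - (k / sigma) * (t - k * sigma)
        val[basin] = np.where(t <= k * sigma, quad, lin)[basin]
    return float(val[mask].sum())
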