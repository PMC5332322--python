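"""Emission forward model, Poisson data generation and likelihood.

The expected count on LOR j is

    phat_j = (1 / (a_j n_j)) * sum_i M_ij lambda_i + s_j / n_j + r_j

with attenuation correction factor a_j = exp(sum_i mu_i l_ij), normalization
n_j, scatter s_j and randoms r_j.  The Poisson log-likelihood is
L = sum_j (p_j ln phat_j - phat_j), dropping the constant ln(p_j!) term.

Division-by-zero guard: a small floor (default 1e-12) is applied inside
logarithms and divisions only; stored sinograms are never modified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import ImageVolume, ScannerGeometry, as_image_array
from .projector import forward_project

__all__ = [
    "SinogramSet",
    "compute_acf",
    "expected_counts",
    "sample_poisson_data",
    "log_likelihood",
    "objective",
]

EPS_FLOOR = 1e-12


@dataclass
class SinogramSet:
    """Per-LOR measured counts and correction terms, all sharing one shape.

    ``prompts`` are coincidences after randoms correction; ``norm`` is the
    dimensionless detector-efficiency factor (strictly positive — dead LORs
    must be excluded from the index set, not zeroed); ``scatter`` and
    ``randoms`` are the additive contributions to the expected counts.
    """

    prompts: np.ndarray
    norm: np.ndarray | None = None
    scatter: np.ndarray | None = None
    randoms: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.prompts = np.asarray(self.prompts, dtype=np.float64)
        if self.norm is None:
            self.norm = np.ones_like(self.prompts)
        if self.scatter is None:
            self.scatter = np.zeros_like(self.prompts)
        if self.randoms is None:
            self.randoms = np.zeros_like(self.prompts)
        self.norm = np.asarray(self.norm, dtype=np.float64)
        self.scatter = np.asarray(self.scatter, dtype=np.float64)
        self.randoms = np.asarray(self.randoms, dtype=np.float64)
        for name in ("norm", "scatter", "randoms"):
            arr = getattr(self, name)
            if arr.shape != self.prompts.shape:
                raise ValueError(f"{name} shape {arr.shape} != prompts shape {self.prompts.shape}")
        if (self.norm <= 0).any():
            raise ValueError("normalization must be strictly positive on every LOR")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.prompts.shape

    def additive_term(self) -> np.ndarray:
        """The affine intercept s/n + r of the expected counts."""
        return self.scatter / self.norm + self.randoms


def compute_acf(mu, geom: ScannerGeometry) -> np.ndarray:
    """Attenuation correction factors a_j = exp(line integral of mu), >= 1
    for non-negative mu; exactly 1 on LORs missing the support of mu."""
    arr = as_image_array(mu, geom)
    if (arr < 0).any():
        raise ValueError("attenuation map must be non-negative")
    return np.exp(forward_project(arr, geom))


def expected_counts(lam, acf, sino: SinogramSet, geom: ScannerGeometry) -> np.ndarray:
    """Expected prompts phat_j for activity ``lam`` under ACFs ``acf``."""
    arr = as_image_array(lam, geom)
    if (arr < 0).any():
        raise ValueError("activity must be non-negative")
    acf = np.asarray(acf, dtype=np.float64)
    if acf.shape != geom.sino_shape:
        raise ValueError("ACF shape does not match geometry")
    return forward_project(arr, geom) / (acf * sino.norm) + sino.additive_term()


def sample_poisson_data(
    phat, total_prompts_target: float | None = None, seed=None
) -> np.ndarray:
    """Draw independent Poisson counts per LOR from ``phat``.

    When ``total_prompts_target`` is given, ``phat`` is first rescaled so its
    total equals the target (a fixed acquisition prompt budget).  A ``None``
    target with ``seed=None`` is the noiseless mode: returns phat unchanged.
    """
    arr = np.asarray(phat, dtype=np.float64)
    if (arr < 0).any():
        raise ValueError("expected counts must be non-negative")
    if total_prompts_target is None and seed is None:
        return arr.copy()
    if total_prompts_target is not None:
        if total_prompts_target < 0:
            raise ValueError("total prompts target must be non-negative")
        total = arr.sum()
        if total > 0:
            arr = arr * (total_prompts_target / total)
    rng = np.random.default_rng(seed)
    return rng.poisson(arr).astype(np.float64)


def log_likelihood(p, phat, eps: float = EPS_FLOOR) -> float:
    """Poisson log-likelihood sum_j (p ln phat - phat), constants dropped.

    LORs with p = phat = 0 contribute zero; p > 0 with phat = 0 is rejected
    (the log is undefined there).
    """
    p = np.asarray(p, dtype=np.float64)
    phat = np.asarray(phat, dtype=np.float64)
    if ((p > 0) & (phat <= 0)).any():
        raise ValueError("log-likelihood undefined: p > 0 on a LOR with phat = 0")
    term = np.where(p > 0, p * np.log(np.maximum(phat, eps)), 0.0)
    return float((term - phat).sum())


def objective(p, phat, mu, priors, hardware_mask=None, eps: float = EPS_FLOOR):
    """Penalized objective Q = L + beta_S * L_S + beta_I * L_I.

    Returns ``(Q, L, L_S, L_I)`` where L_S, L_I are the unweighted log-prior
    values evaluated on the hardware mask (whole grid if no mask is given).
    """
    from .priors import intensity_log_prior, smoothing_log_prior  # cycle guard

    L = log_likelihood(p, phat, eps)
    mu_arr = as_image_array(mu)
    mask = hardware_mask.values if hardware_mask is not None else np.ones(mu_arr.shape, bool)
    LS = smoothing_log_prior(mu_arr, mask, priors)
    LI = intensity_log_prior(mu_arr, mask, priors)
    Q = L + priors.beta_S * LS + priors.beta_I * LI
    return Q, L, LS, LI
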