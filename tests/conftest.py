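"""Shared fixtures: small geometries and cached study runs.

The expensive joint reconstructions are session-scoped so the acceptance
tests and the module tests share one run.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from xmlaa import (
    MaskVolume,
    PriorConfig,
    ReconConfig,
    ScannerGeometry,
    SinogramSet,
    compute_acf,
    expected_counts,
    make_hp_phantom,
    make_simulation_phantom,
    run_xmlaa,
)
from xmlaa.recon import mlem_update

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_geom() -> ScannerGeometry:
    """8x8 grid, 6 views x 9 radial bins — dense-oracle scale."""
    return ScannerGeometry(
        n_views=6, n_radial=9, n_planes=1, fov_mm=18.0,
        grid_shape=(8, 8, 1), voxel_mm=(2.0, 2.0, 2.0),
    )


@pytest.fixture(scope="session")
def small_geom() -> ScannerGeometry:
    """16x16 grid for adjointness and algebraic checks."""
    return ScannerGeometry(
        n_views=12, n_radial=16, n_planes=1, fov_mm=32.0,
        grid_shape=(16, 16, 1), voxel_mm=(2.0, 2.0, 2.0),
    )


@pytest.fixture(scope="session")
def medium_geom() -> ScannerGeometry:
    """32x32 grid with a few planes for 3D-aware checks."""
    return ScannerGeometry(
        n_views=24, n_radial=32, n_planes=3, fov_mm=64.0,
        grid_shape=(32, 32, 3), voxel_mm=(2.0, 2.0, 2.0),
    )


@pytest.fixture(scope="session")
def default_geom() -> ScannerGeometry:
    return ScannerGeometry()


def make_noiseless_sinogram(phantom, geom) -> SinogramSet:
    blank = SinogramSet(np.zeros(geom.sino_shape))
    acf = compute_acf(phantom.mu_true, geom)
    return SinogramSet(expected_counts(phantom.lambda_true, acf, blank, geom))


@pytest.fixture(scope="session")
def sim_study(default_geom):
    """Warm/cold earpad simulation study: noiseless data, uncorrected MLEM
    reconstruction and the 50-iteration joint run at the default settings."""
    geom = default_geom
    ph = make_simulation_phantom(geom)
    sino = make_noiseless_sinogram(ph, geom)
    priors = PriorConfig()
    config = ReconConfig()

    # uncorrected: plain OP-MLEM with the body-only attenuation map, same
    # number of activity updates as the joint loop
    empty = MaskVolume(np.zeros(geom.grid_shape, dtype=bool), "hardware-mask")
    lam_unc, _, _ = run_xmlaa(sino, ph.mu_body, empty, priors, config, geom, ph.body_mask)

    lam_x, mu_x, trace = run_xmlaa(
        sino, ph.mu_body, ph.hardware_mask, priors, config, geom, ph.body_mask
    )
    return {
        "geom": geom,
        "phantom": ph,
        "sino": sino,
        "priors": priors,
        "config": config,
        "lambda_uncorrected": lam_unc,
        "lambda_xmlaa": lam_x,
        "mu_xmlaa": mu_x,
        "trace": trace,
    }


@pytest.fixture(scope="session")
def hp_study(default_geom):
    """Synthetic headphone phantom (all-cold hardware) run to convergence."""
    geom = default_geom
    ph = make_hp_phantom(geom)
    sino = make_noiseless_sinogram(ph, geom)
    priors = PriorConfig()
    config = ReconConfig(n_xmlaa_iters=150)
    lam, mu, trace = run_xmlaa(
        sino, ph.mu_body, ph.hardware_mask, priors, config, geom, ph.body_mask
    )
    return {
        "geom": geom,
        "phantom": ph,
        "sino": sino,
        "priors": priors,
        "config": config,
        "lambda_xmlaa": lam,
        "mu_xmlaa": mu,
    }
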