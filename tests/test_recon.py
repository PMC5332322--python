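"""Activity and attenuation updates, the joint loop, OSEM and post-filter."""

from types import SimpleNamespace

import numpy as np
import pytest

import xmlaa.recon as recon_mod
from xmlaa import (
    ImageVolume,
    MaskVolume,
    PriorConfig,
    ReconConfig,
    ScannerGeometry,
    SinogramSet,
    compute_acf,
    expected_counts,
    forward_project,
    gaussian_postfilter,
    log_likelihood,
    make_simulation_phantom,
    mlem_update,
    osem_reconstruct,
    run_xmlaa,
)
from xmlaa.recon import attenuation_update, _view_subsets
from tests.conftest import make_noiseless_sinogram


def _fov_uniform(geom):
    x, y, _ = geom.coordinate_grids()
    fov = (x**2 + y**2) <= (geom.fov_mm / 2.0) ** 2
    return np.where(np.broadcast_to(fov, geom.grid_shape), 1.0, 0.0)


# --------------------------------------------------------------------------
# scalar (1 voxel, 1 LOR) algebra of the update equations
# --------------------------------------------------------------------------

@pytest.fixture
def scalar_system(monkeypatch):
    """A 1-voxel, 1-LOR system with intersection length l, wired through the
    real update code by replacing the projector with scalar multiplication."""

    def make(l):
        geom = SimpleNamespace(grid_shape=(1, 1, 1), sino_shape=(1, 1, 1), voxel_mm=(1.0, 1.0, 1.0))
        monkeypatch.setattr(
            recon_mod, "forward_project", lambda img, g: np.asarray(img, float).reshape(1, 1, 1) * l
        )
        monkeypatch.setattr(
            recon_mod,
            "back_project",
            lambda s, g: ImageVolume(np.asarray(s, float).reshape(1, 1, 1) * l, (1, 1, 1)),
        )
        return geom

    return make


def test_mlem_single_voxel_exact_recovery(scalar_system):
    """With M = 1, a = n = 1, s = r = 0, p = 5 and lambda = 2 the update gives
    2 * (5/2) / 1 = 5 in one step."""
    geom = scalar_system(1.0)
    sino = SinogramSet(np.full((1, 1, 1), 5.0))
    out = mlem_update(np.full((1, 1, 1), 2.0), np.ones((1, 1, 1)), sino, geom)
    assert out[0, 0, 0] == pytest.approx(5.0, rel=1e-12)


def test_attenuation_update_scalar_step(scalar_system, monkeypatch):
    """1 voxel, 1 LOR, l = 10 mm, p = 50, phat = 60, alpha = 1, no priors:
    delta mu = l(phat-p)(phat/phat) / (l * phat * l) = 100/6000 mm^-1, and the
    step has the sign that lowers phat toward p."""
    geom = scalar_system(10.0)
    monkeypatch.setattr(
        recon_mod, "compute_acf", lambda mu, g: np.exp(np.asarray(mu, float).reshape(1, 1, 1) * 10.0)
    )
    monkeypatch.setattr(
        recon_mod, "expected_counts", lambda lam, acf, sino, g: np.full((1, 1, 1), 60.0)
    )
    sino = SinogramSet(np.full((1, 1, 1), 50.0))
    mask = MaskVolume(np.ones((1, 1, 1), dtype=bool), "hardware-mask")
    priors = PriorConfig(beta_S=0.0, beta_I=0.0)
    config = ReconConfig(alpha=1.0)
    mu0 = np.full((1, 1, 1), 0.02)
    out = attenuation_update(
        mu0, np.ones((1, 1, 1)), sino, mask, priors, config, geom,
        total_chord=np.full((1, 1, 1), 10.0),
    )
    delta = out[0, 0, 0] - 0.02
    assert delta == pytest.approx(100.0 / 6000.0, rel=1e-12)
    assert delta > 0  # more attenuation lowers the overestimated phat


# --------------------------------------------------------------------------
# MLEM properties
# --------------------------------------------------------------------------

def test_mlem_fixed_point(small_geom):
    """If the measured prompts equal the expected prompts, the update is the
    identity."""
    rng = np.random.default_rng(21)
    lam = rng.random(small_geom.grid_shape)
    acf = 1.0 + rng.random(small_geom.sino_shape)
    norm = rng.uniform(0.5, 2.0, small_geom.sino_shape)
    scatter = rng.random(small_geom.sino_shape)
    randoms = rng.random(small_geom.sino_shape)
    blank = SinogramSet(np.zeros(small_geom.sino_shape), norm=norm,
                        scatter=scatter, randoms=randoms)
    prompts = expected_counts(lam, acf, blank, small_geom)
    sino = SinogramSet(prompts, norm=norm, scatter=scatter, randoms=randoms)
    out = mlem_update(lam, acf, sino, small_geom)
    np.testing.assert_allclose(out, lam, rtol=1e-12)


def test_mlem_likelihood_monotone(medium_geom):
    """The Poisson log-likelihood never decreases across EM iterations on a
    seeded noisy problem."""
    geom = medium_geom
    rng = np.random.default_rng(33)
    x, y, _ = geom.coordinate_grids()
    lam_true = np.where((x**2 + y**2) <= 24.0**2, 1.0, 0.0) * np.ones(geom.grid_shape)
    mu = 0.0096 * lam_true
    acf = compute_acf(mu, geom)
    blank = SinogramSet(np.zeros(geom.sino_shape))
    phat_true = expected_counts(lam_true, acf, blank, geom)
    prompts = rng.poisson(phat_true * 20.0).astype(float)
    sino = SinogramSet(prompts)
    lam = _fov_uniform(geom)
    last = -np.inf
    for _ in range(20):
        lam = mlem_update(lam, acf, sino, geom)
        phat = expected_counts(lam, acf, sino, geom)
        ok = phat > 0
        L = float((prompts[ok] * np.log(phat[ok]) - phat[ok]).sum()) - float(phat[~ok].sum())
        assert L >= last - 1e-9 * abs(last)
        last = L


def test_mlem_preserves_nonnegativity_and_freezes_uncovered(small_geom):
    rng = np.random.default_rng(2)
    lam = rng.random(small_geom.grid_shape)
    sino = SinogramSet(rng.random(small_geom.sino_shape))
    out = mlem_update(lam, np.ones(small_geom.sino_shape), sino, small_geom)
    assert np.all(out >= 0)
    # a voxel with zero sensitivity in the subset stays frozen
    out_sub = mlem_update(lam, np.ones(small_geom.sino_shape), sino, small_geom,
                          views=np.array([0]))
    sens = recon_mod.back_project(
        np.concatenate([np.ones((1,) + small_geom.sino_shape[1:]),
                        np.zeros((small_geom.n_views - 1,) + small_geom.sino_shape[1:])]),
        small_geom).values
    frozen = sens == 0
    if frozen.any():
        assert np.array_equal(out_sub[frozen], lam[frozen])


def test_noiseless_self_consistency(default_geom, sim_study):
    """MLEM with the true attenuation map recovers the evaluation-region mean
    within 0.5% by 100 iterations (noiseless, matched projector)."""
    from xmlaa import region_mean_error

    ph = sim_study["phantom"]
    sino = sim_study["sino"]
    acf = compute_acf(ph.mu_true, default_geom)
    lam = _fov_uniform(default_geom)
    for _ in range(100):
        lam = mlem_update(lam, acf, sino, default_geom)
    err = region_mean_error(ImageVolume(lam), ph.lambda_true, ph.evaluation_mask)
    assert abs(err) <= 0.5


# --------------------------------------------------------------------------
# attenuation update contracts
# --------------------------------------------------------------------------

def test_attenuation_update_identity_when_consistent(default_geom, sim_study):
    """phat = p and zero prior gradients leave mu unchanged."""
    ph = sim_study["phantom"]
    sino = sim_study["sino"]  # generated from mu_true and lambda_true
    priors = PriorConfig(beta_S=0.0, beta_I=0.0)
    out = attenuation_update(
        ph.mu_true, ph.lambda_true, sino, ph.hardware_mask, priors,
        ReconConfig(), default_geom,
    )
    np.testing.assert_allclose(out, ph.mu_true.values, atol=1e-12)


def test_attenuation_update_outside_mask_untouched(default_geom, sim_study):
    ph = sim_study["phantom"]
    sino = sim_study["sino"]
    rng = np.random.default_rng(5)
    lam = rng.random(default_geom.grid_shape)
    out = attenuation_update(
        ph.mu_body, lam, sino, ph.hardware_mask, PriorConfig(), ReconConfig(), default_geom
    )
    outside = ~ph.hardware_mask.values
    assert np.array_equal(out[outside], ph.mu_body.values[outside])


def test_attenuation_nonnegative_after_truncation(default_geom, sim_study):
    """Updates that would drive mu negative are truncated to zero."""
    ph = sim_study["phantom"]
    # data with MORE attenuation than the model can explain -> downward pull
    sino = sim_study["sino"]
    mu_over = np.where(ph.hardware_mask.values, 0.02, ph.mu_body.values)
    out = attenuation_update(
        mu_over, ph.lambda_true, sino, ph.hardware_mask, PriorConfig(),
        ReconConfig(alpha=50.0), default_geom,
    )
    assert np.all(out >= 0)


def test_attenuation_update_skips_unsafe_denominators(default_geom, sim_study):
    """With zero counts and zero activity every denominator vanishes and all
    mask voxels skip the step instead of dividing."""
    ph = sim_study["phantom"]
    zero_sino = SinogramSet(np.zeros(default_geom.sino_shape))
    out = attenuation_update(
        ph.mu_body, np.zeros(default_geom.grid_shape), zero_sino, ph.hardware_mask,
        PriorConfig(beta_S=0.0, beta_I=0.0), ReconConfig(), default_geom,
    )
    np.testing.assert_array_equal(out, ph.mu_body.values)


# --------------------------------------------------------------------------
# joint loop
# --------------------------------------------------------------------------

def test_empty_mask_reduces_to_plain_mlem(default_geom, sim_study):
    """With an empty hardware mask the joint loop is OP-MLEM at fixed mu."""
    ph = sim_study["phantom"]
    sino = sim_study["sino"]
    config = ReconConfig(n_xmlaa_iters=10)
    empty = MaskVolume(np.zeros(default_geom.grid_shape, dtype=bool), "hardware-mask")
    lam_joint, mu_out, _ = run_xmlaa(
        sino, ph.mu_body, empty, PriorConfig(), config, default_geom, ph.body_mask
    )
    acf = compute_acf(ph.mu_body, default_geom)
    lam = _fov_uniform(default_geom)
    for _ in range(10):
        lam = mlem_update(lam, acf, sino, default_geom)
    np.testing.assert_allclose(lam_joint.values, lam, rtol=1e-10)
    assert np.array_equal(mu_out.values, ph.mu_body.values)


def test_mask_invariance_every_iteration(default_geom, sim_study):
    """mu outside the hardware mask stays bit-identical to mu_init through
    every alternating iteration."""
    ph = sim_study["phantom"]
    sino = sim_study["sino"]
    outside = ~ph.hardware_mask.values
    lam = _fov_uniform(default_geom)
    mu = ph.mu_body.values.copy()
    for _ in range(5):
        acf = compute_acf(mu, default_geom)
        lam = mlem_update(lam, acf, sino, default_geom)
        mu = attenuation_update(
            mu, lam, sino, ph.hardware_mask, PriorConfig(), ReconConfig(), default_geom
        )
        assert np.array_equal(mu[outside], ph.mu_body.values[outside])
        assert np.all(mu >= 0) and np.all(lam >= 0)


def test_mask_overlapping_body_rejected(default_geom, sim_study):
    ph = sim_study["phantom"]
    bad = MaskVolume(
        ph.hardware_mask.values | ph.body_mask.values, "hardware-mask"
    )
    with pytest.raises(ValueError, match="overlaps"):
        run_xmlaa(
            sim_study["sino"], ph.mu_body, bad, PriorConfig(), ReconConfig(),
            default_geom, ph.body_mask,
        )


def test_near_fixed_point_stability(default_geom, sim_study):
    """Initialized at the true attenuation map, 50 joint iterations keep the
    evaluation-region activity within 0.5% of the truth (the priors may
    redistribute voxelwise attenuation, but the solution stays consistent)."""
    from xmlaa import region_mean_error

    ph = sim_study["phantom"]
    lam, mu, _ = run_xmlaa(
        sim_study["sino"], ph.mu_true, ph.hardware_mask, PriorConfig(),
        ReconConfig(), default_geom, ph.body_mask,
    )
    err = region_mean_error(lam, ph.lambda_true, ph.evaluation_mask)
    assert abs(err) <= 0.5


def test_objective_trace_is_recorded(sim_study):
    trace = sim_study["trace"]
    n = sim_study["config"].n_xmlaa_iters
    assert len(trace["Q"]) == len(trace["L"]) == n
    np.testing.assert_allclose(
        np.asarray(trace["Q"]),
        np.asarray(trace["L"])
        + sim_study["priors"].beta_S * np.asarray(trace["L_S"])
        + sim_study["priors"].beta_I * np.asarray(trace["L_I"]),
    )
    # the likelihood improves over the run
    assert trace["L"][-1] > trace["L"][0]


# --------------------------------------------------------------------------
# OSEM and post-filter
# --------------------------------------------------------------------------

def test_osem_single_subset_equals_mlem(small_geom):
    rng = np.random.default_rng(12)
    sino = SinogramSet(rng.random(small_geom.sino_shape) * 10)
    acf = 1.0 + rng.random(small_geom.sino_shape)
    config = ReconConfig(n_osem_iters=5, n_subsets=1)
    lam_osem = osem_reconstruct(sino, acf, config, small_geom)
    lam = _fov_uniform(small_geom)
    for _ in range(5):
        lam = mlem_update(lam, acf, sino, small_geom)
    np.testing.assert_allclose(lam_osem.values, lam, rtol=1e-10)


def test_osem_subsets_partition_views(small_geom):
    subsets = _view_subsets(12, 4)
    allv = np.sort(np.concatenate(subsets))
    assert np.array_equal(allv, np.arange(12))
    assert all(len(s) == 3 for s in subsets)


def test_osem_indivisible_subsets_rejected(small_geom):
    sino = SinogramSet(np.ones(small_geom.sino_shape))
    with pytest.raises(ValueError, match="does not divide"):
        osem_reconstruct(sino, np.ones(small_geom.sino_shape),
                         ReconConfig(n_subsets=5), small_geom)


def test_postfilter_zero_fwhm_is_identity():
    rng = np.random.default_rng(1)
    vol = ImageVolume(rng.random((16, 16, 1)), (2.0, 2.0, 2.0))
    out = gaussian_postfilter(vol, 0.0)
    assert np.array_equal(out.values, vol.values)


def test_postfilter_preserves_total(default_geom):
    rng = np.random.default_rng(2)
    vol = ImageVolume(rng.random(default_geom.grid_shape), default_geom.voxel_mm)
    out = gaussian_postfilter(vol, 5.0)
    assert out.values.sum() == pytest.approx(vol.values.sum(), rel=1e-6)


def test_postfilter_fwhm_of_delta():
    """Filtering a delta gives a profile whose width at half maximum is the
    requested 5 mm within half a voxel."""
    img = np.zeros((65, 65, 1))
    img[32, 32, 0] = 1.0
    out = gaussian_postfilter(ImageVolume(img, (1.0, 1.0, 1.0)), 5.0)
    prof = out.values[:, 32, 0]
    half = prof.max() / 2.0
    above = np.nonzero(prof >= half)[0]
    # linear interpolation at the crossings
    lo, hi = above[0], above[-1]
    left = lo - 1 + (half - prof[lo - 1]) / (prof[lo] - prof[lo - 1])
    right = hi + (prof[hi] - half) / (prof[hi] - prof[hi + 1])
    assert (right - left) == pytest.approx(5.0, abs=0.5)
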