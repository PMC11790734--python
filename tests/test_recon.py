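"""Reconstruction: reference combination, SENSE unfolding, POCS, shrinkage."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from flairacc.kspace import (KSpaceData, apply_mask, fft2c, ifft2c,
                             make_equidistant_mask, simulate_multicoil_kspace)
from flairacc.phantom import (CoilSensitivities, LABEL_BACKGROUND,
                              generate_coil_sensitivities, generate_phantom)
from flairacc.recon import (PocsConfig, UnresolvableAliasingError,
                            noise_uniformity_map, pocs_wavelet_recon,
                            reference_recon, sense_recon, soft_threshold,
                            zero_filled_recon)


def test_reference_recon_single_unit_channel_is_exact(case64):
    coils = CoilSensitivities(maps=np.ones((1,) + case64.shape, dtype=complex))
    ks = simulate_multicoil_kspace(case64, coils, noise_std=0.0, seed=0)
    rec = reference_recon(ks, coils)
    assert np.allclose(rec.image, case64.image, atol=1e-12)


def test_reference_recon_multicoil_roundtrip(case64, coils64):
    ks = simulate_multicoil_kspace(case64, coils64, noise_std=0.0, seed=0)
    rec = reference_recon(ks, coils64)
    rel = (np.linalg.norm(rec.image - case64.image)
           / np.linalg.norm(case64.image))
    assert rel < 1e-6


def test_noise_strictly_degrades_reference(case64, coils64):
    from flairacc.metrics import compute_ssim

    ks = simulate_multicoil_kspace(case64, coils64, noise_std=0.02, seed=1)
    rec = reference_recon(ks, coils64)
    assert not np.allclose(rec.image, case64.image)
    assert compute_ssim(case64.image, rec.image) < 1


def test_sense_at_af1_equals_reference(case64, coils64):
    ks = simulate_multicoil_kspace(case64, coils64, noise_std=0.01, seed=2)
    ref = reference_recon(ks, coils64)
    sen = sense_recon(ks, coils64, ks.mask)
    assert np.allclose(sen.image, ref.image, atol=1e-10)


def test_sense_unfolds_two_pixel_toy_system_exactly():
    """2 pixels, 2 channels, R=2: the stated sensitivity matrix is solved
    exactly for the true pixel values."""
    truth = np.array([[0.7, 0.3]])  # 1 x 2 image (single frequency-encode row)
    s = np.array([[1.0, 0.5], [0.4, 1.0]])  # channel x pixel
    maps = s[:, None, :].astype(complex)
    coils = CoilSensitivities(maps=maps)
    ks = fft2c(maps * truth[None])
    mask = make_equidistant_mask(2, 2, 0)
    data = np.zeros_like(ks)
    data[..., mask.sampled] = ks[..., mask.sampled]
    rec = sense_recon(KSpaceData(data=data, mask=mask), coils, mask)
    assert np.allclose(rec.image, np.abs(truth), atol=1e-12)


def test_sense_noiseless_af3_recovers_phantom(case126, coils126):
    ks = simulate_multicoil_kspace(case126, coils126, noise_std=0.0, seed=0)
    mask = make_equidistant_mask(126, 3, 0)
    rec = sense_recon(apply_mask(ks, mask), coils126, mask)
    rel = (np.linalg.norm(rec.image - case126.image)
           / np.linalg.norm(case126.image))
    assert rel < 1e-6


def test_sense_single_channel_aliasing_unresolvable(case64):
    coils = CoilSensitivities(maps=np.ones((1,) + case64.shape, dtype=complex))
    ks = simulate_multicoil_kspace(case64, coils, noise_std=0.0, seed=0)
    mask = make_equidistant_mask(64, 2, 0)
    with pytest.raises(UnresolvableAliasingError):
        sense_recon(apply_mask(ks, mask), coils, mask)


def test_sense_matches_full_system_least_squares_oracle():
    """Brute-force joint solve of the masked forward model on a small grid."""
    case = generate_phantom(shape=(33, 33), fov_mm=240.0, n_lesions=0, seed=4)
    case.image = case.image[:12, :12].copy()
    case.labels = case.labels[:12, :12].copy()
    rng = np.random.default_rng(0)
    # smooth random complex maps, well conditioned
    maps = np.empty((4, 12, 12), dtype=complex)
    for c in range(4):
        rr, cc = np.indices((12, 12))
        maps[c] = (0.3 + np.exp(-((rr - 3 * c) ** 2 + (cc - 11 + 3 * c) ** 2)
                                / 60.0)) * np.exp(1j * rng.uniform(0, 2 * np.pi))
    coils = CoilSensitivities(maps=maps)
    img = rng.random((12, 12))
    mask = make_equidistant_mask(12, 3, 0)

    ks = fft2c(maps * img[None])
    data = np.zeros_like(ks)
    data[..., mask.sampled] = ks[..., mask.sampled]

    # explicit forward matrix: unknown image (144) -> masked k-space samples
    n = 12 * 12
    cols = []
    for j in range(n):
        basis = np.zeros(n)
        basis[j] = 1.0
        b2 = basis.reshape(12, 12)
        fwd = fft2c(maps * b2[None])[..., mask.sampled]
        cols.append(fwd.ravel())
    e_mat = np.array(cols).T
    sol, *_ = np.linalg.lstsq(e_mat, data[..., mask.sampled].ravel(),
                              rcond=None)
    oracle = np.abs(sol.reshape(12, 12))

    rec = sense_recon(KSpaceData(data=data, mask=mask), coils, mask)
    assert np.allclose(rec.image, oracle, atol=1e-8)


# ---------------------------------------------------------------------------
# soft thresholding
# ---------------------------------------------------------------------------

def test_soft_threshold_closed_form():
    assert soft_threshold(np.array(5.0), 2.0) == pytest.approx(3.0)
    assert soft_threshold(np.array(-5.0), 2.0) == pytest.approx(-3.0)
    assert soft_threshold(np.array(1.0), 2.0) == 0.0
    with pytest.raises(ValueError):
        soft_threshold(np.array(1.0), -0.1)


@pytest.mark.parametrize("theta", [0.0, 0.7, 2.0, -1.3])
def test_soft_threshold_preserves_complex_phase(theta):
    x = 3.0 * np.exp(1j * theta)
    y = soft_threshold(np.array(x), 1.0)
    assert np.isclose(np.abs(y), 2.0)
    assert np.isclose(np.angle(y), np.angle(x))


@settings(deadline=None, max_examples=50)
@given(
    x=hnp.arrays(np.float64, 16, elements=st.floats(-50, 50)),
    y=hnp.arrays(np.float64, 16, elements=st.floats(-50, 50)),
    lam=st.floats(0, 10),
)
def test_soft_threshold_is_nonexpansive(x, y, lam):
    dx = np.linalg.norm(soft_threshold(x, lam) - soft_threshold(y, lam))
    assert dx <= np.linalg.norm(x - y) + 1e-9


# ---------------------------------------------------------------------------
# POCS
# ---------------------------------------------------------------------------

def test_pocs_af1_lambda0_equals_reference(case64, coils64):
    ks = simulate_multicoil_kspace(case64, coils64, noise_std=0.0, seed=0)
    cfg = PocsConfig(lam_factor=0.0, max_iters=5, tol=1e-12)
    rec = pocs_wavelet_recon(ks, coils64, ks.mask, cfg)
    ref = reference_recon(ks, coils64)
    assert np.allclose(rec.image, ref.image, atol=1e-9)


def test_pocs_residual_monotone_noiseless(case64, coils64):
    ks = simulate_multicoil_kspace(case64, coils64, noise_std=0.0, seed=0)
    mask = make_equidistant_mask(64, 3, 0)
    cfg = PocsConfig(lam_factor=0.0, max_iters=40, tol=1e-14)
    rec = pocs_wavelet_recon(apply_mask(ks, mask), coils64, mask, cfg)
    res = rec.meta["residuals"]
    assert len(res) == 40
    assert all(res[i + 1] <= res[i] + 1e-12 for i in range(len(res) - 1))


def test_pocs_lambda0_data_consistency(case64, coils64):
    """With no shrinkage the sampled lines converge to the measured data."""
    ks = simulate_multicoil_kspace(case64, coils64, noise_std=0.0, seed=0)
    mask = make_equidistant_mask(64, 2, 0)
    cfg = PocsConfig(lam_factor=0.0, max_iters=300, tol=1e-12)
    rec = pocs_wavelet_recon(apply_mask(ks, mask), coils64, mask, cfg)
    assert rec.meta["final_residual"] < 1e-3


def test_pocs_shrinkage_reduces_background_noise(case64, coils64):
    ks = simulate_multicoil_kspace(case64, coils64, noise_std=0.02, seed=7)
    mask = make_equidistant_mask(64, 3, 0)
    ksm = apply_mask(ks, mask)
    bg = case64.labels == LABEL_BACKGROUND
    zf = zero_filled_recon(ksm, coils64)
    cfg = PocsConfig(lam_factor=1.5, max_iters=60, tol=1e-8)
    rec = pocs_wavelet_recon(ksm, coils64, mask, cfg)
    assert rec.image[bg].std() < zf.image[bg].std()
    assert rec.meta["lam"] > 0


def test_pocs_invalid_wavelet_rejected(case64, coils64):
    ks = simulate_multicoil_kspace(case64, coils64, noise_std=0.0, seed=0)
    with pytest.raises(ValueError):
        pocs_wavelet_recon(ks, coils64, ks.mask,
                           PocsConfig(wavelet="not-a-wavelet"))


# ---------------------------------------------------------------------------
# noise maps
# ---------------------------------------------------------------------------

def test_noise_map_zero_for_noiseless_input(case64, coils64):
    mask = make_equidistant_mask(64, 1, 0)
    m = noise_uniformity_map(lambda ks, c, mk: reference_recon(ks, c),
                             case64, coils64, mask, noise_std=0.0,
                             n_reps=3, seed=0)
    assert np.allclose(m, 0.0)


def test_noise_map_scales_linearly_with_sigma(case64, coils64):
    mask = make_equidistant_mask(64, 1, 0)
    fn = lambda ks, c, mk: reference_recon(ks, c)  # noqa: E731
    m1 = noise_uniformity_map(fn, case64, coils64, mask, 0.01, 60, seed=0)
    m2 = noise_uniformity_map(fn, case64, coils64, mask, 0.02, 60, seed=0)
    brain = case64.labels != LABEL_BACKGROUND
    ratio = m2[brain].mean() / m1[brain].mean()
    assert abs(ratio - 2.0) < 0.15
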