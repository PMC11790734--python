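"""Image reconstruction from full or undersampled multi-coil k-space.

Three reconstruction routes:

``reference_recon``
    Fully sampled reference ("std" arm): per-channel inverse FFT followed by
    sensitivity-weighted least-squares coil combination
    ``m = sum_c conj(S_c) x_c / sum_c |S_c|^2``.

``sense_recon``
    Classic SENSE unfolding of equidistantly undersampled data.  Zero-filled
    per-channel images alias R pixels (spaced ``n_lines/af`` along the
    phase-encode axis) onto each other; each aliased group is unfolded by
    least squares against the coil sensitivities.

``pocs_wavelet_recon``
    Iterative reconstruction by projections onto convex sets: alternate a
    k-space data-consistency projection with coil-consistent combination,
    plus wavelet soft-thresholding of detail coefficients to tame the
    spatially non-uniform noise amplification of parallel imaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt

from .kspace import KSpaceData, SamplingMask, fft2c, ifft2c
from .phantom import CoilSensitivities

__all__ = [
    "ReconImage",
    "PocsConfig",
    "UnresolvableAliasingError",
    "reference_recon",
    "zero_filled_recon",
    "sense_recon",
    "soft_threshold",
    "pocs_wavelet_recon",
    "noise_uniformity_map",
]


class UnresolvableAliasingError(RuntimeError):
    """SENSE system is rank-deficient for some aliased pixel group."""


@dataclass
class ReconImage:
    """Magnitude reconstruction tagged with its method."""

    image: np.ndarray  # 2D non-negative real
    method: str  # std | acc_sense | acc_pocs | dlr | zero_filled
    af: int = 1
    meta: dict = field(default_factory=dict)


@dataclass
class PocsConfig:
    """POCS iteration settings.

    ``lam_factor`` scales the soft threshold as a multiple of the noise
    level estimated (via the median absolute deviation) from the finest
    diagonal-detail wavelet band of the initial zero-filled estimate;
    ``lam`` overrides with an absolute threshold when set.
    """

    lam_factor: float = 0.75
    lam: float | None = None
    wavelet: str = "db4"
    levels: int = 3
    max_iters: int = 150
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.lam_factor < 0 or (self.lam is not None and self.lam < 0):
            raise ValueError("threshold must be >= 0")


def _combine(channel_images: np.ndarray, coils: CoilSensitivities) -> np.ndarray:
    sos = coils.sos()
    if np.any(sos <= 0):
        raise ValueError("coil sensitivities vanish somewhere on the grid")
    return np.sum(np.conj(coils.maps) * channel_images, axis=0) / sos


def reference_recon(ks_full: KSpaceData, coils: CoilSensitivities) -> ReconImage:
    """Reference ("std") reconstruction of fully sampled k-space."""
    if not ks_full.mask.is_full:
        raise ValueError("reference_recon requires fully sampled k-space")
    m = _combine(ifft2c(ks_full.data), coils)
    return ReconImage(image=np.abs(m), method="std", af=1)


def zero_filled_recon(ks: KSpaceData, coils: CoilSensitivities) -> ReconImage:
    """Coil-combined zero-filled reconstruction (no unfolding)."""
    m = _combine(ifft2c(ks.data), coils)
    return ReconImage(image=np.abs(m), method="zero_filled", af=ks.mask.af)


def _aliasing_matrix(mask: SamplingMask) -> np.ndarray:
    """R x R matrix mapping true group-pixel values to zero-filled aliased
    values, derived numerically from the package's own FFT convention."""
    n, r = mask.n_lines, mask.af
    e0 = np.zeros(n, dtype=np.complex128)
    e0[0] = 1.0
    z = np.fft.fftshift(np.fft.fft(np.fft.ifftshift(e0), norm="ortho"))
    z[~mask.boolean] = 0.0
    r0 = np.fft.fftshift(np.fft.ifft(np.fft.ifftshift(z), norm="ortho"))
    step = n // r
    idx = (np.arange(r)[:, None] - np.arange(r)[None, :]) * step % n
    return r0[idx]  # phi[q, p]


def sense_recon(
    ks_masked: KSpaceData,
    coils: CoilSensitivities,
    mask: SamplingMask | None = None,
    rcond: float = 1e-10,
) -> ReconImage:
    """SENSE unfolding of equidistantly undersampled multi-coil k-space.

    Raises :class:`UnresolvableAliasingError` when the sensitivity system of
    some aliased pixel group is (numerically) rank deficient — e.g. a single
    channel at af > 1.
    """
    mask = mask if mask is not None else ks_masked.mask
    n_ch = ks_masked.n_channels
    nr, npe = ks_masked.shape
    r = mask.af
    if r == 1:
        m = _combine(ifft2c(ks_masked.data), coils)
        return ReconImage(image=np.abs(m), method="acc_sense", af=1)
    if npe % r != 0:
        raise ValueError(
            f"SENSE unfolding requires af ({r}) to divide the number of "
            f"phase-encode lines ({npe})")

    aliased = ifft2c(ks_masked.data)  # (n_ch, nr, npe)
    step = npe // r
    phi = _aliasing_matrix(mask)  # (r_q, r_p)

    y0 = np.arange(step)
    y_p = (y0[:, None] + np.arange(r)[None, :] * step)  # (ng, r)
    sg = coils.maps[:, :, y_p]  # (n_ch, nr, ng, r_p)
    # A[(q, c), p] per (row, group): phi[q, p] * S_c(row, y_p)
    a = phi[None, None, :, None, :] * sg.transpose(1, 2, 0, 3)[:, :, None, :, :]
    # a: (nr, ng, r_q, n_ch, r_p) -> (nr, ng, r_q * n_ch, r_p)
    a = a.reshape(nr, step, r * n_ch, r)
    b = aliased[:, :, y_p].transpose(1, 2, 3, 0).reshape(nr, step, r * n_ch)

    ah = np.conj(np.swapaxes(a, -1, -2))
    aha = ah @ a[..., :]  # (nr, ng, r, r)
    ahb = np.einsum("...ij,...j->...i", ah, b)
    eig = np.linalg.eigvalsh(aha)
    bad = eig[..., 0] < rcond * np.maximum(eig[..., -1], 1e-300)
    if np.any(bad):
        row, grp = np.argwhere(bad)[0]
        raise UnresolvableAliasingError(
            f"unresolvable aliasing: rank-deficient sensitivity system at "
            f"row {row}, pixel group {{{', '.join(str(int(v)) for v in y_p[grp])}}}")
    sol = np.linalg.solve(aha, ahb[..., None])[..., 0]  # (nr, ng, r)

    m = np.zeros((nr, npe), dtype=np.complex128)
    m[:, y_p.ravel()] = sol.reshape(nr, -1)
    return ReconImage(image=np.abs(m), method="acc_sense", af=r)


def soft_threshold(x: np.ndarray, lam: float) -> np.ndarray:
    """Magnitude shrinkage ``x * max(|x| - lam, 0) / |x|`` (phase preserved)."""
    if lam < 0:
        raise ValueError("lam must be >= 0")
    x = np.asarray(x)
    mag = np.abs(x)
    with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
        scale = np.where(mag > lam, 1.0 - lam / np.where(mag > 0, mag, 1.0), 0.0)
    return x * scale


def _wavelet_shrink(m: np.ndarray, lam: float, wavelet: str, levels: int) -> np.ndarray:
    coeffs = pywt.wavedec2(m, wavelet, level=levels)
    out = [coeffs[0]]  # approximation band untouched
    for detail in coeffs[1:]:
        out.append(tuple(soft_threshold(d, lam) for d in detail))
    rec = pywt.waverec2(out, wavelet)
    return rec[: m.shape[0], : m.shape[1]]


def _estimate_lam(m: np.ndarray, cfg: PocsConfig) -> float:
    if cfg.lam is not None:
        return float(cfg.lam)
    if cfg.lam_factor == 0:
        return 0.0
    # MAD noise estimate from the finest diagonal-detail band
    _, (_, _, hh) = pywt.wavedec2(m, cfg.wavelet, level=1)
    sigma = np.median(np.abs(hh - np.median(hh))) / 0.6745
    return float(cfg.lam_factor * sigma)


def pocs_wavelet_recon(
    ks_masked: KSpaceData,
    coils: CoilSensitivities,
    mask: SamplingMask | None = None,
    cfg: PocsConfig | None = None,
) -> ReconImage:
    """POCS iterative reconstruction with wavelet soft-thresholding.

    Each iteration: (1) data-consistency projection — replace the sampled
    k-space lines of the current coil-weighted estimate with the measured
    data; (2) least-squares coil combination; (3) soft-threshold the wavelet
    detail coefficients.  Stops when the relative image change falls below
    ``cfg.tol`` or at ``cfg.max_iters``; non-convergence is flagged in
    ``meta``, not an error.
    """
    mask = mask if mask is not None else ks_masked.mask
    cfg = cfg or PocsConfig()
    pywt.Wavelet(cfg.wavelet)  # validate the wavelet spec up front
    sampled = mask.sampled
    meas = ks_masked.data[..., sampled]
    meas_norm = np.linalg.norm(meas)

    m = _combine(ifft2c(ks_masked.data), coils)
    lam = _estimate_lam(m, cfg)

    residuals = []
    n_iter = 0
    for n_iter in range(1, cfg.max_iters + 1):
        kc = fft2c(coils.maps * m[None])
        resid = np.linalg.norm(kc[..., sampled] - meas) / max(meas_norm, 1e-300)
        kc[..., sampled] = meas
        m_new = _combine(ifft2c(kc), coils)
        if lam > 0:
            m_new = _wavelet_shrink(m_new, lam, cfg.wavelet, cfg.levels)
        residuals.append(float(resid))
        delta = np.linalg.norm(m_new - m) / max(np.linalg.norm(m), 1e-300)
        m = m_new
        if delta < cfg.tol:
            break

    kc = fft2c(coils.maps * m[None])
    final_resid = float(
        np.linalg.norm(kc[..., sampled] - meas) / max(meas_norm, 1e-300))
    meta = {
        "iterations": n_iter,
        "residuals": residuals,
        "final_residual": final_resid,
        "lam": lam,
        "converged": n_iter < cfg.max_iters,
    }
    return ReconImage(image=np.abs(m), method="acc_pocs", af=mask.af, meta=meta)


def noise_uniformity_map(
    recon_fn,
    case,
    coils: CoilSensitivities,
    mask: SamplingMask,
    noise_std: float,
    n_reps: int,
    seed: int = 0,
) -> np.ndarray:
    """Monte-Carlo pixel-wise noise standard-deviation map.

    ``recon_fn(ks_masked, coils, mask) -> ReconImage`` is evaluated over
    ``n_reps`` independent noise realizations with the phantom fixed; the
    spatial pattern of the returned map reflects the g-factor noise
    amplification of the reconstruction.
    """
    from .kspace import apply_mask, simulate_multicoil_kspace

    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    seeds = np.random.SeedSequence(seed).generate_state(n_reps).astype(np.int64)
    stack = np.empty((n_reps,) + case.image.shape)
    for i, s in enumerate(seeds):
        ks = simulate_multicoil_kspace(case, coils, noise_std, int(s & 0x7FFFFFFF))
        stack[i] = recon_fn(apply_mask(ks, mask), coils, mask).image
    return stack.std(axis=0, ddof=0)
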