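"""Multi-coil k-space simulation and retrospective equidistant undersampling.

Conventions
-----------
* k-space is stored DC-centered; forward/inverse transforms are the unitary
  (orthonormal) 2D FFT wrapped in symmetric shifts, so Parseval holds
  exactly and noise variance is identical in k-space and image space.
* The phase-encode direction is the second (column) axis; an equidistant
  mask keeps every ``af``-th column starting at ``offset``.
* Complex Gaussian noise of standard deviation ``noise_std`` is added
  independently to the real and imaginary part of every k-space sample of
  every channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import CoilSensitivities, PhantomCase

__all__ = [
    "SamplingMask",
    "KSpaceData",
    "fft2c",
    "ifft2c",
    "make_equidistant_mask",
    "simulate_multicoil_kspace",
    "apply_mask",
    "estimate_scan_time",
    "format_scan_time",
]


def fft2c(x: np.ndarray) -> np.ndarray:
    """Unitary, DC-centered 2D FFT over the last two axes."""
    return np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(x, axes=(-2, -1)), norm="ortho"),
        axes=(-2, -1))


def ifft2c(x: np.ndarray) -> np.ndarray:
    """Inverse of :func:`fft2c`."""
    return np.fft.fftshift(
        np.fft.ifft2(np.fft.ifftshift(x, axes=(-2, -1)), norm="ortho"),
        axes=(-2, -1))


@dataclass(frozen=True)
class SamplingMask:
    """Equidistant phase-encode sampling pattern."""

    n_lines: int
    af: int
    offset: int = 0

    def __post_init__(self) -> None:
        if self.af < 1:
            raise ValueError("acceleration factor must be >= 1")
        if not (0 <= self.offset < self.af):
            raise ValueError("offset must satisfy 0 <= offset < af")
        if self.n_lines < 1:
            raise ValueError("n_lines must be >= 1")

    @property
    def sampled(self) -> np.ndarray:
        """Sampled phase-encode line indices (ascending)."""
        return np.arange(self.offset, self.n_lines, self.af)

    @property
    def boolean(self) -> np.ndarray:
        m = np.zeros(self.n_lines, dtype=bool)
        m[self.sampled] = True
        return m

    @property
    def is_full(self) -> bool:
        return self.af == 1


def make_equidistant_mask(n_lines: int, af: int, offset: int = 0) -> SamplingMask:
    """Keep every ``af``-th phase-encode line starting at ``offset``."""
    return SamplingMask(n_lines=n_lines, af=af, offset=offset)


@dataclass
class KSpaceData:
    """Per-channel complex k-space with its sampling mask."""

    data: np.ndarray  # (n_channels, n_freq, n_phase) complex
    mask: SamplingMask
    noise_std: float = 0.0
    seed: int = 0

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[-2:]


def simulate_multicoil_kspace(
    case: PhantomCase,
    coils: CoilSensitivities,
    noise_std: float = 0.0,
    seed: int = 0,
) -> KSpaceData:
    """Fully sampled multi-channel k-space of a phantom.

    Per channel ``c``: ``data_c = F(S_c * image) + eps_c`` with ``eps_c``
    i.i.d. complex Gaussian (``noise_std`` per real/imag component).
    """
    if coils.maps.shape[-2:] != case.image.shape:
        raise ValueError(
            f"coil maps {coils.maps.shape[-2:]} do not match phantom "
            f"{case.image.shape}")
    if noise_std < 0:
        raise ValueError("noise_std must be >= 0")
    ks = fft2c(coils.maps * case.image[None])
    if noise_std > 0:
        rng = np.random.default_rng(seed)
        ks = ks + noise_std * (
            rng.standard_normal(ks.shape) + 1j * rng.standard_normal(ks.shape))
    full = make_equidistant_mask(case.image.shape[1], af=1)
    return KSpaceData(data=ks, mask=full, noise_std=float(noise_std), seed=int(seed))


def apply_mask(ks: KSpaceData, mask: SamplingMask) -> KSpaceData:
    """Zero out unsampled phase-encode lines (idempotent)."""
    if mask.n_lines != ks.shape[1]:
        raise ValueError(
            f"mask covers {mask.n_lines} lines, k-space has {ks.shape[1]}")
    out = np.zeros_like(ks.data)
    out[..., mask.sampled] = ks.data[..., mask.sampled]
    return KSpaceData(data=out, mask=mask, noise_std=ks.noise_std, seed=ks.seed)


def estimate_scan_time(full_time_s: float, af: int) -> float:
    """Accelerated scan time: full-sampling time divided by the AF."""
    if full_time_s <= 0:
        raise ValueError("full_time_s must be positive")
    if af < 1:
        raise ValueError("af must be >= 1")
    return full_time_s / af


def format_scan_time(seconds: float) -> str:
    """Render seconds as e.g. ``"1 min 32 s"`` (rounded to the second)."""
    total = int(round(seconds))
    return f"{total // 60} min {total % 60} s"
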