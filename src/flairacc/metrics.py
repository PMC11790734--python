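"""Quantitative image comparison: SSIM, NRMSE and 25x25 regional variants.

Whole-image SSIM/NRMSE score each accelerated arm against the fully sampled
reference; regional scores are computed on fixed-size windows centered on
each lesion, extracted at identical coordinates from both images so that
the comparison isolates reconstruction differences, not window placement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.metrics import normalized_root_mse, structural_similarity

__all__ = [
    "SsimParams",
    "MetricRecord",
    "compute_ssim",
    "compute_nrmse",
    "extract_region",
    "regional_metrics",
    "summarize_metrics",
]

_NRMSE_MODES = {"range": "min-max", "mean": "mean", "euclidean": "euclidean"}


@dataclass(frozen=True)
class SsimParams:
    """SSIM windowing and stability constants.

    Default: 11x11 Gaussian window (sigma 1.5), k1=0.01, k2=0.03, dynamic
    range taken from the reference image unless given.
    """

    win_size: int = 11
    gaussian: bool = True
    sigma: float = 1.5
    k1: float = 0.01
    k2: float = 0.03
    dynamic_range: float | None = None

    def __post_init__(self) -> None:
        if self.win_size % 2 == 0:
            raise ValueError("SSIM window size must be odd")
        if self.k1 <= 0 or self.k2 <= 0:
            raise ValueError("k1 and k2 must be positive")


@dataclass
class MetricRecord:
    """Whole-image and per-lesion scores of one arm of one case."""

    case_id: int
    arm: str  # "acc" | "dlr"
    ssim: float
    nrmse: float
    regional: list[tuple[int, float, float]] = field(default_factory=list)
    nrmse_mode: str = "range"


def _data_range(ref: np.ndarray, params: SsimParams) -> float:
    if params.dynamic_range is not None:
        rng = float(params.dynamic_range)
    else:
        rng = float(ref.max() - ref.min())
    if rng <= 0:
        raise ValueError("dynamic range must be positive")
    return rng


def compute_ssim(ref: np.ndarray, test: np.ndarray,
                 params: SsimParams | None = None) -> float:
    """Mean structural similarity between two same-shape magnitude images."""
    params = params or SsimParams()
    if ref.shape != test.shape:
        raise ValueError("images must have the same shape")
    return float(structural_similarity(
        ref, test,
        win_size=params.win_size,
        gaussian_weights=params.gaussian,
        sigma=params.sigma,
        K1=params.k1, K2=params.k2,
        use_sample_covariance=False,
        data_range=_data_range(ref, params),
    ))


def compute_nrmse(ref: np.ndarray, test: np.ndarray,
                  normalization: str = "range") -> float:
    """RMSE divided by a normalizer of the reference image.

    ``normalization`` is one of ``"range"`` (max - min, the default),
    ``"mean"`` or ``"euclidean"``.
    """
    if ref.shape != test.shape:
        raise ValueError("images must have the same shape")
    if normalization not in _NRMSE_MODES:
        raise ValueError(f"unknown normalization {normalization!r}")
    if normalization == "range" and ref.max() == ref.min():
        raise ValueError("reference has zero intensity range")
    if normalization == "mean" and ref.mean() == 0:
        raise ValueError("reference has zero mean")
    if normalization == "euclidean" and not np.any(ref):
        raise ValueError("reference has zero norm")
    return float(normalized_root_mse(ref, test,
                                     normalization=_NRMSE_MODES[normalization]))


def extract_region(image: np.ndarray, center_rc: tuple[int, int],
                   size: int = 25) -> np.ndarray:
    """Square window centered at ``center_rc``, clamp-shifted at borders.

    Near an image border the window is shifted (not padded) to stay inside
    the grid, so the same center always yields the same coordinates on every
    arm and no artificial intensities enter the comparison.
    """
    if size % 2 == 0:
        raise ValueError("window size must be odd")
    nr, nc = image.shape
    if size > nr or size > nc:
        raise ValueError(f"image {image.shape} smaller than {size}x{size} window")
    r, c = center_rc
    if not (0 <= r < nr and 0 <= c < nc):
        raise ValueError("window center lies outside the image")
    half = size // 2
    r0 = int(np.clip(r - half, 0, nr - size))
    c0 = int(np.clip(c - half, 0, nc - size))
    return image[r0:r0 + size, c0:c0 + size]


def regional_metrics(ref: np.ndarray, test: np.ndarray, lesions,
                     size: int = 25,
                     ssim_params: SsimParams | None = None,
                     nrmse_mode: str = "range",
                     ) -> list[tuple[int, float, float]]:
    """Per-lesion (id, regional SSIM, regional NRMSE) on ``size`` windows."""
    if not lesions:
        raise ValueError("lesion list is empty")
    # regional windows are small; drop to a smaller SSIM window if needed
    params = ssim_params or SsimParams()
    if params.win_size > size:
        params = SsimParams(win_size=size if size % 2 else size - 1,
                            gaussian=params.gaussian, sigma=params.sigma,
                            k1=params.k1, k2=params.k2,
                            dynamic_range=params.dynamic_range)
    out = []
    for les in lesions:
        try:
            pr = extract_region(ref, les.center_rc, size)
            pt = extract_region(test, les.center_rc, size)
            out.append((les.id, compute_ssim(pr, pt, params),
                        compute_nrmse(pr, pt, nrmse_mode)))
        except ValueError as exc:
            raise ValueError(f"lesion {les.id}: {exc}") from exc
    return out


def summarize_metrics(records: list[MetricRecord]) -> pd.DataFrame:
    """Per-arm mean +/- SD summary of all four metrics.

    SD uses the population convention (ddof=0), so a single record reports
    SD 0.  Returns one row per arm with columns
    ``ssim_mean/sd, nrmse_mean/sd, regional_ssim_mean/sd,
    regional_nrmse_mean/sd`` plus sample sizes.
    """
    if not records:
        raise ValueError("no metric records")
    rows = []
    for arm in sorted({r.arm for r in records}):
        sub = [r for r in records if r.arm == arm]
        ssim = np.array([r.ssim for r in sub])
        nrmse = np.array([r.nrmse for r in sub])
        reg = [(s, e) for r in sub for (_, s, e) in r.regional]
        reg_s = np.array([s for s, _ in reg]) if reg else np.array([np.nan])
        reg_e = np.array([e for _, e in reg]) if reg else np.array([np.nan])
        rows.append({
            "arm": arm,
            "n_cases": len(sub),
            "n_lesions": len(reg),
            "ssim_mean": ssim.mean(), "ssim_sd": ssim.std(ddof=0),
            "nrmse_mean": nrmse.mean(), "nrmse_sd": nrmse.std(ddof=0),
            "regional_ssim_mean": np.nanmean(reg_s),
            "regional_ssim_sd": np.nanstd(reg_s, ddof=0),
            "regional_nrmse_mean": np.nanmean(reg_e),
            "regional_nrmse_sd": np.nanstd(reg_e, ddof=0),
        })
    return pd.DataFrame(rows).set_index("arm")
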