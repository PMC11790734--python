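"""Synthetic FLAIR-like brain phantoms with white-matter hyperintensities.

The cohort generated here stands in for raw patient data: 2D axial
magnitude images with four tissue classes (CSF, gray matter, white matter,
lesion) on a dark background, plus smooth complex coil-sensitivity maps for
multi-channel acquisition simulation.  Geometry is a jittered set of
concentric smoothed ellipses — enough structure to carry the contrast
classes and focal hyperintense lesions the evaluation needs, without any
claim to anatomical realism.

Intensity conventions follow FLAIR: CSF is suppressed (darkest tissue),
gray matter is brighter than white matter, and lesions are hyperintense
relative to white matter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "LABEL_BACKGROUND",
    "LABEL_CSF",
    "LABEL_GM",
    "LABEL_WM",
    "LABEL_LESION",
    "Lesion",
    "PhantomCase",
    "CoilSensitivities",
    "PhantomConfig",
    "PhantomOvercrowdedError",
    "generate_phantom",
    "generate_coil_sensitivities",
    "generate_cohort",
    "save_phantom_nifti",
    "save_phantom_png",
    "lesions_to_csv",
    "read_lesion_csv",
    "save_coils_h5",
    "load_coils_h5",
]

LABEL_BACKGROUND = 0
LABEL_CSF = 1
LABEL_GM = 2
LABEL_WM = 3
LABEL_LESION = 4

# FLAIR-like tissue intensities in arbitrary signal units.
TISSUE_INTENSITY = {
    LABEL_BACKGROUND: 0.0,
    LABEL_CSF: 0.15,
    LABEL_GM: 0.70,
    LABEL_WM: 0.55,
}


class PhantomOvercrowdedError(RuntimeError):
    """Raised when non-overlapping lesion placement fails after bounded retries."""


@dataclass(frozen=True)
class Lesion:
    """A single hyperintense white-matter lesion (rasterized disc)."""

    id: int
    center_rc: tuple[int, int]
    diameter_mm: float
    contrast: float  # multiplicative factor relative to white matter


@dataclass
class PhantomCase:
    """Ground-truth phantom: magnitude image, tissue labels and lesion list."""

    image: np.ndarray  # 2D float, non-negative
    labels: np.ndarray  # 2D int, same shape
    lesions: list[Lesion]
    fov_mm: tuple[float, float]
    seed: int

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape

    @property
    def pixel_mm(self) -> tuple[float, float]:
        return (self.fov_mm[0] / self.shape[0], self.fov_mm[1] / self.shape[1])

    @property
    def brain_mask(self) -> np.ndarray:
        return self.labels != LABEL_BACKGROUND


@dataclass
class CoilSensitivities:
    """Complex receive-sensitivity maps, one 2D map per channel."""

    maps: np.ndarray  # (n_channels, nrow, ncol) complex

    @property
    def n_channels(self) -> int:
        return self.maps.shape[0]

    def sos(self) -> np.ndarray:
        """Sum of squared magnitudes over channels."""
        return np.sum(np.abs(self.maps) ** 2, axis=0)


@dataclass
class PhantomConfig:
    """Cohort-level phantom generation settings."""

    shape: tuple[int, int] = (128, 128)
    fov_mm: tuple[float, float] = (240.0, 240.0)
    n_lesions_range: tuple[int, int] = (3, 5)  # inclusive, per case
    diameter_range_mm: tuple[float, float] = (3.0, 10.0)
    lesion_contrast: float = 1.4
    boundary_jitter: float = 0.012  # std of radial harmonic perturbations

    def __post_init__(self) -> None:
        if min(self.shape) < 32:
            raise ValueError("phantom grid must be at least 32x32")
        lo, hi = self.diameter_range_mm
        if not (0 < lo <= hi <= min(self.fov_mm) / 4):
            raise ValueError("diameter range must lie within (0, min(fov)/4]")


def _normalized_coords(shape):
    r = np.arange(shape[0]) - (shape[0] - 1) / 2.0
    c = np.arange(shape[1]) - (shape[1] - 1) / 2.0
    u = r[:, None] / (shape[0] / 2.0)
    v = c[None, :] / (shape[1] / 2.0)
    return np.broadcast_to(u, shape), np.broadcast_to(v, shape)


def _tissue_labels(shape, rng, jitter: float) -> np.ndarray:
    """Concentric smoothed-ellipse anatomy with two CSF ventricles."""
    u, v = _normalized_coords(shape)
    # per-case jitter of the head ellipse
    a = 0.86 * (1 + 0.03 * rng.standard_normal())
    b = 0.92 * (1 + 0.03 * rng.standard_normal())
    cu = 0.02 * rng.standard_normal()
    cv = 0.02 * rng.standard_normal()
    theta = np.arctan2(v - cv, u - cu)
    pert = np.ones(shape)
    for k in range(2, 6):
        eps = jitter * rng.standard_normal()
        phi = rng.uniform(0, 2 * np.pi)
        pert += eps * np.cos(k * theta + phi)
    rho = np.sqrt(((u - cu) / a) ** 2 + ((v - cv) / b) ** 2) / np.clip(pert, 0.8, 1.2)

    labels = np.full(shape, LABEL_BACKGROUND, dtype=np.int32)
    labels[rho <= 1.0] = LABEL_CSF       # outer CSF rim (sulcal fluid)
    labels[rho <= 0.93] = LABEL_GM       # cortical ribbon
    labels[rho <= 0.72] = LABEL_WM       # white-matter core

    # paired lateral ventricles (CSF) inside the WM core
    for sgn in (-1.0, 1.0):
        vc = sgn * (0.16 + 0.02 * rng.standard_normal())
        uc = -0.08 + 0.02 * rng.standard_normal()
        vent = ((u - uc) / 0.26) ** 2 + ((v - vc) / 0.085) ** 2
        labels[(vent <= 1.0) & (labels == LABEL_WM)] = LABEL_CSF
    return labels


def _place_lesions(labels, pixel_mm, n_lesions, diameter_range_mm, contrast, rng,
                   max_retries: int = 400) -> list[Lesion]:
    px = float(np.mean(pixel_mm))  # isotropic in the default square FOV
    wm = labels == LABEL_WM
    edt = ndimage.distance_transform_edt(wm)
    lesions: list[Lesion] = []
    for lid in range(n_lesions):
        d_mm = rng.uniform(*diameter_range_mm)
        r_pix = (d_mm / 2.0) / px
        cand = np.argwhere(edt >= r_pix + 1.5)
        if cand.size == 0:
            raise PhantomOvercrowdedError(
                f"no white-matter site can host a {d_mm:.1f} mm lesion")
        placed = False
        for _ in range(max_retries):
            rr, cc = cand[rng.integers(len(cand))]
            ok = all(
                np.hypot(rr - l.center_rc[0], cc - l.center_rc[1])
                > r_pix + (l.diameter_mm / 2.0) / px + 2.0
                for l in lesions
            )
            if ok:
                lesions.append(Lesion(lid, (int(rr), int(cc)), float(d_mm), contrast))
                placed = True
                break
        if not placed:
            raise PhantomOvercrowdedError(
                f"phantom overcrowded: could not place lesion {lid} "
                f"after {max_retries} retries")
    return lesions


def generate_phantom(
    shape: tuple[int, int] = (128, 128),
    fov_mm: tuple[float, float] | float = (240.0, 240.0),
    n_lesions: int = 4,
    diameter_range_mm: tuple[float, float] = (3.0, 10.0),
    seed: int = 0,
    lesion_contrast: float = 1.4,
    boundary_jitter: float = 0.012,
) -> PhantomCase:
    """Generate one FLAIR-like phantom with hyperintense WM lesions.

    Deterministic for fixed arguments and ``seed``.  Lesions are
    non-overlapping rasterized discs with a 1-pixel smoothed intensity edge,
    restricted to the white-matter compartment; the label map marks the hard
    disc footprint as ``LABEL_LESION``.
    """
    if np.isscalar(fov_mm):
        fov_mm = (float(fov_mm), float(fov_mm))
    cfg = PhantomConfig(tuple(shape), tuple(fov_mm), (n_lesions, n_lesions),
                        tuple(diameter_range_mm), lesion_contrast, boundary_jitter)
    if n_lesions < 0:
        raise ValueError("n_lesions must be >= 0")
    rng = np.random.default_rng(seed)
    labels = _tissue_labels(cfg.shape, rng, cfg.boundary_jitter)

    image = np.zeros(cfg.shape, dtype=np.float64)
    for lab, inten in TISSUE_INTENSITY.items():
        image[labels == lab] = inten
    image = ndimage.gaussian_filter(image, sigma=0.8)  # soft tissue interfaces
    image[labels == LABEL_BACKGROUND] *= 0.0

    pixel_mm = (cfg.fov_mm[0] / cfg.shape[0], cfg.fov_mm[1] / cfg.shape[1])
    lesions = _place_lesions(labels, pixel_mm, n_lesions, cfg.diameter_range_mm,
                             cfg.lesion_contrast, rng)

    px = float(np.mean(pixel_mm))
    rr, cc = np.indices(cfg.shape)
    wm_level = TISSUE_INTENSITY[LABEL_WM]
    for les in lesions:
        r_pix = (les.diameter_mm / 2.0) / px
        d = np.hypot(rr - les.center_rc[0], cc - les.center_rc[1])
        bump = np.clip(r_pix + 0.5 - d, 0.0, 1.0)  # 1-px smoothed edge
        image += (les.contrast - 1.0) * wm_level * bump
        labels[d <= r_pix] = LABEL_LESION

    return PhantomCase(image=image, labels=labels, lesions=lesions,
                       fov_mm=cfg.fov_mm, seed=int(seed))


def generate_coil_sensitivities(
    shape: tuple[int, int],
    n_channels: int = 8,
    seed: int = 0,
) -> CoilSensitivities:
    """Smooth complex coil maps: Gaussian magnitude lobes on a ring, slowly
    varying phase.  Sum-of-squares is strictly positive on the whole grid.
    """
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    rng = np.random.default_rng(seed)
    nr, nc = shape
    rr, cc = np.indices(shape, dtype=np.float64)
    r0, c0 = (nr - 1) / 2.0, (nc - 1) / 2.0
    radius = 0.95 * min(nr, nc) / 2.0
    width = 0.65 * min(nr, nc)
    maps = np.empty((n_channels, nr, nc), dtype=np.complex128)
    for ch in range(n_channels):
        ang = 2 * np.pi * ch / n_channels + 0.15 * rng.standard_normal()
        cr = r0 + radius * np.cos(ang)
        cw = c0 + radius * np.sin(ang)
        mag = 0.05 + np.exp(-((rr - cr) ** 2 + (cc - cw) ** 2) / (2 * width**2 / 4))
        # slowly varying phase: constant + gentle linear ramp
        g_r = rng.uniform(-1.5, 1.5) * np.pi / max(nr, 1)
        g_c = rng.uniform(-1.5, 1.5) * np.pi / max(nc, 1)
        phase = rng.uniform(0, 2 * np.pi) + g_r * (rr - r0) + g_c * (cc - c0)
        maps[ch] = mag * np.exp(1j * phase)
    return CoilSensitivities(maps=maps)


def case_seeds(master_seed: int, n_cases: int) -> np.ndarray:
    """Reproducible per-case seeds (< 2**31) derived from a master seed."""
    ss = np.random.SeedSequence(master_seed)
    return ss.generate_state(n_cases, dtype=np.uint32).astype(np.int64) & 0x7FFFFFFF


def generate_cohort(
    n_cases: int,
    config: PhantomConfig | None = None,
    master_seed: int = 0,
) -> list[PhantomCase]:
    """Generate a cohort of distinct phantoms with reproducible per-case seeds."""
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    cfg = config or PhantomConfig()
    seeds = case_seeds(master_seed, n_cases)
    cases = []
    lo, hi = cfg.n_lesions_range
    for s in seeds:
        # draw the per-case lesion count from a stream separate from the
        # phantom's own rng so generate_phantom stays a pure function of
        # (args, seed)
        n_les = int(np.random.default_rng(s + 1).integers(lo, hi + 1))
        cases.append(generate_phantom(
            shape=cfg.shape, fov_mm=cfg.fov_mm, n_lesions=n_les,
            diameter_range_mm=cfg.diameter_range_mm, seed=int(s),
            lesion_contrast=cfg.lesion_contrast,
            boundary_jitter=cfg.boundary_jitter))
    return cases


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def save_phantom_nifti(case: PhantomCase, path) -> None:
    import nibabel as nib

    aff = np.diag([case.pixel_mm[0], case.pixel_mm[1], 1.0, 1.0])
    nib.save(nib.Nifti1Image(case.image[..., None].astype(np.float32), aff), str(path))


def save_phantom_png(image: np.ndarray, path, lo_pct: float = 0.0,
                     hi_pct: float = 99.5) -> None:
    """Window-scaled 8-bit PNG of a magnitude image."""
    import imageio.v3 as iio

    lo, hi = np.percentile(image, [lo_pct, hi_pct])
    scaled = np.clip((image - lo) / max(hi - lo, 1e-12), 0, 1)
    iio.imwrite(str(path), (scaled * 255).astype(np.uint8))


def lesions_to_csv(case: PhantomCase, path) -> None:
    import pandas as pd

    pd.DataFrame(
        [{"id": l.id, "row": l.center_rc[0], "col": l.center_rc[1],
          "diameter_mm": l.diameter_mm} for l in case.lesions]
    ).to_csv(path, index=False)


def read_lesion_csv(path) -> list[Lesion]:
    import pandas as pd

    df = pd.read_csv(path)
    return [Lesion(int(r.id), (int(r.row), int(r.col)), float(r.diameter_mm), np.nan)
            for r in df.itertuples()]


def save_coils_h5(coils: CoilSensitivities, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("maps", data=coils.maps)


def load_coils_h5(path) -> CoilSensitivities:
    import h5py

    with h5py.File(path, "r") as f:
        return CoilSensitivities(maps=f["maps"][...])
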