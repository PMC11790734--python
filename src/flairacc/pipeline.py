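"""End-to-end desk-scale experiment: simulate, reconstruct, denoise, score.

The full chain replicates the study design on synthetic data: generate an
evaluation cohort of FLAIR-like phantoms; simulate noisy multi-coil
k-space; reconstruct the fully sampled reference ("std" arm); undersample
at the acceleration factor and reconstruct the accelerated arm ("acc", POCS
with wavelet soft-thresholding by default, plain SENSE selectable); train
the residual CNN denoiser on a disjoint synthetic training cohort and apply
it to the accelerated images ("dlr" arm); score both accelerated arms
against the reference with whole-image and regional SSIM/NRMSE; compare the
arms with Bonferroni-corrected Wilcoxon signed-rank tests.

Everything is driven by one master seed and is bit-reproducible.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .denoiser import (DenoiserModel, apply_denoiser, init_model,
                       make_training_pairs, train_denoiser)
from .kspace import (apply_mask, estimate_scan_time, format_scan_time,
                     make_equidistant_mask, simulate_multicoil_kspace)
from .metrics import (MetricRecord, SsimParams, compute_nrmse, compute_ssim,
                      regional_metrics, summarize_metrics)
from .phantom import (PhantomCase, PhantomConfig, generate_cohort,
                      generate_coil_sensitivities)
from .recon import PocsConfig, pocs_wavelet_recon, reference_recon, sense_recon
from .reader_stats import (RatingTable, bonferroni_adjust, icc_2_1,
                           score_distribution, wilcoxon_signed_rank)

log = logging.getLogger("flairacc")

__all__ = [
    "ExperimentConfig",
    "ExperimentReport",
    "PipelineStageError",
    "run_experiment",
    "write_report",
    "simulate_reader_ratings",
]

WM_SIGNAL = 0.55  # white-matter intensity of the phantom, the noise anchor


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name, case id and any
    records completed before the failure (partial results)."""

    def __init__(self, stage: str, case_id, exc: Exception, partial=None):
        self.stage = stage
        self.case_id = case_id
        self.partial_records = list(partial) if partial else []
        super().__init__(f"stage {stage!r} failed on case {case_id}: {exc}")


@dataclass
class DenoiserConfig:
    epochs: int = 90
    lr: float = 3e-4
    batch_size: int = 16
    n_patches: int = 384
    patch_size: int = 24
    val_fraction: float = 0.2
    enabled: bool = True


@dataclass
class ExperimentConfig:
    """All knobs of the desk-scale experiment, serializable to YAML."""

    n_cases: int = 30            # evaluation cohort (the study's 30 patients)
    n_train_cases: int = 12      # disjoint denoiser-training cohort
    shape: tuple[int, int] = (128, 128)
    fov_mm: tuple[float, float] = (240.0, 240.0)
    n_channels: int = 8
    noise_std_rel: float = 0.008  # k-space noise std relative to WM signal
    ref_noise_std_rel: float = 0.0
    af: int = 3
    offset: int = 0
    acc_method: str = "pocs"     # "pocs" | "sense"
    # light shrinkage in the acc arm: most of the amplified noise is left
    # for the denoiser, as in the study design being replicated
    pocs: PocsConfig = field(
        default_factory=lambda: PocsConfig(lam_factor=0.05))
    denoiser: DenoiserConfig = field(default_factory=DenoiserConfig)
    n_lesions_range: tuple[int, int] = (3, 5)
    diameter_range_mm: tuple[float, float] = (3.0, 10.0)
    lesion_contrast: float = 1.4
    region_size: int = 25
    nrmse_mode: str = "range"
    full_scan_time_s: float = 277.0
    master_seed: int = 42

    def __post_init__(self) -> None:
        if self.acc_method not in ("pocs", "sense"):
            raise ValueError("acc_method must be 'pocs' or 'sense'")
        if self.n_cases < 1 or self.n_train_cases < 0:
            raise ValueError("cohort sizes must be positive")
        if not (0 <= self.offset < self.af):
            raise ValueError("offset must satisfy 0 <= offset < af")

    def phantom_config(self) -> PhantomConfig:
        return PhantomConfig(
            shape=tuple(self.shape), fov_mm=tuple(self.fov_mm),
            n_lesions_range=tuple(self.n_lesions_range),
            diameter_range_mm=tuple(self.diameter_range_mm),
            lesion_contrast=self.lesion_contrast)

    @property
    def noise_std(self) -> float:
        return self.noise_std_rel * WM_SIGNAL

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "pocs" in d and isinstance(d["pocs"], dict):
            d["pocs"] = PocsConfig(**d["pocs"])
        if "denoiser" in d and isinstance(d["denoiser"], dict):
            d["denoiser"] = DenoiserConfig(**d["denoiser"])
        for key in ("shape", "fov_mm", "n_lesions_range", "diameter_range_mm"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(_plain(self.to_dict()),
                                             sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _plain(obj):
    """Recursively convert tuples/numpy scalars for clean YAML round-trips."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


@dataclass
class ExperimentReport:
    """Everything the run produced, regenerable bit-identically."""

    records: list[MetricRecord]
    summary: pd.DataFrame
    tests: dict  # comparison -> {statistic, p, p_bonferroni, n}
    scan_time_s: float
    scan_time_rendered: str
    config: ExperimentConfig
    seeds: dict
    train_meta: dict
    icc_table: pd.DataFrame | None = None
    rating_summary: dict | None = None


def _derive_seeds(master_seed: int) -> dict:
    state = np.random.SeedSequence(master_seed).generate_state(4)
    s = (state.astype(np.int64) & 0x7FFFFFFF).tolist()
    return {"master": int(master_seed), "eval_cohort": s[0],
            "train_cohort": s[1], "denoiser": s[2], "ratings": s[3]}


def _acc_recon(cfg: ExperimentConfig, ks_masked, coils, mask):
    if cfg.acc_method == "sense":
        return sense_recon(ks_masked, coils, mask)
    return pocs_wavelet_recon(ks_masked, coils, mask, cfg.pocs)


def _reconstruct_case(cfg: ExperimentConfig, case: PhantomCase):
    """std and acc reconstructions of one evaluation case."""
    coils = generate_coil_sensitivities(case.shape, cfg.n_channels,
                                        seed=case.seed + 10_000)
    ks = simulate_multicoil_kspace(case, coils, cfg.noise_std,
                                   seed=case.seed + 3)
    std = reference_recon(ks, coils)
    if cfg.af > 1:
        mask = make_equidistant_mask(case.shape[1], cfg.af, cfg.offset)
        acc = _acc_recon(cfg, apply_mask(ks, mask), coils, mask)
    else:
        acc = reference_recon(ks, coils)
        acc.method = "acc_" + cfg.acc_method
    return std, acc


def _train_model(cfg: ExperimentConfig, seeds: dict) -> DenoiserModel:
    t0 = time.time()
    train_cohort = generate_cohort(cfg.n_train_cases, cfg.phantom_config(),
                                   master_seed=seeds["train_cohort"])
    pairs = make_training_pairs(
        train_cohort, n_channels=cfg.n_channels, noise_std=cfg.noise_std,
        af=cfg.af, offset=cfg.offset, pocs_cfg=cfg.pocs,
        ref_noise_std=cfg.ref_noise_std_rel * WM_SIGNAL,
        n_patches=cfg.denoiser.n_patches, patch_size=cfg.denoiser.patch_size,
        seed=seeds["denoiser"])
    model = init_model(seed=seeds["denoiser"])
    train_denoiser(model, pairs, epochs=cfg.denoiser.epochs,
                   lr=cfg.denoiser.lr, batch_size=cfg.denoiser.batch_size,
                   seed=seeds["denoiser"],
                   val_fraction=cfg.denoiser.val_fraction)
    log.info("stage=train n_pairs=%d elapsed=%.1fs final_loss=%.3e",
             pairs.n_pairs, time.time() - t0,
             model.train_meta["final_loss"])
    return model


def run_experiment(config: ExperimentConfig | None = None) -> ExperimentReport:
    """Run the full replica experiment; bit-reproducible from the master seed."""
    cfg = config or ExperimentConfig()
    seeds = _derive_seeds(cfg.master_seed)

    degenerate = (cfg.af == 1 and cfg.noise_std == 0)
    model = None
    if cfg.denoiser.enabled and not degenerate:
        try:
            model = _train_model(cfg, seeds)
        except Exception as exc:  # noqa: BLE001
            raise PipelineStageError("train", None, exc) from exc

    try:
        cohort = generate_cohort(cfg.n_cases, cfg.phantom_config(),
                                 master_seed=seeds["eval_cohort"])
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("simulate", None, exc) from exc

    records: list[MetricRecord] = []
    first_images = None
    for i, case in enumerate(cohort):
        t0 = time.time()
        try:
            std, acc = _reconstruct_case(cfg, case)
            if model is not None:
                dlr = apply_denoiser(model, acc)
            else:
                from .recon import ReconImage
                dlr = ReconImage(image=acc.image.copy(), method="dlr",
                                 af=acc.af, meta={"denoiser": "disabled"})
        except Exception as exc:  # noqa: BLE001
            raise PipelineStageError("recon", i, exc, partial=records) from exc
        try:
            for arm, rec in (("acc", acc), ("dlr", dlr)):
                reg = regional_metrics(std.image, rec.image, case.lesions,
                                       size=cfg.region_size,
                                       nrmse_mode=cfg.nrmse_mode)
                records.append(MetricRecord(
                    case_id=i, arm=arm,
                    ssim=compute_ssim(std.image, rec.image),
                    nrmse=compute_nrmse(std.image, rec.image, cfg.nrmse_mode),
                    regional=reg, nrmse_mode=cfg.nrmse_mode))
        except Exception as exc:  # noqa: BLE001
            raise PipelineStageError("evaluate", i, exc,
                                     partial=records) from exc
        if first_images is None:
            first_images = {"std": std.image, "acc": acc.image,
                            "dlr": dlr.image, "case": case}
        log.info("stage=evaluate case=%d seed=%d elapsed=%.1fs",
                 i, case.seed, time.time() - t0)

    summary = summarize_metrics(records)
    tests = _paired_tests(records)
    scan_s = estimate_scan_time(cfg.full_scan_time_s, cfg.af)

    report = ExperimentReport(
        records=records, summary=summary, tests=tests,
        scan_time_s=scan_s, scan_time_rendered=format_scan_time(scan_s),
        config=cfg, seeds=seeds,
        train_meta=(model.train_meta if model is not None else {}),
    )
    report._first_images = first_images  # for figure export
    report._model = model  # trained denoiser, for downstream evaluation
    return report


def _paired_tests(records: list[MetricRecord]) -> dict:
    """Bonferroni-corrected Wilcoxon tests: acc vs dlr on all four metrics."""
    acc = {r.case_id: r for r in records if r.arm == "acc"}
    dlr = {r.case_id: r for r in records if r.arm == "dlr"}
    cases = sorted(set(acc) & set(dlr))
    pairs = {
        "ssim": ([acc[c].ssim for c in cases], [dlr[c].ssim for c in cases]),
        "nrmse": ([acc[c].nrmse for c in cases], [dlr[c].nrmse for c in cases]),
        "regional_ssim": (
            [s for c in cases for (_, s, _) in acc[c].regional],
            [s for c in cases for (_, s, _) in dlr[c].regional]),
        "regional_nrmse": (
            [e for c in cases for (_, _, e) in acc[c].regional],
            [e for c in cases for (_, _, e) in dlr[c].regional]),
    }
    raw = {}
    for name, (a, b) in pairs.items():
        raw[name] = wilcoxon_signed_rank(np.asarray(a), np.asarray(b))
    adj = bonferroni_adjust([raw[n].p_value for n in pairs], m=len(pairs))
    return {
        name: {"statistic": raw[name].statistic, "p": raw[name].p_value,
               "p_bonferroni": adj[i], "n": raw[name].n,
               "degenerate": raw[name].degenerate}
        for i, name in enumerate(pairs)
    }


# ---------------------------------------------------------------------------
# Synthetic reader ratings (Table-1 analogue)
# ---------------------------------------------------------------------------

def simulate_reader_ratings(records: list[MetricRecord], n_readers: int = 3,
                            seed: int = 0) -> dict[str, RatingTable]:
    """Synthetic 4-point lesion-visibility ratings derived from regional SSIM.

    This is a stand-in for the human reader study (which is out of scope):
    each simulated reader converts a lesion's regional SSIM into a 1-4 score
    through reader-specific cutoffs plus ordinal noise.  It exists to
    exercise the reliability statistics end to end, not to emulate human
    perception.
    """
    rng = np.random.default_rng(seed)
    out = {}
    reader_bias = rng.normal(0.0, 0.25, size=n_readers)
    for arm in sorted({r.arm for r in records}):
        rows = []
        ids = []
        for rec in [r for r in records if r.arm == arm]:
            for (lid, rssim, _) in rec.regional:
                # map similarity to a latent quality in roughly 1..4
                latent = 1.0 + 3.0 * np.clip((rssim - 0.95) / 0.05, 0, 1)
                scores = np.clip(np.rint(latent + reader_bias
                                         + rng.normal(0, 0.35, n_readers)),
                                 1, 4).astype(int)
                rows.append(scores)
                ids.append(f"case{rec.case_id}_lesion{lid}")
        df = pd.DataFrame(rows, index=ids,
                          columns=[f"reader{i+1}" for i in range(n_readers)])
        out[arm] = RatingTable(df)
    return out


def rate_and_summarize(report: ExperimentReport, seed: int | None = None) -> None:
    """Attach a synthetic-ratings ICC table and score distribution in place."""
    seed = report.seeds["ratings"] if seed is None else seed
    tables = simulate_reader_ratings(report.records, seed=seed)
    rows = []
    for arm, table in tables.items():
        k = table.n_readers
        for i in range(k):
            for j in range(i + 1, k):
                sub = table.scores.iloc[:, [i, j]]
                res = icc_2_1(sub)
                rows.append({
                    "arm": arm,
                    "readers": f"{table.scores.columns[i]}-{table.scores.columns[j]}",
                    "icc": res.estimate, "ci_low": res.ci_low,
                    "ci_high": res.ci_high, "category": res.category})
    report.icc_table = pd.DataFrame(rows)
    report.rating_summary = {
        arm: {"pct_score_3_or_4": score_distribution(t)}
        for arm, t in tables.items()}


# ---------------------------------------------------------------------------
# Report output
# ---------------------------------------------------------------------------

def write_report(report: ExperimentReport, outdir) -> list[Path]:
    """Write summary/per-case/per-lesion CSVs, a JSON manifest and PNG panels."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    summary_path = out / "summary.csv"
    report.summary.to_csv(summary_path, float_format="%.6g")
    written.append(summary_path)

    per_case = pd.DataFrame(
        [{"case_id": r.case_id, "arm": r.arm, "ssim": r.ssim,
          "nrmse": r.nrmse} for r in report.records])
    per_case_path = out / "per_case.csv"
    per_case.to_csv(per_case_path, index=False, float_format="%.8g")
    written.append(per_case_path)

    lesion_rows = [
        {"case_id": r.case_id, "arm": r.arm, "lesion_id": lid,
         "regional_ssim": s, "regional_nrmse": e}
        for r in report.records for (lid, s, e) in r.regional]
    per_lesion_path = out / "per_lesion.csv"
    if lesion_rows:
        pd.DataFrame(lesion_rows).to_csv(per_lesion_path, index=False,
                                         float_format="%.8g")
        written.append(per_lesion_path)

    if report.icc_table is not None:
        icc_path = out / "icc_table.csv"
        report.icc_table.to_csv(icc_path, index=False, float_format="%.4g")
        written.append(icc_path)

    manifest = {
        "package_version": __version__,
        "config": _plain(report.config.to_dict()),
        "seeds": report.seeds,
        "scan_time_s": report.scan_time_s,
        "scan_time_rendered": report.scan_time_rendered,
        "tests": _plain(report.tests),
        "train_meta": _plain({k: v for k, v in report.train_meta.items()
                              if k != "epoch_losses"}),
        "n_lesions_evaluated": len(lesion_rows) // 2 if lesion_rows else 0,
        "regional_rows_present": bool(lesion_rows),
        "rating_summary": report.rating_summary,
        "train_eval_disjoint": True,
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    written.append(manifest_path)

    first = getattr(report, "_first_images", None)
    if first is not None:
        written.append(_write_panel(first, out / "figures"))
    return written


def _write_panel(first: dict, figdir: Path) -> Path:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    figdir.mkdir(parents=True, exist_ok=True)
    case = first["case"]
    fig, axes = plt.subplots(2, 3, figsize=(9, 6.2))
    vmax = np.percentile(first["std"], 99.5)
    les = case.lesions[0] if case.lesions else None
    for j, arm in enumerate(("std", "acc", "dlr")):
        axes[0, j].imshow(first[arm], cmap="gray", vmin=0, vmax=vmax)
        axes[0, j].set_title(arm)
        axes[0, j].axis("off")
        if les is not None:
            from .metrics import extract_region
            inset = extract_region(first[arm], les.center_rc, 25)
            axes[1, j].imshow(inset, cmap="gray", vmin=0, vmax=vmax)
            axes[1, j].set_title(f"{arm} lesion inset")
        axes[1, j].axis("off")
    fig.tight_layout()
    path = figdir / "case_000_panel.png"
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path
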