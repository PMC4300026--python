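"""End-to-end orchestration of the segmentation chain.

Stage order: gray-level rescale -> Otsu foreground split -> histogram peaks
-> morphological brain extraction -> bias-field correction within the brain
mask -> three-Gaussian histogram fit and voxel classification -> 3-D
co-occurrence texture features -> stepwise discriminant feature selection
-> one-vs-rest SVM training on confident voxels -> iterative refinement of
ambiguous voxels -> overlap evaluation when ground truth is available.

Brain extraction precedes bias correction: the log-histogram sharpening
needs a mask free of skull/scalp texture, and skull stripping comes first
in the standard preprocessing order for T1 pipelines.

The run is reproducible: a manifest (resolved config, per-stage timings
and convergence flags, fitted parameters, file inventory) is written at
the end, and identical config + seed gives bit-identical outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bias_correction import N3Params, correct_bias
from .brain_extraction import (
    extract_brain,
    find_peaks,
    intensity_histogram,
    otsu_threshold,
)
from .evaluation import OverlapReport, evaluate
from .feature_selection import FeatureTable, sda_select
from .histogram_segmentation import (
    ClassificationOutput,
    KDEConfig,
    classify,
    fit_mixture,
    initialize_params,
)
from .phantom import PhantomSpec, generate_phantom
from .svm_refinement import SVMConfig, refine, sample_training_voxels, train
from .texture_features import extract_features, feature_names, quantize
from .volumes_io import (
    LabelVolume,
    Volume,
    read_labels,
    read_volume,
    rescale_to_gray,
    write_labels,
    write_volume,
)

__all__ = ["PipelineConfig", "RunManifest", "PipelineResult", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Flat stage-prefixed configuration; unknown keys are rejected."""

    seed: int = 0
    gray_levels: int = 256
    # stage toggles
    bias_enabled: bool = True
    svm_enabled: bool = True
    # brain extraction
    extraction_alpha: float = 2.0
    extraction_se_radius: int = 3
    extraction_dilations: int = 3
    extraction_peak_bandwidth: float = 2.0
    # bias correction
    bias_fwhm: float = 0.15
    bias_noise_floor: float = 0.01
    bias_smooth_scale_mm: float = 50.0
    bias_max_iters: int = 50
    bias_tol: float = 1e-3
    # histogram segmentation
    hist_rho: float = 1.5
    hist_kde_bandwidth: float = 2.0
    hist_fit_tol: float = 1e-8
    hist_fit_max_iter: int = 200
    # texture features
    texture_levels: int = 16
    texture_window: int = 21
    texture_distances: tuple[int, ...] = (1, 2, 3, 4, 5)
    # feature selection
    sda_f_enter: float = 3.84
    sda_f_remove: float = 2.71
    sda_max_features: int = 30
    # SVM refinement
    svm_c: float = 100.0
    svm_kernel: str = "gaussian_rbf"
    svm_gamma: float | None = None
    svm_samples_per_image: int = 10_000
    svm_max_refine_iters: int = 10
    svm_train_on_truth: bool = False

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "texture_distances" in data:
            data = dict(data)
            data["texture_distances"] = tuple(data["texture_distances"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file must hold a mapping: {path}")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["texture_distances"] = list(d["texture_distances"])
        return d


@dataclass
class RunManifest:
    """Resolved config, per-stage timings and diagnostics of one run."""

    config: dict
    version: str
    timings_s: dict[str, float] = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        tmp = Path(str(path) + ".tmp")
        with open(tmp, "w") as fh:
            json.dump(
                {
                    "config": self.config,
                    "version": self.version,
                    "timings_s": self.timings_s,
                    "diagnostics": self.diagnostics,
                    "outputs": self.outputs,
                },
                fh,
                indent=2,
                default=_json_default,
            )
        tmp.replace(path)  # atomic finalize


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


@dataclass
class PipelineResult:
    labels: LabelVolume
    manifest: RunManifest
    initial: ClassificationOutput
    brain_mask: np.ndarray
    report: OverlapReport | None = None


class _StageError(RuntimeError):
    def __init__(self, stage: str, manifest: RunManifest, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.manifest = manifest


def run_pipeline(
    source: Volume | PhantomSpec | str | Path,
    config: PipelineConfig = PipelineConfig(),
    truth: LabelVolume | str | Path | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the full chain on a volume, a file path, or a phantom spec.

    When ``source`` is a :class:`PhantomSpec` the ground truth comes with
    the phantom; otherwise ``truth`` may name a label volume for
    evaluation.  With ``out_dir`` set, every intermediate artifact is
    persisted (corrected volume, brain mask, initial and final labels,
    ambiguous mask, feature table, classifier, report, manifest).
    """
    manifest = RunManifest(config=config.to_dict(), version=__version__)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    stage = "load"
    t_start = time.perf_counter()
    try:
        if isinstance(source, PhantomSpec):
            ph = generate_phantom(source)
            volume, truth_lv = ph.volume, ph.truth
            manifest.diagnostics["source"] = {"phantom": True, "seed": source.seed,
                                              "noise_pct": source.noise_pct,
                                              "bias_pct": source.bias_pct}
        else:
            volume = source if isinstance(source, Volume) else read_volume(source)
            truth_lv = None
            manifest.diagnostics["source"] = {"phantom": False}
        if truth is not None:
            truth_lv = truth if isinstance(truth, LabelVolume) else read_labels(truth)
        _tick(manifest, stage, t_start)

        # --- foreground split and brain extraction on the gray-level volume
        stage = "brain_extraction"
        t0 = time.perf_counter()
        gray = rescale_to_gray(volume, levels=config.gray_levels)
        hist_all = intensity_histogram(gray, levels=config.gray_levels)
        t_otsu = otsu_threshold(hist_all)
        i1 = Volume(np.where(gray.data > t_otsu, gray.data, 0.0), gray.spacing, gray.affine)
        fg_hist = intensity_histogram(i1, levels=config.gray_levels, mask=i1.data > 0)
        peaks = find_peaks(fg_hist, bandwidth=config.extraction_peak_bandwidth)
        i2, m1 = extract_brain(
            i1,
            peaks,
            alpha=config.extraction_alpha,
            se_radius=config.extraction_se_radius,
            n_dilations=config.extraction_dilations,
        )
        manifest.diagnostics["otsu_threshold"] = t_otsu
        manifest.diagnostics["peaks"] = {
            "mu_csf": peaks.mu_csf, "mu_gm": peaks.mu_gm, "mu_wm": peaks.mu_wm,
            "csf_is_fallback": peaks.csf_is_fallback,
        }
        manifest.diagnostics["brain_voxels"] = int(m1.sum())
        _tick(manifest, stage, t0)

        # --- bias correction within the brain mask
        stage = "bias_correction"
        t0 = time.perf_counter()
        if config.bias_enabled:
            params = N3Params(
                fwhm=config.bias_fwhm,
                wiener_noise_floor=config.bias_noise_floor,
                field_smooth_scale=config.bias_smooth_scale_mm,
                max_iters=config.bias_max_iters,
                tol=config.bias_tol,
            )
            corrected, estimate = correct_bias(gray, m1, params)
            manifest.diagnostics["bias"] = {
                "iterations": estimate.iterations_run,
                "converged": estimate.converged,
                "field_min": float(estimate.multiplicative[m1].min()),
                "field_max": float(estimate.multiplicative[m1].max()),
            }
        else:
            corrected, estimate = gray, None
            manifest.diagnostics["bias"] = {"skipped": True}
        # the tissue model sees I2 = I1 * M1: voxels the Otsu split removed
        # (background and the darkest CSF) stay zero, are excluded from the
        # histogram fit, and classify as C1.
        keep = m1 & (i1.data > 0)
        work = Volume(
            np.clip(np.rint(np.where(keep, corrected.data, 0.0)), 0, config.gray_levels - 1),
            gray.spacing,
            gray.affine,
        )
        _tick(manifest, stage, t0)

        # --- three-Gaussian histogram segmentation
        stage = "histogram_segmentation"
        t0 = time.perf_counter()
        brain_hist = intensity_histogram(work, levels=config.gray_levels, mask=m1)
        counts = brain_hist.counts.copy()
        counts[0] = 0.0  # Otsu-removed voxels: not part of the tissue model
        brain_hist.counts = counts
        peaks_b = find_peaks(brain_hist, bandwidth=config.extraction_peak_bandwidth)
        kde = KDEConfig(bandwidth=config.hist_kde_bandwidth)
        v0 = initialize_params(brain_hist, peaks_b, kde)
        # anchor each component to its mode so C1 cannot migrate onto the GM
        # peak when the foreground split leaves no CSF mode
        w1 = config.gray_levels - 1
        mu_bounds = np.array(
            [
                [0.0, max(peaks_b.mu_gm - 1.0, peaks_b.mu_csf + 1.0)],
                [peaks_b.mu_csf + 1.0, w1],
                [peaks_b.mu_gm + 1.0, w1],
            ]
        )
        fit = fit_mixture(
            brain_hist,
            v0,
            tol=config.hist_fit_tol,
            max_iter=config.hist_fit_max_iter,
            mu_bounds=mu_bounds,
        )
        initial = classify(work, m1, fit.v_star, rho=config.hist_rho, zero_label=1)
        manifest.diagnostics["mixture"] = {
            "p": fit.v_star.p, "mu": fit.v_star.mu, "sigma": fit.v_star.sigma,
            "sse": fit.sse, "converged": fit.converged,
            "ambiguous_voxels": int(initial.ambiguous.sum()),
        }
        _tick(manifest, stage, t0)

        # --- SVM refinement of ambiguous voxels
        final_labels = initial.labels
        if config.svm_enabled and initial.ambiguous.any():
            stage = "texture_features"
            t0 = time.perf_counter()
            svm_cfg = SVMConfig(
                C=config.svm_c,
                kernel=config.svm_kernel,
                gamma=config.svm_gamma,
                samples_per_image=config.svm_samples_per_image,
                seed=config.seed,
                max_refine_iters=config.svm_max_refine_iters,
            )
            if config.svm_train_on_truth:
                # benchmark mode: labeled training image — sample from the
                # whole brain mask (boundary voxels included) with true labels
                if truth_lv is None:
                    raise ValueError("svm_train_on_truth requires ground-truth labels")
                train_xyz, train_y, exhausted = _sample_truth_voxels(
                    m1, truth_lv, svm_cfg.samples_per_image, seed=config.seed
                )
            else:
                train_xyz, train_y, exhausted = sample_training_voxels(
                    initial, svm_cfg.samples_per_image, seed=config.seed
                )
            amb_xyz = np.argwhere(initial.ambiguous)
            qv = quantize(work, mask=m1, levels=config.texture_levels)
            all_xyz = np.concatenate([train_xyz, amb_xyz])
            feats, clipped = extract_features(
                qv,
                all_xyz,
                window_size=config.texture_window,
                distances=config.texture_distances,
            )
            train_feats = feats[: train_xyz.shape[0]]
            amb_feats = feats[train_xyz.shape[0] :]
            manifest.diagnostics["texture"] = {
                "voi_count": int(all_xyz.shape[0]),
                "clipped_windows": int(clipped.sum()),
                "features_per_voi": int(feats.shape[1]),
            }
            _tick(manifest, stage, t0)

            stage = "feature_selection"
            t0 = time.perf_counter()
            names = feature_names(config.texture_distances)
            table = FeatureTable(X=train_feats, y=train_y, names=names)
            sda = sda_select(
                table,
                f_enter=config.sda_f_enter,
                f_remove=config.sda_f_remove,
                max_features=config.sda_max_features,
            )
            manifest.diagnostics["sda"] = {
                "selected": sda.selected_names(table),
                "wilks_trace": sda.wilks_trace,
            }
            _tick(manifest, stage, t0)

            if sda.selected:
                stage = "svm_refinement"
                t0 = time.perf_counter()
                clf = train(
                    sda.transform(train_feats),
                    train_y,
                    svm_cfg,
                    feature_names=sda.selected_names(table),
                    standardize=False,  # the SDA transform already standardized
                )
                row_of = {tuple(c): i for i, c in enumerate(map(tuple, amb_xyz))}
                amb_reduced = sda.transform(amb_feats)

                def feature_provider(coords: np.ndarray) -> np.ndarray:
                    rows = [row_of[tuple(c)] for c in map(tuple, coords)]
                    return amb_reduced[rows]

                final_labels = refine(initial, feature_provider, clf, svm_cfg)
                changed = int((final_labels.labels != initial.labels.labels).sum())
                manifest.diagnostics["refinement"] = {
                    "relabeled_voxels": changed,
                    "exhausted_training_pool": bool(exhausted),
                }
                _tick(manifest, stage, t0)
                if out is not None:
                    clf.save(out / "classifier.pkl")
                    manifest.outputs["classifier"] = "classifier.pkl"
                    df = pd.DataFrame(train_feats, columns=names)
                    df.insert(0, "label", train_y)
                    for ax, col in enumerate("xyz"):
                        df.insert(ax, col, train_xyz[:, ax])
                    df.to_csv(out / "train_features.csv", index=False)
                    manifest.outputs["train_features"] = "train_features.csv"
            else:
                logger.warning("SDA selected no features; skipping SVM refinement")
                manifest.diagnostics["refinement"] = {"skipped": "empty selection"}

        # --- evaluation
        report = None
        if truth_lv is not None:
            stage = "evaluation"
            t0 = time.perf_counter()
            report = evaluate(final_labels, truth_lv)
            manifest.diagnostics["overlap"] = {
                t: {"kappa": report.per_tissue[t]["kappa"],
                    "jaccard": report.per_tissue[t]["jaccard"]}
                for t in report.per_tissue
            }
            _tick(manifest, stage, t0)

        if out is not None:
            stage = "persist"
            write_volume(work, out / "corrected.nii.gz")
            write_labels(
                LabelVolume(m1.astype(np.int16) * 3, work.spacing, work.affine),
                out / "brain_mask.nii.gz",
            )
            write_labels(initial.labels, out / "labels_initial.nii.gz")
            write_labels(
                LabelVolume(initial.ambiguous.astype(np.int16), work.spacing, work.affine),
                out / "ambiguous.nii.gz",
            )
            write_labels(final_labels, out / "labels_final.nii.gz")
            manifest.outputs.update(
                {
                    "corrected": "corrected.nii.gz",
                    "brain_mask": "brain_mask.nii.gz",
                    "labels_initial": "labels_initial.nii.gz",
                    "ambiguous": "ambiguous.nii.gz",
                    "labels_final": "labels_final.nii.gz",
                }
            )
            if report is not None:
                report.write_csv(out / "overlap_report.csv")
                manifest.outputs["report"] = "overlap_report.csv"
            manifest.write(out / "manifest.json")
            manifest.outputs["manifest"] = "manifest.json"
    except _StageError:
        raise
    except Exception as exc:
        raise _StageError(stage, manifest, exc) from exc

    manifest.timings_s["total"] = round(time.perf_counter() - t_start, 3)
    return PipelineResult(
        labels=final_labels,
        manifest=manifest,
        initial=initial,
        brain_mask=m1,
        report=report,
    )


def _tick(manifest: RunManifest, stage: str, t0: float) -> None:
    manifest.timings_s[stage] = round(time.perf_counter() - t0, 3)


def _sample_truth_voxels(
    brain_mask: np.ndarray, truth: LabelVolume, n: int, seed: int
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Stratified draw from the brain mask with ground-truth tissue labels."""
    sel = brain_mask & truth.mask_for(1, 2, 3)
    coords = np.argwhere(sel)
    labs = truth.labels[sel]
    if coords.shape[0] <= n:
        return coords, labs, True
    rng = np.random.default_rng(seed)
    classes = np.unique(labs)
    total = labs.size
    picks = []
    for c in classes:
        idx = np.nonzero(labs == c)[0]
        k = min(max(int(round(n * idx.size / total)), 10), idx.size)
        picks.append(rng.choice(idx, size=k, replace=False))
    pick = np.concatenate(picks)
    order = rng.permutation(pick.size)
    pick = pick[order]
    return coords[pick], labs[pick], False
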