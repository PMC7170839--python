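"""End-to-end orchestration: cohort -> features -> selection -> CV reports.

``run_pipeline`` consumes either a synthetic-cohort configuration or a cohort
manifest pointing at NIfTI files on disk, extracts the 195-feature table from
the white-matter-normalized volumes, and cross-validates every requested SVM
kernel, writing CSV/plain-text artifacts plus a run log that suffices to
reproduce the bundle (identical config + seed -> byte-identical outputs).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import KERNEL_NAMES, KernelSpec
from .features import GLCMConfig, extract_all_features, feature_names
from .io import (
    CohortManifest,
    normalize_to_reference,
    read_atlas,
    read_manifest,
    read_mask,
    read_volume,
    write_atlas,
    write_feature_table,
    write_manifest,
    write_mask,
    write_volume,
)
from .model import VirtualBiopsyModel
from .synthetic import SubjectCase, SyntheticCohortConfig, generate_cohort

__all__ = ["PipelineConfig", "run_pipeline", "extract_cohort_features",
           "load_cases_from_manifest", "write_cohort"]


@dataclasses.dataclass
class PipelineConfig:
    """Everything one run needs; loadable from a flat YAML mapping."""

    seed: int
    output_dir: str
    manifest_path: str | None = None        # ingest mode when set
    synthetic: SyntheticCohortConfig | None = None
    glcm: GLCMConfig = dataclasses.field(default_factory=GLCMConfig)
    alpha: float = 0.05
    variance_threshold: float = 0.95
    kernels: tuple[str, ...] = KERNEL_NAMES
    n_folds: int = 5
    mode: str = "whole_cohort"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if self.manifest_path is None and self.synthetic is None:
            self.synthetic = SyntheticCohortConfig(seed=self.seed)
        unknown = set(self.kernels) - set(KERNEL_NAMES)
        if unknown:
            raise ValueError(f"unknown kernels: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path, output_dir: str | None = None,
                  seed: int | None = None) -> "PipelineConfig":
        """Load from a flat key:value YAML file (keys documented in README)."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        synth_keys = {f.name for f in dataclasses.fields(SyntheticCohortConfig)}
        synth_raw = {k[len("synthetic_"):]: v for k, v in raw.items()
                     if k.startswith("synthetic_")}
        unknown = set(synth_raw) - synth_keys
        if unknown:
            raise ValueError(f"unknown synthetic_* keys: {sorted(unknown)}")
        cfg_seed = seed if seed is not None else raw.get("seed", 0)
        synthetic = None
        if synth_raw or raw.get("manifest") is None:
            synth_raw.setdefault("seed", cfg_seed)
            for tup_key in ("grid_shape", "spacing", "lesion_radius_range",
                            "location_prior_positive", "location_prior_negative"):
                if tup_key in synth_raw:
                    synth_raw[tup_key] = tuple(synth_raw[tup_key])
            synthetic = SyntheticCohortConfig(**synth_raw)
        glcm = GLCMConfig(
            n_levels=int(raw.get("glcm_levels", 32)),
            distance=int(raw.get("glcm_distance", 8)),
        )
        kernels = tuple(raw.get("kernels", KERNEL_NAMES))
        return cls(
            seed=int(cfg_seed),
            output_dir=output_dir or raw.get("output_dir", "radbiopsy_out"),
            manifest_path=raw.get("manifest"),
            synthetic=synthetic,
            glcm=glcm,
            alpha=float(raw.get("alpha", 0.05)),
            variance_threshold=float(raw.get("variance_threshold", 0.95)),
            kernels=kernels,
            n_folds=int(raw.get("n_folds", 5)),
            mode=raw.get("mode", "whole_cohort"),
        )


def load_cases_from_manifest(manifest: CohortManifest) -> list[SubjectCase]:
    """Read every lesion's volume/masks/atlas; abort naming the lesion on error."""
    cases = []
    for _, row in manifest.table.iterrows():
        try:
            vol = read_volume(row["volume_path"])
            lesion = read_mask(row["lesion_path"])
            reference = read_mask(row["reference_path"])
            atlas = read_atlas(row["atlas_path"])
        except Exception as exc:
            raise RuntimeError(
                f"stage 'ingest' failed for lesion {row['lesion_id']!r} "
                f"(subject {row['subject_id']!r}): {exc}"
            ) from exc
        cases.append(
            SubjectCase(
                subject_id=str(row["subject_id"]),
                lesion_id=str(row["lesion_id"]),
                volume=vol,
                lesion=lesion,
                reference=reference,
                atlas=atlas,
                age=float(row["age"]),
                gender=int(row["gender"]),
                braf_status=str(row["braf_status"]),
                seed_used=-1,
            )
        )
    return cases


def write_cohort(cases: list[SubjectCase], manifest: CohortManifest,
                 out_dir: str | Path) -> CohortManifest:
    """Write a generated cohort as NIfTI + CSV in the layout the reader expects."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = manifest.table.copy()
    for i, case in enumerate(cases):
        stem = f"{case.subject_id}_{case.lesion_id}"
        paths = {
            "volume_path": out / f"{stem}_t1c.nii.gz",
            "lesion_path": out / f"{stem}_lesion.nii.gz",
            "reference_path": out / f"{stem}_nawm.nii.gz",
            "atlas_path": out / f"{stem}_atlas.nii.gz",
        }
        write_volume(case.volume, paths["volume_path"])
        write_mask(case.lesion, paths["lesion_path"])
        write_mask(case.reference, paths["reference_path"])
        write_atlas(case.atlas, paths["atlas_path"])
        for col, p in paths.items():
            table.loc[table.index[i], col] = str(p)
    new_manifest = CohortManifest(table=table)
    write_manifest(new_manifest, out / "manifest.csv")
    return new_manifest


def extract_cohort_features(
    cases: list[SubjectCase], glcm: GLCMConfig | None = None
) -> pd.DataFrame:
    """Normalize each volume to its reference and extract all 195 features."""
    glcm = glcm or GLCMConfig()
    rows = []
    index = []
    for case in cases:
        try:
            norm = normalize_to_reference(case.volume, case.reference)
            normalized_case = dataclasses.replace(case, volume=norm)
            rows.append(extract_all_features(normalized_case, glcm))
        except Exception as exc:
            raise RuntimeError(
                f"stage 'feature-extraction' failed for lesion "
                f"{case.lesion_id!r} (subject {case.subject_id!r}): {exc}"
            ) from exc
        index.append(case.lesion_id)
    return pd.DataFrame(rows, index=index, columns=feature_names(glcm))


def run_pipeline(config: PipelineConfig) -> dict[str, object]:
    """Run the whole analysis and write the artifact bundle.

    Outputs under ``config.output_dir``: ``features.csv``,
    ``selection_report.csv``, ``pca_transform.csv``, per-kernel
    ``cv_metrics_<kernel>.csv`` / ``roc_<kernel>.csv`` /
    ``confusion_<kernel>.txt``, and ``run_log.txt``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.manifest_path is not None:
        manifest = read_manifest(config.manifest_path)
        cases = load_cases_from_manifest(manifest)
    else:
        cases, manifest = generate_cohort(config.synthetic)

    features = extract_cohort_features(cases, config.glcm)
    write_feature_table(
        [row.to_dict() for _, row in features.iterrows()],
        out / "features.csv",
        index=list(features.index),
    )

    model = VirtualBiopsyModel(
        features,
        manifest.labels,
        groups=manifest.groups,
        alpha=config.alpha,
        variance_threshold=config.variance_threshold,
        mode=config.mode,
    )

    results = {}
    for kernel_name in config.kernels:
        res = model.fit(kernel=kernel_name, n_folds=config.n_folds, seed=config.seed)
        results[kernel_name] = res
        cv = res.cv_report
        cv.metrics_frame().to_csv(out / f"cv_metrics_{kernel_name}.csv",
                                  float_format="%.12g", index_label="fold")
        pd.DataFrame(cv.roc_points, columns=["fpr", "tpr"]).to_csv(
            out / f"roc_{kernel_name}.csv", index=False, float_format="%.12g"
        )
        tp, fn = cv.pooled_confusion[0]
        fp, tn = cv.pooled_confusion[1]
        (out / f"confusion_{kernel_name}.txt").write_text(
            f"mode: {cv.mode}\nkernel: {kernel_name}\n"
            f"            pred+  pred-\ntrue+  {tp:6d} {fn:6d}\n"
            f"true-  {fp:6d} {tn:6d}\nAUC: {cv.auc:.6f}\n"
        )
        if res.selection is not None and kernel_name == config.kernels[0]:
            res.selection.to_csv(out / "selection_report.csv")
            if res.pca is not None:
                res.pca.to_csv(out / "pca_transform.csv")

    log = [
        f"radbiopsy version: {__version__}",
        f"seed: {config.seed}",
        f"mode: {config.mode}",
        f"n_folds: {config.n_folds}",
        f"alpha: {config.alpha}",
        f"variance_threshold: {config.variance_threshold}",
        f"glcm: levels={config.glcm.n_levels} distance={config.glcm.distance}",
        f"kernels: {','.join(config.kernels)}",
        f"cohort: {'manifest ' + str(config.manifest_path) if config.manifest_path else 'synthetic'}",
        f"lesions: {len(manifest)}",
    ]
    if config.synthetic is not None and config.manifest_path is None:
        for f in dataclasses.fields(config.synthetic):
            log.append(f"synthetic_{f.name}: {getattr(config.synthetic, f.name)}")
    (out / "run_log.txt").write_text("\n".join(log) + "\n")
    return results
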