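"""Imaging and tabular I/O plus reference-region intensity normalization.

Volumes, masks and atlas parcellations are exchanged as NIfTI-1 files
(``.nii``/``.nii.gz``); cohort manifests and feature tables as UTF-8 CSV
with a header row. Intensities are normalized by dividing the whole volume
by the mean intensity over a normal-appearing-white-matter (NAWM) reference
mask, which puts every scan on a common scale regardless of scanner or
acquisition (the mean over the reference region becomes 1).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "ImageVolume",
    "SegmentationMask",
    "AtlasParcellation",
    "CohortManifest",
    "ATLAS_REGION_NAMES",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_atlas",
    "write_atlas",
    "normalize_to_reference",
    "read_manifest",
    "write_manifest",
    "write_feature_table",
    "read_feature_table",
]

#: The 16 lobar/cerebellar/brainstem regions used for lesion-location
#: features, left/right for each of the eight anatomical divisions.
#: Region codes 1..16 follow this order; code 0 is unlabeled.
ATLAS_REGION_NAMES: tuple[str, ...] = tuple(
    f"{side}_{region}"
    for region in (
        "frontal",
        "parietal",
        "temporal",
        "occipital",
        "limbic",
        "sublobar",
        "cerebellum",
        "brainstem",
    )
    for side in ("left", "right")
)

MANIFEST_COLUMNS = (
    "subject_id",
    "lesion_id",
    "volume_path",
    "lesion_path",
    "reference_path",
    "atlas_path",
    "age",
    "gender",
    "braf_status",
)


@dataclasses.dataclass
class ImageVolume:
    """A 3D scalar grid with physical voxel spacing in millimetres."""

    values: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected 3D volume, got {self.values.ndim}D")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def voxel_volume(self) -> float:
        """Physical volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))


@dataclasses.dataclass
class SegmentationMask:
    """A binary 3D mask on the same grid as its paired :class:`ImageVolume`."""

    values: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 3:
            raise ValueError(f"expected 3D mask, got {self.values.ndim}D")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def count(self) -> int:
        return int(self.values.sum())


@dataclasses.dataclass
class AtlasParcellation:
    """Integer label volume with codes 0 (unlabeled) and 1..16 (regions)."""

    labels: np.ndarray
    spacing: tuple[float, float, float]
    region_names: tuple[str, ...] = ATLAS_REGION_NAMES

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels).astype(np.int32)
        if self.labels.ndim != 3:
            raise ValueError(f"expected 3D atlas, got {self.labels.ndim}D")
        codes = np.unique(self.labels)
        if codes.min() < 0 or codes.max() > len(self.region_names):
            raise ValueError(
                f"atlas codes must lie in 0..{len(self.region_names)}, got "
                f"[{codes.min()}, {codes.max()}]"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        self.region_names = tuple(self.region_names)
        if len(self.region_names) != 16:
            raise ValueError("exactly 16 region names required")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape


@dataclasses.dataclass
class CohortManifest:
    """Tabular index of a cohort: one row per lesion.

    Columns: subject_id, lesion_id, volume_path, lesion_path, reference_path,
    atlas_path, age (years), gender (0/1), braf_status ("positive"/"negative").
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in MANIFEST_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"manifest missing columns: {missing}")
        keys = list(zip(self.table["subject_id"], self.table["lesion_id"]))
        if len(set(keys)) != len(keys):
            raise ValueError("(subject_id, lesion_id) pairs must be unique")
        bad = set(self.table["braf_status"]) - {"positive", "negative"}
        if bad:
            raise ValueError(f"braf_status must be 'positive'/'negative', got {bad}")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def labels(self) -> np.ndarray:
        """Binary labels: 1 for BRAF-positive, 0 for BRAF-negative."""
        return (self.table["braf_status"] == "positive").to_numpy(dtype=int)

    @property
    def groups(self) -> np.ndarray:
        """Patient identifiers, the grouping key for cross-validation."""
        return self.table["subject_id"].to_numpy()


def _load_nifti(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float], nib.Nifti1Image]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
        shape = img.shape
        zooms = img.header.get_zooms()
    except Exception as exc:  # pragma: no cover - nibabel error surface varies
        raise IOError(f"unreadable NIfTI header: {path}: {exc}") from exc
    if len(shape) != 3:
        raise ValueError(f"expected 3D volume, got {len(shape)}D in {path}")
    data = np.asanyarray(img.dataobj)
    return np.asarray(data), tuple(float(z) for z in zooms[:3]), img


def read_volume(path: str | Path) -> ImageVolume:
    """Read a 3D NIfTI volume; grid and spacing come from the header."""
    data, spacing, _ = _load_nifti(path)
    return ImageVolume(values=data.astype(np.float64), spacing=spacing)


def _affine(spacing: tuple[float, float, float]) -> np.ndarray:
    return np.diag([spacing[0], spacing[1], spacing[2], 1.0])


def write_volume(vol: ImageVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(vol.values, dtype=np.float64), _affine(vol.spacing))
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def read_mask(path: str | Path) -> SegmentationMask:
    data, spacing, _ = _load_nifti(path)
    return SegmentationMask(values=data > 0.5, spacing=spacing)


def write_mask(mask: SegmentationMask, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.values.astype(np.uint8), _affine(mask.spacing))
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))


def read_atlas(path: str | Path) -> AtlasParcellation:
    data, spacing, _ = _load_nifti(path)
    return AtlasParcellation(labels=np.rint(data).astype(np.int32), spacing=spacing)


def write_atlas(atlas: AtlasParcellation, path: str | Path) -> None:
    img = nib.Nifti1Image(atlas.labels.astype(np.int16), _affine(atlas.spacing))
    img.header.set_zooms(atlas.spacing)
    nib.save(img, str(path))


def _check_aligned(a, b, what: str) -> None:
    if a.shape != b.shape or not np.allclose(a.spacing, b.spacing):
        raise ValueError(
            f"{what}: grids not aligned (shape {a.shape} vs {b.shape}, "
            f"spacing {a.spacing} vs {b.spacing})"
        )


def normalize_to_reference(vol: ImageVolume, reference: SegmentationMask) -> ImageVolume:
    """Divide every voxel by the mean intensity over the reference region.

    After normalization the mean over the reference mask is 1, so lesion
    intensities are expressed relative to normal-appearing white matter.
    Raises if the reference is empty or has zero mean (division undefined).
    """
    _check_aligned(vol, reference, "normalize_to_reference")
    if reference.count() == 0:
        raise ValueError("reference mask is empty; normalization undefined")
    ref_mean = float(vol.values[reference.values].mean())
    if ref_mean == 0.0:
        raise ValueError("reference region mean intensity is zero; normalization undefined")
    return ImageVolume(values=vol.values / ref_mean, spacing=vol.spacing)


def read_manifest(path: str | Path) -> CohortManifest:
    table = pd.read_csv(path, dtype={"subject_id": str, "lesion_id": str})
    return CohortManifest(table=table)


def write_manifest(manifest: CohortManifest, path: str | Path) -> None:
    manifest.table.to_csv(path, index=False)


def write_feature_table(
    rows: list[dict[str, float]],
    path: str | Path,
    index: list[str] | None = None,
    extra_columns: pd.DataFrame | None = None,
) -> None:
    """Write lesions x features as CSV: one row per lesion, feature-name header.

    All rows must share the same feature names in the same order; a row with a
    missing or extra feature raises an error naming the offending feature.
    Values round-trip through :func:`read_feature_table` to within 1e-9.
    """
    if not rows:
        raise ValueError("no rows to write")
    names = list(rows[0].keys())
    for i, row in enumerate(rows):
        if list(row.keys()) != names:
            missing = set(names) - set(row.keys())
            extra = set(row.keys()) - set(names)
            detail = []
            if missing:
                detail.append(f"missing {sorted(missing)}")
            if extra:
                detail.append(f"unexpected {sorted(extra)}")
            raise ValueError(f"row {i}: inconsistent feature set ({'; '.join(detail)})")
    df = pd.DataFrame(rows, index=index)
    if extra_columns is not None:
        df = pd.concat([extra_columns.set_index(df.index), df], axis=1)
    df.to_csv(path, index=index is not None, index_label="lesion" if index else None,
              float_format="%.12g")


def read_feature_table(path: str | Path, indexed: bool = False) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0 if indexed else None)
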