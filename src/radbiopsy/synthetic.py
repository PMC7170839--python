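"""Seeded synthetic cohorts of contrast-enhancing brain lesions.

Each subject case is a 3D grid holding a homogeneous "brain" background, an
ellipsoidal enhancing lesion whose internal texture is a Gaussian random
field (white noise smoothed at a class-specific correlation length), a
homogeneous white-matter reference region for intensity normalization, and a
16-block grid atlas standing in for a stereotactic parcellation. The two
classes emulate the structure of the clinical problem:

* the BRAF-negative surrogate class has a *shorter* texture correlation
  length, i.e. more heterogeneous lesion signal, reproducing the reported
  direction of the texture difference between genotypes;
* class-specific categorical priors place lesions preferentially in
  different atlas regions;
* ages are drawn from class-specific normals (55 +/- 14 years positive,
  64.4 +/- 12.3 negative) and the cohort defaults to 25 positive and 29
  negative lesions, matching the study cohort's demographics.

All randomness flows from one master seed through per-subject
``numpy.random.SeedSequence`` spawns, so cohorts are bit-reproducible.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import ndtr

from .io import (
    ATLAS_REGION_NAMES,
    AtlasParcellation,
    CohortManifest,
    ImageVolume,
    SegmentationMask,
)

__all__ = [
    "SyntheticCohortConfig",
    "SubjectCase",
    "build_grid_atlas",
    "generate_subject",
    "generate_cohort",
]

# mild default location priors: positive class favours regions 4 (right
# parietal in the left/right-interleaved naming) and 9 (left limbic)... the
# exact regions are arbitrary surrogates; what matters is that the priors
# differ between classes, as the location finding in the clinical cohort did.
def _default_priors() -> tuple[tuple[float, ...], tuple[float, ...]]:
    pos = np.ones(16)
    neg = np.ones(16)
    pos[[3, 8]] = 4.0   # right parietal, left limbic favoured for positives
    neg[[0]] = 4.0      # left frontal favoured for negatives
    return tuple(pos / pos.sum()), tuple(neg / neg.sum())


_POS_PRIOR, _NEG_PRIOR = _default_priors()


@dataclasses.dataclass(frozen=True)
class SyntheticCohortConfig:
    """Study-condition parameters for a synthetic two-class cohort.

    Defaults mirror the clinical cohort: 25 BRAF-positive / 29 BRAF-negative
    lesions on a 64^3 grid at 1 mm isotropic spacing, ages 55 +/- 14 vs
    64.4 +/- 12.3 years, and a shorter texture correlation length (hence
    higher signal heterogeneity) in the negative class.
    """

    n_positive: int = 25
    n_negative: int = 29
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    age_mean_positive: float = 55.0
    age_sd_positive: float = 14.0
    age_mean_negative: float = 64.4
    age_sd_negative: float = 12.3
    female_fraction_positive: float = 9.0 / 25.0
    female_fraction_negative: float = 12.0 / 29.0
    lesion_radius_range: tuple[float, float] = (8.0, 12.0)
    texture_correlation_length_positive: float = 4.0
    texture_correlation_length_negative: float = 1.5
    texture_noise_sd_positive: float = 0.25
    texture_noise_sd_negative: float = 0.25
    lesion_baseline: float = 1.6      # enhancing lesion, in units of WM signal
    wm_intensity: float = 300.0       # raw white-matter signal (arbitrary units)
    background_intensity: float = 240.0
    background_noise_sd: float = 3.0
    location_prior_positive: tuple[float, ...] = _POS_PRIOR
    location_prior_negative: tuple[float, ...] = _NEG_PRIOR
    two_lesion_patient: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_positive < 1 or self.n_negative < 1:
            raise ValueError("class counts must be >= 1")
        if (
            self.texture_correlation_length_positive <= 0
            or self.texture_correlation_length_negative <= 0
        ):
            raise ValueError("correlation lengths must be > 0")
        for prior in (self.location_prior_positive, self.location_prior_negative):
            arr = np.asarray(prior, dtype=float)
            if len(arr) != 16 or (arr < 0).any() or arr.sum() <= 0:
                raise ValueError("location priors must be 16 nonnegative weights, sum > 0")
        if self.lesion_radius_range[0] > self.lesion_radius_range[1]:
            raise ValueError("lesion_radius_range must be (lo, hi) with lo <= hi")

    def class_params(self, braf_status: str) -> dict[str, float]:
        if braf_status == "positive":
            return dict(
                age_mean=self.age_mean_positive,
                age_sd=self.age_sd_positive,
                female_fraction=self.female_fraction_positive,
                corr_length=self.texture_correlation_length_positive,
                noise_sd=self.texture_noise_sd_positive,
                prior=np.asarray(self.location_prior_positive, dtype=float),
            )
        if braf_status == "negative":
            return dict(
                age_mean=self.age_mean_negative,
                age_sd=self.age_sd_negative,
                female_fraction=self.female_fraction_negative,
                corr_length=self.texture_correlation_length_negative,
                noise_sd=self.texture_noise_sd_negative,
                prior=np.asarray(self.location_prior_negative, dtype=float),
            )
        raise ValueError(f"braf_status must be 'positive' or 'negative', got {braf_status!r}")


@dataclasses.dataclass
class SubjectCase:
    """One synthetic lesion: image, masks, atlas and demographics."""

    subject_id: str
    lesion_id: str
    volume: ImageVolume
    lesion: SegmentationMask
    reference: SegmentationMask
    atlas: AtlasParcellation
    age: float
    gender: int
    braf_status: str
    seed_used: int

    def __post_init__(self) -> None:
        shapes = {self.volume.shape, self.lesion.shape, self.reference.shape, self.atlas.shape}
        if len(shapes) != 1:
            raise ValueError("volume, masks and atlas must share one grid")
        if (self.lesion.values & self.reference.values).any():
            raise ValueError("lesion and reference masks must be disjoint")


def build_grid_atlas(
    grid_shape: tuple[int, int, int],
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    margin: int = 4,
) -> AtlasParcellation:
    """Partition the grid interior into 16 rectangular blocks labeled 1..16.

    The interior (the grid inset by ``margin`` voxels on every face,
    standing in for the brain) is split 2 x 2 x 4 along the three axes;
    the exterior is unlabeled (0). Deterministic in the shape alone.
    """
    if any(s < 16 for s in grid_shape):
        raise ValueError(f"grid too small for a 16-region atlas: {grid_shape}")
    labels = np.zeros(grid_shape, dtype=np.int32)
    lo = [margin] * 3
    hi = [s - margin for s in grid_shape]
    splits = (2, 2, 4)  # 2*2*4 = 16 blocks
    edges = [np.linspace(lo[ax], hi[ax], splits[ax] + 1).astype(int) for ax in range(3)]
    code = 1
    for ix in range(splits[0]):
        for iy in range(splits[1]):
            for iz in range(splits[2]):
                labels[
                    edges[0][ix]:edges[0][ix + 1],
                    edges[1][iy]:edges[1][iy + 1],
                    edges[2][iz]:edges[2][iz + 1],
                ] = code
                code += 1
    return AtlasParcellation(labels=labels, spacing=spacing, region_names=ATLAS_REGION_NAMES)


def _gaussian_random_field(
    shape: tuple[int, int, int], corr_length: float, sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Copula texture: smoothed white noise with a uniformized marginal.

    White noise is smoothed at the correlation length, standardized, and
    mapped through the normal CDF, giving a bounded uniform marginal that is
    then centered and rescaled to SD ``sd``. The monotone marginal transform
    preserves the field's spatial rank correlation, so the two classes differ
    in texture correlation (what the co-occurrence features measure) while
    sharing an identical first-order distribution — without it the Gaussian
    tails stretch the range-relative quantization grid of rough fields and
    mask the correlation effect.
    """
    noise = rng.standard_normal(shape)
    field = gaussian_filter(noise, sigma=corr_length, mode="reflect")
    s = field.std()
    if s > 0:
        field /= s
    uniform = ndtr(field)  # standard-normal CDF -> Uniform(0,1) marginal
    return (uniform - 0.5) * (sd * np.sqrt(12.0))


def _place_lesion(
    atlas: AtlasParcellation,
    region_code: int,
    radii: np.ndarray,
    grid_shape: tuple[int, int, int],
    rng: np.random.Generator,
) -> np.ndarray:
    """Binary ellipsoid mask centered in the drawn atlas region."""
    inside = np.argwhere(atlas.labels == region_code)
    if len(inside) == 0:
        raise ValueError(f"atlas region {region_code} is empty")
    center = inside.mean(axis=0) + rng.uniform(-2.0, 2.0, size=3)
    # keep the ellipsoid inside the grid
    center = np.clip(center, radii + 1, np.asarray(grid_shape) - radii - 2)
    if (radii + 1 > np.asarray(grid_shape) - radii - 2).any():
        raise ValueError(f"lesion of radii {radii} cannot fit in grid {grid_shape}")
    grids = np.ogrid[: grid_shape[0], : grid_shape[1], : grid_shape[2]]
    dist2 = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return dist2 <= 1.0


def generate_subject(
    config: SyntheticCohortConfig,
    braf_status: str,
    seed: int,
    subject_id: str = "sub-000",
    lesion_id: str = "les-000",
) -> SubjectCase:
    """One seeded synthetic subject; identical arguments give identical bits."""
    params = config.class_params(braf_status)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    shape = tuple(config.grid_shape)
    atlas = build_grid_atlas(shape, config.spacing)

    region_code = int(rng.choice(16, p=params["prior"] / params["prior"].sum())) + 1
    radii = rng.uniform(*config.lesion_radius_range, size=3)
    lesion = _place_lesion(atlas, region_code, radii, shape, rng)

    # homogeneous WM reference block in the first interior corner, clear of
    # the lesion (overlapping voxels are removed; the block is large enough
    # that it never empties for the default geometry)
    ref = np.zeros(shape, dtype=bool)
    ref[5:13, 5:13, 5:13] = True
    ref &= ~lesion

    volume = np.full(shape, config.background_intensity, dtype=np.float64)
    volume += rng.standard_normal(shape) * config.background_noise_sd
    volume[ref] = config.wm_intensity + rng.standard_normal(int(ref.sum()))  # ~0.3% noise

    texture = _gaussian_random_field(shape, params["corr_length"], params["noise_sd"], rng)
    lesion_signal = config.wm_intensity * (config.lesion_baseline + texture)
    volume[lesion] = lesion_signal[lesion]

    age = float(rng.normal(params["age_mean"], params["age_sd"]))
    gender = int(rng.random() < params["female_fraction"])  # 1 = female

    ref_mask = SegmentationMask(values=ref, spacing=config.spacing)
    if ref_mask.count() == 0:
        raise ValueError("reference region fully occluded by lesion")
    return SubjectCase(
        subject_id=subject_id,
        lesion_id=lesion_id,
        volume=ImageVolume(values=volume, spacing=config.spacing),
        lesion=SegmentationMask(values=lesion, spacing=config.spacing),
        reference=ref_mask,
        atlas=atlas,
        age=age,
        gender=gender,
        braf_status=braf_status,
        seed_used=seed,
    )


def _subject_seed(master_seed: int, index: int) -> int:
    """Deterministic per-subject seed derived from the master seed."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(index,))
    return int(ss.generate_state(1)[0] % (2**31))


def generate_cohort(
    config: SyntheticCohortConfig,
) -> tuple[list[SubjectCase], CohortManifest]:
    """The full two-class cohort plus its manifest.

    Cases are ordered positives first. Per-case seeds derive deterministically
    from ``config.seed``. With ``two_lesion_patient`` the last two negative
    lesions share one subject identifier, exercising group-aware folding.
    """
    cases: list[SubjectCase] = []
    rows = []
    statuses = ["positive"] * config.n_positive + ["negative"] * config.n_negative
    n_total = len(statuses)
    for idx, status in enumerate(statuses):
        subject_id = f"sub-{idx:03d}"
        if config.two_lesion_patient and status == "negative" and idx == n_total - 1:
            subject_id = f"sub-{idx - 1:03d}"  # share the previous negative patient
        case = generate_subject(
            config,
            status,
            seed=_subject_seed(config.seed, idx),
            subject_id=subject_id,
            lesion_id=f"les-{idx:03d}",
        )
        cases.append(case)
        rows.append(
            dict(
                subject_id=case.subject_id,
                lesion_id=case.lesion_id,
                volume_path="",
                lesion_path="",
                reference_path="",
                atlas_path="",
                age=case.age,
                gender=case.gender,
                braf_status=case.braf_status,
            )
        )
    manifest = CohortManifest(table=pd.DataFrame(rows))
    return cases, manifest
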