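"""The 195-feature radiomics vector for one lesion.

Families, in fixed order:

* clinical (2): age, gender
* location (16): percent of lesion voxels in each of 16 atlas regions
* morphology (9): volume, equivalent diameter, extent, three principal-axis
  lengths, convex volume, solidity, surface area
* first-order (12): mean, median, SD, variance, min, max, percentiles
  5/25/75/95, kurtosis (non-excess), skewness
* GLCM (156): 12 Haralick measures x 13 offset directions, computed on the
  lesion after equal-width quantization of the in-lesion intensity range

The gray-level co-occurrence matrix (GLCM) is accumulated symmetrically over
voxel pairs ``(v, v + distance * offset)`` with both voxels inside the lesion,
then normalized to a joint probability table. The 13 offsets are the canonical
half of the 26-neighborhood (4 in-plane directions plus 9 out-of-plane), so
together with their negatives they cover all 26 directions. The displacement
is ``distance`` grid steps along each nonzero component of the direction
vector (a multiplier, not a Euclidean length).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import stats
from skimage import measure
from skimage.morphology import convex_hull_image

from .io import ATLAS_REGION_NAMES, AtlasParcellation, ImageVolume, SegmentationMask

__all__ = [
    "GLCMConfig",
    "GLCMatrix",
    "OFFSETS",
    "GLCM_MEASURES",
    "FEATURE_NAMES",
    "feature_names",
    "extract_location_features",
    "extract_morphology_features",
    "extract_first_order_features",
    "quantize_lesion",
    "compute_glcm",
    "haralick_measures",
    "extract_all_features",
]

#: Canonical half of the 3D 26-neighborhood: the 4 standard in-plane
#: directions (0/45/90/135 degrees in the x-y plane) followed by the 9
#: out-of-plane directions. Offset k and -k index the same symmetric GLCM.
OFFSETS: tuple[tuple[int, int, int], ...] = (
    (1, 0, 0),
    (0, 1, 0),
    (0, 0, 1),
    (1, 1, 0),
    (1, -1, 0),
    (1, 0, 1),
    (1, 0, -1),
    (0, 1, 1),
    (0, 1, -1),
    (1, 1, 1),
    (1, 1, -1),
    (1, -1, 1),
    (1, -1, -1),
)

GLCM_MEASURES: tuple[str, ...] = (
    "energy",
    "entropy",
    "correlation",
    "contrast",
    "variance",
    "sum_mean",
    "inertia",
    "cluster_shade",
    "cluster_tendency",
    "homogeneity",
    "max_probability",
    "inverse_variance",
)

MORPHOLOGY_NAMES: tuple[str, ...] = (
    "volume_mm3",
    "equiv_diameter_mm",
    "extent",
    "principal_axis_length_1_mm",
    "principal_axis_length_2_mm",
    "principal_axis_length_3_mm",
    "convex_volume_mm3",
    "solidity",
    "surface_area_mm2",
)

FIRST_ORDER_NAMES: tuple[str, ...] = (
    "mean",
    "median",
    "std",
    "variance",
    "minimum",
    "maximum",
    "p5",
    "p25",
    "p75",
    "p95",
    "kurtosis",
    "skewness",
)


@dataclasses.dataclass(frozen=True)
class GLCMConfig:
    """Quantization depth, displacement distance and offset set for the GLCM.

    ``distance`` is the inter-voxel displacement in grid steps (default 8,
    the value found experimentally to discriminate the two genotypes);
    ``n_levels`` is the number of equal-width gray-level bins (default 32).
    """

    n_levels: int = 32
    distance: int = 8
    offsets: tuple[tuple[int, int, int], ...] = OFFSETS

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")
        if self.distance < 1:
            raise ValueError("distance must be >= 1")
        if len(self.offsets) != 13:
            raise ValueError("exactly 13 offsets required")
        seen = set()
        for off in self.offsets:
            key = tuple(off)
            anti = tuple(-c for c in off)
            if key in seen or anti in seen:
                raise ValueError(f"offsets must be pairwise non-antiparallel: {off}")
            seen.add(key)


@dataclasses.dataclass
class GLCMatrix:
    """Symmetric joint probability table over gray-level pairs.

    ``pair_count`` is the number of contributing (unordered) voxel pairs; when
    it is 0 the probability grid is all-zero and downstream measures emit NaN.
    """

    probabilities: np.ndarray
    pair_count: int

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=np.float64)
        if p.ndim != 2 or p.shape[0] != p.shape[1]:
            raise ValueError("probabilities must be a square matrix")
        if self.pair_count > 0 and not np.isclose(p.sum(), 1.0):
            raise ValueError("probabilities must sum to 1 when pair_count > 0")
        self.probabilities = p


def feature_names(config: GLCMConfig | None = None) -> list[str]:
    """The full ordered 195-name manifest, ``family.name[.offsetTag]``."""
    config = config or GLCMConfig()
    names = ["clinical.age", "clinical.gender"]
    names += [f"location.{r}" for r in ATLAS_REGION_NAMES]
    names += [f"morph.{m}" for m in MORPHOLOGY_NAMES]
    names += [f"firstorder.{m}" for m in FIRST_ORDER_NAMES]
    for measure_name in GLCM_MEASURES:
        for k in range(13):
            names.append(f"glcm.{measure_name}.d{config.distance}_o{k + 1:02d}")
    return names


#: The default 195-name order (GLCM distance 8).
FEATURE_NAMES: tuple[str, ...] = tuple(feature_names())


def extract_location_features(
    lesion: SegmentationMask, atlas: AtlasParcellation
) -> dict[str, float]:
    """Percent of lesion voxels falling in each of the 16 atlas regions.

    Percentages sum to 100 when every lesion voxel carries a region code and
    to less when part of the lesion lies on unlabeled (code 0) voxels.
    """
    if lesion.shape != atlas.shape:
        raise ValueError("lesion and atlas grids not aligned")
    total = lesion.count()
    if total == 0:
        raise ValueError("empty lesion mask")
    codes = atlas.labels[lesion.values]
    counts = np.bincount(codes, minlength=17)
    return {
        f"location.{name}": 100.0 * counts[code + 1] / total
        for code, name in enumerate(atlas.region_names)
    }


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labeled = measure.label(mask, connectivity=3)  # 26-connectivity
    n = labeled.max()
    if n <= 1:
        return mask
    warnings.warn("mask has multiple connected components; using the largest", stacklevel=3)
    sizes = np.bincount(labeled.ravel())[1:]
    return labeled == (int(np.argmax(sizes)) + 1)


def extract_morphology_features(
    lesion: SegmentationMask, spacing: tuple[float, float, float] | None = None
) -> dict[str, float]:
    """Nine 3D shape descriptors of the lesion in physical units.

    * volume: voxel count x voxel volume (mm^3)
    * equivalent diameter: diameter of the equal-volume sphere,
      ``(6 V / pi)^(1/3)``
    * extent: volume / axis-aligned bounding-box volume
    * principal axis lengths: ``2 sqrt(5 lambda_i)`` from the eigenvalues of
      the physical voxel-coordinate covariance (the axis lengths of the
      uniform ellipsoid with the same second moments), descending
    * convex volume: volume of the convex-hull image of the lesion voxels
    * solidity: volume / convex volume
    * surface area: area of the triangulated 0.5-level iso-surface (mm^2)

    Multi-component masks are reduced to the largest 26-connected component
    with a warning.
    """
    spacing = tuple(spacing if spacing is not None else lesion.spacing)
    mask = lesion.values
    if not mask.any():
        raise ValueError("empty lesion mask")
    mask = _largest_component(mask)

    voxel_vol = float(np.prod(spacing))
    n = int(mask.sum())
    volume = n * voxel_vol
    equiv_diameter = (6.0 * volume / np.pi) ** (1.0 / 3.0)

    coords = np.argwhere(mask)
    bbox = coords.max(axis=0) - coords.min(axis=0) + 1
    extent = n / float(np.prod(bbox))

    phys = coords * np.asarray(spacing)
    cov = np.cov(phys, rowvar=False, ddof=0) if n > 1 else np.zeros((3, 3))
    eigvals = np.sort(np.linalg.eigvalsh(np.atleast_2d(cov)))[::-1]
    axis_lengths = 2.0 * np.sqrt(5.0 * np.clip(eigvals, 0.0, None))

    # crop to the bounding box before hull/meshing; pad so the surface closes
    lo, hi = coords.min(axis=0), coords.max(axis=0) + 1
    crop = mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    hull = convex_hull_image(crop)
    convex_volume = float(hull.sum()) * voxel_vol
    solidity = volume / convex_volume

    padded = np.pad(crop, 1).astype(np.float64)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=spacing)
    surface_area = float(measure.mesh_surface_area(verts, faces))

    values = (
        volume,
        equiv_diameter,
        extent,
        float(axis_lengths[0]),
        float(axis_lengths[1]),
        float(axis_lengths[2]),
        convex_volume,
        solidity,
        surface_area,
    )
    return {f"morph.{name}": v for name, v in zip(MORPHOLOGY_NAMES, values)}


def extract_first_order_features(
    vol: ImageVolume, lesion: SegmentationMask
) -> dict[str, float]:
    """Histogram statistics of the in-lesion intensities.

    Variance and SD use the sample convention (divisor n-1); percentiles use
    linear interpolation between order statistics; skewness and kurtosis are
    the biased standardized moments, kurtosis non-excess (normal -> 3). A
    zero-variance lesion gets skewness and kurtosis 0 with a warning.
    """
    if vol.shape != lesion.shape:
        raise ValueError("volume and lesion grids not aligned")
    if lesion.count() == 0:
        raise ValueError("empty lesion mask")
    x = vol.values[lesion.values].astype(np.float64)
    if np.ptp(x) == 0.0 or x.size < 2:
        warnings.warn("zero-variance lesion: skewness/kurtosis reported as 0", stacklevel=2)
        skew = kurt = 0.0
    else:
        skew = float(stats.skew(x, bias=True))
        kurt = float(stats.kurtosis(x, fisher=False, bias=True))
    p5, p25, p75, p95 = np.percentile(x, [5, 25, 75, 95])
    values = (
        float(x.mean()),
        float(np.median(x)),
        float(x.std(ddof=1)) if x.size > 1 else 0.0,
        float(x.var(ddof=1)) if x.size > 1 else 0.0,
        float(x.min()),
        float(x.max()),
        float(p5),
        float(p25),
        float(p75),
        float(p95),
        kurt,
        skew,
    )
    return {f"firstorder.{name}": v for name, v in zip(FIRST_ORDER_NAMES, values)}


def quantize_lesion(
    vol: ImageVolume, lesion: SegmentationMask, n_levels: int = 32
) -> np.ndarray:
    """Map in-lesion intensities to gray levels 1..n_levels.

    Equal-width bins span the in-lesion min..max; a constant lesion maps
    wholly to level 1. Out-of-lesion voxels carry the sentinel 0. Because the
    bins are range-relative, scaling all intensities by a positive constant
    leaves the quantized grid (and so every GLCM feature) unchanged.
    """
    if vol.shape != lesion.shape:
        raise ValueError("volume and lesion grids not aligned")
    if lesion.count() == 0:
        raise ValueError("empty lesion mask")
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    out = np.zeros(vol.shape, dtype=np.int32)
    x = vol.values[lesion.values]
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        out[lesion.values] = 1
        return out
    levels = np.floor((x - lo) / (hi - lo) * n_levels).astype(np.int32) + 1
    np.clip(levels, 1, n_levels, out=levels)
    out[lesion.values] = levels
    return out


def compute_glcm(
    quantized: np.ndarray,
    offset: tuple[int, int, int],
    distance: int = 8,
    n_levels: int = 32,
) -> GLCMatrix:
    """Symmetric mask-restricted GLCM for one offset direction.

    Counts pairs ``(v, v + distance*offset)`` where both voxels lie inside
    the lesion (level > 0), accumulates them in both orders and normalizes to
    probabilities. A lesion thinner than the displacement yields
    ``pair_count`` 0 with an all-zero probability grid.
    """
    q = np.asarray(quantized)
    d = np.asarray(offset, dtype=int) * int(distance)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for ax in range(3):
        if d[ax] > 0:
            src[ax] = slice(0, q.shape[ax] - d[ax])
            dst[ax] = slice(d[ax], q.shape[ax])
        elif d[ax] < 0:
            src[ax] = slice(-d[ax], q.shape[ax])
            dst[ax] = slice(0, q.shape[ax] + d[ax])
    if any(abs(d[ax]) >= q.shape[ax] for ax in range(3)):
        return GLCMatrix(np.zeros((n_levels, n_levels)), 0)
    a = q[tuple(src)].ravel()
    b = q[tuple(dst)].ravel()
    valid = (a > 0) & (b > 0)
    pair_count = int(valid.sum())
    if pair_count == 0:
        return GLCMatrix(np.zeros((n_levels, n_levels)), 0)
    idx = (a[valid] - 1) * n_levels + (b[valid] - 1)
    counts = np.bincount(idx, minlength=n_levels * n_levels).reshape(n_levels, n_levels)
    counts = counts + counts.T  # each pair in both orders
    return GLCMatrix(counts / counts.sum(), pair_count)


def haralick_measures(g: GLCMatrix) -> dict[str, float]:
    """The 12 scalar texture summaries of a symmetric GLCM.

    With level indices i, j (1-based), marginal mean/SD mu, sigma:

    energy sum p^2; entropy -sum p log2 p; correlation
    sum (i-mu)(j-mu) p / sigma^2; contrast sum (i-j)^2 p; variance
    sum (i-mu)^2 p; sum_mean (1/2) sum (i+j) p; inertia = contrast's formula;
    cluster_shade sum (i+j-2mu)^3 p; cluster_tendency sum (i+j-2mu)^2 p;
    homogeneity sum p/(1+|i-j|); max_probability max p; inverse_variance
    sum_{i!=j} p/(i-j)^2.

    A degenerate GLCM (pair_count 0) yields NaN for every measure; a
    zero-variance marginal yields correlation 0.
    """
    if g.pair_count == 0:
        return {m: float("nan") for m in GLCM_MEASURES}
    p = g.probabilities
    n = p.shape[0]
    i = np.arange(1, n + 1, dtype=np.float64)[:, None]
    j = np.arange(1, n + 1, dtype=np.float64)[None, :]
    pi = p.sum(axis=1)  # marginal (symmetric: rows == cols)
    mu = float((np.arange(1, n + 1) * pi).sum())
    var_marg = float(((np.arange(1, n + 1) - mu) ** 2 * pi).sum())
    sigma = np.sqrt(var_marg)

    with np.errstate(divide="ignore", invalid="ignore"):
        nz = p > 0
        entropy = float(-(p[nz] * np.log2(p[nz])).sum())
    diff = i - j
    summ = i + j
    correlation = (
        float(((i - mu) * (j - mu) * p).sum() / (sigma * sigma)) if sigma > 0 else 0.0
    )
    contrast = float((diff**2 * p).sum())
    off_diag = np.broadcast_to(diff != 0, p.shape)
    diff_full = np.broadcast_to(diff, p.shape)
    inv_var = float((p[off_diag] / diff_full[off_diag] ** 2).sum())
    values = {
        "energy": float((p**2).sum()),
        "entropy": entropy,
        "correlation": correlation,
        "contrast": contrast,
        "variance": float(((i - mu) ** 2 * p).sum()),
        "sum_mean": float(0.5 * (summ * p).sum()),
        "inertia": contrast,
        "cluster_shade": float(((summ - 2 * mu) ** 3 * p).sum()),
        "cluster_tendency": float(((summ - 2 * mu) ** 2 * p).sum()),
        "homogeneity": float((p / (1.0 + np.abs(diff))).sum()),
        "max_probability": float(p.max()),
        "inverse_variance": inv_var,
    }
    return values


def extract_glcm_features(
    vol: ImageVolume,
    lesion: SegmentationMask,
    config: GLCMConfig | None = None,
) -> dict[str, float]:
    """All 156 GLCM features: 12 measures x 13 offsets."""
    config = config or GLCMConfig()
    q = quantize_lesion(vol, lesion, config.n_levels)
    per_offset = [
        haralick_measures(compute_glcm(q, off, config.distance, config.n_levels))
        for off in config.offsets
    ]
    out: dict[str, float] = {}
    for measure_name in GLCM_MEASURES:
        for k, vals in enumerate(per_offset):
            out[f"glcm.{measure_name}.d{config.distance}_o{k + 1:02d}"] = vals[measure_name]
    return out


def extract_all_features(case, config: GLCMConfig | None = None) -> dict[str, float]:
    """The full ordered 195-feature vector for one subject case.

    ``case`` provides ``volume``, ``lesion``, ``atlas``, ``age`` and
    ``gender`` (see :class:`radbiopsy.synthetic.SubjectCase`). Deterministic
    for fixed input; a failure in any stage is re-raised naming the family.
    """
    config = config or GLCMConfig()
    out: dict[str, float] = {
        "clinical.age": float(case.age),
        "clinical.gender": float(case.gender),
    }
    for family, fn in (
        ("location", lambda: extract_location_features(case.lesion, case.atlas)),
        ("morphology", lambda: extract_morphology_features(case.lesion)),
        ("first-order", lambda: extract_first_order_features(case.volume, case.lesion)),
        ("glcm", lambda: extract_glcm_features(case.volume, case.lesion, config)),
    ):
        try:
            out.update(fn())
        except Exception as exc:
            raise RuntimeError(f"feature family '{family}' failed: {exc}") from exc
    expected = feature_names(config)
    if list(out.keys()) != expected:  # defensive: fixed order contract
        raise RuntimeError("feature vector does not match the 195-name manifest")
    return out
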