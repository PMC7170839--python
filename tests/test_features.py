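import dataclasses

import numpy as np
import pytest

from radbiopsy.features import (
    FEATURE_NAMES,
    GLCMConfig,
    GLCMatrix,
    OFFSETS,
    compute_glcm,
    extract_all_features,
    extract_first_order_features,
    extract_location_features,
    extract_morphology_features,
    haralick_measures,
    quantize_lesion,
)
from radbiopsy.io import normalize_to_reference
from radbiopsy.synthetic import build_grid_atlas

from conftest import mask_from, random_lesion, volume_from


def brute_force_glcm(q, offset, distance, n_levels):
    """Independent oracle: enumerate every voxel pair with plain loops."""
    d = np.asarray(offset) * distance
    counts = np.zeros((n_levels, n_levels))
    pairs = 0
    nx, ny, nz = q.shape
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if q[x, y, z] == 0:
                    continue
                x2, y2, z2 = x + d[0], y + d[1], z + d[2]
                if not (0 <= x2 < nx and 0 <= y2 < ny and 0 <= z2 < nz):
                    continue
                if q[x2, y2, z2] == 0:
                    continue
                i, j = q[x, y, z] - 1, q[x2, y2, z2] - 1
                counts[i, j] += 1
                counts[j, i] += 1
                pairs += 1
    if pairs == 0:
        return np.zeros((n_levels, n_levels)), 0
    return counts / counts.sum(), pairs


class TestLocationFeatures:
    def test_containment_and_split(self):
        atlas = build_grid_atlas((32, 32, 32))
        # wholly inside one region: take voxels with a single code
        code = 3
        inside = np.argwhere(atlas.labels == code)[:30]
        mask = np.zeros((32, 32, 32), dtype=bool)
        mask[tuple(inside.T)] = True
        feats = extract_location_features(mask_from(mask), atlas)
        name = f"location.{atlas.region_names[code - 1]}"
        assert feats[name] == pytest.approx(100.0)
        assert sum(feats.values()) == pytest.approx(100.0)

    def test_partial_unlabeled(self):
        atlas = build_grid_atlas((32, 32, 32))
        mask = np.zeros((32, 32, 32), dtype=bool)
        labeled = np.argwhere(atlas.labels > 0)[:30]
        unlabeled = np.argwhere(atlas.labels == 0)[:10]
        mask[tuple(labeled.T)] = True
        mask[tuple(unlabeled.T)] = True
        feats = extract_location_features(mask_from(mask), atlas)
        assert sum(feats.values()) == pytest.approx(75.0)

    def test_empty_lesion_rejected(self):
        atlas = build_grid_atlas((32, 32, 32))
        with pytest.raises(ValueError, match="empty"):
            extract_location_features(mask_from(np.zeros((32, 32, 32))), atlas)


class TestMorphology:
    def test_cube_closed_forms(self):
        mask = np.zeros((20, 20, 20), dtype=bool)
        mask[5:15, 5:15, 5:15] = True
        f = extract_morphology_features(mask_from(mask))
        assert f["morph.volume_mm3"] == pytest.approx(1000.0)
        assert f["morph.extent"] == pytest.approx(1.0)
        assert f["morph.solidity"] == pytest.approx(1.0)
        assert f["morph.equiv_diameter_mm"] == pytest.approx((6000 / np.pi) ** (1 / 3), rel=1e-9)
        assert f["morph.convex_volume_mm3"] == pytest.approx(1000.0)

    def test_digital_ball_continuum_limits(self):
        r = 15
        n = 2 * r + 3
        c = n // 2
        g = np.ogrid[:n, :n, :n]
        mask = sum((gi - c) ** 2 for gi in g) <= r**2
        f = extract_morphology_features(mask_from(mask))
        for i in (1, 2, 3):
            assert f[f"morph.principal_axis_length_{i}_mm"] == pytest.approx(2 * r, rel=0.05)
        assert f["morph.surface_area_mm2"] == pytest.approx(4 * np.pi * r**2, rel=0.10)
        # ball volume within the digitization error of the continuum value
        assert f["morph.volume_mm3"] == pytest.approx(4 / 3 * np.pi * r**3, rel=0.05)

    def test_anisotropic_spacing_scales_volume(self):
        mask = np.zeros((12, 12, 12), dtype=bool)
        mask[2:10, 2:10, 2:10] = True
        f = extract_morphology_features(mask_from(mask, spacing=(0.9, 0.9, 1.6)))
        assert f["morph.volume_mm3"] == pytest.approx(8**3 * 0.9 * 0.9 * 1.6)

    def test_multi_component_uses_largest(self):
        mask = np.zeros((20, 20, 20), dtype=bool)
        mask[2:10, 2:10, 2:10] = True   # 512 voxels
        mask[15:17, 15:17, 15:17] = True  # 8 voxels, disconnected
        with pytest.warns(UserWarning, match="largest"):
            f = extract_morphology_features(mask_from(mask))
        assert f["morph.volume_mm3"] == pytest.approx(512.0)


class TestFirstOrder:
    def test_arithmetic_examples(self):
        vals = np.arange(1, 101, dtype=float)
        vol = volume_from(vals.reshape(10, 10, 1) * np.ones((1, 1, 1)))
        vol = volume_from(vals.reshape(100, 1, 1))
        mask = mask_from(np.ones((100, 1, 1)))
        f = extract_first_order_features(vol, mask)
        assert f["firstorder.mean"] == pytest.approx(50.5)
        assert f["firstorder.median"] == pytest.approx(50.5)
        assert f["firstorder.minimum"] == 1.0
        assert f["firstorder.maximum"] == 100.0

    def test_symmetric_skewness_zero(self):
        vol = volume_from(np.array([-5.0, 0.0, 5.0]).reshape(3, 1, 1))
        f = extract_first_order_features(vol, mask_from(np.ones((3, 1, 1))))
        assert f["firstorder.skewness"] == pytest.approx(0.0, abs=1e-12)

    def test_percentile_linear_interpolation(self):
        # brute-force oracle under the linear-interpolation convention:
        # sorted [0,0,0,0,10], rank position (n-1)*0.75 = 3 -> exactly 0
        vol = volume_from(np.array([0.0, 0, 0, 0, 10]).reshape(5, 1, 1))
        f = extract_first_order_features(vol, mask_from(np.ones((5, 1, 1))))
        assert f["firstorder.p75"] == pytest.approx(0.0)

    def test_normal_kurtosis_convention(self):
        rng = np.random.default_rng(0)
        vol = volume_from(rng.standard_normal((40, 40, 40)))
        f = extract_first_order_features(vol, mask_from(np.ones((40, 40, 40))))
        assert f["firstorder.kurtosis"] == pytest.approx(3.0, abs=0.1)

    def test_constant_lesion_moments_zero(self):
        vol = volume_from(np.full((4, 4, 4), 2.0))
        with pytest.warns(UserWarning, match="zero-variance"):
            f = extract_first_order_features(vol, mask_from(np.ones((4, 4, 4))))
        assert f["firstorder.skewness"] == 0.0
        assert f["firstorder.kurtosis"] == 0.0


class TestQuantization:
    def test_constant_lesion_level_one(self):
        vol = volume_from(np.full((5, 5, 5), 3.0))
        q = quantize_lesion(vol, mask_from(np.ones((5, 5, 5))), 8)
        assert set(np.unique(q)) == {1}

    def test_endpoints(self):
        vals = np.linspace(0, 1, 64).reshape(4, 4, 4)
        q = quantize_lesion(volume_from(vals), mask_from(np.ones((4, 4, 4))), 4)
        assert q.flat[0] == 1
        assert q.flat[-1] == 4

    def test_uniform_occupancy(self):
        rng = np.random.default_rng(9)
        shape = (50, 50, 40)  # 1e5 voxels
        vol = volume_from(rng.random(shape))
        q = quantize_lesion(vol, mask_from(np.ones(shape)), 8)
        shares = np.bincount(q.ravel(), minlength=9)[1:] / q.size
        np.testing.assert_allclose(shares, 0.125, atol=0.03)

    def test_sentinel_outside(self):
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[1:3, 1:3, 1:3] = True
        q = quantize_lesion(volume_from(np.random.default_rng(1).random((4, 4, 4))),
                            mask_from(mask), 4)
        assert (q[~mask] == 0).all()


class TestGLCM:
    def test_three_voxel_row(self):
        q = np.zeros((3, 1, 1), dtype=np.int32)
        q[:, 0, 0] = [1, 1, 2]
        g = compute_glcm(q, (1, 0, 0), distance=1, n_levels=2)
        assert g.pair_count == 2
        np.testing.assert_allclose(
            g.probabilities, [[0.5, 0.25], [0.25, 0.0]]
        )

    def test_constant_lesion_point_mass(self):
        q = np.ones((4, 4, 4), dtype=np.int32)
        g = compute_glcm(q, (0, 0, 1), distance=1, n_levels=3)
        assert g.probabilities[0, 0] == pytest.approx(1.0)

    def test_thin_lesion_no_pairs(self):
        q = np.zeros((20, 20, 20), dtype=np.int32)
        q[5, 5, 5:8] = 1  # 3 voxels long, displacement 8
        g = compute_glcm(q, (0, 0, 1), distance=8, n_levels=4)
        assert g.pair_count == 0
        assert g.probabilities.sum() == 0.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_oracle_equivalence_all_offsets_distances(self, seed):
        """Mask-restricted symmetric GLCM equals exhaustive pair enumeration."""
        rng = np.random.default_rng(seed)
        q = random_lesion(rng, shape=(12, 11, 12), density=0.55, n_levels=4)
        for offset in OFFSETS:
            for distance in range(1, 9):
                g = compute_glcm(q, offset, distance, n_levels=4)
                p_ref, pairs_ref = brute_force_glcm(q, offset, distance, 4)
                assert g.pair_count == pairs_ref
                np.testing.assert_array_equal(g.probabilities * max(2 * pairs_ref, 1),
                                              p_ref * max(2 * pairs_ref, 1))

    def test_rotation_permutes_offset_features(self, default_case):
        """A 90-degree rotation about z permutes the 13 per-offset values."""
        norm = normalize_to_reference(default_case.volume, default_case.reference)
        q = quantize_lesion(norm, default_case.lesion, 16)
        q_rot = np.rot90(q, k=1, axes=(0, 1))  # (x,y,z) -> (-y,x,z) voxelwise

        def canonical(vec):
            vec = tuple(vec)
            return vec if vec in OFFSETS else tuple(-c for c in vec)

        for k, off in enumerate(OFFSETS):
            rotated = canonical((-off[1], off[0], off[2]))
            a = haralick_measures(compute_glcm(q, off, 4, 16))
            b = haralick_measures(compute_glcm(q_rot, rotated, 4, 16))
            for name in a:
                assert a[name] == pytest.approx(b[name], abs=1e-9), (off, name)

    def test_intensity_scaling_invariance(self, default_case):
        norm = normalize_to_reference(default_case.volume, default_case.reference)
        scaled = volume_from(norm.values * 37.5, spacing=norm.spacing)
        cfg = GLCMConfig()
        q1 = quantize_lesion(norm, default_case.lesion, cfg.n_levels)
        q2 = quantize_lesion(scaled, default_case.lesion, cfg.n_levels)
        np.testing.assert_array_equal(q1, q2)


class TestHaralick:
    def test_point_mass(self):
        p = np.zeros((4, 4))
        p[0, 0] = 1.0
        h = haralick_measures(GLCMatrix(p, 10))
        assert h["energy"] == 1.0
        assert h["entropy"] == 0.0
        assert h["contrast"] == 0.0
        assert h["max_probability"] == 1.0

    def test_uniform_distribution(self):
        p = np.full((4, 4), 1 / 16)
        h = haralick_measures(GLCMatrix(p, 100))
        assert h["energy"] == pytest.approx(1 / 16)
        assert h["entropy"] == pytest.approx(4.0)

    def test_hand_summation_oracle(self):
        # p over levels {1,2}: (1,1)=0.5, (1,2)=0.25, (2,1)=0.25
        p = np.array([[0.5, 0.25], [0.25, 0.0]])
        h = haralick_measures(GLCMatrix(p, 2))
        # hand sums: contrast = (1-2)^2*0.25*2 = 0.5; mu = 1.25
        assert h["contrast"] == pytest.approx(0.5)
        assert h["inertia"] == pytest.approx(0.5)
        assert h["max_probability"] == pytest.approx(0.5)
        assert h["sum_mean"] == pytest.approx(0.5 * (2 * 0.5 + 3 * 0.25 + 3 * 0.25))
        assert h["variance"] == pytest.approx((1 - 1.25) ** 2 * 0.75 + (2 - 1.25) ** 2 * 0.25)
        assert h["homogeneity"] == pytest.approx(0.5 + 0.25 / 2 + 0.25 / 2)
        assert h["inverse_variance"] == pytest.approx(0.5)
        assert h["energy"] == pytest.approx(0.25 + 0.0625 + 0.0625)

    def test_degenerate_glcm_emits_nan(self):
        h = haralick_measures(GLCMatrix(np.zeros((4, 4)), 0))
        assert all(np.isnan(v) for v in h.values())


class TestFullVector:
    def test_exactly_195_named_features(self, default_case):
        norm = normalize_to_reference(default_case.volume, default_case.reference)
        case = dataclasses.replace(default_case, volume=norm)
        feats = extract_all_features(case)
        assert list(feats.keys()) == list(FEATURE_NAMES)
        assert len(feats) == 195
        families = {}
        for name in feats:
            families.setdefault(name.split(".")[0], []).append(name)
        assert len(families["clinical"]) == 2
        assert len(families["location"]) == 16
        assert len(families["morph"]) == 9
        assert len(families["firstorder"]) == 12
        assert len(families["glcm"]) == 156

    def test_determinism(self, default_case):
        a = extract_all_features(default_case)
        b = extract_all_features(default_case)
        assert a == b

    def test_name_manifest_file_matches(self):
        import importlib.resources as res

        text = (res.files("radbiopsy") / "data" / "feature_names.txt").read_text()
        names = [l for l in text.splitlines() if l and not l.startswith("#")]
        assert names == list(FEATURE_NAMES)
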