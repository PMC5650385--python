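"""Texture matrices, feature formulas, the catalog, normalization, and the
volume-correlation audit — each checked against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from radprog.features import (
    DIRECTIONS_3D_13,
    FIRSTORDER_FEATURE_NAMES,
    GLCM,
    GLCM_FEATURE_NAMES,
    GLRLM,
    GLRLM_FEATURE_NAMES,
    SHAPE_FEATURE_NAMES,
    FeatureCatalog,
    compute_glcm,
    compute_glrlm,
    extract_all,
    firstorder_features,
    glcm_features,
    glrlm_features,
    shape_features,
    volume_correlation_audit,
    zscore_normalize,
)
from radprog.imaging import DiscretizedROI, ImageVolume, ROIMask


def _roi(levels, n_bins):
    return DiscretizedROI(np.asarray(levels, dtype=np.int64), n_bins)


# ---------------------------------------------------------------- GLCM


def brute_force_glcm(levels: np.ndarray, ng: int, directions, distance=1) -> np.ndarray:
    counts = np.zeros((ng, ng))
    shape = levels.shape
    for dx, dy, dz in directions:
        off = np.array([dx, dy, dz]) * distance
        for idx in np.ndindex(*shape):
            jdx = tuple(np.array(idx) + off)
            if all(0 <= j < n for j, n in zip(jdx, shape)):
                a, b = levels[idx], levels[jdx]
                if a > 0 and b > 0:
                    counts[a - 1, b - 1] += 1
                    counts[b - 1, a - 1] += 1
    return counts / counts.sum()


class TestGLCM:
    def test_single_pair_symmetrized(self):
        d = _roi([[[1, 2]]], 2)
        m = compute_glcm(d, directions=((0, 0, 1),))
        np.testing.assert_allclose(m.p, [[0.0, 0.5], [0.5, 0.0]])

    def test_uniform_level_all_mass_on_diagonal(self):
        d = _roi(np.ones((3, 3, 3)), 4)
        m = compute_glcm(d)
        assert m.p[0, 0] == pytest.approx(1.0)

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(10)
        levels = rng.integers(0, 5, size=(4, 4, 4))
        levels[1, 1, 1] = 1  # guarantee non-empty
        d = _roi(levels, 4)
        m = compute_glcm(d)
        np.testing.assert_allclose(
            m.p, brute_force_glcm(levels, 4, DIRECTIONS_3D_13), atol=1e-12
        )

    def test_sums_to_one_and_symmetric(self):
        rng = np.random.default_rng(11)
        for trial in range(5):
            levels = rng.integers(0, 7, size=(5, 4, 3))
            if (levels > 0).sum() < 2:
                continue
            m = compute_glcm(_roi(levels, 6))
            assert m.p.sum() == pytest.approx(1.0, abs=1e-9)
            np.testing.assert_allclose(m.p, m.p.T, atol=1e-12)


class TestGLCMFeatures:
    def test_full_feature_set_names(self):
        m = GLCM(np.full((3, 3), 1 / 9), 3)
        feats = glcm_features(m)
        assert set(feats) == set(GLCM_FEATURE_NAMES)
        assert len(feats) == 24

    def test_diagonal_matrix_homogeneity_one(self):
        m = GLCM(np.eye(4) / 4, 4)
        assert glcm_features(m)["homogeneity1"] == pytest.approx(1.0)

    def test_independent_matrix_imc1_zero(self):
        px = np.array([0.2, 0.3, 0.5])
        m = GLCM(np.outer(px, px), 3)
        assert glcm_features(m)["imc1"] == pytest.approx(0.0, abs=1e-12)

    def test_two_level_uniform_hand_values(self):
        m = GLCM(np.full((2, 2), 0.25), 2)
        feats = glcm_features(m)
        assert feats["correlation"] == pytest.approx(0.0, abs=1e-12)
        assert feats["inverse_variance"] == pytest.approx(0.5)
        assert feats["contrast"] == pytest.approx(0.5)
        assert feats["energy"] == pytest.approx(0.25)

    def test_degenerate_marginals_convention(self):
        m = GLCM(np.array([[1.0, 0.0], [0.0, 0.0]]), 2)
        feats = glcm_features(m)
        assert feats["correlation"] == 1.0
        assert feats["imc1"] == 0.0


# ---------------------------------------------------------------- GLRLM


def brute_force_glrlm(levels: np.ndarray, ng: int, directions):
    """Walk every scan line of every direction and enumerate maximal runs."""
    shape = levels.shape
    runs = {}
    for d in directions:
        d = np.asarray(d)
        starts = [
            np.array(idx)
            for idx in np.ndindex(*shape)
            if not all(0 <= c < n for c, n in zip(np.array(idx) - d, shape))
        ]
        for s in starts:
            pos = s.copy()
            current, length = 0, 0
            while all(0 <= c < n for c, n in zip(pos, shape)):
                lv = levels[tuple(pos)]
                if lv == current:
                    length += 1
                else:
                    if current > 0:
                        runs[(current, length)] = runs.get((current, length), 0) + 1
                    current, length = lv, 1
                pos += d
            if current > 0:
                runs[(current, length)] = runs.get((current, length), 0) + 1
    rmax = max((l for _, l in runs), default=1)
    r = np.zeros((ng, rmax))
    for (lv, ln), c in runs.items():
        r[lv - 1, ln - 1] = c
    return r


class TestGLRLM:
    def test_single_line_one_run(self):
        d = _roi([[[1, 1, 1]]], 2)
        m = compute_glrlm(d, directions=((0, 0, 1),))
        assert m.r[0, 2] == 1
        assert m.n_runs == 1

    def test_checkerboard_all_runs_length_one(self):
        board = np.indices((4, 4, 1)).sum(axis=0) % 2 + 1
        m = compute_glrlm(_roi(board, 2), directions=((1, 0, 0), (0, 1, 0)))
        assert m.r.shape[1] == 1  # no run longer than 1
        assert m.n_runs == 32

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(12)
        levels = rng.integers(0, 4, size=(4, 4, 4))
        levels[0, 0, 0] = 1
        m = compute_glrlm(_roi(levels, 3))
        expect = brute_force_glrlm(levels, 3, DIRECTIONS_3D_13)
        np.testing.assert_allclose(m.r, expect)


class TestGLRLMFeatures:
    def test_full_feature_set_names(self):
        m = GLRLM(np.array([[1.0]]), 1, 1, 1)
        feats = glrlm_features(m)
        assert set(feats) == set(GLRLM_FEATURE_NAMES)
        assert len(feats) == 11

    def test_srlgle_single_short_low_run(self):
        m = GLRLM(np.array([[1.0]]), 1, 1, 1)
        assert glrlm_features(m)["srlgle"] == pytest.approx(1.0)

    def test_srlgle_level2_length2(self):
        r = np.zeros((2, 2))
        r[1, 1] = 1.0
        m = GLRLM(r, 2, 2, 1)
        assert glrlm_features(m)["srlgle"] == pytest.approx(1.0 / 16.0)

    def test_matches_direct_summation(self):
        rng = np.random.default_rng(13)
        r = rng.integers(0, 5, size=(3, 4)).astype(float)
        r[0, 0] += 1
        m = GLRLM(r, 3, 40, 13)
        feats = glrlm_features(m)
        nr = r.sum()
        srlgle = sum(
            r[i, j] / ((i + 1) ** 2 * (j + 1) ** 2)
            for i in range(3)
            for j in range(4)
        ) / nr
        lre = sum(r[i, j] * (j + 1) ** 2 for i in range(3) for j in range(4)) / nr
        assert feats["srlgle"] == pytest.approx(srlgle)
        assert feats["lre"] == pytest.approx(lre)
        assert feats["rp"] == pytest.approx(nr / (40 * 13))


# ---------------------------------------------------------------- first-order & shape


class TestFirstOrder:
    def test_constant_region(self):
        vol = ImageVolume(np.full((3, 3, 3), 4.2))
        mask = ROIMask(np.ones((3, 3, 3), dtype=bool))
        f = firstorder_features(vol, mask)
        for name in ("mean", "median", "min", "max"):
            assert f[name] == pytest.approx(4.2)
        assert f["variance"] == 0.0
        assert f["skewness"] == 0.0
        assert f["kurtosis"] == 0.0

    def test_small_hand_example(self):
        vals = np.zeros((1, 1, 4))
        vals[0, 0, :] = [1, 2, 3, 4]
        vol = ImageVolume(vals)
        mask = ROIMask(np.ones((1, 1, 4), dtype=bool))
        f = firstorder_features(vol, mask)
        assert f["mean"] == pytest.approx(2.5)
        assert f["range"] == pytest.approx(3.0)

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(14)
        vals = rng.normal(size=(4, 4, 4)) * 3 + 10
        mask_arr = rng.random((4, 4, 4)) > 0.25
        mask_arr[0, 0, 0] = True
        spacing = (0.5, 0.5, 2.0)
        f = firstorder_features(ImageVolume(vals, spacing), ROIMask(mask_arr, spacing))
        v = vals[mask_arr]
        n = v.size
        mu = v.sum() / n
        var = ((v - mu) ** 2).sum() / n
        sd = var**0.5
        hist, _ = np.histogram(v, bins=32)
        pk = hist / n
        pk = pk[pk > 0]
        p10, p25, p75, p90 = np.percentile(v, [10, 25, 75, 90])
        rob = v[(v >= p10) & (v <= p90)]
        oracle = {
            "mean": mu,
            "median": float(np.median(v)),
            "min": v.min(),
            "max": v.max(),
            "range": v.max() - v.min(),
            "variance": var,
            "std": sd,
            "skewness": (((v - mu) / sd) ** 3).sum() / n,
            "kurtosis": (((v - mu) / sd) ** 4).sum() / n,
            "energy": (v**2).sum(),
            "entropy": float(-(pk * np.log2(pk)).sum()),
            "uniformity": float((pk**2).sum()),
            "rms": ((v**2).sum() / n) ** 0.5,
            "mad": np.abs(v - mu).mean(),
            "p10": p10,
            "p90": p90,
            "iqr": p75 - p25,
            "robust_mad": np.abs(rob - rob.mean()).mean(),
            "total_energy": 0.5 * 0.5 * 2.0 * (v**2).sum(),
        }
        assert set(f) == set(FIRSTORDER_FEATURE_NAMES)
        for name, expect in oracle.items():
            assert f[name] == pytest.approx(expect, rel=1e-9), name


class TestShape:
    def test_single_voxel_volume(self):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[2, 2, 2] = True
        f = shape_features(ROIMask(mask, (1, 1, 1)))
        assert f["volume_mm3"] == pytest.approx(1.0)
        assert f["max_3d_diameter_mm"] == 0.0

    def test_cube_volume_with_spacing(self):
        mask = np.zeros((6, 6, 6), dtype=bool)
        mask[2:4, 2:4, 2:4] = True
        f = shape_features(ROIMask(mask, (1, 1, 1)))
        assert f["volume_mm3"] == pytest.approx(8.0)
        f2 = shape_features(ROIMask(mask, (2, 1, 1)))
        assert f2["volume_mm3"] == pytest.approx(16.0)
        assert set(f) == set(SHAPE_FEATURE_NAMES)

    def test_digitized_ball_nearly_spherical(self):
        r = 10
        n = 2 * r + 5
        g = np.indices((n, n, n)) - n // 2
        mask = (g**2).sum(axis=0) <= r**2
        f = shape_features(ROIMask(mask, (1, 1, 1)))
        assert 0.9 <= f["sphericity"] <= 1.0
        assert f["max_3d_diameter_mm"] == pytest.approx(2 * r, rel=0.05)


# ---------------------------------------------------------------- catalog & extraction


class TestCatalog:
    def test_counts(self, catalog):
        assert len(catalog) == 970
        per_seq = sum(1 for s, *_ in catalog.entries if s == "T2w")
        assert per_seq == 485
        assert 11 + 19 + 35 * 13 == 485

    def test_keys_unique_and_stable(self, catalog):
        assert len(set(catalog.keys)) == 970
        assert catalog.checksum() == FeatureCatalog().checksum()

    def test_parse_key_round_trip(self, catalog):
        assert catalog.parse_key("T2w_3_GLCM_homogeneity1") == (
            "T2w", 3, "GLCM", "homogeneity1"
        )
        with pytest.raises(KeyError):
            catalog.parse_key("T2w_99_GLCM_homogeneity1")


class TestExtractAll:
    def test_full_vector_finite(self, default_patient, catalog):
        volumes, mask = default_patient
        vec = extract_all(volumes, mask, catalog)
        assert len(vec) == 970
        assert np.isfinite(vec.to_numpy()).all()
        assert sum(k.startswith("T2w_") for k in vec.index) == 485

    def test_missing_sequence_reported(self, default_patient, catalog):
        volumes, mask = default_patient
        with pytest.raises(ValueError, match="CET1w"):
            extract_all({"T2w": volumes["T2w"]}, mask, catalog)

    def test_mask_locality_of_unfiltered_features(self, default_patient, catalog):
        # Shape, first-order, and original-variant texture features depend
        # only on in-mask voxels.  (Filtered variants are computed from the
        # whole volume, so tissue just outside the ROI contributes to the
        # band-pass response at the boundary by design.)
        volumes, mask = default_patient
        vec = extract_all(volumes, mask, catalog)
        tampered = {}
        for seq, vol in volumes.items():
            vals = vol.values.copy()
            vals[~mask.values] += 500.0
            tampered[seq] = ImageVolume(vals, vol.spacing_mm, seq)
        vec2 = extract_all(tampered, mask, catalog)
        local = [k for k in vec.index if "_1_" in k]
        assert len(local) == 130  # (11 shape + 19 firstorder + 35 texture) x 2
        pd.testing.assert_series_equal(vec[local], vec2[local])

    def test_texture_matrices_never_bridge_mask_gaps(self):
        # two in-mask islands separated by an out-of-mask gap: no pair and
        # no run may cross the gap
        levels = np.array([[[1, 1, 0, 2, 2]]])
        d = DiscretizedROI(levels, 2)
        m = compute_glcm(d, directions=((0, 0, 1),))
        np.testing.assert_allclose(m.p, [[0.5, 0.0], [0.0, 0.5]])
        r = compute_glrlm(d, directions=((0, 0, 1),))
        assert r.r[0, 1] == 1 and r.r[1, 1] == 1
        assert r.n_runs == 2

    def test_bit_identical_across_runs(self, default_patient, catalog):
        volumes, mask = default_patient
        a = extract_all(volumes, mask, catalog)
        b = extract_all(volumes, mask, catalog)
        assert (a.to_numpy() == b.to_numpy()).all()


# ---------------------------------------------------------------- normalization & audit


class TestZScore:
    def test_discovery_mean_zero_sd_one(self):
        rng = np.random.default_rng(15)
        table = pd.DataFrame(rng.normal(5, 3, size=(40, 6)), columns=list("abcdef"))
        out, stats = zscore_normalize(table)
        np.testing.assert_allclose(out.mean(), 0.0, atol=1e-9)
        np.testing.assert_allclose(out.std(ddof=0), 1.0, atol=1e-9)
        assert stats.zero_variance == []

    def test_frozen_stats_applied_to_validation(self):
        rng = np.random.default_rng(16)
        disc = pd.DataFrame(rng.normal(0, 1, size=(30, 3)), columns=list("abc"))
        val = pd.DataFrame(rng.normal(2, 1, size=(20, 3)), columns=list("abc"))
        _, stats = zscore_normalize(disc)
        out, used = zscore_normalize(val, stats)
        assert used is stats
        assert (out.mean().abs() > 0.5).all()  # shifted cohort stays shifted

    def test_population_sd_convention(self):
        table = pd.DataFrame({"x": [2.0, 4.0, 6.0]})
        out, _ = zscore_normalize(table)
        np.testing.assert_allclose(
            out["x"].to_numpy(), [-1.224744871, 0.0, 1.224744871], atol=1e-8
        )

    def test_zero_variance_flagged_not_dropped(self):
        table = pd.DataFrame({"x": [1.0, 2.0, 3.0], "const": [5.0, 5.0, 5.0]})
        out, stats = zscore_normalize(table)
        assert stats.zero_variance == ["const"]
        assert "const" in out.columns
        np.testing.assert_allclose(out["const"], 0.0)


class TestVolumeCorrelationAudit:
    def test_identity_feature_very_high(self):
        vol = np.arange(10, dtype=float) + 1
        table = pd.DataFrame({"T2w_1_shape_volume_mm3": vol})
        per_feature, counts = volume_correlation_audit(table, vol)
        row = per_feature.iloc[0]
        assert row["rho"] == pytest.approx(1.0)
        assert row["category"] == "very high"
        assert counts.loc["T2w", "very high"] == 1

    @pytest.mark.parametrize(
        "ranks,category",
        [
            ((1, 2, 3, 5, 4), "very high"),  # rho = 0.9
            ((2, 1, 3, 5, 4), "high"),  # rho = 0.8
            ((2, 4, 1, 3, 5), "moderate"),  # rho = 0.5
        ],
    )
    def test_category_breakpoints(self, ranks, category):
        vol = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        table = pd.DataFrame({"T2w_1_GLCM_contrast": np.array(ranks, dtype=float)})
        per_feature, _ = volume_correlation_audit(table, vol)
        assert per_feature.iloc[0]["category"] == category

    def test_independent_feature_little_correlation(self):
        rng = np.random.default_rng(17)
        vol = rng.random(200)
        table = pd.DataFrame({"T2w_1_GLCM_contrast": rng.random(200)})
        per_feature, _ = volume_correlation_audit(table, vol)
        assert abs(per_feature.iloc[0]["rho"]) < 0.25

    def test_constant_feature_flagged(self):
        vol = np.arange(5, dtype=float)
        table = pd.DataFrame({"T2w_1_GLCM_contrast": np.ones(5)})
        per_feature, _ = volume_correlation_audit(table, vol)
        row = per_feature.iloc[0]
        assert row["constant"]
        assert row["category"] == "little if any"
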