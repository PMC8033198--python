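import numpy as np
import pytest

from ceusomics.features import (
    compute_glcm,
    compute_glrlm,
    default_catalogue,
    extract_features,
    extract_image_features,
    first_order_features,
    glcm_features,
    glrlm_features,
    gradient_features,
    shape_features,
)
from ceusomics.features.catalogue import build_catalogue
from ceusomics.features.glcm import DegenerateGLCMError, GLCMatrix
from ceusomics.features.shape import ShapeError
from ceusomics.imaging import QuantizedROI, quantize
from oracles import brute_glcm, brute_glrlm


def make_q(levels_arr, mask=None, levels=None):
    levels_arr = np.asarray(levels_arr, dtype=np.int64)
    if mask is None:
        mask = levels_arr > 0
    if levels is None:
        levels = int(levels_arr.max())
    return QuantizedROI(levels=levels, quantized=levels_arr, mask=np.asarray(mask, bool))


class TestCatalogue:
    def test_total_and_family_counts(self):
        cat = default_catalogue()
        assert len(cat) == 1044
        assert cat.family_counts() == {
            "histogram": 42,
            "form_factor": 12,
            "textural": 18,
            "glcm": 780,
            "rlm": 192,
        }

    def test_unique_names(self):
        names = default_catalogue().names()
        assert len(names) == len(set(names))

    def test_custom_composition(self):
        cat = build_catalogue(levels=(16,), distances=(1, 2))
        # 42 + 12 + 18 + 13*2*6 + 16*6
        assert len(cat) == 72 + 156 + 96


class TestFirstOrder:
    def test_constant_roi(self):
        f = first_order_features(np.full((5, 5), 7.0), np.ones((5, 5), bool))
        assert f["hist_mean"] == 7
        assert f["hist_variance"] == 0
        assert f["hist_entropy"] == 0
        assert f["hist_uniformity"] == 1
        assert f["hist_cv"] == 0

    def test_hand_values_1234(self):
        # 16 pixels: {1,2,3,4} each four times; population moments by hand
        img = np.repeat([1.0, 2.0, 3.0, 4.0], 4).reshape(4, 4)
        f = first_order_features(img, np.ones((4, 4), bool))
        assert f["hist_mean"] == pytest.approx(2.5)
        assert f["hist_variance"] == pytest.approx(1.25)
        # sorted x: P25 position 0.25*15 = 3.75 -> between 1 and 2 -> 1.75
        assert f["hist_p25"] == pytest.approx(1.75)
        assert f["hist_total"] == pytest.approx(40.0)

    def test_symmetric_sample_zero_skew(self):
        img = np.repeat([1.0, 2.0, 3.0], 8).reshape(4, 6)
        f = first_order_features(img, np.ones((4, 6), bool))
        assert f["hist_skewness"] == pytest.approx(0.0, abs=1e-12)

    def test_too_small_mask_rejected(self):
        with pytest.raises(ValueError):
            first_order_features(np.ones((3, 3)), np.ones((3, 3), bool))


class TestShape:
    def test_filled_square(self):
        mask = np.zeros((14, 14), bool)
        mask[2:12, 2:12] = True
        f = shape_features(mask)
        assert f["shape_area"] == 100
        assert f["shape_extent"] == pytest.approx(1.0)
        assert f["shape_solidity"] == pytest.approx(1.0)

    def test_disk_circularity(self):
        yy, xx = np.mgrid[0:50, 0:50]
        mask = (xx - 25) ** 2 + (yy - 25) ** 2 < 20.5**2
        f = shape_features(mask)
        assert 0.95 <= f["shape_circularity"] <= 1.05

    def test_rectangle_elongation(self):
        mask = np.zeros((20, 50), bool)
        mask[5:15, 5:45] = True  # 10 x 40
        f = shape_features(mask)
        assert f["shape_elongation"] == pytest.approx(4.0, rel=0.1)

    def test_spacing_scales_lengths(self):
        mask = np.zeros((14, 14), bool)
        mask[2:12, 2:12] = True
        f1 = shape_features(mask)
        f2 = shape_features(mask, spacing=0.5)
        assert f2["shape_area"] == pytest.approx(f1["shape_area"] * 0.25)
        assert f2["shape_perimeter"] == pytest.approx(f1["shape_perimeter"] * 0.5)
        assert f2["shape_circularity"] == pytest.approx(f1["shape_circularity"])

    def test_multiple_components_rejected(self):
        mask = np.zeros((10, 10), bool)
        mask[1:4, 1:4] = True
        mask[6:9, 6:9] = True
        with pytest.raises(ShapeError, match="largest component"):
            shape_features(mask)


class TestGradient:
    def test_constant_image_zero(self):
        f = gradient_features(np.full((10, 10), 3.0), np.ones((10, 10), bool))
        assert f["grad_mean"] == 0
        assert f["grad_maximum"] == 0

    def test_step_edge_height(self):
        h = 13.0
        img = np.zeros((12, 12))
        img[:, 6:] = h
        f = gradient_features(img, np.ones((12, 12), bool))
        # normalized 3x3 Sobel response of an ideal step is exactly h
        assert f["grad_maximum"] == pytest.approx(h)

    def test_rotation_invariance_of_magnitude_stats(self, arterial_image):
        img = arterial_image.pixels.astype(float)
        mask = arterial_image.mask
        f1 = gradient_features(img, mask)
        f2 = gradient_features(np.rot90(img), np.rot90(mask))
        for k in f1:
            assert f1[k] == pytest.approx(f2[k], rel=1e-9), k

    def test_mask_vanishing_after_erosion(self):
        mask = np.zeros((10, 10), bool)
        mask[4, 1:9] = True  # one-pixel line erodes away
        mask[5, 1:9] = True
        with pytest.raises(ValueError):
            gradient_features(np.ones((10, 10)), mask)


class TestGLCM:
    def test_hand_enumerated_2x2(self):
        q = make_q([[1, 1], [1, 2]], mask=np.ones((2, 2), bool), levels=2)
        m = compute_glcm(q, 1, 0)
        assert np.allclose(m.probabilities, [[0.5, 0.25], [0.25, 0.0]])
        f = glcm_features(m)
        assert f["contrast"] == pytest.approx(0.5)
        assert f["energy"] == pytest.approx(0.375)
        assert f["max_probability"] == pytest.approx(0.5)

    def test_constant_roi_single_entry(self):
        q = make_q(np.ones((4, 4), int), levels=8)
        m = compute_glcm(q, 1, 0)
        assert m.probabilities[0, 0] == 1.0
        f = glcm_features(m)
        assert f["contrast"] == 0
        assert f["energy"] == 1
        assert f["entropy"] == 0
        assert f["correlation"] == 1.0

    def test_uniform_matrix_entropy(self):
        ng = 8
        m = GLCMatrix(np.full((ng, ng), 1 / ng**2), distance=1, angle=0, levels=ng)
        assert glcm_features(m)["entropy"] == pytest.approx(2 * np.log2(ng))

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        mask = rng.random((9, 9)) < 0.8
        q = make_q(np.where(mask, rng.integers(1, 6, (9, 9)), 0), mask=mask, levels=5)
        for angle in (0, 45, 90, 135):
            m = compute_glcm(q, 2, angle)
            assert np.allclose(m.probabilities, m.probabilities.T)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(8)
        for trial in range(10):
            arr = rng.integers(1, 7, (10, 12))
            mask = rng.random((10, 12)) < 0.75
            q = make_q(np.where(mask, arr, 0), mask=mask, levels=6)
            for angle in (0, 45, 90, 135):
                for d in (1, 2):
                    m = compute_glcm(q, d, angle)
                    assert np.allclose(m.probabilities, brute_glcm(np.where(mask, arr, 0), mask, 6, d, angle), atol=1e-12)

    def test_rotation_permutes_angles(self):
        rng = np.random.default_rng(9)
        arr = rng.integers(1, 5, (8, 8))
        mask = np.ones((8, 8), bool)
        q = make_q(arr, mask=mask, levels=4)
        qr = make_q(np.rot90(arr).copy(), mask=mask, levels=4)
        mapping = {0: 90, 45: 135, 90: 0, 135: 45}
        for a, b in mapping.items():
            fa = glcm_features(compute_glcm(q, 1, a))
            fb = glcm_features(compute_glcm(qr, 1, b))
            for k in fa:
                assert fa[k] == pytest.approx(fb[k], abs=1e-12), (a, k)

    def test_degenerate_offset_rejected(self):
        mask = np.zeros((6, 6), bool)
        mask[0, ::2] = True  # no horizontally adjacent in-mask pairs
        q = make_q(np.where(mask, 1, 0), mask=mask, levels=2)
        with pytest.raises(DegenerateGLCMError):
            compute_glcm(q, 1, 90)


class TestGLRLM:
    def test_hand_run_scan(self):
        q = make_q([[1, 1, 2, 2, 2]], levels=2)
        r = compute_glrlm(q, 0)
        assert r.counts[0, 1] == 1  # level 1, length 2
        assert r.counts[1, 2] == 1  # level 2, length 3
        assert r.counts.sum() == 2
        f = glrlm_features(r)
        assert f["rp"] == pytest.approx(0.4)
        assert f["sre"] == pytest.approx((1 / 4 + 1 / 9) / 2)

    def test_single_run_closed_form(self):
        n = 9
        q = make_q([[2] * n], levels=2)
        f = glrlm_features(compute_glrlm(q, 0))
        assert f["sre"] == pytest.approx(1 / n**2)
        assert f["lre"] == pytest.approx(n**2)
        assert f["rp"] == pytest.approx(1 / n)

    def test_checkerboard_all_unit_runs(self):
        yy, xx = np.mgrid[0:6, 0:6]
        q = make_q(((xx + yy) % 2) + 1, mask=np.ones((6, 6), bool), levels=2)
        r = compute_glrlm(q, 0)
        assert r.counts.shape[1] == 1
        assert r.counts.sum() == 36
        f = glrlm_features(r)
        assert f["sre"] == 1 and f["lre"] == 1 and f["rp"] == 1

    def test_pixel_count_invariant_and_brute_force(self):
        rng = np.random.default_rng(4)
        for trial in range(10):
            arr = rng.integers(1, 5, (9, 11))
            mask = rng.random((9, 11)) < 0.7
            q = make_q(np.where(mask, arr, 0), mask=mask, levels=4)
            for direction in (0, 45, 90, 135):
                r = compute_glrlm(q, direction)
                lengths = np.arange(1, r.counts.shape[1] + 1)
                assert (r.counts * lengths).sum() == mask.sum()
                got = {
                    (i + 1, j + 1): int(r.counts[i, j])
                    for i in range(r.counts.shape[0])
                    for j in range(r.counts.shape[1])
                    if r.counts[i, j]
                }
                assert got == brute_glrlm(arr, mask, 4, direction)


def naive_glcm_feature_oracle(p: np.ndarray) -> dict:
    """Feature formulas re-evaluated with explicit loops (reference path)."""
    ng = p.shape[0]
    out = dict.fromkeys(
        ["energy", "contrast", "entropy", "homogeneity", "dissimilarity"], 0.0
    )
    mu = sum((i + 1) * p[i, :].sum() for i in range(ng))
    var = sum((i + 1 - mu) ** 2 * p[i, :].sum() for i in range(ng))
    corr_num = 0.0
    for i in range(ng):
        for j in range(ng):
            v = p[i, j]
            out["energy"] += v * v
            out["contrast"] += v * (i - j) ** 2
            out["homogeneity"] += v / (1 + (i - j) ** 2)
            out["dissimilarity"] += v * abs(i - j)
            if v > 0:
                out["entropy"] -= v * np.log2(v)
            corr_num += (i + 1) * (j + 1) * v
    out["correlation"] = (corr_num - mu * mu) / var if var > 0 else 1.0
    return out


class TestReferenceAgreement:
    def test_glcm_features_vs_naive_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(17)
        for trial in range(10):
            arr = rng.integers(1, 9, (12, 12))
            mask = rng.random((12, 12)) < 0.8
            q = make_q(np.where(mask, arr, 0), mask=mask, levels=8)
            m = compute_glcm(q, 1, 45)
            ours = glcm_features(m)
            ref = naive_glcm_feature_oracle(m.probabilities)
            for k, v in ref.items():
                assert abs(ours[k] - v) <= 1e-6, (trial, k)


class TestExtraction:
    def test_single_image_feature_count(self, arterial_image):
        feats = extract_image_features(arterial_image)
        assert len(feats) == 1044
        assert all(np.isfinite(v) for v in feats.values())

    def test_triplet_feature_count(self, small_cfg):
        from ceusomics.synthetic_data import simulate_lesion_image

        trip = {ph: simulate_lesion_image(0, ph, small_cfg, seed=2) for ph in ("baseline", "arterial", "portal")}
        v = extract_features(trip, patient_id="p1")
        assert v.size == 3132
        assert v.index[0].startswith("BL_")
        assert np.isfinite(v.to_numpy()).all()

    def test_duplicated_phase_blocks_identical(self, arterial_image):
        from dataclasses import replace

        trip = {ph: replace(arterial_image, phase=ph) for ph in ("baseline", "arterial", "portal")}
        v = extract_features(trip)
        bl = v.filter(like="BL_").to_numpy()
        ap = v.filter(like="AP_").to_numpy()
        pp = v.filter(like="PP_").to_numpy()
        assert np.array_equal(bl, ap) and np.array_equal(bl, pp)

    def test_intensity_shift_scale_invariance_of_texture_blocks(self, arterial_image):
        img = arterial_image
        f1 = extract_image_features(img)
        from dataclasses import replace

        shifted = replace(img, pixels=img.pixels.astype(float) * 2.0 + 11.0)
        f2 = extract_image_features(shifted)
        for name in f1:
            if name.startswith(("glcm_", "rlm_")):
                assert f1[name] == pytest.approx(f2[name], abs=1e-9), name

    def test_angular_mean_matches_explicit_angles(self, arterial_image):
        f = extract_image_features(arterial_image)
        for feat in ("contrast", "energy"):
            vals = [f[f"glcm_lv32_d1_a{a}_{feat}"] for a in (0, 45, 90, 135)]
            assert f[f"glcm_lv32_d1_amean_{feat}"] == pytest.approx(np.mean(vals))
            assert f[f"glcm_lv32_d1_arange_{feat}"] == pytest.approx(max(vals) - min(vals))
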