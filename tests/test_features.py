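"""Biomarker extractors against brute-force oracles, plus registry contracts."""

import numpy as np
import pytest
from scipy import ndimage, stats
from skimage.feature import graycomatrix, graycoprops

from glompath import features as feat
from glompath import phantom as ph


class TestColorFeatures:
    def test_constant_region_degenerate_values(self):
        m, v, s, k, e, h = feat.color_features(np.full(50, 77.0))
        assert (m, v, s, k) == (77.0, 0.0, 0.0, 0.0)
        assert e == 1.0 and h == 0.0

    def test_two_point_histogram_hand_values(self):
        m, v, s, k, e, h = feat.color_features(np.array([0.0, 0.0, 255.0, 255.0]))
        assert m == 127.5
        assert v == 16256.25
        assert e == 0.5
        assert h == 1.0  # one bit

    def test_moments_match_brute_force_formulas(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 10.0])
        _, v, s, k, _, _ = feat.color_features(x)
        mu = x.mean()
        m2 = ((x - mu) ** 2).mean()
        m3 = ((x - mu) ** 3).mean()
        m4 = ((x - mu) ** 4).mean()
        assert v == pytest.approx(m2)
        assert s == pytest.approx(m3 / m2**1.5)
        assert k == pytest.approx(m4 / m2**2 - 3.0)  # excess kurtosis

    def test_empty_region_all_zero(self):
        assert feat.color_features(np.array([])) == (0.0,) * 6

    def test_hue_channel_scaled_to_255(self):
        img = np.zeros((4, 4, 3), np.uint8)
        img[..., 2] = 255  # pure blue: hue 240 deg = 2/3 of the wheel
        hue = feat.channel_image(img, "Hue")
        assert np.allclose(hue, 255.0 * 2 / 3)


class TestMorphology:
    def test_disc_diameter_circularity_thickness(self):
        yy, xx = np.mgrid[0:128, 0:128]
        disc = (yy - 64) ** 2 + (xx - 64) ** 2 <= 50**2
        area = disc.sum()
        assert abs(feat.equivalent_diameter(area) - 100) <= 1
        assert 0.95 <= feat.circularity(disc) <= 1.05
        mx, med, tot = feat.thickness_features(disc)
        assert abs(mx - 50) <= 1
        edt = ndimage.distance_transform_edt(disc)
        assert med == np.median(edt[disc]) and tot == edt[disc].sum()

    def test_containment_is_pixel_count_ratio(self):
        smap = np.zeros((30, 30), np.uint8)
        mask = np.zeros((30, 30), bool)
        mask[5:25, 5:25] = True
        smap[mask] = ph.TUFT  # tuft covers the whole glomerulus
        smap[10:15, 10:20] = ph.NUCLEI
        vals = feat.morphological_features(smap, mask)
        assert vals["morph_containment_nuclei_in_glomerulus"] == pytest.approx(50 / 400)
        assert vals["morph_containment_tuft_in_glomerulus"] == pytest.approx(350 / 400)

    def test_single_pixel_pair_interstructural_distance(self):
        a = np.zeros((10, 10), bool)
        b = np.zeros((10, 10), bool)
        a[5, 2] = True
        b[5, 5] = True  # 3 px apart on the same row
        mean_d, max_d = feat.interstructural_distance(a, b)
        assert mean_d == 3.0 and max_d == 3.0

    def test_empty_structure_conventions(self):
        smap = np.zeros((20, 20), np.uint8)
        mask = np.zeros((20, 20), bool)
        mask[2:18, 2:18] = True
        smap[mask] = ph.LUMINAL  # no tuft, no nuclei
        vals = feat.morphological_features(smap, mask)
        assert vals["morph_intra_nuclei_thickness_max"] == 0.0
        assert vals["morph_inter_nuclei_to_tuft_mean"] == 0.0
        assert vals["morph_containment_nuclei_in_glomerulus"] == 0.0
        assert all(np.isfinite(v) for v in vals.values())


def brute_force_glcm(q, mask, levels):
    """Enumerate every ordered neighbor pair at distance 1 for 4 angles."""
    m = np.zeros((levels, levels))
    h, w = q.shape
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            for dr, dc in ((0, 1), (-1, 1), (-1, 0), (-1, -1)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w and mask[rr, cc]:
                    m[q[r, c], q[rr, cc]] += 1
                    m[q[rr, cc], q[r, c]] += 1
    return m / m.sum() if m.sum() else m


class TestGLCM:
    def test_constant_image_degenerate_statistics(self):
        img = np.full((10, 10, 3), 100, np.uint8)
        mask = np.ones((10, 10), bool)
        st = feat.glcm_features(img, mask)
        assert st["contrast"] == 0.0
        assert st["energy"] == 1.0
        assert st["homogeneity"] == 1.0

    def test_strip_matches_enumerated_pairs(self):
        # 1 x 4 strip [0, 0, 1, 1]: only the horizontal angle contributes
        q = np.array([[0, 0, 1, 1]])
        mask = np.ones((1, 4), bool)
        glcm = feat.masked_glcm(q, mask, levels=2)
        assert np.allclose(glcm, np.array([[2, 1], [1, 2]]) / 6)
        oracle = brute_force_glcm(q, mask, 2)
        assert np.allclose(glcm, oracle)
        st = feat.glcm_statistics(glcm)
        assert st["contrast"] == pytest.approx(2 / 6)
        assert st["energy"] == pytest.approx((4 + 1 + 1 + 4) / 36)
        assert st["homogeneity"] == pytest.approx(4 / 6 + 2 / 12)

    def test_random_masked_region_matches_oracle(self, rng):
        q = rng.integers(0, 8, (12, 12))
        mask = rng.random((12, 12)) < 0.7
        assert np.allclose(feat.masked_glcm(q, mask, 8), brute_force_glcm(q, mask, 8))

    def test_normalized_distribution(self, rng):
        q = rng.integers(0, 32, (20, 20))
        glcm = feat.masked_glcm(q, np.ones((20, 20), bool))
        assert glcm.sum() == pytest.approx(1.0)
        assert np.allclose(glcm, glcm.T)

    def test_rectangular_region_agrees_with_skimage(self, rng):
        # on a full rectangle the mask constraint is moot -> skimage oracle
        img = rng.integers(0, 255, (16, 16)).astype(np.uint8)
        q = (img // 32).astype(np.int64)
        mine = feat.masked_glcm(q, np.ones((16, 16), bool), levels=8)
        sk = graycomatrix(
            q.astype(np.uint8), [1], [0, np.pi / 4, np.pi / 2, 3 * np.pi / 4], levels=8, symmetric=True
        ).astype(float)
        sk = sk[:, :, 0, :].sum(axis=2)
        sk /= sk.sum()
        assert np.allclose(mine, sk)
        st = feat.glcm_statistics(mine)
        sk_pooled = sk.reshape(8, 8, 1, 1)  # pooled-normalized matrix
        assert st["contrast"] == pytest.approx(graycoprops(sk_pooled, "contrast")[0, 0], rel=1e-9)
        assert st["homogeneity"] == pytest.approx(graycoprops(sk_pooled, "homogeneity")[0, 0], rel=1e-9)
        assert st["energy"] == pytest.approx(graycoprops(sk_pooled, "ASM")[0, 0], rel=1e-9)
        assert st["correlation"] == pytest.approx(graycoprops(sk_pooled, "correlation")[0, 0], rel=1e-9)

    def test_tiny_structure_returns_zeros(self):
        img = np.zeros((5, 5, 3), np.uint8)
        mask = np.zeros((5, 5), bool)
        mask[2, 2] = True
        assert all(v == 0.0 for v in feat.glcm_features(img, mask).values())


class TestLBP:
    def test_flat_texture_concentrates_in_one_bin(self):
        img = np.full((12, 12, 3), 50, np.uint8)
        mask = np.zeros((12, 12), bool)
        mask[2:10, 2:10] = True
        hist = feat.lbp_features(img, mask)
        for k in range(3):
            h = hist[k * 10 : (k + 1) * 10]
            # equal neighbors count as >= center: the all-ones pattern, bin 8
            assert h[8] == 1.0 and h.sum() == 1.0

    def test_step_edge_code_matches_hand_threshold(self):
        # columns [0, 5, 10]: right semicircle >= center, left < center ->
        # 5 contiguous ones -> uniform pattern, riu2 code = 5
        channel = np.tile(np.array([0.0, 5.0, 10.0]), (3, 1))
        codes = feat.lbp_code_image(channel)
        assert codes[1, 1] == 5

    def test_quarter_rotation_leaves_histograms_unchanged(self, mn_phantom):
        mask = mn_phantom.structure_map == ph.TUFT
        h1 = feat.lbp_features(mn_phantom.image, mask)
        h2 = feat.lbp_features(np.rot90(mn_phantom.image), np.rot90(mask))
        assert np.allclose(h1, h2, atol=1e-12)

    def test_empty_structure_zero_histograms(self):
        img = np.zeros((8, 8, 3), np.uint8)
        assert not feat.lbp_features(img, np.zeros((8, 8), bool)).any()


class TestWavelets:
    def test_constant_image_has_no_detail_energy(self):
        img = np.full((32, 32, 3), 200, np.uint8)
        mask = np.ones((32, 32), bool)
        wv = feat.wavelet_features(img, mask)
        for name in ("LH1", "HL1", "HH1", "LH2", "HL2", "HH2"):
            assert wv[f"energy_{name}"] == pytest.approx(0.0, abs=1e-12)

    def test_parseval_energy_conservation(self, rng):
        img = rng.integers(0, 255, (64, 64, 3)).astype(np.uint8)
        mask = np.ones((64, 64), bool)
        wv = feat.wavelet_features(img, mask)
        from skimage.color import rgb2gray

        gray = rgb2gray(img) * 255.0
        total = sum(wv[f"energy_{s}"] for s in ("LL2", "LH2", "HL2", "HH2", "LH1", "HL1", "HH1"))
        assert total == pytest.approx(np.sum(gray**2), rel=1e-6)

    def test_haar_on_block_constant_image_closed_form(self):
        # 4x4 image of 2x2 constant blocks [[a,b],[c,d]]: level-1 details
        # vanish and level-2 Haar coefficients have closed forms
        a, b, c, d = 10.0, 40.0, 90.0, 160.0
        img = np.zeros((4, 4), np.float64)
        img[:2, :2], img[:2, 2:], img[2:, :2], img[2:, 2:] = a, b, c, d
        rgb = np.repeat(np.round(img).astype(np.uint8)[..., None], 3, axis=2)
        wv = feat.wavelet_features(rgb, np.ones((4, 4), bool), wavelet="haar")
        for name in ("LH1", "HL1", "HH1"):
            assert wv[f"energy_{name}"] == pytest.approx(0.0, abs=1e-9)
        assert wv["energy_LL2"] == pytest.approx((a + b + c + d) ** 2, rel=1e-9)
        details = sorted(wv[f"energy_{n}"] for n in ("LH2", "HL2", "HH2"))
        expected = sorted(((a + b - c - d) ** 2, (a - b + c - d) ** 2, (a - b - c + d) ** 2))
        assert np.allclose(details, expected)

    def test_too_small_region_errors_with_min_size(self):
        img = np.zeros((4, 4, 3), np.uint8)
        with pytest.raises(ValueError, match="at least 8"):
            feat.wavelet_features(img, np.ones((4, 4), bool), wavelet="db4")


class TestRegistryAndPanel:
    def test_registry_length_and_allocation(self):
        reg = feat.build_registry()
        assert len(reg) == 233
        assert len(set(reg.names)) == 233
        assert reg.family_counts() == {"color": 96, "morphological": 47, "texture": 90}

    def test_registry_order_is_stable(self):
        assert feat.build_registry().names == feat.DEFAULT_REGISTRY.names
        assert feat.DEFAULT_REGISTRY.version == feat.REGISTRY_VERSION

    def test_panel_is_finite_and_deterministic(self, mn_phantom):
        v1 = feat.extract_all(mn_phantom.image, mn_phantom.structure_map, mn_phantom.boundary_mask)
        v2 = feat.extract_all(mn_phantom.image, mn_phantom.structure_map, mn_phantom.boundary_mask)
        assert len(v1) == 233
        assert np.isfinite(v1.to_numpy()).all()
        assert (v1 == v2).all()

    def test_zero_nuclei_phantom_degenerates_gracefully(self):
        profile = ph.default_profiles(256)["MCD"]
        from dataclasses import replace

        p = ph.generate_glomerulus(replace(profile, nuclei_count_range=(0, 0)), 5)
        vec = feat.extract_all(p.image, p.structure_map, p.boundary_mask)
        assert np.isfinite(vec.to_numpy()).all()
        assert vec["morph_intra_nuclei_thickness_max"] == 0.0
        assert vec["color_nuclei_R_mean"] == 0.0
        assert vec["glcm_nuclei_contrast"] == 0.0

    def test_wrong_registry_length_rejected(self, mn_phantom):
        reg = feat.FeatureRegistry(feat.DEFAULT_REGISTRY.descriptors[:100])
        with pytest.raises(ValueError, match="registry"):
            feat.extract_all(mn_phantom.image, mn_phantom.structure_map, mn_phantom.boundary_mask, reg)


class TestPlantedSeparation:
    def test_tuft_thickness_ordering_across_presets(self, cohort_run):
        tbl = cohort_run.feature_table
        med = tbl.groupby("label")["morph_intra_tuft_thickness_median"].median()
        assert med["MN"] > med["MCD"] > med["TBMN"]
        mn = tbl.loc[tbl["label"] == "MN", "morph_intra_tuft_thickness_median"]
        mcd = tbl.loc[tbl["label"] == "MCD", "morph_intra_tuft_thickness_median"]
        tbmn = tbl.loc[tbl["label"] == "TBMN", "morph_intra_tuft_thickness_median"]
        assert stats.mannwhitneyu(mn, mcd, alternative="greater").pvalue < 1e-6
        assert stats.mannwhitneyu(mcd, tbmn, alternative="greater").pvalue < 1e-6

    def test_luminal_rich_phantoms_have_higher_mean_hue(self, cohort_run):
        tbl = cohort_run.feature_table
        hue = tbl.groupby("label")["color_glomerulus_Hue_mean"].mean()
        assert hue["TBMN"] > hue["MN"]  # thin tuft -> more luminal -> higher hue
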