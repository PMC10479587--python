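"""Naive Bayes pixel segmentation against brute-force Bayes oracles."""

import numpy as np
import pytest

from glompath import phantom as ph
from glompath import segmentation as seg


class TestFitNB:
    def test_population_moments_hand_values(self):
        # one channel, one class with pixels {10, 20}: mu = 15, var = 25
        X = np.array([[10.0], [20.0], [0.0], [1.0]])
        y = np.array([1, 1, 2, 2])
        m = seg.fit_nb(X, y)
        i = list(m.classes_).index(1)
        assert m.theta_[i, 0] == 15.0
        assert m.var_[i, 0] == 25.0

    def test_constant_classes_hit_variance_floor(self):
        X = np.array([[10.0, 0.0], [10.0, 0.0], [200.0, 50.0], [200.0, 50.0]])
        y = np.array([1, 1, 2, 2])
        m = seg.fit_nb(X, y)
        assert np.allclose(m.theta_[0], [10.0, 0.0])
        assert np.allclose(m.var_, seg.VARIANCE_FLOOR)

    def test_duplicating_pixels_leaves_model_unchanged(self, rng):
        X = rng.normal(100, 20, (60, 3))
        y = rng.integers(1, 4, 60)
        m1 = seg.fit_nb(X, y)
        m2 = seg.fit_nb(np.vstack([X, X]), np.concatenate([y, y]))
        assert np.allclose(m1.theta_, m2.theta_)
        assert np.allclose(m1.var_, m2.var_)
        assert np.allclose(m1.class_prior_, m2.class_prior_)

    def test_missing_required_class_error_names_it(self):
        X = np.zeros((4, 3))
        y = np.array([1, 1, 2, 2])
        with pytest.raises(ValueError, match="nuclei"):
            seg.fit_nb(X, y, required_classes=seg.SEGMENT_CLASSES)

    def test_priors_default_to_empirical_frequencies(self):
        X = np.array([[0.0], [0.0], [0.0], [9.0], [9.0], [9.0], [9.0], [9.0], [5.0], [5.0]])
        y = np.array([1] * 3 + [2] * 5 + [3] * 2)
        m = seg.fit_nb(X, y)
        assert np.allclose(m.class_prior_, [0.3, 0.5, 0.2])


def brute_force_log_posterior(x, model):
    """Independent per-pixel Bayes computation from the model parameters."""
    out = []
    for i in range(len(model.classes_)):
        lp = np.log(model.class_prior_[i])
        for k in range(len(x)):
            v = model.var_[i, k]
            lp += -0.5 * np.log(2 * np.pi * v) - (x[k] - model.theta_[i, k]) ** 2 / (2 * v)
        out.append(lp)
    return np.array(out)


class TestPredict:
    def test_argmax_agrees_with_exhaustive_oracle(self, rng):
        X = rng.normal(120, 40, (80, 3))
        y = rng.integers(1, 4, 80)
        m = seg.fit_nb(X, y)
        Q = rng.uniform(0, 255, (100, 3))
        pred = m.predict(Q)
        for q, p in zip(Q, pred):
            lp = brute_force_log_posterior(q, m)
            assert m.classes_[np.argmax(lp)] == p

    def test_single_pixel_goes_to_nearer_mean(self):
        # equal priors, equal variances -> nearest-mean rule
        X = np.array([[10.0], [10.0], [30.0], [30.0]])
        m = seg.fit_nb(X, np.array([1, 1, 2, 2]))
        assert m.predict(np.array([[18.0]]))[0] == 1
        assert m.predict(np.array([[22.0]]))[0] == 2

    def test_equal_posterior_tie_breaks_to_earlier_class(self):
        X = np.array([[10.0], [10.0], [30.0], [30.0]])
        m = seg.fit_nb(X, np.array([1, 1, 2, 2]))
        # exact midpoint: posteriors identical -> earlier class (luminal) wins
        p = m.predict_proba(np.array([[20.0]]))[0]
        assert abs(p[0] - p[1]) < 1e-12
        assert m.predict(np.array([[20.0]]))[0] == 1


class TestSegment:
    def test_separable_constant_colors_give_perfect_dice(self):
        colors = {1: (240, 230, 235), 2: (180, 70, 170), 3: (70, 60, 120)}
        truth = np.zeros((40, 40), np.uint8)
        mask = np.zeros((40, 40), bool)
        mask[4:36, 4:36] = True
        truth[mask] = 1
        truth[10:30, 10:20] = 2
        truth[15:25, 25:32] = 3
        img = np.zeros((40, 40, 3), np.uint8)
        for c, rgb in colors.items():
            img[truth == c] = rgb
        px = img[mask].reshape(-1, 3).astype(float)
        m = seg.fit_nb(px, truth[mask])
        m.smoothing = False  # pure color model: exact recovery
        pred = m.segment(img, mask)
        d = seg.dice_per_class(pred, truth)
        assert all(v == 1.0 for v in d.values())
        # majority smoothing may flip sharp corners but stays near-perfect
        m.smoothing = True
        d2 = seg.dice_per_class(m.segment(img, mask), truth)
        assert all(v >= 0.97 for v in d2.values())

    def test_modal_smoothing_never_invents_local_labels(self, rng):
        labels = rng.integers(1, 4, (30, 30)).astype(np.uint8)
        mask = np.ones((30, 30), bool)
        labels[~mask] = 0
        sm = seg._modal_smooth(labels, mask, [1, 2, 3])
        for r in range(30):
            for c in range(30):
                neigh = labels[max(0, r - 1) : r + 2, max(0, c - 1) : c + 2]
                assert sm[r, c] in neigh

    def test_outside_mask_is_background(self, mn_phantom):
        m = seg.fit_nb(*seg.sample_training_pixels([mn_phantom], np.random.default_rng(0)))
        pred = m.segment(mn_phantom.image, mn_phantom.boundary_mask)
        assert (pred[~mn_phantom.boundary_mask] == ph.BACKGROUND).all()


class TestDice:
    def test_identical_maps_score_one(self, rng):
        t = rng.integers(0, 4, (20, 20)).astype(np.uint8)
        assert all(v == 1.0 for v in seg.dice_per_class(t, t).values())

    def test_disjoint_equal_area_masks_score_zero(self):
        a = np.zeros((10, 10), np.uint8)
        b = np.zeros((10, 10), np.uint8)
        a[0:5, :] = 2
        b[5:10, :] = 2
        assert seg.dice_per_class(a, b)[ph.TUFT] == 0.0

    def test_hand_counted_overlap(self):
        pred = np.zeros((10, 10), np.uint8)
        truth = np.zeros((10, 10), np.uint8)
        pred[0, 0:6] = 3  # |P| = 6
        truth[0, 3:7] = 3  # |T| = 4, overlap = 3
        assert seg.dice_per_class(pred, truth)[ph.NUCLEI] == pytest.approx(0.6)

    def test_both_empty_is_one_by_convention(self):
        z = np.zeros((5, 5), np.uint8)
        assert all(v == 1.0 for v in seg.dice_per_class(z, z).values())

    def test_dim_mismatch_errors(self):
        with pytest.raises(ValueError):
            seg.dice_per_class(np.zeros((5, 5)), np.zeros((6, 6)))


def test_model_json_round_trip(rng):
    X = rng.normal(100, 30, (30, 3))
    y = rng.integers(1, 4, 30)
    m = seg.fit_nb(X, y)
    m2 = seg.model_from_json(seg.model_to_json(m))
    Q = rng.uniform(0, 255, (20, 3))
    assert np.array_equal(m.predict(Q), m2.predict(Q))
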