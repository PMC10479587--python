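"""Sub-glomerular structure segmentation with a Gaussian Naive Bayes color
model plus modal smoothing.

Each pixel inside the glomerulus boundary is assigned to luminal, tuft, or
nuclei by the class maximizing log pi_c + sum_k log N(x_k; mu_ck, var_ck)
over the color channels, followed by one pass of 3x3 modal (majority-vote)
smoothing restricted to the boundary mask.  Ties break to the earlier class
in the fixed order luminal < tuft < nuclei.

Conventions chosen so tests can be exact: per-class moments are population
(ddof=0) statistics; variances are floored at 1e-4 of the squared channel
range; priors default to empirical class frequencies.
"""

from __future__ import annotations

import json

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .phantom import LUMINAL, NUCLEI, STRUCTURE_NAMES, TUFT

SEGMENT_CLASSES = (LUMINAL, TUFT, NUCLEI)

_CHANNEL_RANGE = 255.0
VARIANCE_FLOOR = 1e-4 * _CHANNEL_RANGE**2


class NaiveBayesSegmenter(ClassifierMixin, BaseEstimator):
    """Gaussian Naive Bayes pixel classifier over color channels.

    Parameters
    ----------
    priors : array-like of shape (n_classes,), optional
        Class priors; defaults to empirical frequencies of the training
        pixels.
    smoothing : bool, default True
        Apply one pass of 3x3 modal smoothing inside the boundary mask when
        segmenting whole images.
    variance_floor : float
        Lower bound applied to every per-class per-channel variance.

    Attributes
    ----------
    classes_ : ndarray — sorted class codes seen in fit
    theta_ : ndarray (n_classes, n_channels) — per-channel means
    var_ : ndarray (n_classes, n_channels) — floored population variances
    class_prior_ : ndarray (n_classes,)
    """

    def __init__(self, priors=None, smoothing: bool = True, variance_floor: float = VARIANCE_FLOOR):
        self.priors = priors
        self.smoothing = smoothing
        self.variance_floor = variance_floor

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be (n_pixels, n_channels)")
        self.classes_ = np.unique(y)
        for c in SEGMENT_CLASSES:
            if c in self.classes_ and (y == c).sum() < 2:
                raise ValueError(f"class '{STRUCTURE_NAMES[c]}' has fewer than 2 training pixels")
        n_classes = len(self.classes_)
        if n_classes < 2:
            raise ValueError("need at least 2 classes")
        self.theta_ = np.empty((n_classes, X.shape[1]))
        self.var_ = np.empty((n_classes, X.shape[1]))
        counts = np.empty(n_classes)
        for i, c in enumerate(self.classes_):
            px = X[y == c]
            if px.shape[0] < 2:
                raise ValueError(f"class {c!r} has fewer than 2 training pixels")
            self.theta_[i] = px.mean(axis=0)
            self.var_[i] = np.maximum(px.var(axis=0), self.variance_floor)
            counts[i] = px.shape[0]
        if self.priors is not None:
            p = np.asarray(self.priors, dtype=np.float64)
            self.class_prior_ = p / p.sum()
        else:
            self.class_prior_ = counts / counts.sum()
        return self

    def _joint_log_likelihood(self, X):
        X = np.asarray(X, dtype=np.float64)
        jll = np.empty((X.shape[0], len(self.classes_)))
        for i in range(len(self.classes_)):
            ll = -0.5 * np.sum(
                np.log(2 * np.pi * self.var_[i]) + (X - self.theta_[i]) ** 2 / self.var_[i],
                axis=1,
            )
            jll[:, i] = np.log(self.class_prior_[i]) + ll
        return jll

    def predict(self, X):
        check_is_fitted(self, "theta_")
        # argmax takes the first maximum -> tie-break to earlier class code
        return self.classes_[np.argmax(self._joint_log_likelihood(X), axis=1)]

    def predict_proba(self, X):
        check_is_fitted(self, "theta_")
        jll = self._joint_log_likelihood(X)
        jll -= jll.max(axis=1, keepdims=True)
        p = np.exp(jll)
        return p / p.sum(axis=1, keepdims=True)

    def segment(self, image, boundary_mask):
        """Label every pixel inside the boundary mask; returns a label map.

        Pixels outside the mask are background (0).  With ``smoothing`` on,
        one pass of 3x3 majority voting is applied inside the mask.
        """
        check_is_fitted(self, "theta_")
        image = np.asarray(image)
        mask = np.asarray(boundary_mask, bool)
        labels = np.zeros(mask.shape, dtype=np.uint8)
        if mask.any():
            labels[mask] = self.predict(image[mask].reshape(-1, image.shape[-1]))
        if self.smoothing:
            labels = _modal_smooth(labels, mask, [int(c) for c in self.classes_])
        return labels


def _modal_smooth(labels: np.ndarray, mask: np.ndarray, classes: list[int]) -> np.ndarray:
    """One pass of 3x3 majority voting inside the mask.

    Votes are counted only over in-mask neighbors, so a label can never be
    introduced where it is absent from the pixel's 3x3 neighborhood; ties go
    to the earlier class in the fixed order.
    """
    kernel = np.ones((3, 3))
    votes = np.stack(
        [ndimage.convolve(((labels == c) & mask).astype(np.float64), kernel, mode="constant") for c in classes]
    )
    winner = np.asarray(classes, dtype=np.uint8)[np.argmax(votes, axis=0)]
    out = labels.copy()
    out[mask] = winner[mask]
    return out


def fit_nb(pixels, labels, priors=None, required_classes=None) -> NaiveBayesSegmenter:
    """Fit the Gaussian Naive Bayes color model (thin estimator wrapper).

    If ``required_classes`` is given (e.g. the three structure codes), a
    class absent from the training labels raises an error naming it.
    """
    if required_classes is not None:
        present = set(np.unique(labels).tolist())
        for c in required_classes:
            if c not in present:
                name = STRUCTURE_NAMES.get(c, str(c))
                raise ValueError(f"no training pixels for class '{name}'")
    return NaiveBayesSegmenter(priors=priors).fit(pixels, labels)


def segment(image, boundary_mask, model: NaiveBayesSegmenter) -> np.ndarray:
    """Segment one ROI into {background, luminal, tuft, nuclei}."""
    return model.segment(image, boundary_mask)


def sample_training_pixels(phantoms, rng, pixels_per_class: int = 2000):
    """Draw a balanced pixel sample from ground-truth structure maps."""
    xs, ys = [], []
    per_image = max(1, pixels_per_class // max(1, len(phantoms)))
    for ph in phantoms:
        for c in SEGMENT_CLASSES:
            yy, xx = np.nonzero(ph.structure_map == c)
            if yy.size == 0:
                continue
            take = min(per_image, yy.size)
            idx = rng.choice(yy.size, size=take, replace=False)
            xs.append(ph.image[yy[idx], xx[idx]].astype(np.float64))
            ys.append(np.full(take, c))
    return np.concatenate(xs), np.concatenate(ys)


def dice_per_class(pred: np.ndarray, truth: np.ndarray) -> dict[int, float]:
    """Per-class Dice overlap for the three structures; empty/empty -> 1.0."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    out = {}
    for c in SEGMENT_CLASSES:
        p = pred == c
        t = truth == c
        denom = p.sum() + t.sum()
        out[c] = 1.0 if denom == 0 else 2.0 * np.logical_and(p, t).sum() / denom
    return out


def model_to_json(model: NaiveBayesSegmenter) -> str:
    return json.dumps(
        {
            "classes": [int(c) for c in model.classes_],
            "means": model.theta_.tolist(),
            "variances": model.var_.tolist(),
            "priors": model.class_prior_.tolist(),
            "channel_space": "rgb",
        }
    )


def model_from_json(s: str) -> NaiveBayesSegmenter:
    d = json.loads(s)
    m = NaiveBayesSegmenter()
    m.classes_ = np.asarray(d["classes"])
    m.theta_ = np.asarray(d["means"], dtype=np.float64)
    m.var_ = np.asarray(d["variances"], dtype=np.float64)
    m.class_prior_ = np.asarray(d["priors"], dtype=np.float64)
    return m
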