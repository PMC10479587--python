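"""ROI preprocessing: size-outlier exclusion, Reinhard-style color
normalization in CIELAB, and re-center / crop / resize.

Outlier exclusion uses the Tukey lower fence on boundary-mask pixel area
(only abnormally *small* glomeruli are removed — typically fragments or
mis-crops).  Color normalization matches per-channel Lab mean and standard
deviation to a target, with source statistics computed over tissue pixels
(inside the boundary mask) only, so background white does not dilute them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from skimage import color as skcolor
from skimage.transform import resize as sk_resize


@dataclass(frozen=True)
class NormalizationTarget:
    """Per-channel CIELAB means and standard deviations of the reference."""

    means: tuple[float, float, float]
    sds: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.sds):
            raise ValueError("target standard deviations must be > 0")

    def to_json(self) -> str:
        return json.dumps({"means": list(self.means), "sds": list(self.sds)})

    @classmethod
    def from_json(cls, s: str) -> "NormalizationTarget":
        d = json.loads(s)
        return cls(means=tuple(d["means"]), sds=tuple(d["sds"]))

    @classmethod
    def from_image(cls, image: np.ndarray, boundary_mask: np.ndarray) -> "NormalizationTarget":
        lab = skcolor.rgb2lab(np.asarray(image, dtype=np.uint8))
        px = lab[np.asarray(boundary_mask, bool)]
        sds = px.std(axis=0)
        sds = np.where(sds <= 0, 1.0, sds)
        return cls(means=tuple(px.mean(axis=0)), sds=tuple(sds))


def detect_size_outliers(areas, fence_factor: float = 1.5) -> np.ndarray:
    """Flag abnormally small ROIs by the Tukey lower-fence rule.

    An ROI is flagged when its mask area < Q1 - fence_factor * IQR.  With
    fewer than 4 areas the quartiles are meaningless and nothing is flagged.
    """
    areas = np.asarray(list(areas), dtype=np.float64)
    if areas.size < 4:
        return np.zeros(areas.size, dtype=bool)
    q1, q3 = np.percentile(areas, [25, 75])
    fence = q1 - fence_factor * (q3 - q1)
    return areas < fence


def reinhard_normalize(
    image: np.ndarray, boundary_mask: np.ndarray, target: NormalizationTarget
) -> np.ndarray:
    """Match masked Lab channel statistics to the target; returns uint8 RGB.

    Per channel: x' = (x - mu_src) * (sd_tgt / sd_src) + mu_tgt, where the
    source statistics are computed over pixels inside the boundary mask only.
    A channel with zero source spread is mapped to the target mean.
    """
    image = np.asarray(image, dtype=np.uint8)
    mask = np.asarray(boundary_mask, bool)
    if not mask.any():
        raise ValueError("boundary mask is empty")
    lab = skcolor.rgb2lab(image)
    px = lab[mask]
    mu_src = px.mean(axis=0)
    sd_src = px.std(axis=0)
    out = np.empty_like(lab)
    for k in range(3):
        if sd_src[k] < 1e-6:  # numerically constant channel
            out[..., k] = target.means[k]
        else:
            out[..., k] = (lab[..., k] - mu_src[k]) * (target.sds[k] / sd_src[k]) + target.means[k]
    rgb = skcolor.lab2rgb(out)
    return np.clip(np.round(rgb * 255.0), 0, 255).astype(np.uint8)


def _bbox(mask: np.ndarray) -> tuple[int, int, int, int]:
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        raise ValueError("boundary mask is empty")
    return ys.min(), ys.max(), xs.min(), xs.max()


def compute_global_crop_side(boundary_masks) -> int:
    """Largest bounding-box side over a dataset: the uniform crop side.

    Returns max over ROIs of max(bbox height, bbox width), so one crop
    window fits the largest glomerulus and every ROI is cropped identically.
    """
    masks = list(boundary_masks)
    if not masks:
        raise ValueError("no masks given")
    side = 0
    for m in masks:
        y0, y1, x0, x1 = _bbox(np.asarray(m, bool))
        side = max(side, y1 - y0 + 1, x1 - x0 + 1)
    return int(side)


def _centroid_half_up(mask: np.ndarray) -> tuple[int, int]:
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        raise ValueError("boundary mask is empty")
    return int(np.floor(ys.mean() + 0.5)), int(np.floor(xs.mean() + 0.5))


def recenter_crop_resize(
    image: np.ndarray,
    boundary_mask: np.ndarray,
    side: int,
    out_size: int,
    *,
    return_mask: bool = False,
):
    """Crop a side x side window centered on the mask centroid, then resize.

    The window is half-open ([r0, r0+side) x [c0, c0+side)); parts falling
    outside the image are padded with the background color (per-channel
    median of pixels outside the mask).  Resizing uses bicubic interpolation.
    """
    image = np.asarray(image)
    mask = np.asarray(boundary_mask, bool)
    cy, cx = _centroid_half_up(mask)
    r0 = cy - side // 2
    c0 = cx - side // 2

    outside = ~mask
    if outside.any():
        bg = np.median(image[outside].reshape(-1, image.shape[-1]), axis=0)
    else:
        bg = np.array([255.0, 255.0, 255.0])
    crop = np.empty((side, side, image.shape[-1]), dtype=np.float64)
    crop[...] = bg
    mcrop = np.zeros((side, side), dtype=bool)

    r_lo, r_hi = max(r0, 0), min(r0 + side, image.shape[0])
    c_lo, c_hi = max(c0, 0), min(c0 + side, image.shape[1])
    if r_lo < r_hi and c_lo < c_hi:
        crop[r_lo - r0 : r_hi - r0, c_lo - c0 : c_hi - c0] = image[r_lo:r_hi, c_lo:c_hi]
        mcrop[r_lo - r0 : r_hi - r0, c_lo - c0 : c_hi - c0] = mask[r_lo:r_hi, c_lo:c_hi]

    if out_size == side:
        out_img = crop
        out_mask = mcrop
    else:
        out_img = sk_resize(crop, (out_size, out_size), order=3, anti_aliasing=out_size < side)
        out_mask = (
            sk_resize(mcrop.astype(np.float64), (out_size, out_size), order=1, anti_aliasing=False)
            >= 0.5
        )
    out_img = np.clip(np.round(out_img), 0, 255).astype(np.uint8)
    if return_mask:
        return out_img, out_mask
    return out_img
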