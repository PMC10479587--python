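"""The 233-element explainable biomarker panel.

Three families of features are measured per glomerulus from the normalized
RGB image, the sub-glomerular structure label map, and the boundary mask:

* color (96): first-order statistics (mean, variance, skewness, excess
  kurtosis, histogram energy, histogram entropy) of R, G, B and hue within
  each structure and the whole glomerulus;
* morphological (47): containment area ratios, per-structure shape
  (equivalent diameter, circularity, solidity), interstructural distances
  (mean/max Euclidean distance from one structure to the nearest pixel of
  another), intrastructural thickness (max/median/total of the Euclidean
  distance transform — the thickness maps), and whole-glomerulus shape/size;
* microstructural texture (90): masked Haralick GLCM statistics, color
  vector rotation-invariant uniform LBP histograms, and wavelet subband
  energies/entropies.

The panel is defined by an ordered, versioned registry; the exact identity
of each of the 233 entries is a documented allocation (see the registry
builders), and all degenerate cases (empty structures) map to finite,
documented values so downstream classifiers never see NaNs.

Conventions: population moments (ddof=0); excess kurtosis; entropies in
bits; histograms use 256 bins with hue scaled to [0, 255].
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pywt
from scipy import ndimage, stats
from skimage import color as skcolor
from skimage import measure
from skimage.feature import local_binary_pattern
from skimage.morphology import convex_hull_image

from .phantom import LUMINAL, NUCLEI, TUFT

REGISTRY_VERSION = "1.0"

_STRUCTS = {"luminal": LUMINAL, "tuft": TUFT, "nuclei": NUCLEI}
_COLOR_SCOPES = ("luminal", "tuft", "nuclei", "glomerulus")
_CHANNELS = ("R", "G", "B", "Hue")
_COLOR_STATS = ("mean", "variance", "skewness", "kurtosis", "energy", "entropy")

_CONTAINMENT_PAIRS = (
    ("luminal", "glomerulus"),
    ("tuft", "glomerulus"),
    ("nuclei", "glomerulus"),
    ("luminal", "tuft"),
    ("tuft", "luminal"),
    ("nuclei", "tuft"),
    ("nuclei", "luminal"),
    ("tuft", "nuclei"),
)
_INTER_PAIRS = (
    ("luminal", "tuft"),
    ("tuft", "luminal"),
    ("nuclei", "tuft"),
    ("tuft", "nuclei"),
    ("nuclei", "luminal"),
    ("luminal", "nuclei"),
)
_GLCM_STATS = ("contrast", "correlation", "energy", "homogeneity", "entropy")
_LBP_SCOPES = ("tuft", "glomerulus")
_LBP_BINS = 10  # P + 2 for riu2 with P = 8
_WAVELET_SUBBANDS = ("LL2", "LH2", "HL2", "HH2", "LH1", "HL1", "HH1")
# registry keeps all 7 subband energies plus the 3 level-2 non-diagonal
# entropies, truncating the 14 raw wavelet values to 10
_WAVELET_KEPT = tuple(f"energy_{s}" for s in _WAVELET_SUBBANDS) + (
    "entropy_LL2",
    "entropy_LH2",
    "entropy_HL2",
)

GLCM_LEVELS = 32


@dataclass(frozen=True)
class FeatureDescriptor:
    name: str
    family: str  # color | morphological | texture
    extractor: str
    params: tuple = ()


@dataclass(frozen=True)
class FeatureRegistry:
    """Ordered, versioned list of the 233 biomarker descriptors."""

    descriptors: tuple[FeatureDescriptor, ...]
    version: str = REGISTRY_VERSION

    @property
    def names(self) -> list[str]:
        return [d.name for d in self.descriptors]

    def __len__(self) -> int:
        return len(self.descriptors)

    def family_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for d in self.descriptors:
            out[d.family] = out.get(d.family, 0) + 1
        return out

    def to_json(self) -> str:
        return json.dumps(
            {
                "version": self.version,
                "features": [
                    {"name": d.name, "family": d.family, "extractor": d.extractor, "params": list(d.params)}
                    for d in self.descriptors
                ],
            }
        )


def build_registry() -> FeatureRegistry:
    """Construct the canonical 233-feature registry (96 + 47 + 90)."""
    desc: list[FeatureDescriptor] = []
    # --- color: 6 stats x 4 channels x 4 scopes = 96
    for scope in _COLOR_SCOPES:
        for ch in _CHANNELS:
            for st in _COLOR_STATS:
                desc.append(
                    FeatureDescriptor(f"color_{scope}_{ch}_{st}", "color", "color_stats", (scope, ch, st))
                )
    # --- morphological: 8 + 8 + 12 + 9 + 10 = 47
    for a, b in _CONTAINMENT_PAIRS:
        desc.append(
            FeatureDescriptor(f"morph_containment_{a}_in_{b}", "morphological", "containment", (a, b))
        )
    for s in ("luminal", "tuft", "nuclei"):
        desc.append(FeatureDescriptor(f"morph_shape_{s}_eqdiameter", "morphological", "shape", (s, "eqd")))
        desc.append(FeatureDescriptor(f"morph_shape_{s}_circularity", "morphological", "shape", (s, "circ")))
    for s in ("luminal", "tuft"):
        desc.append(FeatureDescriptor(f"morph_shape_{s}_solidity", "morphological", "shape", (s, "sol")))
    for a, b in _INTER_PAIRS:
        for st in ("mean", "max"):
            desc.append(
                FeatureDescriptor(f"morph_inter_{a}_to_{b}_{st}", "morphological", "interstructural", (a, b, st))
            )
    for s in ("luminal", "tuft", "nuclei"):
        for st in ("max", "median", "total"):
            desc.append(
                FeatureDescriptor(f"morph_intra_{s}_thickness_{st}", "morphological", "intrastructural", (s, st))
            )
    for st in (
        "area",
        "eqdiameter",
        "circularity",
        "perimeter",
        "eccentricity",
        "solidity",
        "extent",
        "major_axis",
        "minor_axis",
        "bbox_aspect",
    ):
        desc.append(FeatureDescriptor(f"morph_glom_{st}", "morphological", "glom_shape", (st,)))
    # --- texture: GLCM 20 + LBP 60 + wavelet 10 = 90
    for scope in _COLOR_SCOPES:
        for st in _GLCM_STATS:
            desc.append(FeatureDescriptor(f"glcm_{scope}_{st}", "texture", "glcm", (scope, st)))
    for scope in _LBP_SCOPES:
        for ch in ("R", "G", "B"):
            for b in range(_LBP_BINS):
                desc.append(
                    FeatureDescriptor(f"lbp_{scope}_{ch}_bin{b:02d}", "texture", "lbp", (scope, ch, b))
                )
    for name in _WAVELET_KEPT:
        desc.append(FeatureDescriptor(f"wavelet_{name}", "texture", "wavelet", (name,)))
    reg = FeatureRegistry(tuple(desc))
    assert len(reg) == 233, f"registry has {len(reg)} entries"
    return reg


DEFAULT_REGISTRY = build_registry()


# ---------------------------------------------------------------------------
# color features


def _hist256(values: np.ndarray) -> np.ndarray:
    counts = np.bincount(np.clip(np.round(values).astype(np.int64), 0, 255), minlength=256)
    return counts / counts.sum()


def color_features(values: np.ndarray) -> tuple[float, float, float, float, float, float]:
    """First-order statistics of a structure's channel intensities.

    Returns (mean, variance, skewness, excess kurtosis, histogram energy
    sum p^2, histogram entropy -sum p log2 p).  Empty input -> six zeros;
    a constant region has skewness/kurtosis 0 by the 0/0 -> 0 convention.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size == 0:
        return (0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    mean = float(values.mean())
    var = float(values.var())
    if var == 0:
        skew = kurt = 0.0
    else:
        skew = float(stats.skew(values, bias=True))
        kurt = float(stats.kurtosis(values, fisher=True, bias=True))
    p = _hist256(values)
    nz = p[p > 0]
    energy = float(np.sum(p**2))
    entropy = float(-np.sum(nz * np.log2(nz)))
    return (mean, var, skew, kurt, energy, entropy)


def channel_image(image: np.ndarray, channel: str) -> np.ndarray:
    """Extract one channel on the [0, 255] scale (hue rescaled from [0,1])."""
    image = np.asarray(image)
    if channel == "Hue":
        return skcolor.rgb2hsv(image)[..., 0] * 255.0
    return image[..., {"R": 0, "G": 1, "B": 2}[channel]].astype(np.float64)


# ---------------------------------------------------------------------------
# morphological features


def equivalent_diameter(area: float) -> float:
    return float(np.sqrt(4.0 * area / np.pi))


def circularity(mask: np.ndarray) -> float:
    """4 pi A / P^2 with P the total contour perimeter; 1.0 for a disc."""
    a = float(mask.sum())
    if a == 0:
        return 0.0
    # Crofton estimator: unbiased for smooth shapes (a disc scores ~1.0)
    p = float(measure.perimeter_crofton(mask, directions=4))
    return 4.0 * np.pi * a / p**2 if p > 0 else 0.0


def solidity(mask: np.ndarray) -> float:
    a = float(mask.sum())
    if a == 0:
        return 0.0
    hull = convex_hull_image(mask)
    h = float(hull.sum())
    return a / h if h > 0 else 0.0


def interstructural_distance(mask_a: np.ndarray, mask_b: np.ndarray) -> tuple[float, float]:
    """(mean, max) Euclidean distance from pixels of A to the nearest B pixel."""
    if not mask_a.any() or not mask_b.any():
        return (0.0, 0.0)
    dist_to_b = ndimage.distance_transform_edt(~mask_b)
    vals = dist_to_b[mask_a]
    return (float(vals.mean()), float(vals.max()))


def thickness_features(mask: np.ndarray) -> tuple[float, float, float]:
    """(max, median, total) of the Euclidean distance transform of the mask.

    The EDT map assigns every structure pixel its distance to the nearest
    non-structure pixel — a per-pixel half-thickness, as in the
    intrastructural thickness maps.
    """
    if not mask.any():
        return (0.0, 0.0, 0.0)
    edt = ndimage.distance_transform_edt(mask)
    vals = edt[mask]
    return (float(vals.max()), float(np.median(vals)), float(vals.sum()))


def _glom_shape(boundary_mask: np.ndarray) -> dict[str, float]:
    labeled = measure.label(boundary_mask)
    props = measure.regionprops(labeled)
    if not props:
        return {k: 0.0 for k in ("area", "eqdiameter", "circularity", "perimeter", "eccentricity", "solidity", "extent", "major_axis", "minor_axis", "bbox_aspect")}
    r = max(props, key=lambda p: p.area)
    bh = r.bbox[2] - r.bbox[0]
    bw = r.bbox[3] - r.bbox[1]
    return {
        "area": float(r.area),
        "eqdiameter": equivalent_diameter(r.area),
        "circularity": circularity(boundary_mask),
        "perimeter": float(r.perimeter_crofton),
        "eccentricity": float(r.eccentricity),
        "solidity": float(r.solidity),
        "extent": float(r.extent),
        "major_axis": float(r.axis_major_length),
        "minor_axis": float(r.axis_minor_length),
        "bbox_aspect": float(max(bh, bw) / min(bh, bw)) if min(bh, bw) > 0 else 0.0,
    }


def morphological_features(structure_map: np.ndarray, boundary_mask: np.ndarray) -> dict[str, float]:
    """All 47 morphological biomarkers as a name -> value mapping."""
    masks = {name: structure_map == code for name, code in _STRUCTS.items()}
    masks["glomerulus"] = np.asarray(boundary_mask, bool)
    areas = {k: float(v.sum()) for k, v in masks.items()}
    out: dict[str, float] = {}
    for a, b in _CONTAINMENT_PAIRS:
        out[f"morph_containment_{a}_in_{b}"] = areas[a] / areas[b] if areas[b] > 0 else 0.0
    for s in ("luminal", "tuft", "nuclei"):
        out[f"morph_shape_{s}_eqdiameter"] = equivalent_diameter(areas[s]) if areas[s] else 0.0
        out[f"morph_shape_{s}_circularity"] = circularity(masks[s])
    for s in ("luminal", "tuft"):
        out[f"morph_shape_{s}_solidity"] = solidity(masks[s])
    for a, b in _INTER_PAIRS:
        mean_d, max_d = interstructural_distance(masks[a], masks[b])
        out[f"morph_inter_{a}_to_{b}_mean"] = mean_d
        out[f"morph_inter_{a}_to_{b}_max"] = max_d
    for s in ("luminal", "tuft", "nuclei"):
        mx, med, tot = thickness_features(masks[s])
        out[f"morph_intra_{s}_thickness_max"] = mx
        out[f"morph_intra_{s}_thickness_median"] = med
        out[f"morph_intra_{s}_thickness_total"] = tot
    for k, v in _glom_shape(masks["glomerulus"]).items():
        out[f"morph_glom_{k}"] = v
    return out


# ---------------------------------------------------------------------------
# GLCM


def masked_glcm(gray_levels: np.ndarray, mask: np.ndarray, levels: int = GLCM_LEVELS) -> np.ndarray:
    """Symmetric, normalized co-occurrence matrix at distance 1 averaged over
    the four standard angles, counting only pixel pairs with BOTH pixels
    inside the mask.  Returns a levels x levels matrix summing to 1, or
    zeros when no valid pair exists.
    """
    q = np.asarray(gray_levels)
    mask = np.asarray(mask, bool)
    glcm = np.zeros((levels, levels), dtype=np.float64)
    offsets = ((0, 1), (-1, 1), (-1, 0), (-1, -1))  # 0, 45, 90, 135 degrees
    for dr, dc in offsets:
        h, w = q.shape
        r0, r1 = max(0, -dr), min(h, h - dr)
        c0, c1 = max(0, -dc), min(w, w - dc)
        src = (slice(r0, r1), slice(c0, c1))
        dst = (slice(r0 + dr, r1 + dr), slice(c0 + dc, c1 + dc))
        valid = mask[src] & mask[dst]
        i = q[src][valid].ravel()
        j = q[dst][valid].ravel()
        np.add.at(glcm, (i, j), 1.0)
        np.add.at(glcm, (j, i), 1.0)  # symmetrize
    total = glcm.sum()
    return glcm / total if total > 0 else glcm


def glcm_statistics(glcm: np.ndarray) -> dict[str, float]:
    """Haralick statistics of a normalized GLCM.

    correlation of a zero-variance (single-level) matrix is 1 by convention
    (matching the usual graycoprops behavior); an all-zero matrix yields
    all-zero statistics.
    """
    if glcm.sum() == 0:
        return {k: 0.0 for k in _GLCM_STATS}
    n = glcm.shape[0]
    i, j = np.mgrid[0:n, 0:n]
    contrast = float(np.sum(glcm * (i - j) ** 2))
    mu_i = float(np.sum(i * glcm))
    mu_j = float(np.sum(j * glcm))
    var_i = float(np.sum((i - mu_i) ** 2 * glcm))
    var_j = float(np.sum((j - mu_j) ** 2 * glcm))
    if var_i * var_j > 0:
        corr = float(np.sum((i - mu_i) * (j - mu_j) * glcm) / np.sqrt(var_i * var_j))
    else:
        corr = 1.0
    energy = float(np.sum(glcm**2))
    homog = float(np.sum(glcm / (1.0 + (i - j) ** 2)))
    nz = glcm[glcm > 0]
    entropy = float(-np.sum(nz * np.log2(nz)))
    return {"contrast": contrast, "correlation": corr, "energy": energy, "homogeneity": homog, "entropy": entropy}


def quantize_gray(image: np.ndarray, levels: int = GLCM_LEVELS) -> np.ndarray:
    """Grayscale 0..255 quantized to ``levels`` equal-width bins."""
    gray = skcolor.rgb2gray(np.asarray(image)) * 255.0
    return np.clip((gray / (256.0 / levels)).astype(np.int64), 0, levels - 1)


def glcm_features(image: np.ndarray, mask: np.ndarray, levels: int = GLCM_LEVELS) -> dict[str, float]:
    """Masked Haralick features for one structure; < 2 pixels -> all zeros."""
    mask = np.asarray(mask, bool)
    if mask.sum() < 2:
        return {k: 0.0 for k in _GLCM_STATS}
    q = quantize_gray(image, levels)
    return glcm_statistics(masked_glcm(q, mask, levels))


# ---------------------------------------------------------------------------
# color vector LBP


def lbp_code_image(channel: np.ndarray, P: int = 8, R: float = 1.0) -> np.ndarray:
    """Rotation-invariant uniform LBP codes (0..P+1) for one channel."""
    channel = np.asarray(channel)
    if channel.dtype.kind == "f":
        channel = np.round(channel).astype(np.int64)
    return local_binary_pattern(channel, P, R, method="uniform")


def lbp_features(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Color-vector LBP: concatenated per-channel riu2 histograms (30 values).

    Each channel's 10-bin histogram is restricted to the structure's pixels
    and normalized to sum 1; an empty structure yields zero histograms.
    """
    image = np.asarray(image)
    mask = np.asarray(mask, bool)
    out = np.zeros(3 * _LBP_BINS)
    if not mask.any():
        return out
    for k in range(3):
        codes = lbp_code_image(image[..., k])
        hist = np.bincount(codes[mask].astype(np.int64), minlength=_LBP_BINS)[:_LBP_BINS]
        out[k * _LBP_BINS : (k + 1) * _LBP_BINS] = hist / hist.sum()
    return out


# ---------------------------------------------------------------------------
# wavelets

MIN_WAVELET_SIDE = 8


def wavelet_features(image: np.ndarray, boundary_mask: np.ndarray, wavelet: str = "db4") -> dict[str, float]:
    """Two-level orthogonal wavelet energies and entropies (14 values).

    The grayscale bounding-box crop of the glomerulus, padded with edge
    values to a multiple of 4, is decomposed with ``pywt.wavedec2`` in
    periodization mode (exact Parseval energy conservation for orthogonal
    wavelets on even sizes).  Per subband: energy = sum of squared
    coefficients; entropy = Shannon entropy (bits) of the normalized squared
    coefficients.
    """
    mask = np.asarray(boundary_mask, bool)
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        raise ValueError("boundary mask is empty")
    crop = skcolor.rgb2gray(np.asarray(image)[ys.min() : ys.max() + 1, xs.min() : xs.max() + 1]) * 255.0
    min_side = max(4, pywt.Wavelet(wavelet).dec_len)
    if min(crop.shape) < min_side:
        raise ValueError(f"region must be at least {min_side} px on each side for the {wavelet} filter support")
    pad_r = (-crop.shape[0]) % 4
    pad_c = (-crop.shape[1]) % 4
    if pad_r or pad_c:
        crop = np.pad(crop, ((0, pad_r), (0, pad_c)), mode="edge")
    cA2, (cH2, cV2, cD2), (cH1, cV1, cD1) = pywt.wavedec2(crop, wavelet, level=2, mode="periodization")
    subbands = dict(zip(_WAVELET_SUBBANDS, (cA2, cH2, cV2, cD2, cH1, cV1, cD1)))
    out: dict[str, float] = {}
    for name, c in subbands.items():
        sq = np.square(c).ravel()
        e = float(sq.sum())
        out[f"energy_{name}"] = e
        if e > 0:
            p = sq[sq > 0] / e
            out[f"entropy_{name}"] = float(-np.sum(p * np.log2(p)))
        else:
            out[f"entropy_{name}"] = 0.0
    return out


# ---------------------------------------------------------------------------
# full panel


def extract_all(
    image: np.ndarray,
    structure_map: np.ndarray,
    boundary_mask: np.ndarray,
    registry: FeatureRegistry = DEFAULT_REGISTRY,
) -> pd.Series:
    """Extract the full ordered biomarker vector for one glomerulus.

    Returns a pandas Series of exactly ``len(registry)`` finite values,
    indexed by the registry feature names.
    """
    if len(registry) != 233:
        raise ValueError(f"registry mismatch: expected 233 features, got {len(registry)}")
    image = np.asarray(image)
    structure_map = np.asarray(structure_map)
    boundary_mask = np.asarray(boundary_mask, bool)

    scope_masks = {name: structure_map == code for name, code in _STRUCTS.items()}
    scope_masks["glomerulus"] = boundary_mask
    channels = {ch: channel_image(image, ch) for ch in _CHANNELS}

    values: dict[str, float] = {}
    for scope in _COLOR_SCOPES:
        m = scope_masks[scope]
        for ch in _CHANNELS:
            six = color_features(channels[ch][m])
            for st, v in zip(_COLOR_STATS, six):
                values[f"color_{scope}_{ch}_{st}"] = v

    values.update(morphological_features(structure_map, boundary_mask))

    q = quantize_gray(image)
    for scope in _COLOR_SCOPES:
        m = scope_masks[scope]
        if m.sum() < 2:
            st_vals = {k: 0.0 for k in _GLCM_STATS}
        else:
            st_vals = glcm_statistics(masked_glcm(q, m))
        for st, v in st_vals.items():
            values[f"glcm_{scope}_{st}"] = v

    for scope in _LBP_SCOPES:
        hist = lbp_features(image, scope_masks[scope])
        i = 0
        for ch in ("R", "G", "B"):
            for b in range(_LBP_BINS):
                values[f"lbp_{scope}_{ch}_bin{b:02d}"] = float(hist[i])
                i += 1

    wv = wavelet_features(image, boundary_mask)
    for name in _WAVELET_KEPT:
        values[f"wavelet_{name}"] = wv[name]

    vec = pd.Series([values[n] for n in registry.names], index=registry.names, dtype=np.float64)
    if not np.all(np.isfinite(vec.to_numpy())):
        bad = vec.index[~np.isfinite(vec.to_numpy())].tolist()
        raise AssertionError(f"non-finite biomarkers: {bad}")
    return vec


def extract_table(records, registry: FeatureRegistry = DEFAULT_REGISTRY) -> pd.DataFrame:
    """Feature table for an iterable of phantoms / ROI records.

    One row per glomerulus: patient_id, glom_id, label, then the 233
    registry columns.
    """
    rows = []
    for rec in records:
        vec = extract_all(rec.image, rec.structure_map, rec.boundary_mask, registry)
        row = {"patient_id": rec.patient_id, "glom_id": rec.glom_id, "label": rec.label}
        row.update(vec.to_dict())
        rows.append(row)
    return pd.DataFrame(rows, columns=["patient_id", "glom_id", "label"] + registry.names)
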