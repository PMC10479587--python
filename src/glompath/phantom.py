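"""Synthetic glomerulus phantoms with known sub-glomerular structure masks.

A phantom imitates a PAS-stained glomerulus ROI: an elliptical Bowman
capsule, a lobulated annular glomerular-tuft band (GBM + mesangial matrix)
whose local full-width is drawn from a disease-dependent thickness
distribution, elliptical nuclei scattered over tuft and luminal regions, and
per-structure Gaussian color models imitating PAS chromatics (pale luminal,
magenta tuft, dark blue-purple nuclei).  The three disease presets differ
chiefly in tuft thickness (MN thick > MCD intermediate > TBMN thin) and
mildly in nuclei geometry, which are exactly the axes the downstream
biomarkers are designed to measure.

Phantoms are not photorealistic histology; they exist so that every stage of
the pipeline (segmentation, 233-feature extraction, selection, LDA,
patient aggregation) can be exercised and validated end to end with known
ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

# structure label codes, shared with segmentation / features
BACKGROUND, LUMINAL, TUFT, NUCLEI = 0, 1, 2, 3
STRUCTURE_NAMES = {BACKGROUND: "background", LUMINAL: "luminal", TUFT: "tuft", NUCLEI: "nuclei"}

DISEASES = ("MCD", "MN", "TBMN")

#: reference canvas the preset geometry (in px) is expressed on
REFERENCE_SIZE = 1500


@dataclass(frozen=True)
class DiseaseProfile:
    """Geometry and color parameters for one disease class.

    All lengths are pixels on a canvas of ``image_size`` px (default 1500,
    the nominal ROI size).  ``tuft_thickness_mean`` is the full width of the
    tuft band, so the maximum of the Euclidean distance transform inside the
    band is about half of it.
    """

    label: str
    tuft_thickness_mean: float
    tuft_thickness_sd: float
    nuclei_count_range: tuple[int, int]
    nuclei_radius_range: tuple[float, float]
    capsule_radius_range: tuple[float, float]
    # per structure: (mean RGB triplet, per-channel sd)
    structure_color_params: dict[int, tuple[tuple[float, float, float], float]] = field(
        default_factory=lambda: dict(DEFAULT_COLORS)
    )
    image_size: int = REFERENCE_SIZE
    blur_sigma: float = 0.6

    def __post_init__(self) -> None:
        if self.tuft_thickness_mean <= 0 or self.tuft_thickness_sd < 0:
            raise ValueError("tuft thickness mean must be > 0 and sd >= 0")
        for lo, hi in (self.nuclei_count_range, self.nuclei_radius_range, self.capsule_radius_range):
            if hi < lo:
                raise ValueError("ranges must be non-empty (hi >= lo)")
        if self.nuclei_count_range[0] < 0:
            raise ValueError("nuclei count must be >= 0")
        for mean, _sd in self.structure_color_params.values():
            if not all(0 <= m <= 255 for m in mean):
                raise ValueError("color means must lie in [0, 255]")

    def scaled(self, image_size: int) -> "DiseaseProfile":
        """Return the profile with all lengths rescaled to a new canvas size."""
        f = image_size / self.image_size
        return replace(
            self,
            image_size=image_size,
            tuft_thickness_mean=self.tuft_thickness_mean * f,
            tuft_thickness_sd=self.tuft_thickness_sd * f,
            nuclei_radius_range=(self.nuclei_radius_range[0] * f, self.nuclei_radius_range[1] * f),
            capsule_radius_range=(self.capsule_radius_range[0] * f, self.capsule_radius_range[1] * f),
        )


# PAS-like palette.  Identical across the disease presets so that the planted
# class contrasts are geometric (thickness, nuclei), not trivial color
# shortcuts.  Hue(luminal pale pink) > hue(magenta tuft) on the [0,255] hue
# scale, matching the direction "more luminal area -> higher mean hue".
DEFAULT_COLORS: dict[int, tuple[tuple[float, float, float], float]] = {
    LUMINAL: ((246.0, 233.0, 240.0), 4.0),
    TUFT: ((180.0, 70.0, 170.0), 12.0),
    NUCLEI: ((70.0, 60.0, 120.0), 8.0),
}

BACKGROUND_COLOR = (248.0, 248.0, 248.0)


def default_profiles(image_size: int = REFERENCE_SIZE) -> dict[str, DiseaseProfile]:
    """Default disease presets, geometry scaled to ``image_size``.

    Thickness ordering MN > MCD > TBMN mirrors capillary-wall thickening in
    MN and thinning in TBMN; MCD glomeruli look closest to normal.
    """
    presets = {
        "MCD": DiseaseProfile(
            label="MCD",
            tuft_thickness_mean=36.0,
            tuft_thickness_sd=6.0,
            nuclei_count_range=(45, 65),
            nuclei_radius_range=(14.0, 24.0),
            capsule_radius_range=(520.0, 650.0),
        ),
        "MN": DiseaseProfile(
            label="MN",
            tuft_thickness_mean=60.0,
            tuft_thickness_sd=8.0,
            nuclei_count_range=(35, 55),
            nuclei_radius_range=(16.0, 26.0),
            capsule_radius_range=(520.0, 650.0),
        ),
        "TBMN": DiseaseProfile(
            label="TBMN",
            tuft_thickness_mean=16.0,
            tuft_thickness_sd=3.0,
            nuclei_count_range=(45, 65),
            nuclei_radius_range=(13.0, 21.0),
            capsule_radius_range=(520.0, 650.0),
        ),
    }
    if image_size != REFERENCE_SIZE:
        presets = {k: p.scaled(image_size) for k, p in presets.items()}
    return presets


@dataclass
class Phantom:
    image: np.ndarray  # H x W x 3 uint8
    structure_map: np.ndarray  # H x W uint8, codes above
    boundary_mask: np.ndarray  # H x W bool
    label: str
    patient_id: str
    glom_id: str
    seed: int


def _smooth_periodic(values: np.ndarray, sigma: float) -> np.ndarray:
    return ndimage.gaussian_filter1d(values, sigma=sigma, mode="wrap")


def generate_glomerulus(
    profile: DiseaseProfile, seed: int, *, patient_id: str = "p0", glom_id: str = "g0"
) -> Phantom:
    """Generate one synthetic glomerulus ROI; deterministic in (profile, seed).

    The capsule is an axis-aligned-ish ellipse; the tuft is an annular band
    around a lobulated mid-contour whose local full-width follows
    N(tuft_thickness_mean, tuft_thickness_sd); nuclei are ellipses scattered
    over tuft and luminal regions.  Colors are sampled per pixel from the
    structure color model and lightly blurred.
    """
    size = int(profile.image_size)
    rng = np.random.default_rng(seed)

    r_lo, r_hi = profile.capsule_radius_range
    a = rng.uniform(r_lo, r_hi)
    b = rng.uniform(r_lo, r_hi)
    if profile.tuft_thickness_mean >= min(a, b):
        raise ValueError(
            f"degenerate geometry: tuft thickness {profile.tuft_thickness_mean:.1f}px "
            f"exceeds capsule radius {min(a, b):.1f}px"
        )
    theta0 = rng.uniform(0, np.pi)
    cy = size / 2 + rng.uniform(-0.02, 0.02) * size
    cx = size / 2 + rng.uniform(-0.02, 0.02) * size

    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    dy, dx = yy - cy, xx - cx
    ct, st = np.cos(theta0), np.sin(theta0)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    # radius of the capsule ellipse along each pixel's direction
    rho = np.hypot(u, v)
    with np.errstate(invalid="ignore"):
        ang = np.arctan2(v, u)
    r_capsule = (a * b) / np.sqrt((b * np.cos(ang)) ** 2 + (a * np.sin(ang)) ** 2)
    boundary_mask = rho <= r_capsule

    # lobulated tuft mid-contour: fraction of capsule radius, low-frequency
    # Fourier perturbation, smooth thickness profile along angle
    n_ang = 720
    grid = np.linspace(-np.pi, np.pi, n_ang, endpoint=False)
    lob = np.zeros(n_ang)
    for k in (2, 3, 5):
        lob += rng.uniform(0.0, 0.05) * np.cos(k * grid + rng.uniform(0, 2 * np.pi))
    mid_frac = 0.72 + lob
    width = rng.normal(profile.tuft_thickness_mean, profile.tuft_thickness_sd, n_ang)
    width = _smooth_periodic(width, sigma=12.0)
    width = np.clip(width, 1.0, None)

    idx = np.floor((ang + np.pi) / (2 * np.pi) * n_ang).astype(int) % n_ang
    r_mid = mid_frac[idx] * r_capsule
    half_w = width[idx] / 2.0
    tuft_mask = boundary_mask & (np.abs(rho - r_mid) <= half_w)

    structure_map = np.zeros((size, size), dtype=np.uint8)
    structure_map[boundary_mask] = LUMINAL
    structure_map[tuft_mask] = TUFT

    # nuclei: small ellipses centered on tuft or luminal pixels
    n_nuc = int(rng.integers(profile.nuclei_count_range[0], profile.nuclei_count_range[1] + 1))
    if n_nuc > 0:
        inner = ndimage.binary_erosion(boundary_mask, iterations=max(1, int(profile.nuclei_radius_range[1])))
        cand_y, cand_x = np.nonzero(inner)
        if cand_y.size:
            pick = rng.integers(0, cand_y.size, n_nuc)
            for i in pick:
                ny, nx = cand_y[i], cand_x[i]
                ra = rng.uniform(*profile.nuclei_radius_range)
                rb = ra * rng.uniform(0.6, 1.0)
                phi = rng.uniform(0, np.pi)
                rmax = int(np.ceil(ra)) + 1
                ys = slice(max(0, ny - rmax), min(size, ny + rmax + 1))
                xs = slice(max(0, nx - rmax), min(size, nx + rmax + 1))
                ly, lx = np.mgrid[ys, xs].astype(np.float64)
                du = (lx - nx) * np.cos(phi) + (ly - ny) * np.sin(phi)
                dv = -(lx - nx) * np.sin(phi) + (ly - ny) * np.cos(phi)
                ell = (du / ra) ** 2 + (dv / rb) ** 2 <= 1.0
                sub = structure_map[ys, xs]
                sub[ell & (sub != BACKGROUND)] = NUCLEI

    # colorize
    image = np.empty((size, size, 3), dtype=np.float64)
    image[...] = BACKGROUND_COLOR
    for code, (mean, sd) in profile.structure_color_params.items():
        m = structure_map == code
        n = int(m.sum())
        if n:
            image[m] = np.asarray(mean) + rng.normal(0.0, sd, (n, 3))
    if profile.blur_sigma > 0:
        image = ndimage.gaussian_filter(image, sigma=(profile.blur_sigma, profile.blur_sigma, 0))
    image = np.clip(np.round(image), 0, 255).astype(np.uint8)

    return Phantom(
        image=image,
        structure_map=structure_map,
        boundary_mask=boundary_mask,
        label=profile.label,
        patient_id=patient_id,
        glom_id=glom_id,
        seed=seed,
    )


#: patient-level random effects: biopsies differ in staining and morphometry
#: even within one disease, so each patient perturbs the disease preset —
#: a multiplicative jitter on tuft thickness and an additive per-structure
#: stain shift (slide-to-slide color variability, the effect Reinhard
#: normalization is there to remove).
PATIENT_THICKNESS_JITTER = 0.10
PATIENT_COLOR_SHIFT_SD = 7.0


def _patient_profile(profile: DiseaseProfile, rng: np.random.Generator) -> DiseaseProfile:
    scale = float(np.clip(rng.normal(1.0, PATIENT_THICKNESS_JITTER), 0.7, 1.3))
    shift = rng.normal(0.0, PATIENT_COLOR_SHIFT_SD, 3)
    colors = {
        code: (tuple(np.clip(np.asarray(mean) + shift, 0, 255)), sd)
        for code, (mean, sd) in profile.structure_color_params.items()
    }
    return replace(
        profile,
        tuft_thickness_mean=profile.tuft_thickness_mean * scale,
        structure_color_params=colors,
    )


def generate_cohort(
    n_patients_per_disease: int,
    glomeruli_per_patient: tuple[int, int] = (6, 10),
    master_seed: int = 0,
    *,
    profiles: dict[str, DiseaseProfile] | None = None,
    image_size: int | None = None,
    patient_effects: bool = True,
) -> tuple[list[Phantom], pd.DataFrame]:
    """Generate a patient-structured phantom cohort plus a manifest table.

    Every patient carries one disease label shared by all of their glomeruli;
    the manifest holds one row per glomerulus.  Seeding is hierarchical
    (master seed -> per-glomerulus substream) so cohorts are reproducible and
    individual phantoms can be regenerated in isolation.  With
    ``patient_effects`` on (default) each patient's geometry and stain
    colors are jittered around the disease preset, emulating biopsy-to-biopsy
    variability.
    """
    if n_patients_per_disease < 1:
        raise ValueError("need at least one patient per disease")
    if profiles is None:
        profiles = default_profiles(image_size or REFERENCE_SIZE)
    elif image_size is not None:
        profiles = {k: p.scaled(image_size) for k, p in profiles.items()}

    master = np.random.default_rng(master_seed)
    phantoms: list[Phantom] = []
    rows = []
    pid_counter = 0
    for disease in DISEASES:
        base_profile = profiles[disease]
        for _ in range(n_patients_per_disease):
            pid_counter += 1
            patient_id = f"P{pid_counter:03d}"
            profile = _patient_profile(base_profile, master) if patient_effects else base_profile
            n_glom = int(master.integers(glomeruli_per_patient[0], glomeruli_per_patient[1] + 1))
            for g in range(n_glom):
                glom_id = f"{patient_id}_g{g:02d}"
                sub_seed = int(master.integers(0, 2**31 - 1))
                ph = generate_glomerulus(profile, sub_seed, patient_id=patient_id, glom_id=glom_id)
                phantoms.append(ph)
                rows.append(
                    {
                        "patient_id": patient_id,
                        "glom_id": glom_id,
                        "label": disease,
                        "image_path": f"{glom_id}_image.png",
                        "mask_path": f"{glom_id}_mask.png",
                        "structmap_path": f"{glom_id}_structmap.png",
                    }
                )
    return phantoms, pd.DataFrame(rows)


def write_cohort(phantoms: list[Phantom], manifest: pd.DataFrame, out_dir) -> None:
    """Write images / masks / structure maps as PNG and the manifest CSV."""
    import imageio.v3 as iio
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for ph, (_, row) in zip(phantoms, manifest.iterrows()):
        iio.imwrite(out / row["image_path"], ph.image)
        iio.imwrite(out / row["mask_path"], (ph.boundary_mask * 255).astype(np.uint8))
        iio.imwrite(out / row["structmap_path"], ph.structure_map)
    manifest.to_csv(out / "manifest.csv", index=False)
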