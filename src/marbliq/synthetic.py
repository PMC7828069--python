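"""Synthetic cutlet images and feature tables with exact ground truth.

Real loin-cutlet photographs and the matched chemical intramuscular-fat
(IMF) determinations behind this kind of study are rarely published, so
every downstream stage here is exercised on synthetic data whose ground
truth is known by construction:

* :func:`generate_cutlet_image` paints a cutlet-like scene — dark
  background, a mid-gray muscle blob (the LTL region of interest), bright
  non-overlapping fat flecks inside it, and a subcutaneous fat band along
  its upper edge — and returns exact per-particle pixel areas and masks.
* :func:`generate_feature_table` draws the 13-predictor measurement table
  (carcass weight, CIELAB color, image-analysis variables) within the
  published descriptive ranges of the study population, and generates the
  IMF% response through a known smooth, monotone link with a
  backfat-by-weight interaction, plus Gaussian measurement noise.

Both generators are fully deterministic given a seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .imaging import CalibratedImage, rle_decode, rle_encode

__all__ = [
    "ImageGroundTruth",
    "TableGroundTruth",
    "DEFAULT_LINK",
    "POPULATION_RANGES",
    "generate_cutlet_image",
    "generate_feature_table",
    "save_ground_truth",
    "load_ground_truth",
]

#: Published min/max of each measured variable in the study population
#: (carcass weight in kg, color in CIELAB units, geometry in cm/cm²,
#: Marb_area in mm², Marb_area% and IMF% in percent).
POPULATION_RANGES: dict[str, tuple[float, float]] = {
    "IMF%": (0.62, 2.08),
    "CW": (14.9, 89.3),
    "L*": (44.8, 61.9),
    "a*": (0.99, 13.6),
    "b*": (6.84, 14.6),
    "C*": (9.00, 17.0),
    "H*": (34.1, 83.8),
    "Width": (5.3, 12.0),
    "Height": (2.74, 8.75),
    "REA": (11.7, 55.0),
    "BFT": (0.39, 6.05),
    "NOParticles": (16, 59),
    "Marb_area": (0.14, 2.03),
    "Marb_area%": (1.03, 3.92),
}


@dataclass(frozen=True)
class ImageGroundTruth:
    """Exact construction record for one synthetic cutlet image."""

    roi_mask: np.ndarray
    fleck_mask: np.ndarray
    fleck_areas_px: tuple[int, ...]
    fat_band_mask: np.ndarray
    mm_per_px: float
    true_marb_area_pct: float
    artifact_mask: np.ndarray | None = None
    artifact_areas_px: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        roi = np.asarray(self.roi_mask, dtype=bool)
        flecks = np.asarray(self.fleck_mask, dtype=bool)
        band = np.asarray(self.fat_band_mask, dtype=bool)
        if (flecks & ~roi).any():
            raise ValueError("fleck mask is not a subset of the ROI mask")
        if (band & roi).any():
            raise ValueError("fat-band mask overlaps the ROI mask")
        if int(flecks.sum()) != sum(self.fleck_areas_px):
            raise ValueError("fleck_areas_px does not sum to the fleck mask area")


@dataclass(frozen=True)
class TableGroundTruth:
    """The generating link of a synthetic feature table.

    ``link_params`` are the coefficients of
    ``IMF% = b0 + b1*BFT + b2*Marb_area% + b3*BFT*CW/100``; ``noise_sd``
    is the SD of the additive Gaussian measurement noise (percent IMF).
    """

    link_name: str = "bft_cw_marb_interaction"
    link_params: dict = field(
        default_factory=lambda: {"b0": 0.45, "b1": 0.12, "b2": 0.10, "b3": 0.10}
    )
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be nonnegative, got {self.noise_sd}")

    def evaluate(self, bft, cw, marb_area_pct):
        """Noise-free link value for the given predictors."""
        p = self.link_params
        bft = np.asarray(bft, dtype=float)
        cw = np.asarray(cw, dtype=float)
        marb = np.asarray(marb_area_pct, dtype=float)
        return p["b0"] + p["b1"] * bft + p["b2"] * marb + p["b3"] * bft * cw / 100.0


DEFAULT_LINK = TableGroundTruth()


# ---------------------------------------------------------------------------
# Cutlet image generation
# ---------------------------------------------------------------------------

def _blob_mask(
    height_px: int, width_px: int, rng: np.random.Generator
) -> np.ndarray:
    """Smooth perturbed-ellipse blob occupying the central image region."""
    cy = height_px * rng.uniform(0.52, 0.60)  # leave headroom for the fat band
    cx = width_px * rng.uniform(0.46, 0.54)
    ry = height_px * rng.uniform(0.26, 0.32)
    rx = width_px * rng.uniform(0.30, 0.38)
    rows, cols = np.mgrid[0:height_px, 0:width_px]
    dy = (rows - cy) / ry
    dx = (cols - cx) / rx
    rho = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx)
    boundary = np.ones_like(rho)
    for k in (2, 3, 4):
        boundary += rng.uniform(0.0, 0.06) * np.cos(k * theta + rng.uniform(0, 2 * np.pi))
    return rho <= boundary


def _ellipse_pixels(
    center: tuple[float, float],
    area_px: float,
    aspect: float,
    angle: float,
    shape: tuple[int, int],
) -> np.ndarray:
    """Boolean mask of a rotated ellipse with approximately ``area_px`` pixels."""
    # semi-axes from target area: pi*a*b = area, b = aspect*a
    a = np.sqrt(area_px / (np.pi * aspect))
    b = aspect * a
    cy, cx = center
    half = int(np.ceil(max(a, b))) + 1
    r0, r1 = int(np.floor(cy)) - half, int(np.ceil(cy)) + half + 1
    c0, c1 = int(np.floor(cx)) - half, int(np.ceil(cx)) + half + 1
    mask = np.zeros(shape, dtype=bool)
    if r0 < 0 or c0 < 0 or r1 > shape[0] or c1 > shape[1]:
        return mask  # would clip at the border; caller retries
    rows, cols = np.mgrid[r0:r1, c0:c1]
    dy, dx = rows - cy, cols - cx
    cos_t, sin_t = np.cos(angle), np.sin(angle)
    u = cos_t * dx + sin_t * dy
    v = -sin_t * dx + cos_t * dy
    mask[r0:r1, c0:c1] = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return mask


def _place_particles(
    rng: np.random.Generator,
    areas: np.ndarray,
    interior: np.ndarray,
    occupied: np.ndarray,
    shape: tuple[int, int],
    max_tries: int = 400,
) -> tuple[np.ndarray, list[int]]:
    """Rejection-sample non-touching particles inside ``interior``.

    Particles are kept 8-disconnected from each other (a one-pixel dilated
    footprint must not touch previously placed particles) so that
    connected-component labelling recovers each one individually, and the
    recorded per-particle pixel areas stay exact.
    """
    from scipy import ndimage

    placed = np.zeros(shape, dtype=bool)
    pixel_areas: list[int] = []
    rows, cols = np.nonzero(interior)
    if rows.size == 0:
        raise ValueError("ROI interior too small to place particles")
    for target in areas:
        ok = False
        for _ in range(max_tries):
            i = rng.integers(rows.size)
            center = (float(rows[i]) + rng.uniform(-0.5, 0.5),
                      float(cols[i]) + rng.uniform(-0.5, 0.5))
            aspect = rng.uniform(0.5, 1.0)
            angle = rng.uniform(0, np.pi)
            mask = _ellipse_pixels(center, float(target), aspect, angle, shape)
            n_px = int(mask.sum())
            if n_px == 0 or (mask & ~interior).any():
                continue
            if target >= 10 and n_px < 10:
                continue  # rasterization undershot the size filter
            if target < 10 and not 1 <= n_px <= 9:
                continue
            grown = ndimage.binary_dilation(mask, structure=np.ones((3, 3)))
            if (grown & (occupied | placed)).any():
                continue
            placed |= mask
            pixel_areas.append(n_px)
            ok = True
            break
        if not ok:
            raise RuntimeError(
                "could not place a particle without overlap; "
                "reduce n_flecks or fleck_area_px_mean"
            )
    return placed, pixel_areas


def generate_cutlet_image(
    width_px: int = 360,
    height_px: int = 280,
    mm_per_px: float = 0.03,
    n_flecks: int = 30,
    fleck_area_px_mean: float = 25.0,
    muscle_gray: int = 120,
    fleck_gray: int = 220,
    noise_sd: float = 0.0,
    seed: int = 0,
    *,
    background_gray: int = 8,
    band_gray: int = 235,
    fleck_area_px_sigma: float = 0.35,
    inject_artifacts: int = 0,
    band_thickness_px: int | None = None,
) -> tuple[CalibratedImage, ImageGroundTruth]:
    """Generate one synthetic cutlet photograph with exact ground truth.

    The scene is a dark background, a smooth perturbed-ellipse muscle ROI
    at ``muscle_gray``, ``n_flecks`` non-overlapping elliptical fat flecks
    at ``fleck_gray`` with lognormal pixel areas (truncated at >= 10 px so
    each planted fleck survives the particle-size filter), and a
    subcutaneous fat band hugging the upper ROI edge. ``inject_artifacts``
    additionally plants that many 1–9 px specks, recorded separately in
    the ground truth, to exercise the artefact filter.

    Gaussian pixel noise of SD ``noise_sd`` gray levels is added last;
    with ``noise_sd=0`` the image is piecewise-constant and segmentation
    recovers the ground truth exactly.

    Returns the calibrated image and an :class:`ImageGroundTruth` whose
    ``true_marb_area_pct`` is computed from the masks themselves.
    """
    if fleck_gray <= muscle_gray:
        raise ValueError("fleck_gray must exceed muscle_gray (fat is brighter)")
    if background_gray >= muscle_gray:
        raise ValueError("background_gray must be below muscle_gray")
    if n_flecks < 0 or inject_artifacts < 0:
        raise ValueError("particle counts must be nonnegative")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    if not mm_per_px > 0:
        raise ValueError("mm_per_px must be positive")

    rng = np.random.default_rng(seed)
    shape = (height_px, width_px)
    roi = _blob_mask(height_px, width_px, rng)
    roi_area = int(roi.sum())
    if roi_area == 0:
        raise ValueError("image too small for a muscle ROI")
    if n_flecks * fleck_area_px_mean > 0.5 * roi_area:
        raise ValueError(
            "requested fleck load exceeds 50% of the ROI area; "
            "real marbling fractions are a few percent"
        )

    from scipy import ndimage

    # flecks must sit strictly inside the ROI, clear of its boundary
    interior = ndimage.binary_erosion(roi, structure=np.ones((3, 3)), iterations=2)

    # lognormal areas truncated at the particle-size filter (>= 10 px)
    mu = np.log(fleck_area_px_mean) - fleck_area_px_sigma**2 / 2
    areas = np.empty(n_flecks)
    filled = 0
    while filled < n_flecks:
        draw = rng.lognormal(mu, fleck_area_px_sigma, size=n_flecks - filled)
        draw = draw[draw >= 10]
        areas[filled : filled + draw.size] = draw
        filled += draw.size

    fleck_mask, fleck_areas = _place_particles(rng, areas, interior, np.zeros(shape, bool), shape)

    artifact_mask = np.zeros(shape, dtype=bool)
    artifact_areas: list[int] = []
    if inject_artifacts:
        small = rng.integers(1, 10, size=inject_artifacts).astype(float)
        artifact_mask, artifact_areas = _place_particles(
            rng, small, interior, fleck_mask, shape
        )

    # subcutaneous fat band: rides the upper ROI boundary with a small gap
    band = np.zeros(shape, dtype=bool)
    thickness = band_thickness_px or int(rng.integers(12, 26))
    gap = 3
    col_has_roi = roi.any(axis=0)
    top_row = np.where(col_has_roi, roi.argmax(axis=0), -1)
    for col in np.flatnonzero(col_has_roi):
        hi = top_row[col] - gap
        lo = max(hi - thickness, 0)
        if hi > lo:
            band[lo:hi, col] = True
    band &= ~roi  # defensive: construction already guarantees disjointness

    image = np.full(shape, background_gray, dtype=float)
    image[roi] = muscle_gray
    image[fleck_mask] = fleck_gray
    image[artifact_mask] = fleck_gray
    image[band] = band_gray
    if noise_sd > 0:
        image += rng.normal(0.0, noise_sd, size=shape)
    pixels = np.clip(np.round(image), 0, 255).astype(np.uint8)

    truth = ImageGroundTruth(
        roi_mask=roi,
        fleck_mask=fleck_mask,
        fleck_areas_px=tuple(fleck_areas),
        fat_band_mask=band,
        mm_per_px=mm_per_px,
        true_marb_area_pct=100.0 * int(fleck_mask.sum()) / roi_area,
        artifact_mask=artifact_mask if inject_artifacts else None,
        artifact_areas_px=tuple(artifact_areas),
    )
    return CalibratedImage(pixels, mm_per_px), truth


# ---------------------------------------------------------------------------
# Feature table generation
# ---------------------------------------------------------------------------

def generate_feature_table(
    n_samples: int,
    seed: int = 0,
    link: TableGroundTruth = DEFAULT_LINK,
) -> pd.DataFrame:
    """Draw a synthetic measurement table within the published ranges.

    Each of the 13 predictors is sampled inside its population min/max;
    chroma C* and hue angle H* are computed from the sampled a*, b* (with
    rejection so they also respect their own published ranges), and the
    rib eye area is kept below its bounding box. IMF% is the link value
    plus N(0, ``link.noise_sd``) noise. Returns a DataFrame with the
    standard column names, one row per measurement.
    """
    if n_samples < 10:
        raise ValueError(f"n_samples must be >= 10, got {n_samples}")
    rng = np.random.default_rng(seed)
    R = POPULATION_RANGES

    def unif(name, size):
        lo, hi = R[name]
        return rng.uniform(lo, hi, size=size)

    n = n_samples
    cw = unif("CW", n)
    lstar = unif("L*", n)

    # a*/b* with derived chroma and hue kept inside their published ranges
    a = np.empty(n)
    b = np.empty(n)
    todo = np.arange(n)
    while todo.size:
        a_try = unif("a*", todo.size)
        b_try = unif("b*", todo.size)
        c_try = np.hypot(a_try, b_try)
        h_try = np.degrees(np.arctan2(b_try, a_try))
        ok = (
            (R["C*"][0] <= c_try) & (c_try <= R["C*"][1])
            & (R["H*"][0] <= h_try) & (h_try <= R["H*"][1])
        )
        a[todo[ok]] = a_try[ok]
        b[todo[ok]] = b_try[ok]
        todo = todo[~ok]
    chroma = np.hypot(a, b)
    hue = np.degrees(np.arctan2(b, a))

    width = unif("Width", n)
    height = unif("Height", n)
    rea = np.empty(n)
    for i in range(n):
        upper = min(R["REA"][1], 0.85 * width[i] * height[i])
        while upper <= R["REA"][0]:
            width[i] = unif("Width", 1)[0]
            height[i] = unif("Height", 1)[0]
            upper = min(R["REA"][1], 0.85 * width[i] * height[i])
        rea[i] = rng.uniform(R["REA"][0], upper)

    bft = unif("BFT", n)
    lo, hi = R["NOParticles"]
    n_particles = rng.integers(int(lo), int(hi) + 1, size=n)
    marb_area = unif("Marb_area", n)
    marb_pct = unif("Marb_area%", n)

    imf = link.evaluate(bft, cw, marb_pct)
    if link.noise_sd > 0:
        imf = imf + rng.normal(0.0, link.noise_sd, size=n)

    return pd.DataFrame(
        {
            "sample_id": [f"S{i + 1:03d}" for i in range(n)],
            "IMF%": imf,
            "CW": cw,
            "L*": lstar,
            "a*": a,
            "b*": b,
            "C*": chroma,
            "H*": hue,
            "Width": width,
            "Height": height,
            "REA": rea,
            "BFT": bft,
            "NOParticles": n_particles,
            "Marb_area": marb_area,
            "Marb_area%": marb_pct,
        }
    )


# ---------------------------------------------------------------------------
# Ground-truth sidecar I/O
# ---------------------------------------------------------------------------

def save_ground_truth(truth: ImageGroundTruth, path) -> None:
    """Write an image ground truth as a JSON sidecar with RLE masks."""
    payload = {
        "roi_mask": rle_encode(truth.roi_mask),
        "fleck_mask": rle_encode(truth.fleck_mask),
        "fleck_areas_px": list(truth.fleck_areas_px),
        "fat_band_mask": rle_encode(truth.fat_band_mask),
        "mm_per_px": truth.mm_per_px,
        "true_marb_area_pct": truth.true_marb_area_pct,
        "artifact_areas_px": list(truth.artifact_areas_px),
    }
    if truth.artifact_mask is not None:
        payload["artifact_mask"] = rle_encode(truth.artifact_mask)
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_ground_truth(path) -> ImageGroundTruth:
    with open(path) as fh:
        payload = json.load(fh)
    return ImageGroundTruth(
        roi_mask=rle_decode(payload["roi_mask"]),
        fleck_mask=rle_decode(payload["fleck_mask"]),
        fleck_areas_px=tuple(payload["fleck_areas_px"]),
        fat_band_mask=rle_decode(payload["fat_band_mask"]),
        mm_per_px=payload["mm_per_px"],
        true_marb_area_pct=payload["true_marb_area_pct"],
        artifact_mask=(
            rle_decode(payload["artifact_mask"]) if "artifact_mask" in payload else None
        ),
        artifact_areas_px=tuple(payload.get("artifact_areas_px", ())),
    )
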