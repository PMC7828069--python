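"""Calibrated-image morphometry and marbling-fleck extraction.

The measurements mirror the standard loin-cutlet image-analysis workflow:
a region of interest (ROI) outlining the Longissimus thoracis et lumborum
(LTL) cross-section, a gray-level threshold that isolates the bright
intramuscular fat flecks, connected-component particle analysis with a
minimum-size filter, and axis-aligned muscle/backfat morphometry, all
expressed in physical units through a known mm-per-pixel scale.

Coordinate convention: row-major, 0-based, origin at the top-left corner.
Marbling polarity: fat is brighter than muscle, so a pixel belongs to a
fleck when its gray value is *greater than or equal to* the threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage.filters import threshold_otsu

__all__ = [
    "CalibratedImage",
    "MarblingResult",
    "Morphometry",
    "to_gray8",
    "anchored_threshold",
    "otsu_threshold",
    "extract_marbling",
    "measure_morphometry",
    "rle_encode",
    "rle_decode",
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
]

# ITU-R BT.601 luma weights used for RGB -> 8-bit gray conversion.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class CalibratedImage:
    """A pixel raster with a physical scale.

    Parameters
    ----------
    pixels : ndarray
        ``(H, W)`` single-channel or ``(H, W, 3)`` RGB raster of 8-bit
        intensities.
    mm_per_px : float
        Side length of one pixel in millimetres; must be positive.
    """

    pixels: np.ndarray
    mm_per_px: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.size == 0:
            raise ValueError("pixel raster is empty")
        if px.ndim not in (2, 3) or (px.ndim == 3 and px.shape[2] != 3):
            raise ValueError(
                f"expected a 2-D gray or (H, W, 3) RGB raster, got shape {px.shape}"
            )
        if not self.mm_per_px > 0:
            raise ValueError(f"mm_per_px must be positive, got {self.mm_per_px}")
        object.__setattr__(self, "pixels", px)

    @property
    def is_gray(self) -> bool:
        return self.pixels.ndim == 2

    @property
    def shape(self) -> tuple[int, ...]:
        return self.pixels.shape


@dataclass(frozen=True)
class MarblingResult:
    """Particle-analysis outputs for one cutlet ROI.

    ``n_particles`` (NOParticles) counts the flecks surviving the
    minimum-size filter, ``marb_area_mm2`` (Marb_area) is their summed
    physical area and ``marb_area_pct`` (Marb_area%) is that area as a
    percentage of the ROI area.
    """

    threshold: int
    particle_areas_px: tuple[int, ...]
    n_particles: int
    marb_area_mm2: float
    marb_area_pct: float
    min_particle_px: int = 10

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "particle_areas_px": list(self.particle_areas_px),
            "NOParticles": self.n_particles,
            "Marb_area": self.marb_area_mm2,
            "Marb_area%": self.marb_area_pct,
            "min_particle_px": self.min_particle_px,
        }


@dataclass(frozen=True)
class Morphometry:
    """Axis-aligned muscle and backfat measurements in centimetres.

    ``width_cm``/``height_cm`` are the maximum horizontal/vertical extents
    of the LTL ROI, ``rea_cm2`` the rib eye area, and ``bft_cm`` the
    backfat thickness taken as the longest vertical run of the
    subcutaneous fat band.
    """

    width_cm: float
    height_cm: float
    rea_cm2: float
    bft_cm: float

    def to_dict(self) -> dict:
        return {
            "Width": self.width_cm,
            "Height": self.height_cm,
            "REA": self.rea_cm2,
            "BFT": self.bft_cm,
        }


def to_gray8(image: CalibratedImage) -> CalibratedImage:
    """Convert an RGB image to a single-channel 8-bit gray image.

    Gray = round(0.299 R + 0.587 G + 0.114 B), clipped to [0, 255].
    A gray input is returned unchanged; the mm-per-pixel scale is
    preserved.
    """
    if image.is_gray:
        return image
    gray = np.clip(np.round(image.pixels.astype(float) @ _LUMA), 0, 255)
    return CalibratedImage(gray.astype(np.uint8), image.mm_per_px)


def _check_gray_and_roi(gray: CalibratedImage, roi: np.ndarray) -> np.ndarray:
    if not gray.is_gray:
        raise ValueError("expected a single-channel gray image; call to_gray8 first")
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != gray.pixels.shape:
        raise ValueError(
            f"ROI shape {roi.shape} does not match image shape {gray.pixels.shape}"
        )
    return roi


def anchored_threshold(
    gray: CalibratedImage,
    roi: np.ndarray,
    anchor_points,
    margin: int = 0,
) -> int:
    """Threshold from operator-identified marbling anchor pixels.

    Emulates the manual protocol of identifying a handful of pixels that
    are unequivocally marbling and reading the gray histogram: the
    returned threshold is the minimum anchor gray value minus ``margin``,
    so every anchor pixel is >= the threshold.

    ``anchor_points`` is a sequence of ``(row, col)`` coordinates that
    must lie inside the ROI.
    """
    roi = _check_gray_and_roi(gray, roi)
    anchors = [tuple(p) for p in anchor_points]
    if not anchors:
        raise ValueError("at least one anchor point is required (or use otsu_threshold)")
    values = []
    for r, c in anchors:
        if not (0 <= r < roi.shape[0] and 0 <= c < roi.shape[1]) or not roi[r, c]:
            raise ValueError(f"anchor point ({r}, {c}) lies outside the ROI")
        values.append(int(gray.pixels[r, c]))
    return max(min(values) - int(margin), 0)


def otsu_threshold(gray: CalibratedImage, roi: np.ndarray) -> int:
    """Automated fallback threshold over ROI pixels only.

    Maximizes the between-class variance of the two gray-level classes
    ``{< t}`` and ``{>= t}`` over the 8-bit histogram of the ROI pixels.
    """
    roi = _check_gray_and_roi(gray, roi)
    vals = gray.pixels[roi]
    if vals.size == 0:
        raise ValueError("ROI is empty")
    if np.all(vals == vals[0]):
        raise ValueError("degenerate histogram: ROI contains a single gray value")
    counts = np.bincount(vals.astype(np.int64), minlength=256)
    # skimage partitions as {<= t} / {> t}; shift to this module's >= rule.
    return int(threshold_otsu(hist=(counts, np.arange(256)))) + 1


def extract_marbling(
    gray: CalibratedImage,
    roi: np.ndarray,
    threshold: int,
    min_particle_px: int = 10,
    connectivity: int = 8,
) -> MarblingResult:
    """Segment marbling flecks and report the particle statistics.

    Pixels inside the ROI with gray value >= ``threshold`` are marked as
    fat, connected components are labelled (8-connectivity by default, the
    convention of ImageJ's particle analyzer), and components smaller than
    ``min_particle_px`` pixels are discarded as artefacts. The surviving
    components are the marbling flecks.
    """
    roi = _check_gray_and_roi(gray, roi)
    if not roi.any():
        raise ValueError("ROI is empty")
    if not 0 <= threshold <= 255:
        raise ValueError(f"threshold must be in [0, 255], got {threshold}")
    if min_particle_px < 1:
        raise ValueError("min_particle_px must be a positive integer")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")

    binary = (gray.pixels >= threshold) & roi
    structure = np.ones((3, 3), dtype=int) if connectivity == 8 else None
    labels, n_components = ndimage.label(binary, structure=structure)
    areas = np.bincount(labels.ravel())[1:] if n_components else np.array([], dtype=int)
    kept = np.sort(areas[areas >= min_particle_px])[::-1]

    roi_area_px = int(roi.sum())
    total_px = int(kept.sum())
    return MarblingResult(
        threshold=int(threshold),
        particle_areas_px=tuple(int(a) for a in kept),
        n_particles=int(kept.size),
        marb_area_mm2=total_px * gray.mm_per_px**2,
        marb_area_pct=100.0 * total_px / roi_area_px,
        min_particle_px=int(min_particle_px),
    )


def _max_vertical_run(mask: np.ndarray) -> int:
    """Longest run of consecutive set pixels within any single column."""
    if not mask.any():
        return 0
    best = 0
    padded = np.zeros((mask.shape[0] + 2, mask.shape[1]), dtype=np.int8)
    padded[1:-1] = mask
    diff = np.diff(padded, axis=0)
    for col in range(mask.shape[1]):
        starts = np.flatnonzero(diff[:, col] == 1)
        if starts.size == 0:
            continue
        ends = np.flatnonzero(diff[:, col] == -1)
        best = max(best, int((ends - starts).max()))
    return best


def measure_morphometry(
    roi: np.ndarray,
    fat_band: np.ndarray | None,
    mm_per_px: float,
) -> Morphometry:
    """Muscle width/height/area and backfat thickness from binary masks.

    Width and height are the axis-aligned extents of the ROI; REA is its
    pixel count converted to cm²; BFT is the maximum vertical run length
    of the fat-band mask (0 when the band is empty or absent).
    """
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("ROI is empty")
    if not mm_per_px > 0:
        raise ValueError(f"mm_per_px must be positive, got {mm_per_px}")
    rows, cols = np.nonzero(roi)
    width_px = int(cols.max() - cols.min() + 1)
    height_px = int(rows.max() - rows.min() + 1)
    if fat_band is None:
        bft_px = 0
    else:
        fat_band = np.asarray(fat_band, dtype=bool)
        bft_px = _max_vertical_run(fat_band)
    return Morphometry(
        width_cm=width_px * mm_per_px / 10.0,
        height_cm=height_px * mm_per_px / 10.0,
        rea_cm2=int(roi.sum()) * mm_per_px**2 / 100.0,
        bft_cm=bft_px * mm_per_px / 10.0,
    )


# ---------------------------------------------------------------------------
# Mask / image I/O helpers (PNG rasters and run-length-encoded JSON masks)
# ---------------------------------------------------------------------------

def rle_encode(mask: np.ndarray) -> dict:
    """Run-length encode a binary mask (row-major runs of alternating 0/1).

    The encoding starts with a run of zeros (possibly empty), so the
    decoder needs no per-run value flags.
    """
    mask = np.asarray(mask, dtype=bool)
    flat = mask.ravel().astype(np.int8)
    change = np.flatnonzero(np.diff(flat)) + 1
    bounds = np.concatenate(([0], change, [flat.size]))
    runs = np.diff(bounds).tolist()
    if flat.size and flat[0] == 1:
        runs = [0] + runs
    return {"shape": list(mask.shape), "runs": runs}


def rle_decode(encoded: dict) -> np.ndarray:
    shape = tuple(encoded["shape"])
    runs = encoded["runs"]
    flat = np.zeros(int(np.prod(shape)), dtype=bool)
    pos, value = 0, False
    for run in runs:
        if value:
            flat[pos : pos + run] = True
        pos += run
        value = not value
    return flat.reshape(shape)


def read_image(path, mm_per_px: float) -> CalibratedImage:
    """Read a PNG/TIFF file into a calibrated 8-bit image."""
    with Image.open(path) as im:
        if im.mode not in ("L", "RGB"):
            im = im.convert("RGB") if len(im.getbands()) >= 3 else im.convert("L")
        pixels = np.asarray(im, dtype=np.uint8)
    return CalibratedImage(pixels, mm_per_px)


def write_image(image: CalibratedImage, path) -> None:
    Image.fromarray(np.asarray(image.pixels, dtype=np.uint8)).save(path)


def read_mask(path) -> np.ndarray:
    """Read a binary mask from a bilevel/gray PNG or an RLE JSON file."""
    path = str(path)
    if path.endswith(".json"):
        with open(path) as fh:
            return rle_decode(json.load(fh))
    with Image.open(path) as im:
        return np.asarray(im.convert("L")) > 127


def write_mask(mask: np.ndarray, path) -> None:
    path = str(path)
    if path.endswith(".json"):
        with open(path, "w") as fh:
            json.dump(rle_encode(mask), fh)
    else:
        Image.fromarray((np.asarray(mask, dtype=np.uint8)) * 255).save(path)
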