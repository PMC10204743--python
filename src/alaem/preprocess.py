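"""Raw nadir RGB image -> cropped, enhanced, green-masked grayscale input.

The pipeline keeps only a narrow field of view about nadir (where leaf
azimuths are not distorted by perspective), stretches contrast, separates
vegetation from soil with an excess-green index, and averages the colour
channels into a [0, 1] grayscale image for the ridge detector.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage import exposure
from skimage.color import rgb2hsv, hsv2rgb
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_objects

logger = logging.getLogger(__name__)

__all__ = [
    "CameraGeometry",
    "PreprocessedImage",
    "crop_fov",
    "enhance",
    "segment_green",
    "to_grayscale",
    "preprocess_image",
]


@dataclass(frozen=True)
class CameraGeometry:
    """Pinhole-camera field-of-view description.

    Defaults match a compact rigid-lens camera with a 70 x 50 degree FOV;
    only a +-10 degree cone about nadir is retained so that perspective does
    not distort apparent leaf azimuths.
    """

    fov_h_deg: float = 70.0
    fov_v_deg: float = 50.0
    crop_half_angle_deg: float = 10.0

    def __post_init__(self) -> None:
        if not (0 < self.crop_half_angle_deg
                <= min(self.fov_h_deg, self.fov_v_deg) / 2):
            raise ValueError(
                "crop_half_angle_deg must be in (0, min(fov_h, fov_v)/2]")


@dataclass
class PreprocessedImage:
    """Detector-ready image: [0,1] grayscale + vegetation mask + provenance."""

    gray: np.ndarray
    green_mask: np.ndarray
    provenance: dict = field(default_factory=dict)


def _half_extent(n_pix: int, fov_deg: float, half_angle_deg: float) -> int:
    return int(round((n_pix / 2.0) * np.tan(np.radians(half_angle_deg))
                     / np.tan(np.radians(fov_deg / 2.0))))


def crop_fov(image: np.ndarray, geom: CameraGeometry) -> np.ndarray:
    """Center crop to +-crop_half_angle about the optical axis (pinhole model).

    The retained half-width in pixels is (W/2) tan(a) / tan(fov_h/2) and the
    half-height analogously with the vertical FOV; the crop is symmetric
    about the image center.
    """
    img = np.asarray(image)
    if img.ndim not in (2, 3) or img.shape[0] == 0 or img.shape[1] == 0:
        raise ValueError("image must be a non-empty 2-D or 3-D array")
    h, w = img.shape[:2]
    half_w = _half_extent(w, geom.fov_h_deg, geom.crop_half_angle_deg)
    half_h = _half_extent(h, geom.fov_v_deg, geom.crop_half_angle_deg)
    half_w = min(half_w, w // 2)
    half_h = min(half_h, h // 2)
    if 2 * half_w < 8 or 2 * half_h < 8:
        raise ValueError(
            f"crop of {2 * half_h}x{2 * half_w} px is smaller than 8x8; "
            "geometry unusable for this image size")
    cy, cx = h // 2, w // 2
    return img[cy - half_h:cy + half_h, cx - half_w:cx + half_w]


def enhance(image: np.ndarray, method: str = "stretch",
            percentiles: tuple[float, float] = (2.0, 98.0),
            clip_limit: float = 0.01) -> np.ndarray:
    """Contrast/brightness enhancement.

    ``"stretch"`` (default) linearly maps the given intensity percentiles of
    each channel onto the full range — deterministic and idempotent up to
    rounding for an already-stretched image.  ``"clahe"`` applies adaptive
    histogram equalisation to the luminance channel.  A constant image is
    returned unchanged with a warning (the stretch is undefined).
    """
    img = np.asarray(image)
    was_uint8 = img.dtype == np.uint8
    arr = img.astype(float) / 255.0 if was_uint8 else img.astype(float)
    if arr.ndim == 2:
        arr = arr[..., None]

    if np.ptp(arr) == 0:
        warnings.warn("constant image: enhancement is undefined, "
                      "returning input unchanged", stacklevel=2)
        return image

    if method == "stretch":
        out = np.empty_like(arr)
        for c in range(arr.shape[2]):
            lo, hi = np.percentile(arr[..., c], percentiles)
            if hi <= lo:
                out[..., c] = arr[..., c]
                continue
            out[..., c] = np.clip((arr[..., c] - lo) / (hi - lo), 0.0, 1.0)
    elif method == "clahe":
        if arr.shape[2] == 3:
            hsv = rgb2hsv(arr)
            hsv[..., 2] = exposure.equalize_adapthist(hsv[..., 2],
                                                      clip_limit=clip_limit)
            out = hsv2rgb(hsv)
        else:
            out = exposure.equalize_adapthist(arr[..., 0],
                                              clip_limit=clip_limit)[..., None]
    else:
        raise ValueError(f"unknown enhancement method: {method!r}")

    if image.ndim == 2:
        out = out[..., 0]
    if was_uint8:
        return np.clip(np.rint(out * 255.0), 0, 255).astype(np.uint8)
    return out


def segment_green(image: np.ndarray, min_area: int = 64,
                  min_exg: float = 0.05) -> np.ndarray:
    """Vegetation mask from the excess-green index on chromaticity channels.

    Channels are normalised to chromaticity coordinates r+g+b = 1 (so the
    mask is invariant to global brightness scaling), ExG = 2g - r - b is
    computed per pixel, and the vegetation/background split is found
    automatically by Otsu's method on the ExG histogram.  The Otsu threshold
    is floored at ``min_exg`` so an image with no green pixels yields an
    empty mask instead of an arbitrary split of the soil histogram.
    Components smaller than ``min_area`` pixels are removed.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("segment_green expects an RGB image")
    total = img.sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        chrom = img / total[..., None]
    chrom[total == 0] = 1.0 / 3.0
    exg = 2.0 * chrom[..., 1] - chrom[..., 0] - chrom[..., 2]

    thresh = min_exg
    if np.ptp(exg) > 0:
        thresh = max(threshold_otsu(exg), min_exg)
    mask = exg > thresh
    if not mask.any():
        logger.info("no vegetation pixels found; returning empty mask")
        return mask
    if min_area > 1:
        mask = remove_small_objects(mask, max_size=min_area - 1, connectivity=2)
    return mask


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Average the three colour channels and rescale to [0, 1].

    out = (R + G + B) / 3, divided by the dtype maximum (255 for 8-bit
    input; float input is assumed already in [0, 1]).
    """
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("to_grayscale expects a 3-channel image")
    scale = 255.0 if img.dtype == np.uint8 else (
        65535.0 if img.dtype == np.uint16 else 1.0)
    return img.astype(float).mean(axis=2) / scale


def preprocess_image(image: np.ndarray, geom: CameraGeometry | None = None,
               enhance_method: str = "stretch",
               percentiles: tuple[float, float] = (2.0, 98.0),
               min_green_area: int = 64,
               source: str | None = None) -> PreprocessedImage:
    """Run the full preprocessing chain: crop, enhance, segment, grayscale.

    The vegetation mask is computed from the *unenhanced* crop: chromaticity
    coordinates are invariant to brightness there, whereas the per-channel
    stretch can saturate individual channels and corrupt hue on the
    brightest vegetation (the midribs themselves).  The enhanced image feeds
    only the grayscale ridge input, where contrast is what matters.
    """
    img = np.asarray(image)
    prov: dict = {"source": source, "shape_in": list(img.shape)}
    if geom is not None:
        img = crop_fov(img, geom)
        prov["crop"] = {"half_angle_deg": geom.crop_half_angle_deg,
                        "shape_out": list(img.shape)}
    mask = segment_green(img, min_area=min_green_area)
    enhanced = enhance(img, method=enhance_method, percentiles=percentiles)
    prov["enhance"] = {"method": enhance_method,
                       "percentiles": list(percentiles)}
    gray = to_grayscale(enhanced)
    return PreprocessedImage(gray=gray, green_mask=mask, provenance=prov)
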