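"""Midrib detection as bright-ridge extraction via Hessian eigen-analysis.

A maize midrib appears in a nadir grayscale image as a bright elongated ridge:
a curve along which intensity is locally maximal in the transverse direction.
After Gaussian smoothing at scale sigma (matched to the midrib width, hence
growth stage), the 2x2 Hessian of second derivatives is computed per pixel.
Its signed-ascending eigenvalues (lam1 <= lam2) characterise local structure:
a bright ridge has lam1 strongly negative (strong downward curvature across
the ridge) and lam2 near zero (little curvature along it).

Eigenvalues are scale-normalised (multiplied by sigma^2) by default so that
the classification threshold is comparable across scales, and the grayscale
input is expected in [0, 1] so the default threshold magnitude of 0.125 has a
defined intensity scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import remove_small_objects

__all__ = [
    "SIGMA_BY_GDD",
    "RidgeParams",
    "EigenMaps",
    "gaussian_smooth",
    "hessian_eigenvalues",
    "eigen_maps",
    "ridge_mask",
]

#: Default Gaussian scale (pixels) per growth stage in growing degree days,
#: for field-scale imagery (~0.5 mm/pixel): leaves, and hence midribs, widen
#: with development.  sigma is always settable explicitly per run.
SIGMA_BY_GDD: dict[int, float] = {220: 8.0, 430: 12.0, 650: 16.0}


@dataclass(frozen=True)
class RidgeParams:
    """Parameters of the ridge classifier.

    sigma : Gaussian smoothing scale in pixels (match to midrib half-width).
    eig_threshold : magnitude threshold on lam1; a pixel is a ridge candidate
        when lam1 <= -eig_threshold (bright-ridge convention on [0,1] images).
    scale_normalize : multiply second derivatives by sigma^2 so responses are
        comparable across scales.
    min_component_px : connected ridge components smaller than this are noise.
    anisotropy_ratio : require |lam2| < anisotropy_ratio * |lam1| so that
        isotropic blobs (both curvatures strong) are rejected.
    derivative : "finite" = central differences of the sigma-smoothed image;
        "gaussian" = direct Gaussian-derivative kernels at scale sigma.
    """

    sigma: float
    eig_threshold: float = 0.125
    scale_normalize: bool = True
    min_component_px: int = 50
    anisotropy_ratio: float = 0.5
    derivative: str = "finite"

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.eig_threshold <= 0:
            raise ValueError("eig_threshold must be > 0")
        if self.min_component_px < 1:
            raise ValueError("min_component_px must be >= 1")
        if self.derivative not in ("finite", "gaussian"):
            raise ValueError("derivative must be 'finite' or 'gaussian'")


@dataclass
class EigenMaps:
    """Per-pixel Hessian eigenvalue fields, signed-ascending (lam1 <= lam2)."""

    lam1: np.ndarray
    lam2: np.ndarray
    sigma: float


def gaussian_smooth(gray: np.ndarray, sigma: float) -> np.ndarray:
    """Convolve with the unit-mass 2-D Gaussian, reflective boundaries.

    G(x, y, sigma) = exp(-(x^2 + y^2) / (2 sigma^2)) / (2 pi sigma^2), so a
    constant image is a fixed point and total intensity is preserved up to
    boundary effects.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    return ndi.gaussian_filter(np.asarray(gray, dtype=float), sigma,
                               mode="reflect")


def _second_derivatives(img: np.ndarray):
    # central differences; x = columns, y = rows
    fy, fx = np.gradient(img)
    fxy, fxx = np.gradient(fx)
    fyy, _ = np.gradient(fy)
    return fxx, fxy, fyy


def hessian_eigenvalues(smoothed: np.ndarray,
                        params: RidgeParams) -> EigenMaps:
    """Eigenvalues of the per-pixel Hessian H = [[fxx, fxy], [fxy, fyy]].

    Second derivatives come from central finite differences of the (already
    smoothed) input.  For a symmetric 2x2 matrix the eigenvalues are
    (fxx + fyy)/2 -+ sqrt(((fxx - fyy)/2)^2 + fxy^2), returned sorted
    ascending by signed value.  If ``params.scale_normalize`` the derivatives
    are multiplied by sigma^2 first.
    """
    img = np.asarray(smoothed, dtype=float)
    if img.ndim != 2 or min(img.shape) < 3:
        raise ValueError("image must be 2-D and at least 3x3")
    fxx, fxy, fyy = _second_derivatives(img)
    if params.scale_normalize:
        s2 = params.sigma ** 2
        fxx, fxy, fyy = fxx * s2, fxy * s2, fyy * s2
    half_trace = (fxx + fyy) / 2.0
    disc = np.sqrt(((fxx - fyy) / 2.0) ** 2 + fxy ** 2)
    return EigenMaps(lam1=half_trace - disc, lam2=half_trace + disc,
                     sigma=params.sigma)


def eigen_maps(gray: np.ndarray, params: RidgeParams) -> EigenMaps:
    """Smooth at scale sigma and compute Hessian eigenvalue maps.

    With ``derivative="finite"`` the image is Gaussian-smoothed and second
    derivatives are taken by central differences; with ``"gaussian"`` the
    second derivatives are computed directly with Gaussian-derivative kernels
    at scale sigma (mathematically the derivative of the smoothed image).
    """
    img = np.asarray(gray, dtype=float)
    if img.ndim != 2 or min(img.shape) < 3:
        raise ValueError("image must be 2-D and at least 3x3")
    if params.derivative == "finite":
        return hessian_eigenvalues(gaussian_smooth(img, params.sigma), params)
    fxx = ndi.gaussian_filter(img, params.sigma, order=(0, 2), mode="reflect")
    fyy = ndi.gaussian_filter(img, params.sigma, order=(2, 0), mode="reflect")
    fxy = ndi.gaussian_filter(img, params.sigma, order=(1, 1), mode="reflect")
    if params.scale_normalize:
        s2 = params.sigma ** 2
        fxx, fxy, fyy = fxx * s2, fxy * s2, fyy * s2
    half_trace = (fxx + fyy) / 2.0
    disc = np.sqrt(((fxx - fyy) / 2.0) ** 2 + fxy ** 2)
    return EigenMaps(lam1=half_trace - disc, lam2=half_trace + disc,
                     sigma=params.sigma)


def ridge_mask(eig: EigenMaps, params: RidgeParams,
               green_mask: np.ndarray | None = None) -> np.ndarray:
    """Classify bright-ridge pixels from the eigenvalue maps.

    A pixel is a ridge iff lam1 <= -eig_threshold (strong transverse downward
    curvature), |lam2| < anisotropy_ratio * |lam1| (elongated, not blob-like),
    and it lies inside the vegetation mask when one is given.  8-connected
    components smaller than ``min_component_px`` are removed.
    """
    mask = eig.lam1 <= -params.eig_threshold
    mask &= np.abs(eig.lam2) < params.anisotropy_ratio * np.abs(eig.lam1)
    if green_mask is not None:
        gm = np.asarray(green_mask).astype(bool)
        if gm.shape != mask.shape:
            raise ValueError("green_mask shape does not match eigenvalue maps")
        mask &= gm
    if params.min_component_px > 1:
        mask = remove_small_objects(mask,
                                    max_size=params.min_component_px - 1,
                                    connectivity=2)
    return mask
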