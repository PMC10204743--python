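"""End-to-end midrib detector: image in, oriented-midrib table out."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import geometry, preprocess, ridge

__all__ = ["DetectionResult", "MidribDetector", "detect_midribs"]


@dataclass
class DetectionResult:
    """Output of one image: the midrib table plus per-stage accounting."""

    table: pd.DataFrame                 # one row per ridge component
    records: list = field(default_factory=list)
    counts: dict = field(default_factory=dict)
    ridge_mask: np.ndarray | None = None
    pre: preprocess.PreprocessedImage | None = None

    @property
    def kept(self) -> pd.DataFrame:
        return self.table[self.table["kept"]]


class MidribDetector(BaseEstimator):
    """Detect leaf midribs in a nadir RGB image and orient them.

    Chains the whole workflow: optional FOV crop, contrast enhancement,
    green segmentation, channel-average grayscale, Gaussian smoothing at
    scale ``sigma``, Hessian-eigenvalue ridge classification, connected
    components, convex hull + minimum-area rectangle, rectangle denoising,
    and folding of each rectangle's long-side orientation against the row
    direction.

    ``sigma`` should track midrib width: for field imagery at ~0.5 mm/pixel
    the stage lookup :data:`alaem.ridge.SIGMA_BY_GDD` (220 -> 8, 430 -> 12,
    650 -> 16) applies; pass ``stage_gdd`` to use it, or set ``sigma``
    directly for other scales.
    """

    def __init__(self, sigma: float | None = None,
                 stage_gdd: int | None = None,
                 eig_threshold: float = 0.125,
                 scale_normalize: bool = True,
                 anisotropy_ratio: float = 0.5,
                 min_component_px: int = 50,
                 derivative: str = "finite",
                 min_aspect: float = 3.0,
                 iqr_factor: float = 1.5,
                 enhance_method: str = "stretch",
                 percentiles: tuple[float, float] = (2.0, 98.0),
                 min_green_area: int = 64,
                 geom: preprocess.CameraGeometry | None = None):
        self.sigma = sigma
        self.stage_gdd = stage_gdd
        self.eig_threshold = eig_threshold
        self.scale_normalize = scale_normalize
        self.anisotropy_ratio = anisotropy_ratio
        self.min_component_px = min_component_px
        self.derivative = derivative
        self.min_aspect = min_aspect
        self.iqr_factor = iqr_factor
        self.enhance_method = enhance_method
        self.percentiles = percentiles
        self.min_green_area = min_green_area
        self.geom = geom

    def _resolve_sigma(self) -> float:
        if self.sigma is not None:
            return float(self.sigma)
        if self.stage_gdd is not None:
            try:
                return ridge.SIGMA_BY_GDD[int(self.stage_gdd)]
            except KeyError:
                raise ValueError(
                    f"no default sigma for stage {self.stage_gdd} degCd; "
                    f"known stages: {sorted(ridge.SIGMA_BY_GDD)}") from None
        raise ValueError("either sigma or stage_gdd must be set")

    def ridge_params(self) -> ridge.RidgeParams:
        return ridge.RidgeParams(
            sigma=self._resolve_sigma(),
            eig_threshold=self.eig_threshold,
            scale_normalize=self.scale_normalize,
            min_component_px=self.min_component_px,
            anisotropy_ratio=self.anisotropy_ratio,
            derivative=self.derivative)

    def detect(self, image: np.ndarray, row_azimuth_deg: float = 0.0,
               keep_intermediates: bool = False) -> DetectionResult:
        """Run the full pipeline on one RGB image.

        Returns a :class:`DetectionResult` whose table has one row per ridge
        component (kept flag marks survivors of rectangle denoising) and
        whose ``counts`` dict tracks components found / kept per stage.
        """
        params = self.ridge_params()
        pre = preprocess.preprocess_image(
            image, geom=self.geom, enhance_method=self.enhance_method,
            percentiles=self.percentiles, min_green_area=self.min_green_area)
        eig = ridge.eigen_maps(pre.gray, params)
        mask = ridge.ridge_mask(eig, params, green_mask=pre.green_mask)
        records = geometry.extract_midribs(
            mask, row_azimuth_deg,
            min_aspect=self.min_aspect, iqr_factor=self.iqr_factor)
        table = geometry.midrib_table(records)
        counts = {
            "green_px": int(pre.green_mask.sum()),
            "ridge_px": int(mask.sum()),
            "components": len(records),
            "kept": int(table["kept"].sum()),
        }
        return DetectionResult(
            table=table, records=records, counts=counts,
            ridge_mask=mask if keep_intermediates else None,
            pre=pre if keep_intermediates else None)


def detect_midribs(image: np.ndarray, sigma: float,
                   row_azimuth_deg: float = 0.0,
                   **params) -> pd.DataFrame:
    """Functional one-shot wrapper around :class:`MidribDetector`."""
    det = MidribDetector(sigma=sigma, **params)
    return det.detect(image, row_azimuth_deg=row_azimuth_deg).table
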