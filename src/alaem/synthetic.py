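"""Synthetic nadir canopies with known midrib azimuths, and simulated fp tables.

The renderer emulates what the detector actually relies on in real imagery:
green elongated leaf blades over brown textured soil, each blade carrying a
brighter midrib line along its major axis.  Every rendered leaf's true
azimuth is recorded, so detection recall and angular error can be measured
exactly.  ``simulate_fp_table`` plants known genotype / environment main
effects and a (possibly rank-1) interaction into a two-way table, giving the
AMMI decomposition a ground truth to recover.

Rendering is deterministic given the scene seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.draw import polygon as draw_polygon

from .geometry import relative_azimuth

__all__ = [
    "SceneValidationError",
    "LeafSpec",
    "CanopyScene",
    "FpTableSpec",
    "render_scene",
    "random_scene",
    "sample_azimuths",
    "simulate_fp_table",
    "rank_one_interaction",
]


class SceneValidationError(ValueError):
    """A scene or table spec violates its invariants."""


@dataclass
class LeafSpec:
    """One leaf blade: attachment point, orientation, size and colouring.

    The blade is a lens-shaped polygon of the given length and maximum width,
    oriented at ``azimuth_deg`` (a line orientation, degrees in [0, 180) in
    the image frame), with a midrib line along the major axis drawn at
    ``midrib_gain`` times the blade brightness.
    """

    base_xy: tuple[float, float]
    azimuth_deg: float
    length_px: float
    width_px: float
    midrib_gain: float = 1.4
    blade_green: tuple[int, int, int] = (70, 150, 60)

    def __post_init__(self) -> None:
        if not (0 <= self.azimuth_deg < 180):
            raise SceneValidationError(
                f"azimuth_deg must be in [0, 180), got {self.azimuth_deg}")
        if not (self.length_px > self.width_px > 0):
            raise SceneValidationError(
                "leaf requires length_px > width_px > 0")
        if self.midrib_gain < 1:
            raise SceneValidationError("midrib_gain must be >= 1")

    @property
    def direction(self) -> np.ndarray:
        th = np.radians(self.azimuth_deg)
        return np.array([np.cos(th), np.sin(th)])  # (dx, dy), x=col y=row

    @property
    def tip_xy(self) -> np.ndarray:
        return np.asarray(self.base_xy, float) + self.length_px * self.direction

    def blade_polygon(self, n: int = 24) -> np.ndarray:
        """Lens-shaped outline as an (m, 2) array of (x, y) vertices."""
        base = np.asarray(self.base_xy, float)
        d = self.direction
        nvec = np.array([-d[1], d[0]])
        t = np.linspace(0.0, 1.0, n)
        half = (self.width_px / 2.0) * np.sin(np.pi * t)
        axis = base + np.outer(t * self.length_px, d)
        side1 = axis + np.outer(half, nvec)
        side2 = (axis - np.outer(half, nvec))[::-1]
        return np.vstack([side1, side2])

    def midrib_polygon(self, width_px: float,
                       inset: float = 0.05) -> np.ndarray:
        """Rectangle of the given width along the major axis (slightly inset
        from the blade tips so the midrib stays on the blade)."""
        base = np.asarray(self.base_xy, float)
        d = self.direction
        nvec = np.array([-d[1], d[0]])
        p0 = base + inset * self.length_px * d
        p1 = base + (1.0 - inset) * self.length_px * d
        h = (width_px / 2.0) * nvec
        return np.array([p0 + h, p1 + h, p1 - h, p0 - h])


@dataclass
class CanopyScene:
    """Parametric description of a synthetic nadir canopy image."""

    image_hw: tuple[int, int] = (768, 768)
    row_azimuth_deg: float = 0.0
    leaves: list[LeafSpec] = field(default_factory=list)
    soil_rgb: tuple[int, int, int] = (120, 95, 70)
    soil_noise_sd: float = 5.0
    illum_gradient: float = 0.10
    midrib_width_px: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.row_azimuth_deg < 180):
            raise SceneValidationError("row_azimuth_deg must be in [0, 180)")
        h, w = self.image_hw
        for i, leaf in enumerate(self.leaves):
            poly = leaf.blade_polygon()
            if (poly[:, 0].min() < 0 or poly[:, 0].max() > w - 1
                    or poly[:, 1].min() < 0 or poly[:, 1].max() > h - 1):
                raise SceneValidationError(
                    f"leaf {i} extends outside the {h}x{w} canvas")


def render_scene(scene: CanopyScene) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a scene to an 8-bit RGB image plus its ground-truth table.

    Returns
    -------
    image : (H, W, 3) uint8
    ground_truth : DataFrame with one row per leaf: leaf_id, azimuth_deg
        (absolute, image frame), rel_azimuth_deg (folded against the row
        direction, [0, 90]) and an ``occluded`` flag set when a later leaf
        covers more than 10% of this leaf's midrib pixels.
    """
    h, w = scene.image_hw
    rng = np.random.default_rng(scene.seed)

    # soil: brown base + low-frequency mottling + per-pixel speckle
    low = ndi.gaussian_filter(rng.standard_normal((h, w)), 24.0)
    if low.std() > 0:
        low = low / low.std()
    speckle = rng.standard_normal((h, w, 3)) * scene.soil_noise_sd
    img = np.empty((h, w, 3), dtype=float)
    hue = (1.0, 0.9, 0.78)                     # keep the mottling brown
    for c in range(3):
        img[..., c] = scene.soil_rgb[c] * (1.0 + 0.10 * low * hue[c])
    img += speckle

    owner = np.full((h, w), -1, dtype=int)     # topmost leaf per pixel
    midrib_pixels: list[tuple[np.ndarray, np.ndarray]] = []
    for i, leaf in enumerate(scene.leaves):
        poly = leaf.blade_polygon()
        rr, cc = draw_polygon(poly[:, 1], poly[:, 0], shape=(h, w))
        img[rr, cc] = np.array(leaf.blade_green, dtype=float)
        owner[rr, cc] = i
        mpoly = leaf.midrib_polygon(scene.midrib_width_px)
        mr, mc = draw_polygon(mpoly[:, 1], mpoly[:, 0], shape=(h, w))
        img[mr, mc] = np.minimum(
            np.array(leaf.blade_green, dtype=float) * leaf.midrib_gain, 255.0)
        owner[mr, mc] = i
        midrib_pixels.append((mr, mc))

    if scene.illum_gradient:
        ramp = 1.0 + scene.illum_gradient * (np.arange(w) / max(w - 1, 1) - 0.5)
        img *= ramp[None, :, None]
    image = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    rows = []
    for i, leaf in enumerate(scene.leaves):
        mr, mc = midrib_pixels[i]
        visible = float(np.mean(owner[mr, mc] == i)) if len(mr) else 0.0
        rows.append({
            "leaf_id": i,
            "azimuth_deg": leaf.azimuth_deg,
            "rel_azimuth_deg": relative_azimuth(leaf.azimuth_deg,
                                                scene.row_azimuth_deg),
            "occluded": visible < 0.9,
        })
    gt = pd.DataFrame(rows, columns=["leaf_id", "azimuth_deg",
                                     "rel_azimuth_deg", "occluded"])
    return image, gt


def sample_azimuths(n: int, rng: np.random.Generator,
                    perpendicular_fraction: float = 0.7,
                    row_azimuth_deg: float = 0.0,
                    spread_sd_deg: float = 10.0) -> np.ndarray:
    """Draw leaf azimuths from a perpendicular-biased mixture.

    With probability ``perpendicular_fraction`` an azimuth is normal around
    the direction perpendicular to the rows (sd ``spread_sd_deg``), otherwise
    uniform on [0, 180); all values are folded into [0, 180).  This mimics
    the shade-avoidance reorientation of crowded canopies, where a fraction
    of leaves turns across the inter-row gap.
    """
    if not 0 <= perpendicular_fraction <= 1:
        raise SceneValidationError("perpendicular_fraction must be in [0, 1]")
    perp = rng.random(n) < perpendicular_fraction
    az = rng.uniform(0.0, 180.0, size=n)
    n_perp = int(perp.sum())
    az[perp] = (row_azimuth_deg + 90.0
                + rng.normal(0.0, spread_sd_deg, size=n_perp))
    return az % 180.0


def _segment_distance(p0, p1, q0, q1) -> float:
    """Minimum distance between two 2-D segments."""
    p0, p1, q0, q1 = (np.asarray(a, float) for a in (p0, p1, q0, q1))

    def point_seg(pt, a, b):
        ab = b - a
        denom = ab @ ab
        t = 0.0 if denom == 0 else np.clip((pt - a) @ ab / denom, 0.0, 1.0)
        return float(np.hypot(*(pt - (a + t * ab))))

    d1, d2 = p1 - p0, q1 - q0
    r = q0 - p0
    a, b, c = d1 @ d1, d1 @ d2, d2 @ d2
    e, f = d1 @ r, d2 @ r
    den = a * c - b * b
    if den > 1e-12:
        s = np.clip((e * c - b * f) / den, 0.0, 1.0)
        t = np.clip((e * b - a * f) / den, 0.0, 1.0)
        cand = float(np.hypot(*((p0 + s * d1) - (q0 + t * d2))))
    else:
        cand = np.inf
    return min(cand,
               point_seg(p0, q0, q1), point_seg(p1, q0, q1),
               point_seg(q0, p0, p1), point_seg(q1, p0, p1))


def random_scene(n_leaves: int = 20,
                 image_hw: tuple[int, int] = (768, 768),
                 row_azimuth_deg: float = 0.0,
                 perpendicular_fraction: float = 0.7,
                 spread_sd_deg: float = 10.0,
                 length_range: tuple[float, float] = (100.0, 130.0),
                 width_range: tuple[float, float] = (16.0, 22.0),
                 midrib_gain: float = 1.4,
                 allow_overlap: bool = False,
                 clearance_px: float = 6.0,
                 seed: int = 0,
                 max_tries: int = 50_000) -> CanopyScene:
    """Place ``n_leaves`` random leaves, by default without overlap.

    Leaf azimuths come from :func:`sample_azimuths`.  Non-overlap is enforced
    by rejection sampling on the leaf axes treated as capsules (segment plus
    half-width plus clearance).  Raises if the canvas cannot accommodate the
    requested count.
    """
    h, w = image_hw
    rng = np.random.default_rng(seed)
    leaves: list[LeafSpec] = []
    placed: list[tuple[np.ndarray, np.ndarray, float]] = []
    tries = 0
    while len(leaves) < n_leaves:
        if tries >= max_tries:
            raise SceneValidationError(
                f"could not place {n_leaves} non-overlapping leaves "
                f"in a {h}x{w} canvas after {max_tries} tries")
        tries += 1
        az = float(sample_azimuths(1, rng, perpendicular_fraction,
                                   row_azimuth_deg, spread_sd_deg)[0])
        length = rng.uniform(*length_range)
        width = rng.uniform(*width_range)
        margin = length / 2.0 + width / 2.0 + 2.0
        if 2 * margin >= min(h, w):
            raise SceneValidationError("leaves too large for the canvas")
        center = np.array([rng.uniform(margin, w - 1 - margin),
                           rng.uniform(margin, h - 1 - margin)])
        th = np.radians(az)
        d = np.array([np.cos(th), np.sin(th)])
        base = center - (length / 2.0) * d
        tip = center + (length / 2.0) * d
        if not allow_overlap:
            ok = all(
                _segment_distance(base, tip, b2, t2)
                > (width + w2) / 2.0 + clearance_px
                for (b2, t2, w2) in placed)
            if not ok:
                continue
        leaves.append(LeafSpec(base_xy=(float(base[0]), float(base[1])),
                               azimuth_deg=az, length_px=float(length),
                               width_px=float(width),
                               midrib_gain=midrib_gain))
        placed.append((base, tip, width))
    return CanopyScene(image_hw=image_hw, row_azimuth_deg=row_azimuth_deg,
                       leaves=leaves, seed=int(rng.integers(2 ** 31)))


# ---------------------------------------------------------------------------
# fp-table simulation for the statistics layer


def rank_one_interaction(lam: float, b: np.ndarray,
                         z: np.ndarray) -> np.ndarray:
    """Rank-1 interaction lam * b z^T from centered unit-norm score vectors."""
    b = np.asarray(b, float)
    z = np.asarray(z, float)
    b = b - b.mean()
    z = z - z.mean()
    nb, nz = np.linalg.norm(b), np.linalg.norm(z)
    if nb == 0 or nz == 0:
        raise SceneValidationError("score vectors must be non-constant")
    return lam * np.outer(b / nb, z / nz)


@dataclass
class FpTableSpec:
    """Planted two-way model for a genotype x environment fp table.

    The table follows Y_ij = mu + G_i + R_j + interaction_ij + eps, with
    G and R centered main-effect vectors and a double-centered interaction
    matrix (e.g. from :func:`rank_one_interaction`).
    """

    mu: float
    g_effects: np.ndarray
    r_effects: np.ndarray
    interaction: np.ndarray | None = None
    noise_sd: float = 0.0
    replicates: int = 1
    seed: int = 0
    clip: bool = False
    genotype_names: list[str] | None = None
    env_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.g_effects = np.asarray(self.g_effects, float)
        self.r_effects = np.asarray(self.r_effects, float)
        g, e = len(self.g_effects), len(self.r_effects)
        if self.interaction is None:
            self.interaction = np.zeros((g, e))
        self.interaction = np.asarray(self.interaction, float)
        if abs(self.g_effects.sum()) > 1e-8 or abs(self.r_effects.sum()) > 1e-8:
            raise SceneValidationError("main-effect vectors must sum to zero")
        if self.interaction.shape != (g, e):
            raise SceneValidationError("interaction must be g x e")
        if (np.abs(self.interaction.sum(axis=0)).max() > 1e-8
                or np.abs(self.interaction.sum(axis=1)).max() > 1e-8):
            raise SceneValidationError("interaction must be double-centered")
        if self.replicates < 1:
            raise SceneValidationError("replicates must be >= 1")
        if self.genotype_names is None:
            self.genotype_names = [f"G{i + 1}" for i in range(g)]
        if self.env_names is None:
            self.env_names = [f"R{j + 1}" for j in range(e)]


def simulate_fp_table(spec: FpTableSpec) -> pd.DataFrame:
    """Simulate a tidy fp table from a planted additive + interaction model.

    Returns a DataFrame with columns (genotype, environment, replicate,
    value): Y = mu + G_i + R_j + interaction_ij + N(0, noise_sd^2).  Values
    are clipped to [0, 1] only when ``spec.clip`` is set, so that the
    additive model stays exact for recovery tests by default.
    """
    rng = np.random.default_rng(spec.seed)
    g, e = len(spec.g_effects), len(spec.r_effects)
    cell = (spec.mu + spec.g_effects[:, None] + spec.r_effects[None, :]
            + spec.interaction)
    rows = []
    for r in range(spec.replicates):
        noise = rng.normal(0.0, spec.noise_sd, size=(g, e)) \
            if spec.noise_sd > 0 else np.zeros((g, e))
        vals = cell + noise
        if spec.clip:
            vals = np.clip(vals, 0.0, 1.0)
        for i in range(g):
            for j in range(e):
                rows.append({"genotype": spec.genotype_names[i],
                             "environment": spec.env_names[j],
                             "replicate": r + 1,
                             "value": vals[i, j]})
    return pd.DataFrame(rows)
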