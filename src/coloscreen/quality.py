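"""Quality control: blur, pen-mark and shadow detection.

Out-of-focus regions, marker ink and scanner shadows corrupt every
downstream measurement, so each tissue is screened first.  Focus is scored
per tile as the variance of the Laplacian of the luminance channel — a
standard, deterministic focus metric that collapses by orders of magnitude
under Gaussian defocus.  Tissues dominated by artifacts are ruled
unusable (they end as Unclassifiable); lightly affected tissues proceed
with their degraded tiles masked out.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .config import QualityConfig
from .slide_io import TissueImage


def _luminance(rgb: np.ndarray) -> np.ndarray:
    f = rgb.astype(np.float32)
    return 0.299 * f[..., 0] + 0.587 * f[..., 1] + 0.114 * f[..., 2]


def _saturation(rgb: np.ndarray) -> np.ndarray:
    f = rgb.astype(np.float32)
    return (f.max(axis=-1) - f.min(axis=-1)) / (f.max(axis=-1) + 1e-6)


@dataclass
class SharpnessMap:
    """Per-tile focus scores with a foreground flag grid."""

    tile_size_px: int
    scores: np.ndarray  # (n_rows, n_cols) float, variance of Laplacian
    foreground: np.ndarray  # (n_rows, n_cols) bool

    def __post_init__(self) -> None:
        if self.scores.shape != self.foreground.shape:
            raise ValueError("score and foreground grids must be congruent")
        if not np.isfinite(self.scores).all():
            raise ValueError("focus scores must be finite")


@dataclass
class QualityVerdict:
    status: str  # ok | partial_degraded | unusable
    blurred_fraction: float
    pen_mark_fraction: float
    shadow_fraction: float

    def to_dict(self) -> dict:
        return {
            "status": self.status,
            "blurred_fraction": self.blurred_fraction,
            "pen_mark_fraction": self.pen_mark_fraction,
            "shadow_fraction": self.shadow_fraction,
        }


def _tile_view(arr: np.ndarray, t: int) -> np.ndarray:
    """Crop to a multiple of the tile size and reshape to (nr, nc, t, t)."""
    h, w = arr.shape
    nr, nc = h // t, w // t
    return arr[: nr * t, : nc * t].reshape(nr, t, nc, t).swapaxes(1, 2)


def sharpness_map(tissue: TissueImage, tile_size_px: int = 64) -> SharpnessMap:
    """Variance-of-Laplacian focus score for each foreground tile.

    A tile is foreground when enough of its pixels look stained (saturation
    above a small floor and luminance below near-white); background tiles
    carry no focus information and are excluded from all fractions.
    """
    if tile_size_px < 32:
        raise ValueError("tile_size_px must be >= 32")
    h, w = tissue.shape
    if h < tile_size_px or w < tile_size_px:
        raise ValueError("tissue smaller than one tile")
    lum = _luminance(tissue.pixels)
    sat = _saturation(tissue.pixels)
    lap = ndi.laplace(lum)
    tiles_lap = _tile_view(lap, tile_size_px)
    scores = tiles_lap.var(axis=(2, 3))
    stained = (sat > 0.08) & (lum < 235.0)
    fg_frac = _tile_view(stained.astype(np.float32), tile_size_px).mean(axis=(2, 3))
    return SharpnessMap(tile_size_px=tile_size_px, scores=scores, foreground=fg_frac > 0.5)


def detect_pen_marks(tissue: TissueImage, min_area_mm2: float = 0.01) -> np.ndarray:
    """Mask marker-ink pixels (blue/green/black pen annotations).

    Ink is far more chromatic than H&E tissue (or, for black ink, far
    darker): flagged pixels have saturation above a high quantile with a hue
    away from the H&E pink-purple band, or a very low value.  Components
    smaller than ``min_area_mm2`` are treated as noise and dropped.
    """
    f = tissue.pixels.astype(np.float32) / 255.0
    mx = f.max(axis=-1)
    mn = f.min(axis=-1)
    sat = (mx - mn) / (mx + 1e-6)
    # hue in degrees
    r, g, b = f[..., 0], f[..., 1], f[..., 2]
    denom = (mx - mn) + 1e-6
    hue = np.where(
        mx == r,
        (60 * (g - b) / denom) % 360,
        np.where(mx == g, 60 * (b - r) / denom + 120, 60 * (r - g) / denom + 240),
    )
    # H&E hues live in magenta/pink/red (>290 deg or <40 deg); ink hues
    # (blue ~220, green ~140) sit far from both stains
    ink_hue = (hue > 70) & (hue < 280)
    sat_hi = sat > max(0.35, float(np.quantile(sat, 0.98)) * 0.9)
    very_dark = mx < 0.18
    mask = (sat_hi & ink_hue) | very_dark
    if not mask.any():
        return mask
    min_px = int(min_area_mm2 * 1e6 / (tissue.um_per_px**2))
    labels, n = ndi.label(mask)
    if n:
        sizes = np.bincount(labels.ravel())
        keep = sizes >= min_px
        keep[0] = False
        mask = keep[labels]
    return mask


def detect_shadow(tissue: TissueImage, smooth_um: float = 30.0) -> np.ndarray:
    """Mask shadowed background beside the tissue.

    The illumination field is estimated by heavy Gaussian smoothing of the
    luminance; pixels where it falls more than 20% below the background
    white point, and which are not stained tissue (multiplicative darkening
    leaves saturation low), are shadow.
    """
    lum = _luminance(tissue.pixels)
    sat = _saturation(tissue.pixels)
    white = float(np.percentile(lum, 99))
    # illumination field from background pixels only: stained tissue is dark
    # for staining reasons, not lighting, and must not drag the field down
    background_lum = np.where(sat < 0.12, lum, white)
    sigma = smooth_um / tissue.um_per_px
    field = ndi.gaussian_filter(background_lum, sigma)
    return (field < 0.8 * white) & (sat < 0.12)


def assess_quality(
    sharpness: SharpnessMap,
    pen_mask: np.ndarray,
    shadow_mask: np.ndarray,
    cfg: QualityConfig | None = None,
) -> QualityVerdict:
    """Combine the evidence maps into an ok / partial_degraded / unusable verdict.

    All fractions are computed over foreground tiles: a tile is blurred when
    its focus score is below the blur threshold, and pen/shadow tiles are
    those where the artifact covers more than 10% of the tile.
    """
    cfg = cfg or QualityConfig()
    fg = sharpness.foreground
    n_fg = int(fg.sum())
    if n_fg == 0:
        return QualityVerdict("unusable", 1.0, 0.0, 0.0)
    t = sharpness.tile_size_px
    blurred = (sharpness.scores < cfg.blur_threshold) & fg
    blurred_fraction = float(blurred.sum() / n_fg)

    def tile_fraction(mask: np.ndarray) -> float:
        nr, nc = fg.shape
        cov = _tile_view(mask[: nr * t, : nc * t].astype(np.float32), t).mean(axis=(2, 3))
        return float(((cov > 0.10) & fg).sum() / n_fg)

    pen_fraction = tile_fraction(pen_mask)
    shadow_fraction = tile_fraction(shadow_mask)
    if (
        blurred_fraction >= cfg.blur_frac_unusable
        or pen_fraction >= cfg.pen_frac_unusable
        or shadow_fraction >= cfg.shadow_frac_unusable
    ):
        status = "unusable"
    elif max(blurred_fraction, pen_fraction, shadow_fraction) > cfg.degraded_frac_partial:
        status = "partial_degraded"
    else:
        status = "ok"
    return QualityVerdict(status, blurred_fraction, pen_fraction, shadow_fraction)


def degraded_tile_mask(sharpness: SharpnessMap, pen_mask: np.ndarray, shadow_mask: np.ndarray, cfg: QualityConfig) -> np.ndarray:
    """Full-resolution mask of pixels in degraded tiles (to exclude from analysis)."""
    t = sharpness.tile_size_px
    nr, nc = sharpness.scores.shape
    blurred = (sharpness.scores < cfg.blur_threshold) & sharpness.foreground
    full = np.kron(blurred, np.ones((t, t), dtype=bool))
    out = np.zeros(pen_mask.shape, dtype=bool)
    out[: nr * t, : nc * t] |= full
    out |= pen_mask
    out |= shadow_mask
    return out
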