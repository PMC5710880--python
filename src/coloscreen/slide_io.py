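"""Slide loading, tissue-region detection and per-tissue cropping.

A biopsy slide typically carries several tissue fragments.  The pipeline
works on one fragment at a time: the slide overview (coarsest pyramid
level) is segmented into individual tissue regions, and each region is then
cropped from the pyramid at the analysis resolution.

Conventions used throughout the package: 0-based row-major coordinates,
origin at the top-left, and half-open crop intervals ``[row0, row1) x
[col0, col1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.transform import resize


@dataclass
class TissueImage:
    """One cropped tissue region with its pixel spacing.

    The unit of classification: every downstream stage (quality control,
    normalization, atypia analysis) consumes a TissueImage.
    """

    pixels: np.ndarray  # (H, W, 3) uint8 RGB
    um_per_px: float
    region_id: int = 0
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be positive")
        if self.pixels.size == 0:
            raise ValueError("empty pixel array")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


@dataclass
class SlidePyramid:
    """Multi-resolution slide: levels sorted coarse -> fine."""

    levels: list[tuple[np.ndarray, float]]  # (image, um_per_px)
    base_um_per_px: float

    def __post_init__(self) -> None:
        self.levels = sorted(self.levels, key=lambda lv: -lv[1])
        if not self.levels:
            raise ValueError("pyramid has no levels")

    @property
    def base(self) -> np.ndarray:
        return self.levels[-1][0]

    @property
    def overview(self) -> tuple[np.ndarray, float]:
        return self.levels[0]


@dataclass
class TissueRegion:
    """A connected tissue fragment found on the overview."""

    region_id: int
    bbox: tuple[int, int, int, int]  # (row0, col0, row1, col1), base-level px, half-open
    mask: np.ndarray  # binary, at detection level
    area_mm2: float


def load_slide(path: str | Path, um_per_px: float | None = None) -> SlidePyramid:
    """Load a plain/pyramidal TIFF or a PNG (single level).

    ``um_per_px`` gives the base (finest) level's pixel spacing; it is
    required unless the TIFF carries resolution metadata.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in (".png", ".jpg", ".jpeg"):
        if um_per_px is None:
            raise ValueError("pixel spacing metadata missing: pass um_per_px for PNG input")
        img = np.asarray(iio.imread(path))
        return SlidePyramid(levels=[(img, float(um_per_px))], base_um_per_px=float(um_per_px))
    if suffix in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            pages = [p.asarray() for p in tf.pages]
            if um_per_px is None:
                res = tf.pages[0].tags.get("XResolution")
                unit = tf.pages[0].tags.get("ResolutionUnit")
                if res is not None and unit is not None and getattr(unit.value, "value", unit.value) == 3:
                    num, den = res.value  # pixels per cm
                    um_per_px = 1e4 * den / num
                else:
                    raise ValueError("pixel spacing metadata missing: pass um_per_px for this TIFF")
        base_w = max(p.shape[1] for p in pages)
        levels = [(p, float(um_per_px) * base_w / p.shape[1]) for p in pages]
        return SlidePyramid(levels=levels, base_um_per_px=float(um_per_px))
    raise ValueError(f"unsupported slide format: {suffix}")


def write_pyramid(path: str | Path, base: np.ndarray, base_um_per_px: float, n_levels: int = 3) -> None:
    """Write a plain pyramidal TIFF (successive 2x downsamples as pages)."""
    pages = [base]
    for _ in range(n_levels - 1):
        prev = pages[-1]
        h, w = prev.shape[0] // 2, prev.shape[1] // 2
        pages.append(
            (resize(prev, (h, w, 3), order=1, anti_aliasing=True, preserve_range=True)).astype(np.uint8)
        )
    with tifffile.TiffWriter(path) as tw:
        for page in pages:
            tw.write(page, photometric="rgb")


def _luminance(rgb: np.ndarray) -> np.ndarray:
    f = rgb.astype(np.float32)
    return 0.299 * f[..., 0] + 0.587 * f[..., 1] + 0.114 * f[..., 2]


def _saturation(rgb: np.ndarray) -> np.ndarray:
    f = rgb.astype(np.float32)
    mx = f.max(axis=-1)
    mn = f.min(axis=-1)
    return (mx - mn) / (mx + 1e-6)


def _edt_closing(mask: np.ndarray, radius_px: float) -> np.ndarray:
    """Binary closing with a Euclidean disk via two distance transforms.

    Equivalent to dilation-then-erosion with a disk of ``radius_px`` but
    O(N) regardless of radius, which matters for the 250 um closing used at
    overview scale.
    """
    if radius_px <= 0 or not mask.any():
        return mask.copy()
    dilated = ndi.distance_transform_edt(~mask) <= radius_px
    closed = ndi.distance_transform_edt(dilated) > radius_px
    return closed | mask


def detect_tissues(
    overview: np.ndarray,
    um_per_px: float,
    min_area_mm2: float = 0.05,
    base_um_per_px: float | None = None,
    closing_radius_um: float = 250.0,
) -> list[TissueRegion]:
    """Find individual tissue fragments on a brightfield overview.

    Background is removed with image-derived thresholds (Otsu on the
    saturation channel combined with a luminance quantile), fragments closer
    than the closing radius are merged, and components smaller than
    ``min_area_mm2`` are dropped.  Regions are returned in reading order
    (top-to-bottom, then left-to-right).
    """
    if base_um_per_px is None:
        base_um_per_px = um_per_px
    sat = _saturation(overview)
    lum = _luminance(overview)
    finite_sat = sat[np.isfinite(sat)]
    if finite_sat.size == 0 or finite_sat.max() < 1e-3:
        return []
    try:
        sat_thr = threshold_otsu(sat)
    except ValueError:
        return []
    lum_q = np.quantile(lum, 0.92)
    fg = (sat > sat_thr) & (lum < 0.98 * lum_q)
    if not fg.any():
        return []
    fg = _edt_closing(fg, closing_radius_um / um_per_px)
    fg = ndi.binary_fill_holes(fg)
    labels, n = ndi.label(fg)
    regions: list[TissueRegion] = []
    px_mm2 = (um_per_px / 1000.0) ** 2
    scale = um_per_px / base_um_per_px
    for lab in range(1, n + 1):
        mask = labels == lab
        area = float(mask.sum() * px_mm2)
        if area < min_area_mm2:
            continue
        rows, cols = np.nonzero(mask)
        r0, r1 = int(rows.min()), int(rows.max()) + 1
        c0, c1 = int(cols.min()), int(cols.max()) + 1
        bbox = (
            int(round(r0 * scale)),
            int(round(c0 * scale)),
            int(round(r1 * scale)),
            int(round(c1 * scale)),
        )
        regions.append(TissueRegion(region_id=0, bbox=bbox, mask=mask, area_mm2=area))
    regions.sort(key=lambda r: (r.bbox[0], r.bbox[1]))
    for i, r in enumerate(regions):
        r.region_id = i
    return regions


def crop_tissue(slide: SlidePyramid, region: TissueRegion, target_um_per_px: float) -> TissueImage:
    """Crop one region from the pyramid at the requested pixel spacing.

    The pyramid level closest to the target spacing is cropped with
    half-open bounds and resampled to the exact target spacing when the
    level spacing differs by more than 1%.  Padding outside the slide is
    forbidden.
    """
    if target_um_per_px < slide.base_um_per_px:
        raise ValueError("target spacing finer than the base level")
    r0, c0, r1, c1 = region.bbox
    base_h, base_w = slide.base.shape[:2]
    if r0 < 0 or c0 < 0 or r1 > base_h or c1 > base_w or r1 <= r0 or c1 <= c0:
        raise ValueError(f"bbox {region.bbox} exceeds slide bounds {base_h}x{base_w}")
    level_img, level_um = min(slide.levels, key=lambda lv: abs(lv[1] - target_um_per_px))
    s = slide.base_um_per_px / level_um
    lr0, lc0 = int(round(r0 * s)), int(round(c0 * s))
    lr1, lc1 = int(round(r1 * s)), int(round(c1 * s))
    crop = level_img[lr0:lr1, lc0:lc1]
    if abs(level_um / target_um_per_px - 1.0) > 0.01:
        out_h = int(round((r1 - r0) * slide.base_um_per_px / target_um_per_px))
        out_w = int(round((c1 - c0) * slide.base_um_per_px / target_um_per_px))
        crop = resize(
            crop,
            (out_h, out_w, 3),
            order=1,
            anti_aliasing=level_um < target_um_per_px,
            preserve_range=True,
        ).astype(np.uint8)
    return TissueImage(
        pixels=np.ascontiguousarray(crop),
        um_per_px=target_um_per_px,
        region_id=region.region_id,
        provenance=f"bbox={region.bbox}",
    )


def regions_to_csv(regions: list[TissueRegion], path: str | Path) -> None:
    rows = [
        {
            "region_id": r.region_id,
            "row0": r.bbox[0],
            "col0": r.bbox[1],
            "row1": r.bbox[2],
            "col1": r.bbox[3],
            "area_mm2": r.area_mm2,
        }
        for r in regions
    ]
    pd.DataFrame(rows, columns=["region_id", "row0", "col0", "row1", "col1", "area_mm2"]).to_csv(
        path, index=False
    )
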