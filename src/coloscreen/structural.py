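"""Structural (glandular) atypia analysis.

Architectural abnormality of colonic glands — thickened, pseudostratified
nuclear rims — separates adenoma from well/moderately differentiated
adenocarcinoma.  The analysis mimics how a pathologist scans a slide, in
two magnification passes to keep computation bounded:

1. a tissue mask is made (lumina kept as holes);
2. at low magnification, glandular nuclear components are extracted by
   hematoxylin thresholding plus a closing that links the nuclei of one
   gland rim; each component's rim thickness (2x median skeleton distance)
   is discretized into gland level 1-10 on fixed micrometre bins, shown
   cool -> warm;
3. only for components at or above a trigger level, a high-magnification
   pass segments nuclei vs cytoplasm inside the gland and scores the loss
   of basal nuclear polarity (the arrangement score in [0, 1]).

The tissue is then rated low / middle / high / unclassifiable from the
maximum gland level and the arrangement scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import skeletonize
from skimage.transform import resize

from .config import StructuralConfig
from .slide_io import TissueImage
from .stains import StainEstimate, hematoxylin_map

STRUCTURAL_LEVELS = ("low", "middle", "high", "unclassifiable")

#: 10-entry cool->warm palette for gland-level overlays (blue -> red)
LEVEL_PALETTE = np.array(
    [
        [49, 54, 149],
        [69, 117, 180],
        [116, 173, 209],
        [171, 217, 233],
        [224, 243, 248],
        [254, 224, 144],
        [253, 174, 97],
        [244, 109, 67],
        [215, 48, 39],
        [165, 0, 38],
    ],
    dtype=np.uint8,
)


@dataclass
class GlandComponent:
    """One connected glandular nuclear component (low-mag pass)."""

    component_id: int
    pixel_mask: np.ndarray  # bool, full-image frame
    thickness_um: float = 0.0
    gland_level: int = 0

    def to_dict(self) -> dict:
        return {
            "component_id": self.component_id,
            "thickness_um": round(self.thickness_um, 2),
            "gland_level": self.gland_level,
        }


@dataclass
class GlandSegmentation:
    """High-mag nuclei/cytoplasm split of one gland, with polarity score."""

    component_id: int
    nuclei_mask: np.ndarray
    cytoplasm_mask: np.ndarray
    arrangement_score: float

    def __post_init__(self) -> None:
        if (self.nuclei_mask & self.cytoplasm_mask).any():
            raise ValueError("nuclei and cytoplasm masks must be disjoint")
        if not np.isfinite(self.arrangement_score):
            raise ValueError("arrangement_score must be finite")


@dataclass
class StructuralResult:
    level: str
    components: list[GlandComponent] = field(default_factory=list)
    segmentations: list[GlandSegmentation] = field(default_factory=list)

    def max_level(self) -> int:
        return max((c.gland_level for c in self.components), default=0)

    def to_dict(self) -> dict:
        return {
            "level": self.level,
            "max_gland_level": self.max_level(),
            "components": [c.to_dict() for c in self.components],
            "arrangement_scores": [round(s.arrangement_score, 3) for s in self.segmentations],
        }


def _edt_closing(mask: np.ndarray, radius_px: float) -> np.ndarray:
    if radius_px <= 0 or not mask.any():
        return mask.copy()
    dilated = ndi.distance_transform_edt(~mask) <= radius_px
    closed = ndi.distance_transform_edt(dilated) > radius_px
    return closed | mask


def make_mask(tissue: TissueImage, od_threshold: float = 0.12) -> np.ndarray:
    """Tissue-foreground mask, excluding background and lumina.

    OD-based threshold on the normalized image; holes (gland lumina) are
    deliberately NOT filled so they stay available as landmarks.
    """
    f = tissue.pixels.astype(np.float32)
    white = np.maximum(np.percentile(f.reshape(-1, 3), 99, axis=0), 1.0)
    od = -np.log(np.clip(f, 1.0, None) / white)
    mask = np.linalg.norm(od, axis=-1) > od_threshold
    mask = _edt_closing(mask, 2.0)
    if not mask.any():
        raise ValueError("empty tissue foreground")
    return mask


def extract_glandular_nuclei_lowmag(
    tissue: TissueImage,
    mask: np.ndarray,
    cfg: StructuralConfig | None = None,
    stain_estimate: StainEstimate | None = None,
) -> list[GlandComponent]:
    """Extract glandular nuclear components at low magnification.

    Hematoxylin concentration above the nuclear threshold marks nuclei; a
    closing of one nuclear width links the nuclei of one gland rim into a
    single connected component; components smaller than the configured
    minimum (in nuclei-equivalents of area) are discarded.
    """
    cfg = cfg or StructuralConfig()
    h = hematoxylin_map(tissue, stain_estimate)
    nuclear = (h > cfg.h_conc_threshold) & mask
    radius_px = cfg.nuclear_width_um / tissue.um_per_px
    linked = _edt_closing(nuclear, radius_px)
    labels, n = ndi.label(linked)
    if n == 0:
        return []
    nucleus_area_px = np.pi * (0.45 * radius_px) * (0.42 * radius_px)
    min_area = cfg.min_component_nuclei * nucleus_area_px
    comps: list[GlandComponent] = []
    sizes = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    cid = 0
    for lab, size in enumerate(sizes, start=1):
        if size < min_area:
            continue
        comps.append(GlandComponent(component_id=cid, pixel_mask=labels == lab))
        cid += 1
    return comps


def quantify_thickness(pixel_mask: np.ndarray, um_per_px: float) -> float:
    """Rim thickness: 2x the median Euclidean distance over the skeleton.

    Robust to branch points and to the scalloped boundary left by
    individual nuclei; returned in micrometres.
    """
    if not pixel_mask.any():
        raise ValueError("empty component mask")
    rows, cols = np.nonzero(pixel_mask)
    r0, r1 = rows.min(), rows.max() + 1
    c0, c1 = cols.min(), cols.max() + 1
    crop = np.pad(pixel_mask[r0:r1, c0:c1], 1)
    edt = ndi.distance_transform_edt(crop)
    skel = skeletonize(crop)
    if not skel.any():
        return 2.0 * um_per_px  # single-pixel structure: minimal width
    return float(2.0 * np.median(edt[skel]) * um_per_px)


def assign_gland_levels(
    components: list[GlandComponent], cfg: StructuralConfig | None = None
) -> list[GlandComponent]:
    """Map thickness to gland level 1..10 on fixed equal-width bins.

    Bins are absolute micrometre widths (default 10 bins over 5-55 um,
    clipped at both ends) so levels are comparable across images.
    """
    cfg = cfg or StructuralConfig()
    width = (cfg.bin_max_um - cfg.bin_min_um) / cfg.n_levels
    for comp in components:
        lvl = 1 + int(np.floor((comp.thickness_um - cfg.bin_min_um) / width))
        comp.gland_level = int(np.clip(lvl, 1, cfg.n_levels))
    return components


def render_levels(tissue: TissueImage, components: list[GlandComponent]) -> np.ndarray:
    """Overlay: each component painted with its level's cool->warm color."""
    overlay = tissue.pixels.copy()
    for comp in components:
        overlay[comp.pixel_mask] = LEVEL_PALETTE[comp.gland_level - 1]
    return overlay


def _zoom_crop(tissue: TissueImage, bbox: tuple[int, int, int, int], target_um_per_px: float) -> tuple[np.ndarray, float]:
    """Resampled crop emulating a high-magnification fetch of one gland."""
    r0, c0, r1, c1 = bbox
    crop = tissue.pixels[r0:r1, c0:c1]
    scale = tissue.um_per_px / target_um_per_px
    out_shape = (int(round(crop.shape[0] * scale)), int(round(crop.shape[1] * scale)), 3)
    up = resize(crop, out_shape, order=1, preserve_range=True, anti_aliasing=scale < 1).astype(np.uint8)
    return up, target_um_per_px


def segment_gland_cells_highmag(
    tissue: TissueImage,
    component: GlandComponent,
    cfg: StructuralConfig | None = None,
    stain_estimate: StainEstimate | None = None,
) -> GlandSegmentation:
    """High-magnification nuclei/cytoplasm segmentation and polarity scoring.

    Within the dilated component, nuclei are high-hematoxylin pixels and
    cytoplasm the remaining eosin-dominant gland pixels.  The arrangement
    score is the fraction of angular cross-sections of the gland whose
    nuclei are NOT confined to the basal (outer) half of the epithelium:
    0 for a perfectly polarized single layer, approaching 1 when nuclei are
    stratified through to the luminal surface.
    """
    cfg = cfg or StructuralConfig()
    if not component.pixel_mask.any():
        raise ValueError("component absent from high-mag crop")
    rows, cols = np.nonzero(component.pixel_mask)
    pad = int(2 * cfg.nuclear_width_um / tissue.um_per_px)
    r0 = max(0, rows.min() - pad)
    r1 = min(tissue.shape[0], rows.max() + 1 + pad)
    c0 = max(0, cols.min() - pad)
    c1 = min(tissue.shape[1], cols.max() + 1 + pad)
    hi_px, hi_um = _zoom_crop(tissue, (r0, c0, r1, c1), cfg.highmag_um_per_px)
    hi = TissueImage(pixels=hi_px, um_per_px=hi_um, region_id=tissue.region_id)
    h = hematoxylin_map(hi, stain_estimate)

    f = hi_px.astype(np.float32)
    white = np.maximum(np.percentile(f.reshape(-1, 3), 99, axis=0), 1.0)
    od_norm = np.linalg.norm(-np.log(np.clip(f, 1.0, None) / white), axis=-1)
    tissue_px = od_norm > 0.12

    comp_crop = component.pixel_mask[r0:r1, c0:c1]
    comp_hi = resize(comp_crop.astype(float), h.shape, order=0, preserve_range=True) > 0.5
    region = ndi.distance_transform_edt(~comp_hi) <= 2.5 * cfg.nuclear_width_um / hi_um

    nuclei = (h > cfg.h_conc_threshold) & region & tissue_px
    gland_solid = ndi.binary_fill_holes(region & tissue_px)
    lumen = gland_solid & ~tissue_px
    cytoplasm = gland_solid & tissue_px & ~nuclei

    if not nuclei.any() or not lumen.any():
        # no lumen (solid nest) or no nuclei: polarity not assessable
        return GlandSegmentation(component.component_id, nuclei, cytoplasm, 0.0)

    # Polarity: a polarized epithelium keeps a nucleus-free apical cytoplasm
    # band against the lumen; stratified nuclei invade it.  An angular
    # cross-section violates polarity when a nuclear pixel approaches the
    # lumen closer than half a nuclear width.
    gap_px = 0.5 * cfg.nuclear_width_um / hi_um
    d_lumen = ndi.distance_transform_edt(~lumen)
    luminal_nuclei = nuclei & (d_lumen < gap_px)

    cy, cx = ndi.center_of_mass(gland_solid)
    yy, xx = np.nonzero(nuclei)
    theta = np.arctan2(yy - cy, xx - cx)
    n_bins = 48
    bins = ((theta + np.pi) / (2 * np.pi) * n_bins).astype(int) % n_bins
    has_nuc = np.bincount(bins, minlength=n_bins) > 0
    viol = luminal_nuclei[yy, xx]
    has_violation = np.bincount(bins[viol], minlength=n_bins) > 0
    n_sections = int(has_nuc.sum())
    score = float(has_violation.sum() / n_sections) if n_sections else 0.0
    return GlandSegmentation(component.component_id, nuclei, cytoplasm, score)


def classify_structural(
    components: list[GlandComponent],
    segmentations: list[GlandSegmentation],
    cfg: StructuralConfig | None = None,
    glands_expected: bool = True,
) -> StructuralResult:
    """Rate the tissue low / middle / high / unclassifiable.

    Pure function of the assigned levels and arrangement scores:
    no measurable component -> unclassifiable (or low when the tissue is
    known gland-free); max level <= cut_low -> low; max level >= cut_high
    or any arrangement score >= the cut -> high; otherwise middle.
    """
    cfg = cfg or StructuralConfig()
    measurable = [c for c in components if c.gland_level >= 1]
    if not measurable:
        level = "unclassifiable" if glands_expected else "low"
        return StructuralResult(level=level, components=components, segmentations=segmentations)
    max_level = max(c.gland_level for c in measurable)
    max_arr = max((s.arrangement_score for s in segmentations), default=0.0)
    if max_level >= cfg.cut_high or max_arr >= cfg.arrangement_cut:
        level = "high"
    elif max_level <= cfg.cut_low:
        level = "low"
    else:
        level = "middle"
    return StructuralResult(level=level, components=measurable, segmentations=segmentations)


def analyze_structural(
    tissue: TissueImage,
    cfg: StructuralConfig | None = None,
    stain_estimate: StainEstimate | None = None,
    _highmag_counter: list | None = None,
) -> StructuralResult:
    """Full two-pass structural analysis of one (normalized) tissue image."""
    cfg = cfg or StructuralConfig()
    try:
        mask = make_mask(tissue)
    except ValueError:
        return StructuralResult(level="unclassifiable")
    comps = extract_glandular_nuclei_lowmag(tissue, mask, cfg, stain_estimate)
    for comp in comps:
        comp.thickness_um = quantify_thickness(comp.pixel_mask, tissue.um_per_px)
    assign_gland_levels(comps, cfg)
    segs: list[GlandSegmentation] = []
    for comp in comps:
        if comp.gland_level >= cfg.trigger_level:
            if _highmag_counter is not None:
                _highmag_counter.append(comp.component_id)
            segs.append(segment_gland_cells_highmag(tissue, comp, cfg, stain_estimate))
    return classify_structural(comps, segs, cfg)
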