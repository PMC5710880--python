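"""Seeded generator of synthetic H&E-like colonic mucosa with ground truth.

Renders tissue fragments built from tubular glands — an elliptical lumen,
an apical cytoplasm band, and a basal rim of hematoxylin-dark nuclei — on
an eosinophilic stromal background, plus a dissociated-cell mode emulating
poorly differentiated / signet-ring carcinoma.  Per-pixel hematoxylin and
eosin optical densities are composited to RGB through the Beer-Lambert
relation ``I = background * exp(-OD)`` with Ruifrok-style stain direction
defaults, so stain-estimation code can be tested against known vectors.

The morphology dial is the phenotype: rim thickness in nuclear widths
(normal mucosa ~1, adenoma ~2-3, carcinoma >=3), nuclear stratification
(loss of basal polarity, 0..1), and dissociated-cell density for the
gland-free carcinoma mode.  Batch effects (stain vector shifts, intensity
and contrast changes) and acquisition artifacts (blur, shadow, pen marks)
are applied as separate, composable operations.

Everything is a pure function of its seed: each operation draws from a
fresh ``numpy`` Generator keyed on (seed, operation name).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import line as draw_line

from .slide_io import TissueImage

# Ruifrok & Johnston H / E optical-density directions (unit-normalized).
HEMATOXYLIN_OD = np.array([0.650, 0.704, 0.286]) / np.linalg.norm([0.650, 0.704, 0.286])
EOSIN_OD = np.array([0.072, 0.990, 0.105]) / np.linalg.norm([0.072, 0.990, 0.105])

DEFAULT_CANVAS = (1024, 1024)
DEFAULT_UM_PER_PX = 0.92  # 4x downsample of a 0.23 um/px 40x scan

CLASS_LABELS = ("negative", "adenoma", "carcinoma")
#: synthetic class -> Japanese Group Classification row used in evaluation
CLASS_TO_GROUP = {"negative": "Group1", "adenoma": "Group3", "carcinoma": "Group5"}

MANIFEST_COLUMNS = [
    "tissue_id",
    "class",
    "gland_count",
    "rim_thickness",
    "stratification",
    "dissociated_density",
    "blur_sigma",
    "pen_mark",
    "shadow",
    "seed",
]


def _op_rng(seed: int, op_name: str) -> np.random.Generator:
    """One RNG stream per (seed, operation) — no hidden global state."""
    tag = zlib.crc32(op_name.encode())
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, tag]))


@dataclass(frozen=True)
class StainProfile:
    """Batch-dependent staining/acquisition parameters.

    ``contrast_scale`` < 1 compresses stain concentrations around their
    tissue mean, emulating washed-out low-contrast batches in which
    color-based nuclear extraction fails.
    """

    hematoxylin_od_vector: np.ndarray = field(default_factory=lambda: HEMATOXYLIN_OD.copy())
    eosin_od_vector: np.ndarray = field(default_factory=lambda: EOSIN_OD.copy())
    background_rgb: np.ndarray = field(default_factory=lambda: np.array([245.0, 245.0, 245.0]))
    intensity_scale: float = 1.0
    contrast_scale: float = 1.0

    def __post_init__(self) -> None:
        h = np.asarray(self.hematoxylin_od_vector, dtype=float)
        e = np.asarray(self.eosin_od_vector, dtype=float)
        for name, v in (("hematoxylin", h), ("eosin", e)):
            if v.shape != (3,) or (v < 0).any():
                raise ValueError(f"{name} OD vector must be a non-negative 3-vector")
            if abs(np.linalg.norm(v) - 1.0) > 1e-6:
                raise ValueError(f"{name} OD vector must have unit norm")
        bg = np.asarray(self.background_rgb, dtype=float)
        if bg.shape != (3,) or (bg < 200).any():
            raise ValueError("background_rgb components must be >= 200 (brightfield white)")
        if self.intensity_scale <= 0:
            raise ValueError("intensity_scale must be positive")
        if not (0 < self.contrast_scale <= 1.5):
            raise ValueError("contrast_scale must lie in (0, 1.5]")
        object.__setattr__(self, "hematoxylin_od_vector", h)
        object.__setattr__(self, "eosin_od_vector", e)
        object.__setattr__(self, "background_rgb", bg)


DEFAULT_STAIN = StainProfile()


@dataclass(frozen=True)
class TissuePhenotype:
    """Morphological ground truth of one synthetic tissue."""

    class_label: str
    gland_count: int
    rim_thickness_nuclei: float  # basal nuclear rim thickness, in nuclear widths
    stratification: float  # 0 = polarized single layer, 1 = fully stratified
    dissociated_cell_density: float  # cells per 1000 um^2 (signet-ring mode)
    nuclear_size_um: float = 7.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"class_label must be one of {CLASS_LABELS}")
        if self.gland_count < 0:
            raise ValueError("gland_count must be >= 0")
        if self.rim_thickness_nuclei <= 0 or self.nuclear_size_um <= 0:
            raise ValueError("rim thickness and nuclear size must be positive")
        if not (0 <= self.stratification <= 1):
            raise ValueError("stratification must lie in [0, 1]")
        if self.dissociated_cell_density < 0:
            raise ValueError("dissociated_cell_density must be >= 0")
        if self.class_label == "negative" and (
            self.rim_thickness_nuclei > 1.5 or self.dissociated_cell_density != 0
        ):
            raise ValueError("negative phenotype requires rim <= 1.5 nuclei and no dissociated cells")
        if self.class_label == "carcinoma" and not (
            self.rim_thickness_nuclei >= 3 or self.dissociated_cell_density > 0
        ):
            raise ValueError("carcinoma phenotype requires rim >= 3 or dissociated cells")


@dataclass(frozen=True)
class ArtifactSpec:
    """Acquisition artifacts: out-of-focus blur, pen ink, shadow."""

    blur_sigma: float = 0.0
    blur_coverage: float = 0.0
    pen_mark: bool = False
    pen_color: str = "blue"
    shadow: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.blur_sigma < 0 or not (0 <= self.blur_coverage <= 1):
            raise ValueError("invalid blur parameters")
        if (self.blur_coverage == 0) != (self.blur_sigma == 0):
            raise ValueError("blur_coverage must be 0 exactly when blur_sigma is 0")
        if self.pen_color not in ("blue", "green", "black"):
            raise ValueError("pen_color must be blue, green or black")


NO_ARTIFACTS = ArtifactSpec()

PEN_COLORS = {
    "blue": np.array([30.0, 60.0, 200.0]),
    "green": np.array([25.0, 150.0, 70.0]),
    "black": np.array([25.0, 25.0, 25.0]),
}


@dataclass
class GroundTruth:
    """Per-pixel ground truth rendered alongside the image."""

    nuclei_mask: np.ndarray  # int32 label image, one label per nucleus
    cytoplasm_mask: np.ndarray  # int32 label image (gland id / dissociated id)
    gland_mask: np.ndarray  # int32 label image of whole gland discs
    lumen_mask: np.ndarray  # bool
    artifact_mask: np.ndarray  # bool, union of all artifact footprints
    phenotype: TissuePhenotype | None = None
    stroma_mask: np.ndarray | None = None
    blur_mask: np.ndarray | None = None
    pen_mask: np.ndarray | None = None
    shadow_mask: np.ndarray | None = None
    nucleus_gland_id: dict[int, int] = field(default_factory=dict)  # 0 = dissociated


def _stroma_blob(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """Rounded tissue-fragment mask covering most of the canvas."""
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w].astype(np.float32)
    cy, cx = h / 2 + rng.uniform(-0.02, 0.02) * h, w / 2 + rng.uniform(-0.02, 0.02) * w
    ay, ax = 0.40 * h, 0.40 * w
    theta = np.arctan2(rr - cy, cc - cx)
    # low-order harmonic wobble on the boundary radius
    amps = rng.uniform(-0.05, 0.05, size=3)
    phases = rng.uniform(0, 2 * np.pi, size=3)
    wobble = 1.0 + sum(a * np.sin((k + 2) * theta + p) for k, (a, p) in enumerate(zip(amps, phases)))
    r2 = ((rr - cy) / ay) ** 2 + ((cc - cx) / ax) ** 2
    return r2 <= wobble


def _stamp_nucleus(
    nuclei: np.ndarray,
    h_conc: np.ndarray,
    e_conc: np.ndarray,
    label: int,
    center: tuple[float, float],
    semi_axes: tuple[float, float],
    angle: float,
    intensity: float,
) -> None:
    rr, cc = draw_ellipse(
        center[0], center[1], semi_axes[0], semi_axes[1], shape=nuclei.shape, rotation=angle
    )
    nuclei[rr, cc] = label
    h_conc[rr, cc] = intensity
    e_conc[rr, cc] = 0.08  # chromatin displaces eosinophilic material


def render_tissue(
    phenotype: TissuePhenotype,
    stain: StainProfile = DEFAULT_STAIN,
    size_px: tuple[int, int] = DEFAULT_CANVAS,
    um_per_px: float = DEFAULT_UM_PER_PX,
) -> tuple[TissueImage, GroundTruth]:
    """Render one tissue fragment and its per-pixel ground truth.

    Glands are placed without overlap inside a stromal blob; each gland is
    an elliptical lumen, an apical cytoplasm band one nuclear width thick,
    and a basal rim of stamped nuclei whose radial extent equals
    ``rim_thickness_nuclei`` nuclear widths.  Stratification jitters nuclei
    toward the lumen and seeds extra luminal nuclei.  Deterministic for a
    fixed phenotype seed.
    """
    h_px, w_px = int(size_px[0]), int(size_px[1])
    if h_px < 256 or w_px < 256:
        raise ValueError("canvas must be at least 256x256")
    if um_per_px <= 0:
        raise ValueError("um_per_px must be positive")
    rng = _op_rng(phenotype.seed, "render_tissue")

    w_um = phenotype.nuclear_size_um  # nominal nuclear width
    w = w_um / um_per_px  # in px
    nuclei = np.zeros((h_px, w_px), dtype=np.int32)
    cytoplasm = np.zeros((h_px, w_px), dtype=np.int32)
    glands = np.zeros((h_px, w_px), dtype=np.int32)
    lumen = np.zeros((h_px, w_px), dtype=bool)
    nucleus_gland: dict[int, int] = {}

    stroma = _stroma_blob(rng, (h_px, w_px))
    h_conc = np.zeros((h_px, w_px), dtype=np.float32)
    e_conc = np.zeros((h_px, w_px), dtype=np.float32)
    # stromal background: light eosin with smooth mottle, faint hematoxylin
    mottle = ndi.gaussian_filter(rng.normal(0, 1, (h_px, w_px)).astype(np.float32), 9)
    mottle /= max(np.abs(mottle).max(), 1e-6)
    e_conc[stroma] = 0.30 + 0.08 * mottle[stroma]
    h_conc[stroma] = 0.04

    # ---- gland geometry (all radial quantities in px) ----
    rim_t = phenotype.rim_thickness_nuclei * w
    cyto_t = 1.0 * w
    label = 0
    centers: list[tuple[float, float, float]] = []  # (r, c, outer_radius)
    rows_idx, cols_idx = np.nonzero(stroma)
    interior = ndi.distance_transform_edt(stroma)
    for g in range(phenotype.gland_count):
        lumen_r = rng.uniform(1.2, 2.2) * w
        outer = lumen_r + cyto_t + rim_t
        placed = False
        for _ in range(60):
            k = rng.integers(0, rows_idx.size)
            cy, cx = float(rows_idx[k]), float(cols_idx[k])
            if interior[int(cy), int(cx)] < outer + 1.5 * w:
                continue
            if all((cy - py) ** 2 + (cx - px) ** 2 > (outer + pr + 4 * w) ** 2 for py, px, pr in centers):
                placed = True
                break
        if not placed:
            continue
        centers.append((cy, cx, outer))
        gid = g + 1
        ecc = rng.uniform(0.78, 1.0)  # mild gland ellipticity
        ang = rng.uniform(0, np.pi)
        rr, cc = draw_ellipse(cy, cx, outer, outer * ecc, shape=(h_px, w_px), rotation=ang)
        glands[rr, cc] = gid
        rr, cc = draw_ellipse(cy, cx, lumen_r, lumen_r * ecc, shape=(h_px, w_px), rotation=ang)
        lumen[rr, cc] = True
        e_conc[rr, cc] = 0.03
        h_conc[rr, cc] = 0.0
        # apical cytoplasm band
        rr, cc = draw_ellipse(cy, cx, lumen_r + cyto_t, (lumen_r + cyto_t) * ecc, shape=(h_px, w_px), rotation=ang)
        band = np.zeros((h_px, w_px), dtype=bool)
        band[rr, cc] = True
        band &= ~lumen
        cytoplasm[band] = gid
        e_conc[band] = 0.45
        h_conc[band] = 0.06

        # basal nuclear rim: layers of tangentially elongated nuclei
        n_layers = max(1, int(round(phenotype.rim_thickness_nuclei)))
        if n_layers == 1:
            layer_radii = [lumen_r + cyto_t + 0.45 * w]
        else:
            inner = lumen_r + cyto_t + 0.45 * w
            outer_c = lumen_r + cyto_t + rim_t - 0.45 * w
            layer_radii = list(np.linspace(inner, outer_c, n_layers))
        for r_layer in layer_radii:
            n_around = max(6, int(np.ceil(2 * np.pi * r_layer * np.sqrt(ecc) / (1.12 * w))))
            phase = rng.uniform(0, 2 * np.pi)
            for j in range(n_around):
                theta = phase + 2 * np.pi * j / n_around
                # inward (luminal) jitter grows with stratification
                delta = phenotype.stratification * rng.uniform(0, 1) * 0.6 * cyto_t
                rad = r_layer - delta
                ny = cy + rad * np.sin(theta)
                nx = cx + rad * ecc * np.cos(theta)
                size_j = rng.uniform(0.85, 1.15)
                label += 1
                _stamp_nucleus(
                    nuclei,
                    h_conc,
                    e_conc,
                    label,
                    (ny, nx),
                    (0.45 * w * size_j, 0.42 * w * size_j),
                    # radial major axis orientation: tangent to the rim
                    -(theta + np.pi / 2),
                    float(rng.uniform(0.8, 1.05)),
                )
                nucleus_gland[label] = gid
        # stratified glands grow extra luminal nuclei (lost polarity)
        n_extra = int(round(1.2 * phenotype.stratification * 2 * np.pi * (lumen_r + cyto_t) / (1.12 * w)))
        for _ in range(n_extra):
            theta = rng.uniform(0, 2 * np.pi)
            rad = lumen_r + rng.uniform(0.2, 0.9) * cyto_t
            ny = cy + rad * np.sin(theta)
            nx = cx + rad * ecc * np.cos(theta)
            label += 1
            _stamp_nucleus(
                nuclei,
                h_conc,
                e_conc,
                label,
                (ny, nx),
                (0.42 * w, 0.40 * w),
                -(theta + np.pi / 2),
                float(rng.uniform(0.8, 1.05)),
            )
            nucleus_gland[label] = gid

    # ---- dissociated (signet-ring / poorly differentiated) cells ----
    if phenotype.dissociated_cell_density > 0:
        area_um2 = float(stroma.sum()) * um_per_px**2
        n_cells = int(round(phenotype.dissociated_cell_density * area_um2 / 1000.0))
        diss_id = 1000
        for _ in range(n_cells):
            for _try in range(20):
                k = rng.integers(0, rows_idx.size)
                cy, cx = float(rows_idx[k]), float(cols_idx[k])
                if interior[int(cy), int(cx)] < 1.5 * w:
                    continue
                if all(
                    (cy - py) ** 2 + (cx - px) ** 2 > (pr + 3 * w) ** 2 for py, px, pr in centers
                ):
                    break
            else:
                continue
            diss_id += 1
            cell_r = rng.uniform(0.8, 1.1) * w
            ang = rng.uniform(0, 2 * np.pi)
            rr, cc = draw_ellipse(cy, cx, cell_r, cell_r, shape=(h_px, w_px))
            cell = np.zeros((h_px, w_px), dtype=bool)
            cell[rr, cc] = True
            cytoplasm[cell] = diss_id
            e_conc[cell] = 0.22  # pale mucinous cytoplasm
            h_conc[cell] = 0.05
            # eccentric crescent nucleus pressed against the membrane
            off = 0.40 * cell_r
            ny, nx = cy + off * np.sin(ang), cx + off * np.cos(ang)
            label += 1
            _stamp_nucleus(
                nuclei,
                h_conc,
                e_conc,
                label,
                (ny, nx),
                (0.50 * w, 0.34 * w),
                -ang,
                float(rng.uniform(0.9, 1.15)),
            )
            nucleus_gland[label] = 0  # dissociated

    lumen &= nuclei == 0  # lumen strictly disjoint from nuclei

    img = compose_he(h_conc, e_conc, stain, rng=rng, noise_sigma=1.5, tissue_mask=stroma)
    gt = GroundTruth(
        nuclei_mask=nuclei,
        cytoplasm_mask=cytoplasm,
        gland_mask=glands,
        lumen_mask=lumen,
        artifact_mask=np.zeros((h_px, w_px), dtype=bool),
        phenotype=phenotype,
        stroma_mask=stroma,
        nucleus_gland_id=nucleus_gland,
    )
    tissue = TissueImage(pixels=img, um_per_px=um_per_px, provenance=f"synthetic seed={phenotype.seed}")
    return tissue, gt


def compose_he(
    h_conc: np.ndarray,
    e_conc: np.ndarray,
    stain: StainProfile,
    rng: np.random.Generator | None = None,
    noise_sigma: float = 0.0,
    tissue_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Beer-Lambert composition of H/E concentration maps to 8-bit RGB."""
    h = h_conc.astype(np.float32)
    e = e_conc.astype(np.float32)
    if stain.contrast_scale != 1.0:
        sel = tissue_mask if tissue_mask is not None else np.ones_like(h, dtype=bool)
        for c in (h, e):
            m = float(c[sel].mean())
            c[sel] = m + stain.contrast_scale * (c[sel] - m)
            np.clip(c, 0, None, out=c)
    od = (
        h[..., None] * stain.hematoxylin_od_vector.astype(np.float32)
        + e[..., None] * stain.eosin_od_vector.astype(np.float32)
    ) * stain.intensity_scale
    img = stain.background_rgb.astype(np.float32) * np.exp(-od)
    if noise_sigma > 0 and rng is not None:
        img = img + rng.normal(0, noise_sigma, img.shape).astype(np.float32)
    return np.clip(img, 0, 255).astype(np.uint8)


def apply_batch_effect(image: TissueImage, stain_shift: StainProfile) -> TissueImage:
    """Re-render an image's estimated stain content under a shifted profile.

    The optical density of each pixel (relative to the image's white point)
    is decomposed on the canonical H/E directions; the concentrations are
    contrast-compressed and intensity-scaled per the shifted profile and
    recomposed with its stain vectors.  The off-plane OD residual is kept,
    so an identity profile reproduces the input to within quantization.
    """
    f = image.pixels.astype(np.float32)
    white = np.maximum(np.percentile(f.reshape(-1, 3), 99, axis=0), 1.0)
    od = -np.log(np.clip(f, 1.0, None) / white)
    basis = np.stack([HEMATOXYLIN_OD, EOSIN_OD]).astype(np.float32)  # (2, 3)
    pinv = np.linalg.pinv(basis)  # (3, 2)
    conc = od.reshape(-1, 3) @ pinv  # (N, 2)
    residual = od.reshape(-1, 3) - conc @ basis
    fg = np.linalg.norm(od, axis=-1).reshape(-1) > 0.1
    if stain_shift.contrast_scale != 1.0 and fg.any():
        m = conc[fg].mean(axis=0)
        conc[fg] = m + stain_shift.contrast_scale * (conc[fg] - m)
    conc = conc * stain_shift.intensity_scale
    new_basis = np.stack(
        [stain_shift.hematoxylin_od_vector, stain_shift.eosin_od_vector]
    ).astype(np.float32)
    od_new = (conc @ new_basis + residual).reshape(od.shape)
    out_white = white * stain_shift.background_rgb.astype(np.float32) / DEFAULT_STAIN.background_rgb
    out = np.clip(out_white * np.exp(-od_new), 0, 255).astype(np.uint8)
    return replace_pixels(image, out)


def replace_pixels(image: TissueImage, pixels: np.ndarray) -> TissueImage:
    return TissueImage(
        pixels=pixels,
        um_per_px=image.um_per_px,
        region_id=image.region_id,
        provenance=image.provenance,
    )


def apply_artifacts(image: TissueImage, spec: ArtifactSpec) -> tuple[TissueImage, GroundTruth]:
    """Degrade an image with blur / pen ink / shadow; record the footprints."""
    rng = _op_rng(spec.seed, "apply_artifacts")
    h, w = image.shape
    out = image.pixels.astype(np.float32)
    blur_mask = np.zeros((h, w), dtype=bool)
    pen_mask = np.zeros((h, w), dtype=bool)
    shadow_mask = np.zeros((h, w), dtype=bool)

    if spec.blur_sigma > 0:
        blurred = np.stack(
            [ndi.gaussian_filter(out[..., c], spec.blur_sigma) for c in range(3)], axis=-1
        )
        if spec.blur_coverage >= 0.999:
            blur_mask[:] = True
        else:
            area = spec.blur_coverage * h * w
            bh = int(np.clip(np.sqrt(area) * rng.uniform(0.8, 1.25), 8, h))
            bw = int(np.clip(area / bh, 8, w))
            # bias placement toward the tissue-bearing centre of the canvas
            r0 = int(np.clip(rng.uniform(0.15, 0.85) * h - bh / 2, 0, h - bh))
            c0 = int(np.clip(rng.uniform(0.15, 0.85) * w - bw / 2, 0, w - bw))
            blur_mask[r0 : r0 + bh, c0 : c0 + bw] = True
        out[blur_mask] = blurred[blur_mask]

    if spec.shadow:
        edge = rng.integers(0, 4)  # 0=left 1=right 2=top 3=bottom
        depth = rng.uniform(0.18, 0.30) * (w if edge < 2 else h)
        coord = np.arange(w if edge < 2 else h, dtype=np.float32)
        if edge in (1, 3):
            coord = coord[::-1]
        ramp = 1.0 - 0.45 * np.clip(1.0 - coord / depth, 0, 1)
        factor = np.tile(ramp, (h, 1)) if edge < 2 else np.tile(ramp[:, None], (1, w))
        out *= factor[..., None]
        shadow_mask = factor < 0.8

    if spec.pen_mark:
        color = PEN_COLORS[spec.pen_color]
        thickness = int(rng.uniform(18, 24))
        n_seg = 3
        pts = [np.array([rng.uniform(0.15, 0.85) * h, rng.uniform(0.1, 0.3) * w])]
        for _ in range(n_seg):
            step = np.array([rng.uniform(-0.25, 0.25) * h, rng.uniform(0.2, 0.35) * w])
            pts.append(np.clip(pts[-1] + step, 0, [h - 1, w - 1]))
        stroke = np.zeros((h, w), dtype=bool)
        for p0, p1 in zip(pts[:-1], pts[1:]):
            rr, cc = draw_line(int(p0[0]), int(p0[1]), int(p1[0]), int(p1[1]))
            stroke[rr, cc] = True
        pen_mask = ndi.distance_transform_edt(~stroke) <= thickness / 2
        out[pen_mask] = color

    artifact = blur_mask | pen_mask | shadow_mask
    gt = GroundTruth(
        nuclei_mask=np.zeros((h, w), dtype=np.int32),
        cytoplasm_mask=np.zeros((h, w), dtype=np.int32),
        gland_mask=np.zeros((h, w), dtype=np.int32),
        lumen_mask=np.zeros((h, w), dtype=bool),
        artifact_mask=artifact,
        blur_mask=blur_mask,
        pen_mask=pen_mask,
        shadow_mask=shadow_mask,
    )
    return replace_pixels(image, np.clip(out, 0, 255).astype(np.uint8)), gt


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


@dataclass
class CohortRecord:
    tissue_id: str
    class_label: str
    phenotype: TissuePhenotype
    artifact: ArtifactSpec

    @property
    def group(self) -> str:
        return CLASS_TO_GROUP[self.class_label]


def _sample_phenotype(class_label: str, rng: np.random.Generator, seed: int) -> TissuePhenotype:
    """Draw one phenotype from the per-class morphology distributions.

    Ranges reflect colonic histology at the rendered scale: normal mucosa
    has a single basal nuclear layer, adenomas pseudostratified rims of
    2-3 nuclear widths, carcinomas either markedly thickened disorganized
    rims (well/moderately differentiated) or — in ~30% of draws — the
    gland-free dissociated-cell pattern of poorly differentiated and
    signet-ring carcinoma with enlarged nuclei.
    """
    if class_label == "negative":
        return TissuePhenotype(
            class_label="negative",
            gland_count=int(rng.integers(8, 14)),
            rim_thickness_nuclei=float(rng.uniform(0.8, 1.4)),
            stratification=float(rng.uniform(0.0, 0.08)),
            dissociated_cell_density=0.0,
            nuclear_size_um=float(rng.uniform(6.5, 7.5)),
            seed=seed,
        )
    if class_label == "adenoma":
        return TissuePhenotype(
            class_label="adenoma",
            gland_count=int(rng.integers(7, 13)),
            rim_thickness_nuclei=float(rng.uniform(1.9, 2.9)),
            stratification=float(rng.uniform(0.1, 0.4)),
            dissociated_cell_density=0.0,
            nuclear_size_um=float(rng.uniform(7.0, 8.0)),
            seed=seed,
        )
    if rng.uniform() < 0.3:  # poorly differentiated / signet-ring mode
        return TissuePhenotype(
            class_label="carcinoma",
            gland_count=int(rng.integers(0, 3)),
            rim_thickness_nuclei=float(rng.uniform(0.9, 1.4)),
            stratification=0.0,
            dissociated_cell_density=float(rng.uniform(0.6, 1.4)),
            nuclear_size_um=float(rng.uniform(9.0, 11.0)),
            seed=seed,
        )
    return TissuePhenotype(
        class_label="carcinoma",
        gland_count=int(rng.integers(5, 10)),
        rim_thickness_nuclei=float(rng.uniform(3.3, 4.8)),
        stratification=float(rng.uniform(0.45, 0.95)),
        dissociated_cell_density=0.0,
        nuclear_size_um=float(rng.uniform(8.0, 10.0)),
        seed=seed,
    )


def _sample_artifact(rng: np.random.Generator, seed: int) -> ArtifactSpec:
    kind = rng.choice(["overall_blur", "partial_blur", "pen", "shadow"])
    if kind == "overall_blur":
        return ArtifactSpec(blur_sigma=float(rng.uniform(2.5, 4.0)), blur_coverage=1.0, seed=seed)
    if kind == "partial_blur":
        return ArtifactSpec(
            blur_sigma=3.0, blur_coverage=float(rng.uniform(0.10, 0.25)), seed=seed
        )
    if kind == "pen":
        return ArtifactSpec(pen_mark=True, pen_color=str(rng.choice(["blue", "green"])), seed=seed)
    return ArtifactSpec(shadow=True, seed=seed)


def generate_cohort(
    n_per_class: dict[str, int],
    stain: StainProfile = DEFAULT_STAIN,
    artifact_rate: float = 0.0,
    seed: int = 0,
    out_dir: str | Path | None = None,
    size_px: tuple[int, int] = DEFAULT_CANVAS,
    um_per_px: float = DEFAULT_UM_PER_PX,
) -> tuple[list[CohortRecord], pd.DataFrame]:
    """Sample a labeled cohort of phenotypes; optionally render it to disk.

    Returns the cohort records (phenotype + artifact specs, renderable on
    demand with :func:`render_record`) and the manifest table.  With
    ``out_dir`` set, per-tissue PNG images, 16-bit label-mask PNGs and the
    manifest CSV are written.
    """
    unknown = set(n_per_class) - set(CLASS_LABELS)
    if unknown:
        raise ValueError(f"unknown classes in n_per_class: {unknown}")
    rng = _op_rng(seed, "generate_cohort")
    records: list[CohortRecord] = []
    i = 0
    for class_label in CLASS_LABELS:
        for _ in range(int(n_per_class.get(class_label, 0))):
            t_seed = int(rng.integers(0, 2**31 - 1))
            phen = _sample_phenotype(class_label, rng, t_seed)
            art = NO_ARTIFACTS
            if rng.uniform() < artifact_rate:
                art = _sample_artifact(rng, t_seed)
            records.append(CohortRecord(tissue_id=f"t{i:04d}", class_label=class_label, phenotype=phen, artifact=art))
            i += 1
    rows = [
        {
            "tissue_id": r.tissue_id,
            "class": r.class_label,
            "gland_count": r.phenotype.gland_count,
            "rim_thickness": r.phenotype.rim_thickness_nuclei,
            "stratification": r.phenotype.stratification,
            "dissociated_density": r.phenotype.dissociated_cell_density,
            "blur_sigma": r.artifact.blur_sigma,
            "pen_mark": r.artifact.pen_mark,
            "shadow": r.artifact.shadow,
            "seed": r.phenotype.seed,
        }
        for r in records
    ]
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest.to_csv(out / "manifest.csv", index=False)
        for rec in records:
            img, gt = render_record(rec, stain=stain, size_px=size_px, um_per_px=um_per_px)
            iio.imwrite(out / f"{rec.tissue_id}.png", img.pixels)
            iio.imwrite(out / f"{rec.tissue_id}_nuclei.png", gt.nuclei_mask.astype(np.uint16))
            iio.imwrite(out / f"{rec.tissue_id}_glands.png", gt.gland_mask.astype(np.uint16))
            iio.imwrite(
                out / f"{rec.tissue_id}_artifact.png",
                (gt.artifact_mask.astype(np.uint16) * 65535),
            )
    return records, manifest


def render_record(
    rec: CohortRecord,
    stain: StainProfile = DEFAULT_STAIN,
    size_px: tuple[int, int] = DEFAULT_CANVAS,
    um_per_px: float = DEFAULT_UM_PER_PX,
) -> tuple[TissueImage, GroundTruth]:
    """Render a cohort record: tissue, then its artifacts (if any)."""
    img, gt = render_tissue(rec.phenotype, stain=stain, size_px=size_px, um_per_px=um_per_px)
    if rec.artifact != NO_ARTIFACTS:
        img, art_gt = apply_artifacts(img, rec.artifact)
        gt.artifact_mask = art_gt.artifact_mask
        gt.blur_mask = art_gt.blur_mask
        gt.pen_mask = art_gt.pen_mask
        # shadow ground truth: the darkened zone beside (not over) the tissue
        if art_gt.shadow_mask is not None and gt.stroma_mask is not None:
            gt.shadow_mask = art_gt.shadow_mask & ~gt.stroma_mask
        else:
            gt.shadow_mask = art_gt.shadow_mask
    return img, gt


def render_slide_overview(
    centers_px: list[tuple[float, float]],
    radii_px: list[float],
    size_px: tuple[int, int] = (768, 768),
    seed: int = 0,
) -> np.ndarray:
    """Low-resolution slide overview: pink tissue blobs on brightfield white.

    A lightweight stand-in for a scanned-slide thumbnail, used to exercise
    tissue detection; blobs are eosin-toned ellipses with wobbly borders.
    """
    rng = _op_rng(seed, "render_slide_overview")
    h, w = size_px
    e_conc = np.zeros((h, w), dtype=np.float32)
    h_conc = np.zeros((h, w), dtype=np.float32)
    rr, cc = np.mgrid[0:h, 0:w].astype(np.float32)
    for (cy, cx), rad in zip(centers_px, radii_px):
        wob = 1.0 + 0.08 * np.sin(3 * np.arctan2(rr - cy, cc - cx) + rng.uniform(0, 2 * np.pi))
        blob = ((rr - cy) ** 2 + (cc - cx) ** 2) <= (rad**2) * wob
        e_conc[blob] = 0.35
        h_conc[blob] = 0.10
    return compose_he(h_conc, e_conc, DEFAULT_STAIN, rng=rng, noise_sigma=1.0)
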