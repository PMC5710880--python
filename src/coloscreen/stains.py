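"""H&E stain estimation and color normalization.

Slide preparation varies between laboratories and staining batches, which
shifts image color and contrast enough to break color-based segmentation.
Normalization estimates each image's own hematoxylin/eosin optical-density
directions (Macenko-style: robust extreme angles in the top-2 OD singular
plane), then re-projects the per-pixel stain concentrations onto a fixed
reference profile with percentile-matched concentration scaling.

The package's reference profile is computed from a fixed-seed generator
image and shipped as JSON (see ``data/reference_stain.json``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .config import NormalizationConfig
from .slide_io import TissueImage


@dataclass
class StainEstimate:
    """Estimated stain geometry of one image."""

    h_vector: np.ndarray  # unit 3-vector in OD space
    e_vector: np.ndarray
    h_scale_percentiles: tuple[float, float]  # (p50, p99) concentration percentiles
    e_scale_percentiles: tuple[float, float]
    white_point: np.ndarray  # per-channel RGB white

    def __post_init__(self) -> None:
        for v in (self.h_vector, self.e_vector):
            if abs(np.linalg.norm(v) - 1) > 1e-5:
                raise ValueError("stain vectors must be unit-norm")
        if self.angle_between_deg() <= 10.0:
            raise ValueError("degenerate stain estimate: H/E angle <= 10 degrees")

    def angle_between_deg(self) -> float:
        c = float(np.clip(np.dot(self.h_vector, self.e_vector), -1, 1))
        return float(np.degrees(np.arccos(c)))

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "h_vector": self.h_vector.tolist(),
                "e_vector": self.e_vector.tolist(),
                "h_scale_percentiles": list(self.h_scale_percentiles),
                "e_scale_percentiles": list(self.e_scale_percentiles),
                "white_point": self.white_point.tolist(),
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "StainEstimate":
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(source).read_text()
        d = json.loads(text)
        return cls(
            h_vector=np.array(d["h_vector"]),
            e_vector=np.array(d["e_vector"]),
            h_scale_percentiles=tuple(d["h_scale_percentiles"]),
            e_scale_percentiles=tuple(d["e_scale_percentiles"]),
            white_point=np.array(d["white_point"]),
        )


def load_reference_estimate() -> StainEstimate:
    """The packaged normalization target (fixed-seed generator image)."""
    ref = resources.files("coloscreen.data") / "reference_stain.json"
    return StainEstimate.from_json(ref.read_text())


def _od_and_white(pixels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    f = pixels.reshape(-1, 3).astype(np.float32)
    lum = 0.299 * f[:, 0] + 0.587 * f[:, 1] + 0.114 * f[:, 2]
    bright = f[lum >= np.percentile(lum, 99)]
    white = np.maximum(bright.mean(axis=0), 1.0)
    od = -np.log(np.clip(f, 1.0, None) / white)
    return od, white


def estimate_stains(tissue: TissueImage, cfg: NormalizationConfig | None = None) -> StainEstimate:
    """Macenko-style stain-vector estimation.

    White point from the brightest percentile; foreground pixels are those
    with OD magnitude above a small threshold; the H and E directions are
    the robust extreme angles (alpha = 1st/99th percentile) within the
    plane of the top two OD singular vectors.  The vector with the larger
    red-channel OD is hematoxylin.
    """
    cfg = cfg or NormalizationConfig()
    od, white = _od_and_white(tissue.pixels)
    fg = np.linalg.norm(od, axis=1) > cfg.od_foreground_threshold
    if int(fg.sum()) < cfg.min_foreground_px:
        raise ValueError(f"too few foreground pixels ({int(fg.sum())}) for stain estimation")
    od_fg = od[fg]
    # principal OD plane from the 3x3 second-moment matrix (cheap SVD)
    evals, evecs = np.linalg.eigh((od_fg.T @ od_fg) / od_fg.shape[0])
    plane = evecs[:, np.argsort(evals)[::-1][:2]].T.copy()  # (2, 3)
    # orient the plane so projected coordinates are mostly positive
    proj = od_fg @ plane.T
    for k in range(2):
        if proj[:, k].sum() < 0:
            plane[k] *= -1
            proj[:, k] *= -1
    phi = np.arctan2(proj[:, 1], proj[:, 0])
    lo = np.percentile(phi, cfg.angle_percentile)
    hi = np.percentile(phi, 100 - cfg.angle_percentile)
    v1 = np.cos(lo) * plane[0] + np.sin(lo) * plane[1]
    v2 = np.cos(hi) * plane[0] + np.sin(hi) * plane[1]
    # flip any direction pointing away from the OD cloud
    v1 = v1 if v1 @ od_fg.mean(axis=0) > 0 else -v1
    v2 = v2 if v2 @ od_fg.mean(axis=0) > 0 else -v2
    v1 /= np.linalg.norm(v1)
    v2 /= np.linalg.norm(v2)
    h_vec, e_vec = (v1, v2) if v1[0] > v2[0] else (v2, v1)
    angle = np.degrees(np.arccos(np.clip(h_vec @ e_vec, -1, 1)))
    if angle <= cfg.min_stain_angle_deg:
        raise ValueError(f"degenerate single-stain image: H/E angle {angle:.1f} deg")
    conc = concentrations(od, h_vec, e_vec)
    h_p = (float(np.percentile(conc[fg, 0], 50)), float(np.percentile(conc[fg, 0], 99)))
    e_p = (float(np.percentile(conc[fg, 1], 50)), float(np.percentile(conc[fg, 1], 99)))
    return StainEstimate(
        h_vector=h_vec,
        e_vector=e_vec,
        h_scale_percentiles=h_p,
        e_scale_percentiles=e_p,
        white_point=white,
    )


def concentrations(od: np.ndarray, h_vec: np.ndarray, e_vec: np.ndarray) -> np.ndarray:
    """Least-squares per-pixel (H, E) concentrations; od is (N, 3)."""
    basis = np.stack([h_vec, e_vec]).astype(np.float32)  # (2, 3)
    return od @ np.linalg.pinv(basis)


def hematoxylin_map(tissue: TissueImage, estimate: StainEstimate | None = None) -> np.ndarray:
    """Per-pixel hematoxylin concentration image (nuclear stain intensity)."""
    od, _ = _od_and_white(tissue.pixels)
    if estimate is None:
        estimate = load_reference_estimate()
    conc = concentrations(od, estimate.h_vector, estimate.e_vector)
    return conc[:, 0].reshape(tissue.shape)


def normalize(
    tissue: TissueImage,
    target: StainEstimate,
    source: StainEstimate | None = None,
    cfg: NormalizationConfig | None = None,
) -> TissueImage:
    """Map an image onto the target stain profile.

    Concentrations under the source estimate are rescaled so their 99th
    percentiles match the target's, recomposed with the target vectors and
    white point, and clipped to valid RGB.  Approximately idempotent: a
    second pass changes the image by well under 2 gray levels.
    """
    if source is None:
        source = estimate_stains(tissue, cfg)
    od, _ = _od_and_white(tissue.pixels)
    conc = concentrations(od, source.h_vector, source.e_vector)
    h_scale = target.h_scale_percentiles[1] / max(source.h_scale_percentiles[1], 1e-6)
    e_scale = target.e_scale_percentiles[1] / max(source.e_scale_percentiles[1], 1e-6)
    conc[:, 0] *= h_scale
    conc[:, 1] *= e_scale
    basis = np.stack([target.h_vector, target.e_vector]).astype(np.float32)
    od_new = conc @ basis
    out = target.white_point.astype(np.float32) * np.exp(-od_new)
    pixels = np.clip(out, 0, 255).astype(np.uint8).reshape(tissue.pixels.shape)
    return TissueImage(
        pixels=pixels,
        um_per_px=tissue.um_per_px,
        region_id=tissue.region_id,
        provenance=tissue.provenance,
    )
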