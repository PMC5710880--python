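"""Overall 4-way classification and diagnosis-vocabulary mapping.

The final call per tissue is Positive / Adenoma / Negative /
Unclassifiable.  Structural (low/middle/high) and cytological (low/high)
atypia results are combined by adopting the higher atypia level —
formally, the maximum over the ordering Negative < Adenoma < Positive,
where structural low/middle/high map to N/A/P and cytological low/high to
N/P.  Cytology has no middle grade, so Adenoma can only arise from
structure.  Quality takes precedence: an unusable image's scores are
untrustworthy by definition and the tissue is Unclassifiable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import PipelineConfig
from .cytology import CytoResult, MilModel, analyze_cyto
from .quality import (
    QualityVerdict,
    assess_quality,
    degraded_tile_mask,
    detect_pen_marks,
    detect_shadow,
    sharpness_map,
)
from .slide_io import TissueImage
from .stains import StainEstimate, load_reference_estimate, normalize
from .structural import StructuralResult, analyze_structural
from .synthetic import replace_pixels

FINAL_CLASSES = ("Positive", "Adenoma", "Negative", "Unclassifiable")
STRUCTURAL_INPUTS = ("low", "middle", "high", "unclassifiable")
CYTO_INPUTS = ("low", "high")
QUALITY_INPUTS = ("ok", "partial_degraded", "unusable")

#: Japanese Group Classification -> system truth class.  Lymphoma and
#: carcinoid map to P for bookkeeping, but they are separate confusion-matrix
#: rows and never enter the G5/G3/G1 counts of the screening indices.
DIAGNOSIS_TO_CLASS = {
    "Group1": "N",
    "Group2": "N",
    "Group3": "A",
    "Group4": "P",
    "Group5": "P",
    "GroupX": "X",
    "lymphoma": "P",
    "carcinoid": "P",
}


@dataclass
class TissueClassification:
    tissue_id: str
    final_class: str
    structural_level: str
    cyto_level: str
    quality_status: str
    explanation: list[str] = field(default_factory=list)
    structural: StructuralResult | None = None
    cyto: CytoResult | None = None
    quality: QualityVerdict | None = None

    def to_dict(self) -> dict:
        return {
            "tissue_id": self.tissue_id,
            "final_class": self.final_class,
            "structural": self.structural.to_dict() if self.structural else {"level": self.structural_level},
            "cyto": self.cyto.to_dict() if self.cyto else {"level": self.cyto_level},
            "quality": self.quality.to_dict() if self.quality else {"status": self.quality_status},
            "explanation": self.explanation,
        }


def combine(structural: str, cyto: str, quality: QualityVerdict | str) -> TissueClassification:
    """Fixed rule table over the finite (structural x cyto x quality) lattice.

    Rule order: (1) unusable quality -> Unclassifiable; (2) structural high
    or cytological high -> Positive (the higher atypia level is adopted
    preferentially); (3) structural middle -> Adenoma; (4) both low ->
    Negative; (5) structural unclassifiable with cytological low ->
    Unclassifiable.
    """
    status = quality.status if isinstance(quality, QualityVerdict) else quality
    if structural not in STRUCTURAL_INPUTS:
        raise ValueError(f"unknown structural level {structural!r}")
    if cyto not in CYTO_INPUTS:
        raise ValueError(f"unknown cytological level {cyto!r}")
    if status not in QUALITY_INPUTS:
        raise ValueError(f"unknown quality status {status!r}")
    explanation: list[str] = []
    if status == "unusable":
        final = "Unclassifiable"
        explanation.append("rule1: quality unusable -> Unclassifiable")
    elif structural == "high" or cyto == "high":
        final = "Positive"
        explanation.append("rule2: higher atypia level adopted -> Positive")
        if structural == "unclassifiable":
            explanation.append("note: structural unclassifiable overridden by cytological high")
    elif structural == "middle":
        final = "Adenoma"
        explanation.append("rule3: structural middle -> Adenoma")
    elif structural == "low":
        final = "Negative"
        explanation.append("rule4: structural low and cytological low -> Negative")
    else:  # structural unclassifiable, cyto low
        final = "Unclassifiable"
        explanation.append("rule5: structural unclassifiable, cytological low -> Unclassifiable")
    return TissueClassification(
        tissue_id="",
        final_class=final,
        structural_level=structural,
        cyto_level=cyto,
        quality_status=status,
        explanation=explanation,
    )


def map_diagnosis(label: str) -> str:
    """Pathologist diagnosis label -> truth class P/A/N/X."""
    try:
        return DIAGNOSIS_TO_CLASS[label]
    except KeyError:
        raise ValueError(f"unknown diagnosis label {label!r}") from None


def classify_tissue(
    tissue: TissueImage,
    model: MilModel,
    config: PipelineConfig | None = None,
    reference: StainEstimate | None = None,
    tissue_id: str = "",
    _highmag_counter: list | None = None,
    _stage_trace: list | None = None,
) -> TissueClassification:
    """Run the full per-tissue pipeline.

    Stage order: quality control -> color normalization -> structural
    atypia -> cytological atypia -> overall classification.  An unusable
    verdict short-circuits to Unclassifiable; partial degradation masks the
    degraded tiles (painted to background white) before analysis.
    """
    config = config or PipelineConfig()
    trace = _stage_trace if _stage_trace is not None else []

    trace.append("quality")
    smap = sharpness_map(tissue, config.quality.tile_size_px)
    pen = detect_pen_marks(tissue, config.quality.pen_min_area_mm2)
    shadow = detect_shadow(tissue, config.quality.shadow_smooth_um)
    verdict = assess_quality(smap, pen, shadow, config.quality)
    if verdict.status == "unusable":
        result = combine("unclassifiable", "low", verdict)
        result.tissue_id = tissue_id
        result.quality = verdict
        result.explanation.insert(0, "quality: unusable, atypia analyses skipped")
        return result
    if verdict.status == "partial_degraded":
        bad = degraded_tile_mask(smap, pen, shadow, config.quality)
        px = tissue.pixels.copy()
        px[bad] = 245
        tissue = replace_pixels(tissue, px)

    trace.append("normalize")
    if reference is None:
        reference = load_reference_estimate()
    try:
        normalized = normalize(tissue, reference, cfg=config.normalization)
    except ValueError:
        normalized = tissue  # degenerate stain content: analyze as-is

    trace.append("structural")
    structural = analyze_structural(
        normalized, config.structural, reference, _highmag_counter=_highmag_counter
    )

    trace.append("cyto")
    cyto = analyze_cyto(normalized, model, config.cyto, reference)

    result = combine(structural.level, cyto.level, verdict)
    result.tissue_id = tissue_id
    result.structural = structural
    result.cyto = cyto
    result.quality = verdict
    return result
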