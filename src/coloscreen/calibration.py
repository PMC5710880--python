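"""Threshold calibration on a synthetic validation cohort.

The screening targets are asymmetric: missing a carcinoma is the failure
mode to suppress, missed adenomas come second, and over-detection is
tolerable.  Calibration therefore proceeds in that order:

1. the MIL instance scorer is trained on the validation cohort's ROI bags
   (bag label: carcinoma vs not);
2. the cytological threshold is set just below the smallest top-3
   aggregate among carcinoma tissues, so no validation carcinoma is missed;
3. the structural low/middle cutpoint is the largest gland level that still
   keeps at least 95% of validation adenomas above it, and the high
   cutpoint sits one level above the largest adenoma level.

The validation cohort composition defaults to 15% carcinoma / 35% adenoma /
50% negative, matching how such screening systems are tuned in practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import PipelineConfig
from .cytology import MilModel, aggregate_top3, detect_nuclei, form_rois, score_rois, train_mil
from .slide_io import TissueImage
from .stains import StainEstimate, load_reference_estimate, normalize
from .structural import analyze_structural
from .synthetic import CohortRecord, StainProfile, DEFAULT_STAIN, generate_cohort, render_record


@dataclass
class CalibrationResult:
    config: PipelineConfig
    model: MilModel
    diagnostics: dict = field(default_factory=dict)


def _tissue_observations(
    records: list[CohortRecord],
    config: PipelineConfig,
    reference: StainEstimate,
    stain: StainProfile,
) -> tuple[list[np.ndarray], list[int], list[int]]:
    """Per-tissue ROI feature bags and structural max gland levels."""
    bags: list[np.ndarray] = []
    labels: list[int] = []
    max_levels: list[int] = []
    for rec in records:
        img, _ = render_record(rec, stain=stain)
        try:
            norm = normalize(img, reference, cfg=config.normalization)
        except ValueError:
            norm = img
        structural = analyze_structural(norm, config.structural, reference)
        max_levels.append(structural.max_level())
        det = detect_nuclei(norm, config.cyto, reference)
        rois = form_rois(
            det, norm.shape, norm.um_per_px, config.cyto.roi_size_px, config.cyto.min_nuclei_per_roi
        )
        feats = (
            np.stack([r.features for r in rois])
            if rois
            else np.zeros((0, 10))
        )
        bags.append(feats)
        labels.append(1 if rec.class_label == "carcinoma" else 0)
    return bags, labels, max_levels


def calibrate(
    n_validation: dict[str, int] | None = None,
    seed: int = 0,
    config: PipelineConfig | None = None,
    stain: StainProfile = DEFAULT_STAIN,
    reference: StainEstimate | None = None,
) -> CalibrationResult:
    """Tune the pipeline thresholds on a freshly generated validation cohort."""
    config = (config or PipelineConfig()).model_copy(deep=True)
    if n_validation is None:
        n_validation = {"carcinoma": 22, "adenoma": 53, "negative": 75}
    if reference is None:
        reference = load_reference_estimate()
    records, _ = generate_cohort(n_validation, stain=stain, artifact_rate=0.0, seed=seed)
    bags, labels, max_levels = _tissue_observations(records, config, reference, stain)

    nonempty = [i for i, b in enumerate(bags) if len(b)]
    mil_cfg = config.mil.model_copy(update={"seed": seed})
    model = train_mil([bags[i] for i in nonempty], [labels[i] for i in nonempty], mil_cfg)

    aggregates = np.array(
        [aggregate_top3(model.score_instances(b) if len(b) else []) for b in bags]
    )
    labels_arr = np.array(labels)
    classes = np.array([r.class_label for r in records])
    max_levels = np.array(max_levels)

    # cytological threshold: just below the weakest validation carcinoma
    carc_aggs = aggregates[labels_arr == 1]
    thr = float(np.clip(0.999 * carc_aggs.min(), 1e-4, 1 - 1e-4))
    config.cyto.threshold = thr

    # structural cutpoints: adenoma sensitivity second, over-detection last
    aden_levels = max_levels[classes == "adenoma"]
    cut_low = 1
    for cand in range(1, 10):
        if np.mean(aden_levels <= cand) <= 0.05:
            cut_low = cand
        else:
            break
    cut_high = int(np.clip(aden_levels.max() + 1 if len(aden_levels) else 8, cut_low + 2, 10))
    config.structural.cut_low = cut_low
    config.structural.cut_high = cut_high
    config.structural.trigger_level = min(config.structural.trigger_level, cut_high)

    diagnostics = {
        "n_validation": dict(n_validation),
        "cyto_threshold": thr,
        "cut_low": cut_low,
        "cut_high": cut_high,
        "carcinoma_aggregate_min": float(carc_aggs.min()),
        "noncarcinoma_aggregate_max": float(aggregates[labels_arr == 0].max()),
        "adenoma_max_level_range": [int(aden_levels.min()), int(aden_levels.max())]
        if len(aden_levels)
        else None,
    }
    return CalibrationResult(config=config, model=model, diagnostics=diagnostics)
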