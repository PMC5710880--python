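"""Pipeline configuration: every tunable threshold in one validated object.

Tuning lives in the config, not in code: the calibration step rewrites the
thresholds (cytological atypia threshold, gland-level cutpoints, blur
threshold) and the classification stages only ever read them from here.
Unknown keys are rejected so stale config files fail loudly.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict


class QualityConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    tile_size_px: int = 64
    #: variance-of-Laplacian focus score below which a tile counts as blurred;
    #: calibrated once on generator output (sharp vs sigma=3 tiles)
    blur_threshold: float = 7.0
    blur_frac_unusable: float = 0.5
    pen_frac_unusable: float = 0.2
    shadow_frac_unusable: float = 0.3
    degraded_frac_partial: float = 0.05
    pen_min_area_mm2: float = 0.01
    shadow_smooth_um: float = 30.0


class NormalizationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    min_foreground_px: int = 10_000
    od_foreground_threshold: float = 0.15
    angle_percentile: float = 1.0  # robust extreme-angle percentile (Macenko alpha)
    min_stain_angle_deg: float = 10.0


class StructuralConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    nuclear_width_um: float = 7.0
    h_conc_threshold: float = 0.45  # nuclear hematoxylin-concentration cut
    min_component_nuclei: int = 5
    #: gland-level bins: 10 equal-width bins spanning [bin_min_um, bin_max_um]
    bin_min_um: float = 5.0
    bin_max_um: float = 55.0
    n_levels: int = 10
    trigger_level: int = 5  # high-magnification pass only at/above this level
    cut_low: int = 3  # max level <= cut_low -> low atypia
    cut_high: int = 8  # max level >= cut_high -> high atypia
    arrangement_cut: float = 0.5
    highmag_um_per_px: float = 0.46


class CytoConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    roi_size_px: int = 256
    min_nuclei_per_roi: int = 10
    h_conc_threshold: float = 0.45
    min_nucleus_area_um2: float = 8.0
    #: decision threshold on the top-3 mean-square ROI aggregate; calibrated
    #: so no carcinoma-phenotype tissue in the validation cohort is missed
    threshold: float = 0.5


class MilConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    hidden_sizes: tuple[int, ...] = (16, 8)
    epochs: int = 400
    learning_rate: float = 0.01
    tau: float = 8.0  # smooth-max temperature
    aggregator: str = "lse"  # "lse" or "noisy_or"
    seed: int = 0
    l2: float = 1e-4


class DetectionConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    min_area_mm2: float = 0.05
    closing_radius_um: float = 250.0


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    quality: QualityConfig = QualityConfig()
    normalization: NormalizationConfig = NormalizationConfig()
    structural: StructuralConfig = StructuralConfig()
    cyto: CytoConfig = CytoConfig()
    mil: MilConfig = MilConfig()
    detection: DetectionConfig = DetectionConfig()
    seed: int = 0

    @classmethod
    def load(cls, path: str | Path | None = None) -> "PipelineConfig":
        """Defaults, optionally overridden by a YAML file (unknown keys rejected)."""
        if path is None:
            return cls()
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(data)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=False))
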