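"""Gland extraction, thickness quantification, level binning, structural rating."""

import numpy as np
import pytest

from coloscreen.config import StructuralConfig
from coloscreen.structural import (
    LEVEL_PALETTE,
    GlandComponent,
    analyze_structural,
    assign_gland_levels,
    classify_structural,
    extract_glandular_nuclei_lowmag,
    make_mask,
    quantify_thickness,
    render_levels,
    segment_gland_cells_highmag,
)
from coloscreen.slide_io import TissueImage
from coloscreen.synthetic import StainProfile, TissuePhenotype, render_tissue


def _phen(**kw):
    base = dict(
        class_label="adenoma",
        gland_count=6,
        rim_thickness_nuclei=2.2,
        stratification=0.2,
        dissociated_cell_density=0.0,
        nuclear_size_um=7.0,
        seed=0,
    )
    base.update(kw)
    return TissuePhenotype(**base)


class TestMask:
    def test_covers_tissue(self, negative_tissue):
        img, gt = negative_tissue
        mask = make_mask(img)
        target = gt.stroma_mask & ~gt.lumen_mask
        dice = 2 * (mask & target).sum() / (mask.sum() + target.sum())
        assert dice >= 0.9

    def test_white_image_rejected(self):
        white = TissueImage(pixels=np.full((300, 300, 3), 250, np.uint8), um_per_px=0.92)
        with pytest.raises(ValueError, match="foreground"):
            make_mask(white)

    def test_stable_under_brightness_shift(self, negative_tissue):
        img, _ = negative_tissue
        shifted = TissueImage(
            pixels=np.clip(img.pixels.astype(int) + 5, 0, 255).astype(np.uint8),
            um_per_px=img.um_per_px,
        )
        m0, m1 = make_mask(img), make_mask(shifted)
        dice = 2 * (m0 & m1).sum() / (m0.sum() + m1.sum())
        assert dice > 0.95


class TestExtraction:
    def test_component_count_matches_glands(self, reference_estimate):
        img, gt = render_tissue(_phen(gland_count=6, seed=21))
        placed = gt.gland_mask.max()
        comps = extract_glandular_nuclei_lowmag(img, make_mask(img), stain_estimate=reference_estimate)
        assert abs(len(comps) - placed) <= 1

    def test_gland_free_tissue_has_no_components(self, reference_estimate):
        img, _ = render_tissue(_phen(class_label="negative", gland_count=0,
                                     rim_thickness_nuclei=1.0, stratification=0.0, seed=22))
        comps = extract_glandular_nuclei_lowmag(img, make_mask(img), stain_estimate=reference_estimate)
        assert comps == []

    def test_count_invariant_to_eosin_scale(self, reference_estimate):
        phen = _phen(seed=23)
        img_a, _ = render_tissue(phen)
        img_b, _ = render_tissue(phen, stain=StainProfile(intensity_scale=1.15))
        na = len(extract_glandular_nuclei_lowmag(img_a, make_mask(img_a), stain_estimate=reference_estimate))
        nb = len(extract_glandular_nuclei_lowmag(img_b, make_mask(img_b), stain_estimate=reference_estimate))
        assert na == nb


class TestThickness:
    def test_straight_bar(self):
        bar = np.zeros((60, 200), dtype=bool)
        bar[25:35] = True  # 10 px wide at 1 um/px
        assert quantify_thickness(bar, 1.0) == pytest.approx(10.0, abs=1.0)

    def test_one_pixel_line(self):
        line = np.zeros((30, 100), dtype=bool)
        line[15] = True
        assert quantify_thickness(line, 1.0) == pytest.approx(2.0, abs=0.5)

    def test_generator_rim_geometry(self, reference_estimate):
        """rim = 3 nuclear widths of 7 um -> ~21 um measured thickness."""
        img, _ = render_tissue(_phen(class_label="carcinoma", rim_thickness_nuclei=3.0,
                                     stratification=0.0, seed=24))
        comps = extract_glandular_nuclei_lowmag(img, make_mask(img), stain_estimate=reference_estimate)
        assert comps
        th = [quantify_thickness(c.pixel_mask, img.um_per_px) for c in comps]
        assert np.median(th) == pytest.approx(21.0, abs=5.0)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            quantify_thickness(np.zeros((10, 10), dtype=bool), 1.0)


class TestLevels:
    @pytest.mark.parametrize("thickness,expected", [(4.0, 1), (7.5, 1), (12.0, 2), (56.0, 10)])
    def test_binning_with_clipping(self, thickness, expected):
        comp = GlandComponent(0, np.ones((5, 5), bool), thickness_um=thickness)
        assign_gland_levels([comp])
        assert comp.gland_level == expected

    def test_levels_monotone_in_thickness(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            ths = np.sort(rng.uniform(0, 60, size=8))
            comps = [GlandComponent(i, np.ones((2, 2), bool), thickness_um=t) for i, t in enumerate(ths)]
            assign_gland_levels(comps)
            levels = [c.gland_level for c in comps]
            assert levels == sorted(levels)

    def test_render_levels_palette(self, negative_tissue):
        img, _ = negative_tissue
        m1 = np.zeros(img.pixels.shape[:2], bool)
        m1[10:20, 10:20] = True
        m10 = np.zeros_like(m1)
        m10[30:40, 30:40] = True
        comps = [
            GlandComponent(0, m1, thickness_um=4.0, gland_level=1),
            GlandComponent(1, m10, thickness_um=60.0, gland_level=10),
        ]
        overlay = render_levels(img, comps)
        assert (overlay[m1] == LEVEL_PALETTE[0]).all()
        assert (overlay[m10] == LEVEL_PALETTE[9]).all()
        untouched = ~(m1 | m10)
        assert np.array_equal(overlay[untouched], img.pixels[untouched])


class TestArrangement:
    def _seg_scores(self, strat, seed, reference_estimate):
        img, _ = render_tissue(
            _phen(class_label="carcinoma", rim_thickness_nuclei=3.0,
                  stratification=strat, gland_count=5, seed=seed)
        )
        mask = make_mask(img)
        comps = extract_glandular_nuclei_lowmag(img, mask, stain_estimate=reference_estimate)
        return [
            segment_gland_cells_highmag(img, c, stain_estimate=reference_estimate).arrangement_score
            for c in comps
        ]

    def test_polarized_gland_scores_low(self, reference_estimate):
        scores = self._seg_scores(0.0, 31, reference_estimate)
        assert scores and max(scores) <= 0.2

    def test_stratified_gland_scores_high(self, reference_estimate):
        scores = self._seg_scores(1.0, 31, reference_estimate)
        assert scores and max(scores) >= 0.6

    def test_masks_always_disjoint(self, reference_estimate):
        img, _ = render_tissue(_phen(class_label="carcinoma", rim_thickness_nuclei=3.5,
                                     stratification=0.6, seed=33))
        comps = extract_glandular_nuclei_lowmag(img, make_mask(img), stain_estimate=reference_estimate)
        for c in comps[:3]:
            seg = segment_gland_cells_highmag(img, c, stain_estimate=reference_estimate)
            assert not (seg.nuclei_mask & seg.cytoplasm_mask).any()


class TestClassify:
    def _comp(self, level):
        return GlandComponent(0, np.ones((2, 2), bool), thickness_um=0.0, gland_level=level)

    def test_rule_applications(self):
        from coloscreen.structural import GlandSegmentation

        assert classify_structural([self._comp(2)], []).level == "low"
        seg = GlandSegmentation(0, np.zeros((2, 2), bool), np.zeros((2, 2), bool), 0.3)
        assert classify_structural([self._comp(6)], [seg]).level == "middle"
        assert classify_structural([self._comp(9)], []).level == "high"
        seg_hi = GlandSegmentation(0, np.zeros((2, 2), bool), np.zeros((2, 2), bool), 0.7)
        assert classify_structural([self._comp(6)], [seg_hi]).level == "high"

    def test_no_components(self):
        assert classify_structural([], []).level == "unclassifiable"
        assert classify_structural([], [], glands_expected=False).level == "low"

    def test_pure_function_of_levels_and_scores(self):
        a = classify_structural([self._comp(5)], [])
        b = classify_structural([self._comp(5)], [])
        assert a.level == b.level


def test_highmag_pass_only_triggered_above_level(reference_estimate):
    """Two-pass economy: thin-gland tissue never invokes the high-mag pass."""
    cfg = StructuralConfig()
    img, _ = render_tissue(_phen(class_label="negative", rim_thickness_nuclei=1.0,
                                 stratification=0.0, seed=41))
    counter: list = []
    res = analyze_structural(img, cfg, reference_estimate, _highmag_counter=counter)
    assert res.max_level() < cfg.trigger_level
    assert counter == []
    assert res.segmentations == []
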