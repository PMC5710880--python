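"""Generator contracts: determinism, ground-truth geometry, batch effects, artifacts."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from coloscreen.synthetic import (
    ArtifactSpec,
    StainProfile,
    TissuePhenotype,
    apply_artifacts,
    apply_batch_effect,
    generate_cohort,
    render_record,
    render_tissue,
)


def _phen(**kw):
    base = dict(
        class_label="negative",
        gland_count=6,
        rim_thickness_nuclei=1.0,
        stratification=0.0,
        dissociated_cell_density=0.0,
        nuclear_size_um=7.0,
        seed=0,
    )
    base.update(kw)
    return TissuePhenotype(**base)


def mean_rim_width(nuclei_mask: np.ndarray) -> float:
    """Oracle rim width: close small inter-nucleus gaps, then per-component
    width = 2x the maximum of the distance transform (half-thickness of the
    annular band), averaged over gland-scale components."""
    mask = nuclei_mask > 0
    dil = ndi.distance_transform_edt(~mask) <= 2.5
    closed = (ndi.distance_transform_edt(dil) > 2.5) | mask
    labels, n = ndi.label(closed)
    widths = []
    for lab in range(1, n + 1):
        m = labels == lab
        if m.sum() < 200:
            continue
        widths.append(2.0 * ndi.distance_transform_edt(m).max())
    assert widths, "no gland-scale components found"
    return float(np.mean(widths))


class TestRenderTissue:
    def test_empty_phenotype_has_empty_nuclei_mask(self):
        img, gt = render_tissue(_phen(gland_count=0), size_px=(256, 256))
        assert gt.nuclei_mask.max() == 0

    def test_deterministic_for_fixed_seed(self):
        a, _ = render_tissue(_phen(seed=5), size_px=(256, 256))
        b, _ = render_tissue(_phen(seed=5), size_px=(256, 256))
        assert np.array_equal(a.pixels, b.pixels)

    def test_rim_thickness_scales_measured_width(self):
        _, gt1 = render_tissue(_phen(seed=42, gland_count=8))
        _, gt4 = render_tissue(
            _phen(class_label="carcinoma", rim_thickness_nuclei=4.0, seed=42, gland_count=8)
        )
        ratio = mean_rim_width(gt4.nuclei_mask) / mean_rim_width(gt1.nuclei_mask)
        assert 3.0 <= ratio <= 5.0  # factor ~4 +- 25%

    def test_rim_width_monotone_in_thickness(self):
        widths = []
        for rim in (1.0, 2.0, 3.0, 4.0, 5.0):
            label = "negative" if rim <= 1.5 else "carcinoma" if rim >= 3 else "adenoma"
            _, gt = render_tissue(_phen(class_label=label, rim_thickness_nuclei=rim, seed=3))
            widths.append(mean_rim_width(gt.nuclei_mask))
        assert all(b > a for a, b in zip(widths, widths[1:]))

    def test_nuclei_darker_than_stroma_in_hematoxylin(self, reference_estimate):
        """Mask consistency: rendered nuclei really are hematoxylin-dark."""
        from coloscreen.stains import hematoxylin_map

        img, gt = render_tissue(_phen(seed=9, gland_count=8))
        h = hematoxylin_map(img, reference_estimate)
        nuclei = gt.nuclei_mask > 0
        stroma = (
            (gt.stroma_mask) & (gt.gland_mask == 0) & (gt.cytoplasm_mask == 0) & ~nuclei
        )
        assert np.median(h[nuclei]) > np.median(h[stroma])
        assert (h[nuclei] > np.median(h[stroma])).mean() > 0.99

    def test_lumen_disjoint_from_nuclei_and_masks_congruent(self):
        img, gt = render_tissue(_phen(seed=2, gland_count=8))
        assert not (gt.lumen_mask & (gt.nuclei_mask > 0)).any()
        assert gt.nuclei_mask.shape == img.pixels.shape[:2] == gt.lumen_mask.shape

    def test_rejects_bad_canvas(self):
        with pytest.raises(ValueError):
            render_tissue(_phen(), size_px=(128, 128))
        with pytest.raises(ValueError):
            render_tissue(_phen(), um_per_px=0.0)


class TestPhenotypeInvariants:
    def test_negative_cannot_have_thick_rim(self):
        with pytest.raises(ValueError):
            _phen(rim_thickness_nuclei=2.0)

    def test_carcinoma_needs_rim_or_dissociation(self):
        with pytest.raises(ValueError):
            _phen(class_label="carcinoma", rim_thickness_nuclei=1.0)


class TestBatchEffect:
    def test_identity_profile_near_noop(self, negative_tissue):
        img, _ = negative_tissue
        out = apply_batch_effect(img, StainProfile())
        diff = np.abs(out.pixels.astype(float) - img.pixels.astype(float)).mean(axis=(0, 1))
        assert (diff < 1.0).all()

    def test_low_contrast_reduces_tissue_std(self, negative_tissue):
        img, gt = negative_tissue
        out = apply_batch_effect(img, StainProfile(contrast_scale=0.4))
        m = gt.stroma_mask
        before = img.pixels[m].std(axis=0)
        after = out.pixels[m].std(axis=0)
        assert (after < before).all()

    def test_distinct_shifts_produce_distinct_images(self, negative_tissue):
        img, _ = negative_tissue
        a = apply_batch_effect(img, StainProfile(intensity_scale=1.3))
        b = apply_batch_effect(img, StainProfile(intensity_scale=0.7))
        assert np.abs(a.pixels.astype(float) - b.pixels.astype(float)).mean() > 5.0


class TestArtifacts:
    def test_no_artifacts_is_identity(self, negative_tissue):
        img, _ = negative_tissue
        out, gt = apply_artifacts(img, ArtifactSpec())
        assert np.array_equal(out.pixels, img.pixels)
        assert not gt.artifact_mask.any()

    def test_full_coverage_blur_marks_everything(self, negative_tissue):
        img, _ = negative_tissue
        out, gt = apply_artifacts(img, ArtifactSpec(blur_sigma=3.0, blur_coverage=1.0))
        assert gt.artifact_mask.all()
        assert not np.array_equal(out.pixels, img.pixels)

    def test_pen_mark_is_saturated(self, negative_tissue):
        img, _ = negative_tissue
        out, gt = apply_artifacts(img, ArtifactSpec(pen_mark=True, seed=3))
        assert gt.pen_mask.sum() > 0
        f = out.pixels.astype(float)
        sat = (f.max(axis=-1) - f.min(axis=-1)) / (f.max(axis=-1) + 1e-6)
        assert np.median(sat[gt.pen_mask]) > np.median(sat[~gt.pen_mask])

    def test_blur_coverage_zero_iff_sigma_zero(self):
        with pytest.raises(ValueError):
            ArtifactSpec(blur_sigma=2.0, blur_coverage=0.0)
        with pytest.raises(ValueError):
            ArtifactSpec(blur_sigma=0.0, blur_coverage=0.5)


class TestCohort:
    def test_single_class_manifest(self):
        _, manifest = generate_cohort({"negative": 5}, seed=1)
        assert len(manifest) == 5
        assert (manifest["class"] == "negative").all()

    def test_same_seed_same_manifest(self):
        _, m1 = generate_cohort({"negative": 3, "adenoma": 3, "carcinoma": 3}, seed=11)
        _, m2 = generate_cohort({"negative": 3, "adenoma": 3, "carcinoma": 3}, seed=11)
        assert m1.equals(m2)

    def test_artifact_rate_binomial(self):
        """Flagged-tissue count over seeds matches Binomial(n=30, p=0.1)."""
        counts = []
        for seed in range(20):
            _, m = generate_cohort(
                {"carcinoma": 10, "adenoma": 10, "negative": 10}, artifact_rate=0.1, seed=seed
            )
            flagged = ((m["blur_sigma"] > 0) | m["pen_mark"] | m["shadow"]).sum()
            counts.append(int(flagged))
        mean = np.mean(counts)
        # Binomial(30, 0.1): mean 3, sd of the 20-run average ~0.37
        assert 1.8 <= mean <= 4.2

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError, match="unknown classes"):
            generate_cohort({"metaplasia": 2}, seed=0)

    def test_cohort_written_to_disk(self, tmp_path):
        records, manifest = generate_cohort(
            {"negative": 1}, seed=4, out_dir=tmp_path, size_px=(256, 256)
        )
        assert (tmp_path / "manifest.csv").exists()
        assert (tmp_path / "t0000.png").exists()
        img, gt = render_record(records[0], size_px=(256, 256))
        import imageio.v3 as iio

        assert np.array_equal(iio.imread(tmp_path / "t0000.png"), img.pixels)
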