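"""Nuclei detection, ROI formation, MIL training/scoring, top-3 aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coloscreen.config import MilConfig
from coloscreen.cytology import (
    MilModel,
    NucleiDetection,
    Roi,
    aggregate_top3,
    classify_cyto,
    detect_nuclei,
    form_rois,
    score_rois,
    train_mil,
)
from coloscreen.slide_io import TissueImage


class TestDetectNuclei:
    def test_count_close_to_ground_truth(self, negative_tissue, reference_estimate):
        img, gt = negative_tissue
        det = detect_nuclei(img, stain_estimate=reference_estimate)
        truth = int(gt.nuclei_mask.max())
        assert truth > 100
        assert abs(det.count - truth) / truth <= 0.15

    def test_blank_stroma_has_no_nuclei(self, reference_estimate):
        from coloscreen.synthetic import TissuePhenotype, render_tissue

        phen = TissuePhenotype("negative", 0, 1.0, 0.0, 0.0, 7.0, seed=2)
        img, _ = render_tissue(phen, size_px=(512, 512))
        det = detect_nuclei(img, stain_estimate=reference_estimate)
        assert det.count == 0

    def test_dissociated_nuclei_are_larger(self, negative_tissue, signet_tissue, reference_estimate):
        neg_img, _ = negative_tissue
        sig_img, _ = signet_tissue
        a = detect_nuclei(neg_img, stain_estimate=reference_estimate).morphometry["area_um2"].mean()
        b = detect_nuclei(sig_img, stain_estimate=reference_estimate).morphometry["area_um2"].mean()
        assert b > 1.3 * a


class TestFormRois:
    def _detection(self, centroids, shape):
        n = len(centroids)
        import pandas as pd

        morph = pd.DataFrame(
            {
                "area_um2": np.full(n, 30.0),
                "eccentricity": np.full(n, 0.5),
                "h_conc": np.full(n, 0.8),
                "solidity": np.full(n, 0.7),
            }
        )
        return NucleiDetection(np.asarray(centroids, float), np.zeros(shape, np.int32), morph)

    def test_no_nuclei_no_rois(self):
        det = self._detection(np.zeros((0, 2)), (512, 512))
        assert form_rois(det, (512, 512), 0.92) == []

    def test_uniform_field_keeps_full_grid(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 1024, (400, 2))
        det = self._detection(pts, (1024, 1024))
        rois = form_rois(det, (1024, 1024), 0.92, roi_size_px=256, min_nuclei=10)
        assert len(rois) == 16

    def test_kept_rois_satisfy_minimum(self):
        rng = np.random.default_rng(1)
        pts = np.concatenate([rng.uniform(0, 250, (40, 2)), rng.uniform(500, 1020, (7, 2))])
        det = self._detection(pts, (1024, 1024))
        rois = form_rois(det, (1024, 1024), 0.92, roi_size_px=256, min_nuclei=10)
        assert rois
        assert all(r.nuclei_count >= 10 for r in rois)

    def test_small_roi_size_rejected(self):
        det = self._detection(np.zeros((1, 2)), (256, 256))
        with pytest.raises(ValueError):
            form_rois(det, (256, 256), 0.92, roi_size_px=32)


def _make_bags(rng, n_bags, positive):
    bags = []
    for _ in range(n_bags):
        x = rng.normal(0, 1, (int(rng.integers(8, 15)), 10))
        if positive:
            k = int(rng.integers(3, 6))
            x[:k] += rng.normal(1.5, 0.3, (k, 10))
        bags.append(x)
    return bags


class TestMil:
    def test_recovery_experiment_auc(self):
        """Bags with >= 3 shifted instances are separable at AUC >= 0.9."""
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(0)
        train = _make_bags(rng, 20, True) + _make_bags(rng, 20, False)
        labels = [1] * 20 + [0] * 20
        test = _make_bags(rng, 20, True) + _make_bags(rng, 20, False)
        test_labels = [1] * 20 + [0] * 20
        model = train_mil(train, labels, MilConfig(seed=1))
        scores = [model.bag_score(model.score_instances(b)) for b in test]
        assert roc_auc_score(test_labels, scores) >= 0.9

    def test_no_signal_control(self):
        from sklearn.metrics import roc_auc_score

        bags = [np.ones((10, 10)) for _ in range(40)]
        labels = [1] * 20 + [0] * 20
        model = train_mil(bags, labels, MilConfig(seed=2))
        scores = [model.bag_score(model.score_instances(b)) for b in bags]
        assert roc_auc_score(labels, scores) == pytest.approx(0.5, abs=0.15)

    def test_training_deterministic(self):
        rng = np.random.default_rng(3)
        bags = _make_bags(rng, 12, True) + _make_bags(rng, 12, False)
        labels = [1] * 12 + [0] * 12
        cfg = MilConfig(seed=7, epochs=50)
        m1 = train_mil(bags, labels, cfg)
        m2 = train_mil(bags, labels, cfg)
        assert all(np.array_equal(a, b) for a, b in zip(m1.weights, m2.weights))

    def test_single_class_rejected(self):
        bags = [np.zeros((5, 10))] * 20
        with pytest.raises(ValueError, match="per class"):
            train_mil(bags, [1] * 20, MilConfig())

    def test_scores_bounded_and_pure(self):
        rng = np.random.default_rng(4)
        bags = _make_bags(rng, 10, True) + _make_bags(rng, 10, False)
        model = train_mil(bags, [1] * 10 + [0] * 10, MilConfig(seed=5, epochs=30))
        feats = rng.normal(0, 3, (1000, 10))
        scores = model.score_instances(feats)
        assert ((scores >= 0) & (scores <= 1)).all()
        roi = Roi((0, 0, 10, 10), 5, feats[0])
        assert score_rois(model, [roi, roi])[0] == score_rois(model, [roi, roi])[1]
        assert score_rois(model, []) == []

    def test_feature_length_mismatch_rejected(self):
        rng = np.random.default_rng(5)
        bags = _make_bags(rng, 10, True) + _make_bags(rng, 10, False)
        model = train_mil(bags, [1] * 10 + [0] * 10, MilConfig(seed=6, epochs=10))
        with pytest.raises(ValueError, match="feature length"):
            model.score_instances(np.zeros((3, 7)))

    def test_serialization_round_trip(self, tmp_path):
        rng = np.random.default_rng(6)
        bags = _make_bags(rng, 10, True) + _make_bags(rng, 10, False)
        model = train_mil(bags, [1] * 10 + [0] * 10, MilConfig(seed=8, epochs=20))
        model.to_json(tmp_path / "m.json")
        back = MilModel.from_json(tmp_path / "m.json")
        x = rng.normal(0, 1, (5, 10))
        assert np.allclose(model.score_instances(x), back.score_instances(x))


def _oracle_top3(scores):
    padded = sorted(list(scores) + [0.0, 0.0, 0.0], reverse=True)[:3]
    return sum(s * s for s in padded) / 3.0


class TestAggregateTop3:
    @pytest.mark.parametrize(
        "scores,expected",
        [([1, 1, 1, 0.2], 1.0), ([0.9, 0.8, 0.7, 0.1], 0.646667), ([0.6], 0.12), ([], 0.0)],
    )
    def test_known_values(self, scores, expected):
        assert aggregate_top3(scores) == pytest.approx(expected, abs=1e-6)

    def test_matches_oracle_on_random_lists(self):
        rng = np.random.default_rng(9)
        for _ in range(2000):
            scores = rng.uniform(0, 1, size=int(rng.integers(0, 12)))
            assert aggregate_top3(scores) == pytest.approx(_oracle_top3(scores), abs=1e-12)

    @given(
        st.lists(st.floats(min_value=0, max_value=1), max_size=10),
        st.integers(min_value=0, max_value=9),
        st.floats(min_value=0, max_value=1),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_every_coordinate(self, scores, idx, bump):
        if not scores:
            return
        idx %= len(scores)
        raised = list(scores)
        raised[idx] = min(1.0, raised[idx] + bump)
        assert aggregate_top3(raised) >= aggregate_top3(scores) - 1e-12


class TestClassifyCyto:
    def test_boundary_and_extremes(self):
        assert classify_cyto(0.0, 0.5) == "low"
        assert classify_cyto(1.0, 0.5) == "high"
        assert classify_cyto(0.5, 0.5) == "high"  # boundary favors sensitivity

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            classify_cyto(0.5, 0.0)
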