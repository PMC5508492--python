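"""Feature extraction, scorers, TPR/TNR sweeps and the threshold rule."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import icadenoise as icd
from icadenoise import classify
from icadenoise.classify import FEATURE_COLUMNS
from icadenoise.harness import load_reference_sweep

from conftest import TINY, make_decomposition


@pytest.fixture(scope="module")
def tiny_geometry():
    img, masks, _ = icd.make_subject(TINY, 42)
    return img.brain_mask, masks


def _features_row(**overrides) -> pd.DataFrame:
    row = {"edge_fraction": 0.0, "speckle_extent": 0.02, "n_clusters": 1,
           "high_freq_fraction": 0.02, "spike_score": 0.0,
           "sawtooth_score": 0.0, "csf_vessel_fraction": 0.0}
    row.update(overrides)
    return pd.DataFrame([row], columns=list(FEATURE_COLUMNS))


class TestFeatures:
    def test_map_confined_to_rim_has_edge_fraction_one(self, tiny_geometry):
        mask, masks = tiny_geometry
        T = 30
        grid = np.where(masks.edge_rim, 5.0, 0.0)
        tc = np.sin(np.arange(T))
        d = make_decomposition(mask, [grid], tc[:, None])
        feats = classify.component_features(d, masks)
        assert feats.loc[0, "edge_fraction"] == 1.0

    def test_slow_sine_has_negligible_high_frequency_power(self, tiny_geometry):
        mask, masks = tiny_geometry
        T, tr = 120, 3.0
        tc = np.sin(2 * np.pi * 0.05 * tr * np.arange(T))
        grid = np.zeros(mask.shape)
        d = make_decomposition(mask, [grid], tc[:, None], tr_seconds=tr)
        feats = classify.component_features(d, masks)
        assert feats.loc[0, "high_freq_fraction"] < 0.05

    def test_impulse_time_course_scores_as_spike(self, tiny_geometry):
        mask, masks = tiny_geometry
        tc = np.zeros(60)
        tc[30] = 1.0
        d = make_decomposition(mask, [np.zeros(mask.shape)], tc[:, None])
        feats = classify.component_features(d, masks)
        assert feats.loc[0, "spike_score"] > 10

    def test_constant_time_course_has_zero_spike_score(self, tiny_geometry):
        mask, masks = tiny_geometry
        d = make_decomposition(mask, [np.zeros(mask.shape)],
                               np.ones((60, 1)))
        feats = classify.component_features(d, masks)
        assert feats.loc[0, "spike_score"] == 0.0

    def test_grid_mismatch_rejected(self, tiny_geometry):
        mask, _ = tiny_geometry
        other = icd.make_subject(TINY.replace(grid_shape=(12, 12, 10)), 0)[1]
        d = make_decomposition(mask, [np.zeros(mask.shape)],
                               np.zeros((30, 1)))
        with pytest.raises(ValueError):
            classify.component_features(d, other)

    def test_all_features_in_range(self, tiny_subject):
        img, masks, _ = tiny_subject
        d = icd.decompose(img, k=6, seed=0)
        feats = classify.component_features(d, masks)
        for col in ("edge_fraction", "speckle_extent", "high_freq_fraction",
                    "csf_vessel_fraction"):
            assert feats[col].between(0, 1).all()
        assert (feats["spike_score"] >= 0).all()
        assert (feats["n_clusters"] >= 0).all()


class TestNoiseScore:
    def test_signal_like_extreme_scores_low(self):
        feats = _features_row()
        assert classify.noise_score(feats).scores[0] < 20

    def test_noise_like_extreme_scores_high(self):
        feats = _features_row(edge_fraction=1.0, speckle_extent=0.4,
                              n_clusters=25, high_freq_fraction=1.0,
                              spike_score=30.0, sawtooth_score=3.0,
                              csf_vessel_fraction=1.0)
        assert classify.noise_score(feats).scores[0] > 80

    def test_all_zero_noise_features_score_zero(self):
        feats = _features_row(speckle_extent=0.0, n_clusters=1,
                              high_freq_fraction=0.0)
        assert classify.noise_score(feats).scores[0] == 0.0

    def test_motion_only_ignores_csf_vessel(self):
        a = _features_row(edge_fraction=0.6, spike_score=8.0)
        b = _features_row(edge_fraction=0.6, spike_score=8.0,
                          csf_vessel_fraction=0.9)
        sa = classify.noise_score(a, mode="motion-only").scores
        sb = classify.noise_score(b, mode="motion-only").scores
        assert np.array_equal(sa, sb)

    def test_all_noise_mode_dominates_motion_only(self):
        rng = np.random.default_rng(0)
        feats = pd.DataFrame({
            "edge_fraction": rng.uniform(0, 1, 50),
            "speckle_extent": rng.uniform(0, 0.5, 50),
            "n_clusters": rng.integers(1, 30, 50),
            "high_freq_fraction": rng.uniform(0, 1, 50),
            "spike_score": rng.uniform(0, 30, 50),
            "sawtooth_score": rng.uniform(0, 3, 50),
            "csf_vessel_fraction": rng.uniform(0, 1, 50),
        })
        s_all = classify.noise_score(feats, "all-noise").scores
        s_mo = classify.noise_score(feats, "motion-only").scores
        assert np.all(s_all >= s_mo)


def _separable_cohort(n_subjects=4, n_sig=5, n_noise=6, seed=0):
    """Feature tables where noise components are cleanly noise-like."""
    rng = np.random.default_rng(seed)
    cohort = []
    for _ in range(n_subjects):
        rows, tags = [], []
        for _ in range(n_sig):
            rows.append({"edge_fraction": rng.uniform(0, 0.1),
                         "speckle_extent": rng.uniform(0, 0.05),
                         "n_clusters": rng.integers(1, 3),
                         "high_freq_fraction": rng.uniform(0, 0.1),
                         "spike_score": rng.uniform(0, 2),
                         "sawtooth_score": rng.uniform(0, 0.2),
                         "csf_vessel_fraction": rng.uniform(0, 0.1)})
            tags.append("signal")
        for _ in range(n_noise):
            rows.append({"edge_fraction": rng.uniform(0.6, 1.0),
                         "speckle_extent": rng.uniform(0.2, 0.5),
                         "n_clusters": rng.integers(10, 30),
                         "high_freq_fraction": rng.uniform(0.5, 1.0),
                         "spike_score": rng.uniform(10, 30),
                         "sawtooth_score": rng.uniform(1, 3),
                         "csf_vessel_fraction": rng.uniform(0.5, 1.0)})
            tags.append("motion")
        cohort.append((pd.DataFrame(rows, columns=list(FEATURE_COLUMNS)),
                       classify.LabelSet.from_subtypes(tags)))
    return cohort


class TestTrainedScorer:
    def test_separable_features_give_perfect_loso(self):
        sweep = classify.loso_sweep(_separable_cohort(), [25.0])
        assert sweep.mean_tpr[0] == 100.0
        assert sweep.mean_tnr[0] == 100.0

    def test_shuffled_labels_give_chance_accuracy(self):
        rng = np.random.default_rng(1)
        cohort = []
        for (feats, labels) in _separable_cohort(n_subjects=6, n_sig=10,
                                                 n_noise=10, seed=1):
            shuffled = rng.permutation(labels.labels)
            cohort.append((feats, classify.LabelSet(shuffled)))
        sweep = classify.loso_sweep(cohort, [50.0])
        accuracy = (sweep.mean_tpr[0] + sweep.mean_tnr[0]) / 2
        # binomial: 120 components, chance 50% -> 3 sigma ~ 14 points
        assert abs(accuracy - 50.0) < 15.0

    def test_training_is_deterministic(self):
        cohort = _separable_cohort()
        s1 = classify.train_scorer(cohort).score(cohort[0][0]).scores
        s2 = classify.train_scorer(cohort).score(cohort[0][0]).scores
        assert np.array_equal(s1, s2)

    def test_single_class_rejected(self):
        cohort = _separable_cohort(n_sig=0)
        with pytest.raises(ValueError, match="single class"):
            classify.train_scorer(cohort)

    def test_needs_two_subjects(self):
        with pytest.raises(ValueError):
            classify.train_scorer(_separable_cohort(n_subjects=1))


class TestTprTnr:
    def test_perfect_prediction(self):
        truth = classify.LabelSet.from_subtypes(["signal"] * 4 + ["motion"] * 6)
        assert classify.evaluate_tpr_tnr(truth, truth) == (100.0, 100.0)

    def test_all_predicted_noise(self):
        truth = classify.LabelSet.from_subtypes(["signal"] * 4 + ["motion"] * 6)
        pred = classify.LabelSet(np.array(["noise"] * 10, dtype=object))
        assert classify.evaluate_tpr_tnr(pred, truth) == (0.0, 100.0)

    def test_partial_counts(self):
        truth = classify.LabelSet.from_subtypes(["signal"] * 10 + ["motion"] * 10)
        pred_labels = (["signal"] * 9 + ["noise"]) + (["noise"] * 8 + ["signal"] * 2)
        pred = classify.LabelSet(np.array(pred_labels, dtype=object))
        assert classify.evaluate_tpr_tnr(pred, truth) == (90.0, 80.0)

    def test_invariant_to_component_reordering(self):
        rng = np.random.default_rng(2)
        truth = classify.LabelSet.from_subtypes(["signal"] * 5 + ["motion"] * 5)
        pred = classify.LabelSet(rng.permutation(truth.labels.copy()))
        base = classify.evaluate_tpr_tnr(pred, truth)
        perm = rng.permutation(10)
        reord = classify.evaluate_tpr_tnr(
            classify.LabelSet(pred.labels[perm]),
            classify.LabelSet(truth.labels[perm], subtype=None))
        assert base == reord

    def test_undefined_class_rejected(self):
        all_noise = classify.LabelSet(np.array(["noise"] * 5, dtype=object))
        with pytest.raises(ValueError):
            classify.evaluate_tpr_tnr(all_noise, all_noise)


class TestLosoSweep:
    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_monotone_in_threshold(self, seed):
        """With 'score >= threshold -> noise', raising the threshold never
        lowers mean TPR and never raises mean TNR."""
        rng = np.random.default_rng(seed)
        cohort = []
        for _ in range(3):
            n = 12
            feats = pd.DataFrame(
                {c: rng.uniform(0, 1, n) for c in FEATURE_COLUMNS})
            feats["n_clusters"] = rng.integers(1, 30, n)
            feats["spike_score"] = rng.uniform(0, 30, n)
            tags = rng.choice(["signal", "motion"], n)
            if len(set(tags)) < 2:
                tags[:2] = ["signal", "motion"]
            cohort.append((feats, classify.LabelSet.from_subtypes(tags)))
        sweep = classify.loso_sweep(cohort, [1, 10, 25, 50, 75, 99])
        assert np.all(np.diff(sweep.mean_tpr) >= -1e-9)
        assert np.all(np.diff(sweep.mean_tnr) <= 1e-9)

    def test_single_class_fold_excluded_not_fatal(self, caplog):
        cohort = _separable_cohort(n_subjects=3)
        feats, _ = _separable_cohort(n_subjects=1, n_sig=0, n_noise=8,
                                     seed=7)[0]
        cohort.append((feats, classify.LabelSet.from_subtypes(["motion"] * 8)))
        with caplog.at_level("WARNING"):
            sweep = classify.loso_sweep(cohort, [25.0])
        assert "excluded from TPR" in caplog.text
        assert np.isfinite(sweep.mean_tpr).all()


class TestOptimalThreshold:
    def test_single_qualifying_threshold(self):
        sweep = classify.ThresholdSweep([30.0], [100.0], [100.0], [50.0],
                                        [50.0])
        assert classify.select_optimal_threshold(sweep) == 30.0

    def test_none_when_tpr_floor_never_met(self):
        sweep = classify.ThresholdSweep([1, 2, 3], [80, 85, 90], [80, 85, 90],
                                        [50, 60, 70], [50, 60, 70])
        assert classify.select_optimal_threshold(sweep) is None

    def test_none_when_best_tnr_below_minimum(self):
        sweep = classify.ThresholdSweep([1, 2], [95, 99], [95, 99], [4, 9],
                                        [4, 9])
        assert classify.select_optimal_threshold(sweep) is None

    def test_ties_resolve_to_largest_threshold(self):
        sweep = classify.ThresholdSweep([1, 2, 3], [95, 95, 95], [95] * 3,
                                        [60, 60, 40], [60, 60, 40])
        assert classify.select_optimal_threshold(sweep) == 2.0

    @given(st.lists(st.floats(0, 90), min_size=1, max_size=8))
    @settings(max_examples=30, deadline=None)
    def test_any_sweep_below_floor_selects_none(self, tprs):
        n = len(tprs)
        sweep = classify.ThresholdSweep(np.arange(n), tprs, tprs,
                                        np.linspace(0, 100, n),
                                        np.linspace(0, 100, n))
        assert classify.select_optimal_threshold(sweep, tpr_floor=90) is None


class TestReferenceTables:
    def test_patient_trained_selects_twenty(self):
        sweep = load_reference_sweep("patient")
        assert classify.select_optimal_threshold(sweep) == 20.0

    def test_generic_trained_selects_nothing(self):
        assert classify.select_optimal_threshold(
            load_reference_sweep("generic")) is None

    def test_tsv_round_trip(self, tmp_path):
        sweep = load_reference_sweep("patient")
        sweep.to_tsv(tmp_path / "sweep.tsv")
        back = classify.ThresholdSweep.from_tsv(tmp_path / "sweep.tsv")
        for attr in ("thresholds", "mean_tpr", "mean_tnr", "median_tpr",
                     "median_tnr"):
            assert np.allclose(getattr(sweep, attr), getattr(back, attr))

    def test_malformed_tsv_reports_row(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("statistic\t1\t2\nmean_tpr\t90\toops\n")
        with pytest.raises(ValueError, match="lacks rows|mean_tnr"):
            classify.ThresholdSweep.from_tsv(path)


class TestLesionOverlap:
    def test_disjoint_zero_and_subset_one(self):
        comp = np.zeros((5, 5, 5), dtype=bool)
        comp[0, 0, :3] = True
        lesion = np.zeros_like(comp)
        lesion[4, 4, :] = True
        assert classify.lesion_overlap(comp, lesion) == 0.0
        assert classify.lesion_overlap(comp, comp | lesion) == 1.0

    def test_fractional_overlap(self):
        comp = np.zeros(100, dtype=bool).reshape(10, 10, 1)
        comp[:] = True
        lesion = np.zeros_like(comp)
        lesion[0, :2] = True
        assert classify.lesion_overlap(comp, lesion) == pytest.approx(0.02)

    def test_empty_component_rejected(self):
        empty = np.zeros((3, 3, 3), dtype=bool)
        with pytest.raises(ValueError):
            classify.lesion_overlap(empty, empty)
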