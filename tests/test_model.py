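"""Metrics, ROC, SVM training/tuning/CV, site scanning, and persistence."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import rankdata

import succpred as sp
from succpred.model import (DEFAULT_C_EXPONENTS, DEFAULT_GAMMA_EXPONENTS,
                            ModelArchiveError, SitePrediction, SvmConfig,
                            cross_validate_matrix, decision_values)
from succpred.seqio import NEGATIVE, POSITIVE, ProteinRecord, SiteAnnotation


class TestComputeMetrics:
    def test_first_case_study_counts(self):
        m = sp.compute_metrics(tp=4, fp=1, tn=12, fn=2)
        assert round(m.acc * 100) == 84
        assert round(m.sn * 100) == 67
        assert round(m.sp * 100) == 92

    def test_second_case_study_counts(self):
        m = sp.compute_metrics(tp=1, fp=0, tn=17, fn=1)
        assert round(m.acc * 100) == 95
        assert round(m.sp * 100) == 100

    def test_balanced_numerator_gives_zero_mcc(self):
        assert sp.compute_metrics(5, 5, 5, 5).mcc == 0.0

    def test_zero_denominator_factor_gives_zero_mcc(self):
        assert sp.compute_metrics(0, 0, 10, 5).mcc == 0.0

    def test_perfect_prediction(self):
        m = sp.compute_metrics(10, 0, 20, 0)
        assert m.mcc == pytest.approx(1.0)
        assert (m.sn, m.sp, m.acc) == (1.0, 1.0, 1.0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            sp.compute_metrics(-1, 0, 1, 0)

    def test_empty_confusion_rejected(self):
        with pytest.raises(ValueError):
            sp.compute_metrics(0, 0, 0, 0)

    @given(st.tuples(*[st.integers(0, 40)] * 4))
    def test_metric_ranges(self, counts):
        tp, fp, tn, fn = counts
        if tp + fp + tn + fn == 0:
            return
        m = sp.compute_metrics(tp, fp, tn, fn)
        assert -1.0 - 1e-12 <= m.mcc <= 1.0 + 1e-12
        assert 0.0 <= m.acc <= 1.0
        assert 0.0 <= m.sn <= 1.0
        assert 0.0 <= m.sp <= 1.0


def rank_statistic_auc(scores, labels):
    """Oracle: AUC as the tie-corrected Mann-Whitney U normalization."""
    scores = np.asarray(scores, dtype=float)
    pos = np.asarray(labels) == 1
    r = rankdata(scores)
    n1 = pos.sum()
    n0 = (~pos).sum()
    u = r[pos].sum() - n1 * (n1 + 1) / 2
    return u / (n1 * n0)


class TestRocAuc:
    def test_perfect_ranking(self):
        curve = sp.roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert curve.auc == pytest.approx(1.0)

    def test_inverted_ranking(self):
        curve = sp.roc_auc([0.9, 0.8, 0.2, 0.1], [0, 0, 1, 1])
        assert curve.auc == pytest.approx(0.0)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(0)
        scores = rng.random(1000)
        labels = rng.integers(0, 2, size=1000)
        assert sp.roc_auc(scores, labels).auc == pytest.approx(0.5, abs=0.05)

    def test_monotone_curve(self):
        rng = np.random.default_rng(1)
        curve = sp.roc_auc(rng.random(50), rng.integers(0, 2, size=50))
        assert np.all(np.diff(curve.fpr) >= 0)
        assert np.all(np.diff(curve.tpr) >= 0)

    def test_matches_rank_statistic_with_ties(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            n = int(rng.integers(10, 60))
            labels = np.r_[np.ones(3, int),
                           rng.integers(0, 2, size=n - 3)]  # both classes
            scores = np.round(rng.random(n), 1)  # heavy ties
            if labels.sum() == n:
                labels[0] = 0
            assert sp.roc_auc(scores, labels).auc == pytest.approx(
                rank_statistic_auc(scores, labels), abs=1e-12)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            sp.roc_auc([0.1, 0.2], [1, 1])


def _blobs(seed=0, n=40, gap=6.0):
    rng = np.random.default_rng(seed)
    y = np.arange(n) % 2
    X = rng.normal(size=(n, 2)) + gap * y[:, None]
    return X, y


class TestTrainSvm:
    def test_separable_training_set_perfect(self):
        X, y = _blobs()
        clf = sp.train_svm(X, y, SvmConfig(c=8.0, gamma=0.5), seed=0)
        pred = clf.predict(X)
        assert (pred == y).all()

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            sp.train_svm(np.zeros((5, 2)), np.ones(5))

    def test_deterministic_decision_values(self):
        X, y = _blobs(seed=3)
        d1 = decision_values(sp.train_svm(X, y, seed=5), X)
        d2 = decision_values(sp.train_svm(X, y, seed=5), X)
        np.testing.assert_array_equal(d1, d2)

    def test_probabilities_in_unit_interval(self):
        X, y = _blobs(seed=4)
        proba = sp.train_svm(X, y, seed=0).predict_proba(X)
        assert np.all((proba >= 0) & (proba <= 1))
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)

    def test_shuffled_labels_give_null_mcc(self):
        # permutation null: with labels shuffled, CV MCC averages near zero
        rng = np.random.default_rng(6)
        X = rng.normal(size=(120, 4))
        y = np.arange(120) % 2
        mccs = []
        for _ in range(10):
            y_perm = rng.permutation(y)
            pooled, _ = cross_validate_matrix(X, y_perm, folds=4, seed=0)
            mccs.append(pooled.mcc)
        assert abs(np.mean(mccs)) < 0.15


class TestGridSearch:
    def test_separable_data_reaches_perfect_mcc(self):
        X, y = _blobs(n=30)
        config = sp.grid_search(X, y, cv_folds=3, seed=0)
        pooled, _ = cross_validate_matrix(X, y, config, folds=3, seed=0)
        assert pooled.mcc == pytest.approx(1.0)

    def test_declared_grid_size(self):
        assert len(DEFAULT_C_EXPONENTS) * len(DEFAULT_GAMMA_EXPONENTS) == 110

    def test_deterministic(self):
        X, y = _blobs(seed=7, gap=1.5)
        a = sp.grid_search(X, y, cv_folds=3, seed=1)
        b = sp.grid_search(X, y, cv_folds=3, seed=1)
        assert a == b

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SvmConfig(c=-1.0)
        with pytest.raises(ValueError):
            SvmConfig(gamma=0.0)


class TestCrossValidate:
    def test_each_sample_tested_once(self):
        X = np.array([[0.0], [0.1], [10.0], [10.1]])
        y = np.array([0, 0, 1, 1])
        pooled, cv = cross_validate_matrix(X, y, folds=2, seed=0)
        assert pooled.total == 4
        assert pooled.tp + pooled.fn == 2   # positives conserved
        assert pooled.tn + pooled.fp == 2
        assert len(cv.folds) == 2

    def test_pooled_counts_conserve_class_totals(self, motif_fixture):
        _, _, windows, y = motif_fixture
        recipe = sp.FeatureRecipe(feature_set="AAC")
        pooled, _ = sp.cross_validate(windows, y, recipe, folds=5, seed=0)
        assert pooled.tp + pooled.fn == int(y.sum())
        assert pooled.tn + pooled.fp == int((1 - y).sum())

    def test_stratified_fold_balance(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(83, 3))
        y = (rng.random(83) < 0.3).astype(int)
        _, cv = cross_validate_matrix(X, y, folds=5, seed=0)
        global_frac = y.mean()
        for fold in cv.folds:
            # per-fold positive count within one sample of proportionality
            expected = global_frac * fold.total
            assert abs((fold.tp + fold.fn) - expected) <= 1.0

    def test_class_too_small_to_stratify_errors(self):
        X = np.zeros((10, 2))
        y = np.array([1, 1] + [0] * 8)
        with pytest.raises(ValueError, match="stratify"):
            cross_validate_matrix(X, y, folds=3, seed=0)


class TestEstimator:
    def test_sklearn_param_interface(self):
        clf = sp.SuccinylationSiteClassifier(feature_set="AAC", C=4.0)
        assert clf.get_params()["C"] == 4.0
        clf.set_params(C=2.0)
        assert clf.C == 2.0

    def test_unknown_feature_set_rejected(self, motif_fixture):
        _, _, windows, y = motif_fixture
        clf = sp.SuccinylationSiteClassifier(feature_set="PSSM")
        with pytest.raises(ValueError, match="feature_set"):
            clf.fit(windows[:40], y[:40])

    def test_predictions_deterministic(self, motif_fixture,
                                       fitted_aac_model):
        _, _, windows, y = motif_fixture
        clf2 = sp.SuccinylationSiteClassifier(feature_set="AAC",
                                              random_state=7)
        clf2.fit(windows, y)
        np.testing.assert_array_equal(
            fitted_aac_model.predict_proba(windows[:30]),
            clf2.predict_proba(windows[:30]))

    def test_recipe_reproduces_training_encoding(self, fitted_aac_model,
                                                 motif_fixture):
        _, _, windows, _ = motif_fixture
        X = fitted_aac_model.recipe_.encode(windows[:10])
        assert X.shape == (10, 20)
        assert fitted_aac_model.n_features_in_ == 20


class TestPredictSites:
    def _protein_with_k(self, n_residues=266, n_lysines=19):
        rng = np.random.default_rng(9)
        letters = [c for c in sp.seqio.STANDARD_AA if c != "K"]
        seq = list(rng.choice(letters, size=n_residues))
        for pos in rng.choice(n_residues, size=n_lysines, replace=False):
            seq[pos] = "K"
        return ProteinRecord("case1", "".join(seq))

    def test_every_lysine_scored(self, fitted_aac_model):
        prot = self._protein_with_k()
        preds = sp.predict_sites(fitted_aac_model, [prot])
        assert len(preds) == 19
        assert [p.position for p in preds] == sorted(p.position
                                                     for p in preds)
        assert all(prot.sequence[p.position - 1] == "K" for p in preds)

    def test_scores_are_probabilities(self, fitted_aac_model):
        preds = sp.predict_sites(fitted_aac_model, [self._protein_with_k()])
        assert all(0.0 <= p.score <= 1.0 for p in preds)

    def test_impossible_threshold_means_no_calls(self, fitted_aac_model):
        preds = sp.predict_sites(fitted_aac_model, [self._protein_with_k()],
                                 threshold=1.01)
        assert not any(p.call for p in preds)

    def test_lysine_free_protein_gives_no_rows(self, fitted_aac_model):
        prot = ProteinRecord("nok", "ACDEFGH" * 10)
        assert sp.predict_sites(fitted_aac_model, [prot]) == []


class TestEvaluatePredictions:
    def _preds(self, calls):
        return [SitePrediction("p1", pos, "A" * 15 + "K" + "A" * 15,
                               0.9 if call else 0.1, call)
                for pos, call in calls.items()]

    def test_exact_match_is_perfect(self):
        anns = [SiteAnnotation("p1", 5, POSITIVE),
                SiteAnnotation("p1", 9, NEGATIVE)]
        m = sp.evaluate_predictions(self._preds({5: True, 9: False}), anns)
        assert (m.sn, m.sp, m.acc, m.mcc) == (1.0, 1.0, 1.0, 1.0)

    def test_counts_by_label(self):
        anns = [SiteAnnotation("p1", 1, POSITIVE),
                SiteAnnotation("p1", 2, POSITIVE),
                SiteAnnotation("p1", 3, NEGATIVE),
                SiteAnnotation("p1", 4, NEGATIVE)]
        m = sp.evaluate_predictions(
            self._preds({1: True, 2: False, 3: True, 4: False}), anns)
        assert (m.tp, m.fn, m.fp, m.tn) == (1, 1, 1, 1)

    def test_disjoint_keys_error(self):
        anns = [SiteAnnotation("p2", 5, POSITIVE)]
        with pytest.raises(ValueError, match="no .*keys"):
            sp.evaluate_predictions(self._preds({5: True}), anns)


class TestPersistence:
    def test_roundtrip_predictions_identical(self, tmp_path,
                                             fitted_aac_model,
                                             motif_fixture):
        _, _, windows, _ = motif_fixture
        sp.save_model(fitted_aac_model, tmp_path / "arch")
        loaded = sp.load_model(tmp_path / "arch")
        np.testing.assert_array_equal(
            fitted_aac_model.predict_proba(windows[:20]),
            loaded.predict_proba(windows[:20]))
        assert loaded.recipe_.feature_set == "AAC"

    def test_missing_archive_errors(self, tmp_path):
        with pytest.raises(ModelArchiveError):
            sp.load_model(tmp_path / "nope")

    def test_corrupted_sidecar_errors(self, tmp_path, fitted_aac_model):
        sp.save_model(fitted_aac_model, tmp_path / "arch")
        (tmp_path / "arch" / "model.json").write_text("{not json")
        with pytest.raises(ModelArchiveError, match="malformed"):
            sp.load_model(tmp_path / "arch")

    def test_prediction_tsv_roundtrip(self, tmp_path):
        preds = [SitePrediction("p1", 4, "A" * 15 + "K" + "A" * 15, 0.75,
                                True),
                 SitePrediction("p2", 8, "C" * 15 + "K" + "C" * 15, 0.25,
                                False)]
        path = tmp_path / "preds.tsv"
        sp.model.write_predictions(preds, path)
        assert sp.model.read_predictions(path) == preds
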