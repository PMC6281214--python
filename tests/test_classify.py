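import math

import numpy as np
import pytest

from niptcall import (FeatureVector, SvmConfig, baseline_predict,
                      class_weights, grid_search_train, load_model, predict,
                      save_model, train_baseline)
from niptcall.classify import extra_baseline
from niptcall.errors import NiptError, ParameterError


def _vectors(X, y):
    """Wrap a 2-column design into ten-feature vectors (rest zero)."""
    out = []
    for i, (row, label) in enumerate(zip(np.atleast_2d(X), y)):
        vals = [0.0] * 10
        vals[0], vals[1] = float(row[0]), float(row[1])
        out.append(FeatureVector(f"s{i}", "21", tuple(vals), int(label)))
    return out


def _blobs(n=200, sep=10.0, seed=0, flip=False):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(0, 1, (n // 2, 2)),
                   rng.normal(sep, 1, (n // 2, 2))])
    y = np.array([-1] * (n // 2) + [1] * (n // 2))
    if flip:
        y = rng.permutation(y)
    return _vectors(X, y)


FAST = SvmConfig(log2c_range=(-5, 9), log2g_range=(-9, 3), coarse_step=2.0,
                 fine_span=0.5, seed=0)


class TestClassWeights:
    def test_inverse_instance_number(self):
        w = class_weights([-1] * 100 + [1] * 10)
        assert w[-1] == pytest.approx(0.55)
        assert w[1] == pytest.approx(5.5)
        assert w[1] / w[-1] == pytest.approx(10.0)

    def test_balanced_classes_get_unit_weights(self):
        w = class_weights([-1, -1, 1, 1])
        assert w == {-1: 1.0, 1: 1.0}

    def test_screening_scale_imbalance(self):
        w = class_weights([-1] * 4672 + [1] * 19)
        assert w[1] / w[-1] == pytest.approx(4672 / 19)

    def test_single_class_rejected(self):
        with pytest.raises(ParameterError):
            class_weights([1, 1, 1])


class TestGridSearchTrain:
    def test_separable_blobs_are_learned_perfectly(self):
        train = _blobs()
        model = grid_search_train(train, FAST)
        assert model.cv_accuracy == 1.0
        correct = sum(predict(model, v)[0] == v.label for v in train)
        assert correct == len(train)

    def test_permuted_labels_give_chance_cv(self):
        model = grid_search_train(_blobs(flip=True), FAST)
        assert abs(model.cv_accuracy - 0.5) <= 0.1

    def test_conflicting_duplicates_do_not_crash(self):
        vals = tuple([1.0] * 10)
        train = ([FeatureVector(f"a{i}", "21", vals, 1) for i in range(5)]
                 + [FeatureVector(f"b{i}", "21", vals, -1) for i in range(5)])
        model = grid_search_train(train, FAST)
        correct = sum(predict(model, v)[0] == v.label for v in train)
        assert correct < len(train)

    def test_single_class_rejected(self):
        with pytest.raises(ParameterError):
            grid_search_train(_vectors([[0, 0], [1, 1]], [1, 1]), FAST)

    def test_degenerate_grid_rejected(self):
        with pytest.raises(ParameterError):
            SvmConfig(coarse_step=0.0)

    def test_probabilities_sum_to_one(self):
        model = grid_search_train(_blobs(), FAST)
        for v in _blobs(n=20, seed=3):
            _, p_neg, p_pos = predict(model, v)
            assert p_neg + p_pos == pytest.approx(1.0, abs=1e-9)

    def test_dual_feasibility_of_trained_model(self):
        """The fitted dual solution satisfies sum(alpha_i y_i) = 0 and the
        class-weighted box constraints 0 <= alpha_i <= C w_k."""
        model = grid_search_train(_blobs(n=100, sep=3.0, seed=2), FAST)
        balance, violation = model.dual_feasibility()
        assert balance < 1e-6
        assert violation <= 1e-6

    def test_model_persistence_roundtrip(self, tmp_path):
        model = grid_search_train(_blobs(), FAST)
        save_model(model, tmp_path / "m.joblib")
        back = load_model(tmp_path / "m.joblib")
        probe = _blobs(n=10, seed=4)
        assert [predict(back, v)[0] for v in probe] == \
               [predict(model, v)[0] for v in probe]


class TestBaselines:
    def _gauss_1d(self, mu0, mu1, sd0, sd1, n=4000, seed=0):
        rng = np.random.default_rng(seed)
        X = np.empty((n, 2))
        X[:, 1] = rng.normal(0, 0.3, n)  # second feature: no class signal
        y = np.array([-1] * (n // 2) + [1] * (n // 2))
        X[: n // 2, 0] = rng.normal(mu0, sd0, n // 2)
        X[n // 2:, 0] = rng.normal(mu1, sd1, n // 2)
        return _vectors(X, y)

    def test_lda_boundary_at_midpoint(self):
        """Two equal-variance classes at 0 and 2 with equal priors: the
        linear discriminant boundary sits at x = 1."""
        model = train_baseline(self._gauss_1d(0, 2, 1, 1), "LDA")
        below = [0.0] * 10
        above = [0.0] * 10
        below[0], above[0] = 0.9, 1.1
        assert baseline_predict(model, np.array(below)) == -1
        assert baseline_predict(model, np.array(above)) == 1
        d = model.discriminants(np.array([1.0] + [0.0] * 9))
        assert d[-1] == pytest.approx(d[1], abs=0.05)

    def test_qda_separates_equal_means_lda_cannot(self):
        train = self._gauss_1d(0, 0, 0.3, 3.0)
        test = self._gauss_1d(0, 0, 0.3, 3.0, n=1000, seed=9)
        qda = train_baseline(train, "QDA")
        lda = train_baseline(train, "LDA")
        qda_acc = np.mean([baseline_predict(qda, v) == v.label for v in test])
        lda_acc = np.mean([baseline_predict(lda, v) == v.label for v in test])
        assert qda_acc > 0.75
        assert abs(lda_acc - 0.5) < 0.1

    def test_qda_reduces_to_lda_with_shared_covariance(self):
        train = self._gauss_1d(0, 2, 1, 1, n=1000)
        lda = train_baseline(train, "LDA")
        qda = train_baseline(train, "QDA")
        qda.covariances = {k: lda.covariances[0] for k in qda.classes}
        qda._inv = {k: lda._inv[0] for k in qda.classes}
        qda._logdet = {k: lda._logdet[0] for k in qda.classes}
        probes = self._gauss_1d(0, 2, 1, 1, n=200, seed=5)
        assert all(baseline_predict(qda, v) == baseline_predict(lda, v)
                   for v in probes)

    def test_closed_forms_match_sklearn(self):
        from sklearn.discriminant_analysis import (
            LinearDiscriminantAnalysis, QuadraticDiscriminantAnalysis)

        rng = np.random.default_rng(7)
        X = rng.normal(0, 1, (300, 2))
        y = np.where(X[:, 0] + 0.5 * X[:, 1] + rng.normal(0, 0.5, 300) > 0,
                     1, -1)
        train = _vectors(X, y)
        probes = _vectors(rng.normal(0, 1.5, (100, 2)), [0] * 100)
        Xp = np.array([v.values for v in probes])
        lda = train_baseline(train, "LDA")
        qda = train_baseline(train, "QDA")
        Xt = np.array([v.values[:2] for v in train])
        sk_lda = LinearDiscriminantAnalysis(solver="svd").fit(Xt, y)
        sk_qda = QuadraticDiscriminantAnalysis(reg_param=0.0).fit(Xt, y)
        ours_lda = [baseline_predict(lda, v) for v in probes]
        ours_qda = [baseline_predict(qda, v) for v in probes]
        assert np.mean(ours_lda == sk_lda.predict(Xp[:, :2])) > 0.98
        assert np.mean(ours_qda == sk_qda.predict(Xp[:, :2])) > 0.98

    def test_unknown_kind_rejected(self):
        with pytest.raises(ParameterError):
            train_baseline(self._gauss_1d(0, 2, 1, 1, n=20), "KNN")


class TestExtraBaselineHook:
    def test_any_sklearn_estimator_plugs_in(self):
        from sklearn.tree import DecisionTreeClassifier

        train = _blobs(n=100)
        preds = extra_baseline(DecisionTreeClassifier(random_state=0), train,
                               train)
        assert np.mean(preds == [v.label for v in train]) == 1.0


class TestDefaultCohortModels:
    def test_increasing_d1_never_flips_positive_to_negative(
            self, default_screen):
        """Raising the baseline Z alone (other features fixed) never turns a
        positive call negative for the default-cohort RBF model — probed on
        a grid up to D1 = 12 for every positively-called chr21 row."""
        model = default_screen.models["21"]
        for row in default_screen.rows:
            if row.chrom != "21" or row.predicted_class != 1:
                continue
            base = list(row.features)
            for d1 in np.linspace(base[0], 12.0, 15):
                vals = (float(d1),) + tuple(base[1:])
                cls, _, _ = predict(
                    model, FeatureVector(row.sample_id, "21", vals))
                assert cls == 1

    def test_rbf_svm_matches_or_beats_discriminant_baselines(
            self, default_cohort, default_screen):
        """Grey-zone sensitivity (pooled over the three chromosomes) of the
        corrected SVM is at least that of closed-form LDA and QDA trained on
        the same scaled features — the qualitative model-comparison pattern."""
        from niptcall import fit_scaler

        sens = {"svm": [0, 0], "LDA": [0, 0], "QDA": [0, 0]}
        for chrom in ("13", "18", "21"):
            train_rows = [r for r in default_screen.rows
                          if r.chrom == chrom
                          and default_cohort.arms[r.sample_id] == "train"
                          and r.triage_group in ("N", "P")]
            grey_rows = [r for r in default_screen.rows
                         if r.chrom == chrom
                         and default_cohort.arms[r.sample_id] == "grey"]
            train = [FeatureVector(r.sample_id, chrom, r.features,
                                   1 if r.triage_group == "P" else -1)
                     for r in train_rows]
            scaler = fit_scaler(train)
            strain = scaler.transform_all(train)
            models = {"LDA": train_baseline(strain, "LDA"),
                      "QDA": train_baseline(strain, "QDA")}
            for r in grey_rows:
                if default_cohort.records[r.sample_id].real_state[chrom] != 1:
                    continue
                sens["svm"][1] += 1
                sens["svm"][0] += r.predicted_class == 1
                v = scaler.transform(
                    FeatureVector(r.sample_id, chrom, r.features))
                for name, mdl in models.items():
                    sens[name][1] += 1
                    sens[name][0] += baseline_predict(mdl, v) == 1
        svm = sens["svm"][0] / sens["svm"][1]
        assert svm >= sens["LDA"][0] / sens["LDA"][1]
        assert svm >= sens["QDA"][0] / sens["QDA"][1]


class TestCorrectionWorkflow:
    def test_no_positive_training_samples_is_informative_error(
            self, small_null_cohort):
        from niptcall import (build_reference_panel, correction_workflow,
                              normalize_pipeline)

        profiles = normalize_pipeline(small_null_cohort.depth)
        by_id = {p.sample_id: p for p in profiles}
        panel = build_reference_panel(
            [by_id[s] for s in small_null_cohort.arm_ids("reference")])
        analysis = [by_id[s] for s in small_null_cohort.arm_ids("train")]
        with pytest.raises(NiptError, match="simulat"):
            correction_workflow(analysis, small_null_cohort.records, panel,
                                chroms=("21",))

    def test_every_analysis_sample_receives_a_call(self, default_cohort,
                                                   default_screen):
        """Totality: each non-reference sample gets a class and normalized
        probabilities on every target chromosome — no abstentions."""
        n_analysis = sum(1 for a in default_cohort.arms.values()
                         if a != "reference")
        assert len(default_screen.rows) == n_analysis * 3
        for row in default_screen.rows:
            assert row.predicted_class in (-1, 1)
            assert row.probability_negative + row.probability_positive == \
                pytest.approx(1.0, abs=1e-9)
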