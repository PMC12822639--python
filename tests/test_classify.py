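"""Stratified splitting, SMOTE, LDA/SVM fitting, metrics, and the
end-to-end binary discrimination tasks."""

import numpy as np
import pytest

import fossilftir as ff
from fossilftir.classify import (
    DEFAULT_C_GRID,
    DEFAULT_GAMMA_GRID,
    MetricsReport,
    loo_accuracy,
    run_binary_task,
    stratified_split,
)
from fossilftir.io import SpectrumError
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis


def _two_clouds(n=20, sep=6.0, seed=0):
    rng = np.random.default_rng(seed)
    x = np.vstack([rng.normal(0, 1, (n, 2)), rng.normal(sep, 1, (n, 2))])
    y = np.array(["neg"] * n + ["Prototaxites"] * n)
    return x, y


class TestStratifiedSplit:
    def test_largest_remainder_example(self):
        # 12 Prototaxites + 24 Fungi at 30%: global target 11; floors
        # 3 + 7, largest remainder (.6) sends the extra slot to the
        # smaller class -> test counts 4 and 7
        labels = ["Prototaxites"] * 12 + ["Fungi"] * 24
        plan = stratified_split(labels, 0.30, seed=0)
        assert plan.per_class["Prototaxites"]["n_test"] == 4
        assert plan.per_class["Fungi"]["n_test"] == 7
        assert len(plan.test_indices) == 11

    def test_partition_is_exact(self):
        labels = ["a"] * 9 + ["b"] * 21
        plan = stratified_split(labels, 0.30, seed=3)
        joined = np.sort(np.concatenate([plan.train_indices,
                                         plan.test_indices]))
        np.testing.assert_array_equal(joined, np.arange(30))

    def test_deterministic_given_seed(self):
        labels = ["a"] * 10 + ["b"] * 14
        p1 = stratified_split(labels, 0.30, seed=5)
        p2 = stratified_split(labels, 0.30, seed=5)
        np.testing.assert_array_equal(p1.test_indices, p2.test_indices)

    def test_degenerate_fractions_rejected(self):
        labels = ["a"] * 5 + ["b"] * 5
        for frac in (0.0, 1.0):
            with pytest.raises(SpectrumError):
                stratified_split(labels, frac, seed=0)

    def test_singleton_class_rejected(self):
        with pytest.raises(SpectrumError, match="stratify"):
            stratified_split(["a", "b", "b", "b"], 0.3, seed=0)


class TestSmote:
    def test_balances_to_majority_count(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, (32, 3))
        y = np.array(["min"] * 8 + ["maj"] * 24)
        xa, ya = ff.smote(x, y, k=5, seed=1)
        assert len(ya) == 48
        assert (ya == "min").sum() == 24           # 16 synthetic appended
        np.testing.assert_array_equal(xa[:32], x)  # originals untouched

    def test_synthetic_points_lie_on_minority_segments(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, (14, 4))
        y = np.array(["min"] * 4 + ["maj"] * 10)
        xa, ya = ff.smote(x, y, k=3, seed=2)
        minority = x[:4]
        for p in xa[14:]:
            # p = a + u (b - a) for some minority pair (a, b)
            on_segment = False
            for i in range(4):
                for j in range(4):
                    if i == j:
                        continue
                    d = minority[j] - minority[i]
                    t = np.dot(p - minority[i], d) / np.dot(d, d)
                    if -1e-10 <= t <= 1 + 1e-10 and np.linalg.norm(
                        p - (minority[i] + t * d)
                    ) < 1e-10:
                        on_segment = True
            assert on_segment

    def test_deterministic_and_k_reduction_warns(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, (13, 2))
        y = np.array(["min"] * 3 + ["maj"] * 10)
        with pytest.warns(UserWarning, match="k reduced"):
            a1 = ff.smote(x, y, k=5, seed=7)
        with pytest.warns(UserWarning, match="k reduced"):
            a2 = ff.smote(x, y, k=5, seed=7)
        np.testing.assert_array_equal(a1[0], a2[0])

    def test_singleton_minority_rejected(self):
        x = np.zeros((4, 2))
        y = np.array(["min", "maj", "maj", "maj"])
        with pytest.raises(SpectrumError):
            ff.smote(x, y, seed=0)


class TestLDA:
    def test_separable_point_masses(self):
        x = np.array([[0.0, 0], [0.1, 0], [5.0, 5], [5.1, 5]])
        y = np.array(["a", "a", "b", "b"])
        model = ff.fit_lda(x, y)
        assert (model.predict(x) == y).all()

    def test_two_well_separated_clouds_loo_perfect(self):
        x, y = _two_clouds(sep=6.0, seed=3)
        acc = loo_accuracy(lambda: LinearDiscriminantAnalysis(solver="svd"),
                           x, y)
        assert acc == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(SpectrumError):
            ff.fit_lda(np.zeros((4, 2)), np.array(["a"] * 4))


class TestSVMGrid:
    def test_tie_breaks_to_smallest_parameters(self):
        # trivially separable data where every grid point reaches LOO
        # accuracy 1: the smallest (C, gamma) pair must win
        x, y = _two_clouds(n=8, sep=20.0, seed=4)
        model = ff.fit_svm_grid(x, y, C_grid=(50.0, 5.0, 1.0),
                                gamma_grid=(0.05, 0.005))
        assert model.loo_accuracy == 1.0
        assert (model.best_C, model.best_gamma) == (1.0, 0.005)

    def test_best_parameters_member_of_grid(self):
        x, y = _two_clouds(n=10, sep=3.0, seed=5)
        model = ff.fit_svm_grid(x, y)
        assert model.best_C in DEFAULT_C_GRID
        assert model.best_gamma in DEFAULT_GAMMA_GRID


class TestMetrics:
    def test_perfect_prediction_all_ones(self):
        x, y = _two_clouds(sep=8.0, seed=6)
        model = ff.fit_lda(x, y)
        rep = ff.evaluate(model, x, y)
        for value in (rep.accuracy, rep.precision, rep.recall, rep.f1,
                      rep.mcc):
            assert value == 1.0

    def test_mcc_matches_direct_formula(self):
        rep = MetricsReport(tp=4, tn=25, fp=2, fn=1)
        assert rep.mcc == pytest.approx(98 / np.sqrt(21060), abs=1e-12)
        assert rep.accuracy == pytest.approx(29 / 32)

    def test_one_sided_prediction_gives_zero_mcc(self):
        rep = MetricsReport(tp=5, fp=7, fn=0, tn=0)
        with pytest.warns(UserWarning, match="MCC"):
            assert rep.mcc == 0.0

    def test_foreign_labels_rejected(self):
        x, y = _two_clouds(seed=7)
        model = ff.fit_lda(x, y)
        with pytest.raises(SpectrumError, match="outside"):
            ff.evaluate(model, x[:3], np.array(["Fungi"] * 3))


class TestBinaryTasks:
    def test_vs_bacteria_lda_suffices(self, preprocessed_dataset):
        rep = run_binary_task(preprocessed_dataset, "vs-bacteria", seed=11)
        assert rep.model.kind == "lda"
        assert rep.params["n_pcs"] == 2
        for value in rep.test_metrics.as_dict().values():
            if isinstance(value, float):
                assert value >= 0.9

    def test_vs_chitinous_negative_group_size(self, preprocessed_dataset):
        rep = run_binary_task(preprocessed_dataset, "vs-chitinous", seed=11)
        n = rep.params["n_train"] + rep.params["n_test"]
        assert n == 48                       # 12 Prototaxites + 24 + 12
        assert rep.params["n_pcs"] == 4

    def test_audit_trail_complete(self, preprocessed_dataset):
        rep = run_binary_task(preprocessed_dataset, "vs-fungi", seed=11)
        for key in ("n_pcs", "test_fraction", "smote_applied", "smote_k",
                    "lda_loo_accuracy", "escalated_to_svm", "recipe", "seed",
                    "n_train", "n_test"):
            assert key in rep.params

    def test_unknown_task_rejected(self, preprocessed_dataset):
        with pytest.raises(SpectrumError, match="unknown task"):
            run_binary_task(preprocessed_dataset, "vs-lichen")

    def test_no_leakage_pca_depends_on_train_rows_only(
        self, preprocessed_dataset
    ):
        rep = run_binary_task(preprocessed_dataset, "vs-fungi", seed=3)
        sub = preprocessed_dataset.subset_classes(("Prototaxites", "Fungi"))
        x = sub.matrix()
        train_pca = ff.fit_pca(x[rep.split.train_indices],
                               n_components=rep.params["n_pcs"])
        np.testing.assert_allclose(rep.model.pca.mean, train_pca.mean)
        np.testing.assert_allclose(rep.model.pca.loadings, train_pca.loadings)

    def test_label_permutation_collapses_to_majority_rate(
        self, preprocessed_dataset
    ):
        # shuffled labels carry no class signal: mean test accuracy over
        # permutations must sit near the majority-class rate, far below
        # the genuine-label accuracy
        sub = preprocessed_dataset.subset_classes(("Prototaxites", "Fungi"))
        rng = np.random.default_rng(0)
        accs = []
        for rep_i in range(10):
            spectra = list(sub.spectra)
            taxa = rng.permutation([sp.taxon for sp in spectra])
            shuffled = ff.SpectralDataset(
                [ff.Spectrum(sp.sample_id, sp.wavenumbers, sp.absorbance,
                             taxon=t, history=sp.history)
                 for sp, t in zip(spectra, taxa)]
            )
            rep = run_binary_task(shuffled, "vs-fungi", seed=rep_i)
            accs.append(rep.test_metrics.accuracy)
        majority = 24 / 36
        assert abs(np.mean(accs) - majority) < 0.15
        genuine = run_binary_task(sub, "vs-fungi", seed=0)
        assert genuine.test_metrics.accuracy > np.mean(accs)


class TestLearningCurve:
    def test_one_row_per_feasible_fraction_and_final_sd_zero(self):
        x, y = _two_clouds(n=12, sep=5.0, seed=8)
        rows = ff.learning_curve(x, y, fractions=(0.3, 0.6, 1.0),
                                 n_repeats=3, seed=1)
        assert [r[0] for r in rows] == [0.3, 0.6, 1.0]
        assert rows[-1][2] == 0.0

    def test_accuracy_does_not_degrade_with_more_data(self):
        x, y = _two_clouds(n=15, sep=4.0, seed=9)
        rows = ff.learning_curve(x, y, fractions=(0.3, 1.0), n_repeats=5,
                                 seed=2)
        assert rows[-1][1] >= rows[0][1]
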