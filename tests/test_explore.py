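"""PCA diagnostics, bootstrap stability, T²/Q screening, and CCA."""

import numpy as np
import pytest

import fossilftir as ff
from fossilftir.explore import (
    detect_outliers,
    fit_cca,
    fit_pca,
    q_residual_threshold,
)
from fossilftir.io import SpectrumError
from fossilftir.synthgen import StudyDesign, default_profiles, generate_spectrum


class TestPCA:
    def test_rank_one_data_explained_by_first_component(self):
        rng = np.random.default_rng(0)
        direction = rng.normal(0, 1, 6)
        x = np.outer(rng.normal(0, 2, 20), direction) + 5.0
        model = fit_pca(x, n_components=3)
        assert model.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_loadings_orthonormal(self):
        rng = np.random.default_rng(1)
        model = fit_pca(rng.normal(0, 1, (30, 8)), n_components=5)
        gram = model.loadings.T @ model.loadings
        np.testing.assert_allclose(gram, np.eye(5), atol=1e-10)

    def test_eigenvalues_match_dense_covariance_eigendecomposition(self):
        x = np.array([[1.0, 2.0, 0.5],
                      [2.0, 0.0, 1.5],
                      [3.0, 1.0, -1.0],
                      [0.0, 4.0, 2.0]])
        model = fit_pca(x, n_components=3)
        brute = np.sort(np.linalg.eigvalsh(np.cov(x, rowvar=False)))[::-1]
        np.testing.assert_allclose(model.eigenvalues, brute, atol=1e-10)

    def test_full_reconstruction(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, (15, 6))
        model = fit_pca(x, n_components=6)
        back = model.inverse_transform(model.transform(x))
        assert np.linalg.norm(back - x) < 1e-8

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, (25, 7))
        a, b = fit_pca(x, 4), fit_pca(x.copy(), 4)
        np.testing.assert_array_equal(a.loadings, b.loadings)
        for j in range(4):
            k = np.argmax(np.abs(a.loadings[:, j]))
            assert a.loadings[k, j] > 0

    def test_component_bound_enforced(self):
        with pytest.raises(SpectrumError):
            fit_pca(np.eye(3), n_components=3)


class TestBootstrapStability:
    def test_noiseless_rank_one_perfectly_stable(self):
        rng = np.random.default_rng(0)
        x = np.outer(rng.normal(0, 1, 30), rng.normal(0, 1, 5))
        rep = ff.bootstrap_stability(x, n_components=1, n_boot=50, seed=1)
        assert rep.mean_cosines[0] == pytest.approx(1.0, abs=1e-9)

    def test_isotropic_noise_has_no_stable_axis(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, (50, 20))
        rep = ff.bootstrap_stability(x, n_components=3, n_boot=100, seed=2)
        assert rep.mean_cosines[0] < 0.9

    def test_cosines_within_unit_interval_and_deterministic(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, (20, 6))
        a = ff.bootstrap_stability(x, 3, n_boot=40, seed=9)
        b = ff.bootstrap_stability(x, 3, n_boot=40, seed=9)
        assert ((a.cosines >= 0) & (a.cosines <= 1)).all()
        np.testing.assert_array_equal(a.cosines, b.cosines)


class TestOutlierScreening:
    def test_mean_sample_has_zero_t2(self):
        rng = np.random.default_rng(6)
        x = rng.normal(0, 1, (30, 5))
        model = fit_pca(x, 2)
        rep = detect_outliers(model, np.vstack([x, model.mean]))
        assert rep.t2[-1] == pytest.approx(0.0, abs=1e-20)

    def test_full_rank_model_disables_q_rule(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0, 1, (30, 4))
        model = fit_pca(x, 4)
        with pytest.warns(UserWarning, match="Q rule disabled"):
            rep = detect_outliers(model, x)
        np.testing.assert_allclose(rep.q, 0.0, atol=1e-18)
        assert np.isnan(rep.q_threshold)

    def test_q_threshold_requires_residual_variance(self):
        assert np.isnan(q_residual_threshold([], 0.99))
        assert q_residual_threshold([0.5, 0.1, 0.01], 0.99) > 0

    def test_flags_invariant_under_joint_rescaling(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0, 1, (40, 6))
        x[0] += 8.0
        r1 = detect_outliers(fit_pca(x, 2), x)
        r2 = detect_outliers(fit_pca(10.0 * x, 2), 10.0 * x)
        np.testing.assert_array_equal(r1.flags, r2.flags)

    def test_injected_spike_is_screened_out(self):
        # 40 in-class spectra plus one carrying a 10x-noise spike: the
        # spiked sample must be flagged at 99% confidence, with at most
        # one stray inlier flag per trial
        prof = default_profiles()["Prototaxites"]
        grid = StudyDesign().grid()
        for seed in range(10):
            spectra = [
                generate_spectrum(prof, grid, seed=[seed, i],
                                  sample_id=f"s{i}")
                for i in range(41)
            ]
            pre = ff.apply_recipe(ff.SpectralDataset(spectra), "atr-paper")
            spiked = ff.inject_outlier(
                pre.spectra[-1], "spike", 10 * prof.noise_sd, seed=[seed, 99]
            )
            mat = np.vstack(
                [s.absorbance for s in pre.spectra[:-1]] + [spiked.absorbance]
            )
            rep = detect_outliers(fit_pca(mat, 5), mat, confidence=0.99)
            assert rep.flags[-1]
            assert rep.flags[:-1].sum() <= 1

    def test_remove_and_recompile(self, default_dataset):
        sub = default_dataset.subset(range(10))
        mat = sub.matrix()
        rep = detect_outliers(fit_pca(mat, 2), mat)
        if not rep.flags.any():
            out = ff.remove_outliers_and_recompile(sub, rep)
            assert len(out) == 10
        rep.flags = np.zeros(10, dtype=bool)
        rep.flags[[2, 7]] = True
        out = ff.remove_outliers_and_recompile(sub, rep)
        assert len(out) == 8
        assert out.onehot.shape[0] == 8

    def test_all_flagged_rejected(self, default_dataset):
        sub = default_dataset.subset(range(4))
        mat = sub.matrix()
        rep = detect_outliers(fit_pca(mat, 2), mat)
        rep.flags = np.ones(4, dtype=bool)
        with pytest.raises(SpectrumError, match="all samples"):
            ff.remove_outliers_and_recompile(sub, rep)


class TestCCA:
    def test_perfect_binary_predictor_explains_everything(self):
        y = np.zeros((10, 2))
        y[:5, 0] = 1
        y[5:, 1] = 1
        x = y[:, [0]].astype(float)
        res = fit_cca(y, x)
        assert len(res.eigenvalues) == 1
        assert res.constrained_inertia / res.total_inertia == (
            pytest.approx(1.0, abs=1e-10)
        )

    def test_eigenvalues_match_vegan_reference(self):
        # fixture cross-checked against vegan::cca (R): eigenvalues
        # 0.8233298, 0.5674551
        rng = np.random.default_rng(42)
        y = np.zeros((12, 3), int)
        y[:4, 0] = 1
        y[4:8, 1] = 1
        y[8:, 2] = 1
        x = rng.normal(0, 1, (12, 4))
        x[:, 0] += y[:, 0] * 2.0
        res = fit_cca(y, x)
        np.testing.assert_allclose(
            res.eigenvalues, [0.8233298, 0.5674551], atol=5e-7
        )
        assert res.total_inertia == pytest.approx(2.0)

    def test_total_inertia_equals_ca_inertia_of_onehot(self, band_table):
        # independent closed form: CA inertia of a one-hot response is
        # (number of classes - 1), whatever the class counts
        taxa = np.asarray(band_table.attrs["taxon"])
        y = ff.one_hot(taxa, sorted(set(taxa)))
        res = fit_cca(y, band_table.to_numpy())
        assert res.total_inertia == pytest.approx(len(set(taxa)) - 1)
        assert res.constrained_inertia <= res.total_inertia + 1e-12

    def test_axis_count_bound(self, band_table):
        taxa = np.asarray(band_table.attrs["taxon"])
        y = ff.one_hot(taxa, sorted(set(taxa)))
        res = fit_cca(y, band_table.to_numpy())
        assert len(res.eigenvalues) <= min(6, len(set(taxa)) - 1)
        assert ((res.eigenvalues >= 0) & (res.eigenvalues <= 1)).all()
        assert (np.diff(res.eigenvalues) <= 1e-12).all()

    def test_noise_predictors_not_significant_under_permutation(self):
        rng = np.random.default_rng(11)
        labels = np.repeat(["a", "b", "c"], 10)
        y = ff.one_hot(labels, ["a", "b", "c"])
        x = rng.normal(0, 1, (30, 4))
        observed = fit_cca(y, x)
        obs_frac = observed.constrained_inertia / observed.total_inertia
        perm = []
        for _ in range(200):
            p = rng.permutation(30)
            res = fit_cca(y, x[p])
            perm.append(res.constrained_inertia / res.total_inertia)
        pval = np.mean(np.asarray(perm) >= obs_frac)
        assert pval > 0.05

    def test_zero_class_rejected(self):
        y = np.zeros((4, 2))
        y[:, 0] = 1
        with pytest.raises(SpectrumError):
            fit_cca(y, np.random.default_rng(0).normal(0, 1, (4, 2)))
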