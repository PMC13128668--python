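import numpy as np
import pytest
from scipy import stats

from protlife.features import (
    FeatureProcessingConfig,
    anova_select,
    apply_state,
    fit_feature_state,
    fit_pca,
    fit_zscore,
    output_names,
)


class TestZscore:
    def test_column_statistics(self):
        means, stds, zero = fit_zscore(np.array([[1.0], [2.0], [3.0]]))
        assert means[0] == 2.0
        assert stds[0] == pytest.approx(1.0)  # sample std, ddof=1
        assert not zero[0]

    def test_applied_to_train_gives_mean0_var1(self, rng):
        X = rng.normal(5, 3, size=(40, 6))
        means, stds, _ = fit_zscore(X)
        Z = (X - means) / stds
        np.testing.assert_allclose(Z.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(Z.std(axis=0, ddof=1), 1, atol=1e-12)

    def test_constant_column_flagged(self):
        _, _, zero = fit_zscore(np.array([[1.0, 2.0], [1.0, 3.0], [1.0, 4.0]]))
        assert zero.tolist() == [True, False]

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            fit_zscore(np.empty((0, 3)))


class TestAnovaSelect:
    def test_f_equals_pooled_t_squared(self, rng):
        X = rng.normal(size=(60, 100))
        y = np.repeat([0, 1], 30)
        _, pvals = anova_select(X, y, alpha=0.01)
        t, p_t = stats.ttest_ind(X[y == 0], X[y == 1], equal_var=True)
        np.testing.assert_allclose(pvals, p_t, atol=1e-8)

    def test_identical_feature_discarded(self, rng):
        X = np.column_stack([np.ones(40), rng.normal(size=40)])
        y = np.repeat([0, 1], 20)
        mask, pvals = anova_select(X, y, alpha=0.01)
        assert not mask[0] and pvals[0] == 1.0

    def test_planted_shift_retained(self, rng):
        X = rng.normal(size=(100, 5))
        y = np.repeat([0, 1], 50)
        X[y == 1, 0] += 3.0  # 3 pooled SDs
        mask, pvals = anova_select(X, y, alpha=0.01)
        assert mask[0] and pvals[0] < 1e-10
        # direct F CDF cross-check
        f = stats.f_oneway(X[y == 0, 0], X[y == 1, 0]).statistic
        assert stats.f.sf(f, 1, 98) == pytest.approx(pvals[0], rel=1e-6)

    def test_threshold_monotone(self, rng):
        X = rng.normal(size=(60, 50))
        y = np.repeat([0, 1], 30)
        X[y == 1, :10] += rng.uniform(0.3, 1.5, size=10)
        loose, _ = anova_select(X, y, alpha=0.05)
        tight, _ = anova_select(X, y, alpha=0.005)
        assert np.all(loose[tight])  # selected(alpha') subset of selected(alpha)

    def test_small_class_rejected(self):
        with pytest.raises(ValueError):
            anova_select(np.zeros((3, 2)), np.array([0, 1, 1]))


class TestPca:
    def test_line_in_5d_needs_one_component(self, rng):
        t = rng.normal(size=(100, 1))
        X = t @ rng.normal(size=(1, 5)) + 0.001 * rng.normal(size=(100, 5))
        pca = fit_pca(X, 0.95)
        assert pca.components_.shape[0] == 1

    def test_isotropic_gaussian_needs_nearly_all(self, rng):
        X = rng.normal(size=(2000, 10))
        pca = fit_pca(X, 0.95)
        assert pca.components_.shape[0] in (9, 10)

    def test_basis_orthonormal(self, rng):
        pca = fit_pca(rng.normal(size=(50, 8)), 0.9)
        B = pca.components_
        np.testing.assert_allclose(B @ B.T, np.eye(B.shape[0]), atol=1e-8)

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            fit_pca(np.ones((10, 4)), 0.95)


def _toy_inputs(rng, n=40, p=30, d=12):
    X = rng.normal(size=(n, p))
    y = np.repeat([0.0, 1.0], n // 2)
    X[y == 1, :3] += 2.5
    E = rng.normal(size=(n, d))
    names = [f"f{i}" for i in range(p)]
    return X, names, y, E


class TestFeatureState:
    def test_apply_reproduces_fit_dimensions(self, rng):
        X, names, y, E = _toy_inputs(rng)
        state = fit_feature_state(X, names, y, E)
        out = apply_state(state, X, names, E)
        assert out.shape == (len(y), state.output_dim)
        assert len(output_names(state)) == state.output_dim

    def test_state_checksum_unchanged_by_apply(self, rng):
        X, names, y, E = _toy_inputs(rng)
        state = fit_feature_state(X, names, y, E)
        before = state.checksum()
        apply_state(state, rng.normal(size=(7, X.shape[1])), names, rng.normal(size=(7, E.shape[1])))
        assert state.checksum() == before

    def test_fit_ignores_rows_outside_training_set(self, rng):
        # leakage guard: the state depends only on the rows passed to fit
        X, names, y, E = _toy_inputs(rng)
        s1 = fit_feature_state(X[:30], names, y[:30], E[:30])
        X2, E2 = X.copy(), E.copy()
        X2[30:] = 999.0
        E2[30:] = -999.0
        s2 = fit_feature_state(X2[:30], names, y[:30], E2[:30])
        assert s1.checksum() == s2.checksum()

    def test_name_mismatch_rejected(self, rng):
        X, names, y, E = _toy_inputs(rng)
        state = fit_feature_state(X, names, y, E)
        wrong = list(names)
        wrong[0] = "other"
        with pytest.raises(ValueError, match="mismatch"):
            apply_state(state, X, wrong, E)

    def test_all_false_mask_still_runs(self, rng):
        X, names, y, E = _toy_inputs(rng)
        # pure-noise features at a tiny alpha: nothing survives selection
        X_noise = rng.normal(size=X.shape)
        state = fit_feature_state(
            X_noise, names, y, E, FeatureProcessingConfig(anova_alpha=1e-12)
        )
        assert state.n_selected == 0
        out = apply_state(state, X_noise, names, E)
        assert out.shape[1] == state.n_components

    def test_config_validation(self):
        with pytest.raises(ValueError):
            FeatureProcessingConfig(anova_alpha=0)
        with pytest.raises(ValueError):
            FeatureProcessingConfig(pca_variance=1.5)
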