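"""PLS1 (NIPALS) regression and its composed coefficient vector."""

import numpy as np
import pytest

import forcemode as fm
from forcemode.pls import (DegenerateTargetError, RankDeficiencyWarning,
                           UndefinedContributionError)

from oracles import oracle_ols_predict, oracle_pls_predict


def _random_problem(seed, n=60, p=8, noise=0.0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    beta = rng.normal(size=p)
    y = X @ beta + 3.0 + noise * rng.normal(size=n)
    return X, y


class TestFit:
    def test_exact_recovery_noiseless_full_rank(self):
        X, y = _random_problem(0)
        model = fm.fit_pls(X, y, n_components=X.shape[1])
        assert np.allclose(fm.predict(model, X), y, rtol=1e-8)

    def test_single_informative_column(self):
        # other columns orthogonalised in-sample so only column 3
        # covaries with y
        rng = np.random.default_rng(1)
        X = rng.normal(size=(200, 6))
        X -= X.mean(axis=0)
        target = X[:, 3].copy()
        for j in range(6):
            if j != 3:
                X[:, j] -= (X[:, j] @ target) / (target @ target) * target
        y = 2.5 * target
        coef = fm.fit_pls(X, y, 1).coefficient_vector
        off = np.delete(coef, 3)
        assert np.abs(off).max() < 1e-6 * abs(coef[3])
        assert np.isclose(coef[3], 2.5, rtol=1e-8)

    def test_zero_variance_target_raises(self):
        X, _ = _random_problem(2)
        with pytest.raises(DegenerateTargetError):
            fm.fit_pls(X, np.ones(len(X)), 2)

    def test_rank_deficiency_truncates_with_warning(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=(50, 2))
        X = base @ rng.normal(size=(2, 6))  # rank 2
        y = X @ rng.normal(size=6)
        with pytest.warns(RankDeficiencyWarning):
            model = fm.fit_pls(X, y, 5)
        assert model.n_components <= 2
        assert np.allclose(fm.predict(model, X), y, rtol=1e-8)

    def test_score_orthogonality(self):
        X, y = _random_problem(4, noise=0.5)
        model = fm.fit_pls(X, y, 5)
        gram = model.scores.T @ model.scores
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8 * np.abs(np.diag(gram)).max()

    def test_ols_limit_at_full_rank(self):
        X, y = _random_problem(5, noise=0.3)
        model = fm.fit_pls(X, y, X.shape[1])
        assert np.allclose(fm.predict(model, X),
                           oracle_ols_predict(X, y, X), rtol=1e-6)

    def test_scale_equivariance(self):
        X, y = _random_problem(6, noise=0.2)
        base = fm.fit_pls(X, y, 3).coefficient_vector
        scaled_y = fm.fit_pls(X, 4.0 * y, 3).coefficient_vector
        assert np.allclose(scaled_y, 4.0 * base, rtol=1e-8)
        # column scaling: exact equivariance holds in the OLS limit
        # (K = rank), where the fit is basis-independent
        k = X.shape[1]
        base_full = fm.fit_pls(X, y, k).coefficient_vector
        X2 = X.copy()
        X2[:, 2] *= 5.0
        scaled_x = fm.fit_pls(X2, y, k).coefficient_vector
        expected = base_full.copy()
        expected[2] /= 5.0
        assert np.allclose(scaled_x, expected, rtol=1e-6)

    def test_matches_sklearn_reference(self):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X, y = _random_problem(7, n=120, p=15, noise=1.0)
        ours = fm.fit_pls(X, y, 4).coefficient_vector
        ref = sklearn.PLSRegression(n_components=4, scale=False).fit(X, y)
        assert np.allclose(ours, ref.coef_.ravel(), rtol=1e-8)


class TestPredict:
    def test_mean_row_predicts_mean(self):
        X, y = _random_problem(8, noise=0.5)
        model = fm.fit_pls(X, y, 3)
        assert np.isclose(fm.predict(model, model.x_mean)[0], model.y_mean,
                          rtol=1e-10)

    def test_column_mismatch_raises(self):
        X, y = _random_problem(9)
        model = fm.fit_pls(X, y, 2)
        with pytest.raises(ValueError):
            fm.predict(model, X[:, :-1])

    def test_composed_coefficients_match_iterative_oracle(self):
        X, y = _random_problem(10, noise=0.7)
        model = fm.fit_pls(X, y, 4)
        X_new = np.random.default_rng(11).normal(size=(7, X.shape[1]))
        assert np.allclose(fm.predict(model, X_new),
                           oracle_pls_predict(model, X_new), rtol=1e-10)


class TestComponentContribution:
    def test_single_direction_noiseless_is_one(self):
        # y covaries with exactly one in-sample direction, so the first
        # component alone reproduces it
        rng = np.random.default_rng(12)
        X = rng.normal(size=(80, 5))
        X -= X.mean(axis=0)
        target = X[:, 0].copy()
        for j in range(1, 5):
            X[:, j] -= (X[:, j] @ target) / (target @ target) * target
        y = -1.7 * target
        with pytest.warns(RankDeficiencyWarning):
            model = fm.fit_pls(X, y, 3)  # residual y vanishes after one
        contrib = fm.component_contribution(model, X, y)
        assert np.isclose(contrib[0], 1.0, atol=1e-6)

    def test_k_equals_one_is_trivially_one(self):
        X, y = _random_problem(13, noise=0.5)
        model = fm.fit_pls(X, y, 1)
        assert fm.component_contribution(model, X, y).tolist() == [1.0]

    def test_unrelated_data_raises(self):
        X, y = _random_problem(14, noise=0.5)
        model = fm.fit_pls(X, y, 2)
        rng = np.random.default_rng(15)
        with pytest.raises(UndefinedContributionError):
            fm.component_contribution(model, rng.normal(size=X.shape),
                                      rng.normal(size=len(y)) * 100 + 1e4)


class TestEnsembleAverage:
    def test_identical_vectors_average_to_themselves(self):
        v = np.array([1.0, -2.0, 3.0])
        mean, sim = fm.ensemble_average_vectors([v, v, v])
        assert np.allclose(mean, v)
        assert np.allclose(sim, 1.0)

    def test_sign_alignment_prevents_cancellation(self):
        v = np.array([1.0, -2.0, 3.0])
        mean, sim = fm.ensemble_average_vectors([v, -v])
        assert np.allclose(np.abs(mean), np.abs(v))
        assert np.allclose(sim, 1.0)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            fm.ensemble_average_vectors([])

    def test_averaging_beats_median_individual_vector(self):
        rng = np.random.default_rng(16)
        w = rng.normal(size=50)
        w /= np.linalg.norm(w)
        noisy = [w + 0.4 * rng.normal(size=50) for _ in range(10)]
        mean, _ = fm.ensemble_average_vectors(noisy)
        cos = lambda a: float(a @ w / np.linalg.norm(a))
        assert cos(mean) > np.median([cos(v) for v in noisy])


class TestSyntheticRecovery:
    def test_coefficient_recovery_on_default_ensemble(self, default_ensemble,
                                                      default_cv):
        # the ensemble-averaged cross-validation vector (the estimator
        # used for hotspot ranking) points along the planted hotspots
        tc = default_ensemble.true_coefficients
        ev = default_cv.ensemble_vector
        cos = ev @ tc / (np.linalg.norm(ev) * np.linalg.norm(tc))
        assert cos >= 0.95

    def test_mean_recovery_across_seeds(self, multi_seed_metrics):
        assert np.mean([m["cosine"] for m in multi_seed_metrics]) >= 0.9

    def test_first_component_dominates(self, default_ensemble):
        X = np.vstack(default_ensemble.features)
        y = np.concatenate(default_ensemble.observable)
        model = fm.fit_pls(X, y, 5)
        contrib = fm.component_contribution(model, X, y)
        assert contrib[0] >= 0.67
        assert np.all(np.diff(contrib) >= -1e-10)


def test_select_n_components_stops_when_gain_fades(default_ensemble):
    k = fm.select_n_components(default_ensemble.replicas())
    assert 1 <= k <= 20
    # one latent mode: a handful of components suffices
    assert k <= 5
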