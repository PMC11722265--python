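import numpy as np
import pandas as pd
import pytest
from scipy.linalg import subspace_angles

from ephyslink.srrr import (
    GeneMatrix,
    cv_srrr,
    fit_srrr,
    group_compare,
    lambda_max,
    latent_coords,
    preprocess_expression,
    r2_per_parameter,
)


def _lowrank_data(n=200, p=100, q=13, n_active=10, rank=2, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    W = np.zeros((p, rank))
    active = rng.choice(p, n_active, replace=False)
    W[active] = rng.normal(size=(n_active, rank))
    V, _ = np.linalg.qr(rng.normal(size=(q, rank)))
    X = rng.normal(size=(n, p))
    Y = X @ W @ V.T + noise * rng.normal(size=(n, q))
    return X, Y, W, V, active


class TestPreprocess:
    def test_identical_cells_map_to_identical_rows(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(5.0, size=(6, 30)) + 1
        counts[3] = counts[0]
        gm = preprocess_expression(counts)
        assert np.allclose(gm.values[0], gm.values[3])

    def test_depth_invariance(self):
        rng = np.random.default_rng(1)
        counts = (rng.poisson(5.0, size=(6, 30)) + 1).astype(float)
        doubled = counts.copy()
        doubled[2] *= 2
        a = preprocess_expression(counts)
        b = preprocess_expression(doubled)
        assert np.allclose(a.values, b.values)

    def test_zero_gene_dropped_with_warning(self):
        rng = np.random.default_rng(2)
        counts = rng.poisson(5.0, size=(6, 10)) + 1
        counts[:, 4] = 0
        with pytest.warns(UserWarning, match="zero-variance"):
            gm = preprocess_expression(counts)
        assert gm.values.shape[1] == 9
        assert "g4" not in gm.gene_names

    def test_duplicate_gene_names_rejected(self):
        with pytest.raises(ValueError):
            GeneMatrix(values=np.ones((3, 2)), gene_names=np.array(["a", "a"]))


class TestFitSRRR:
    def test_noiseless_exact_recovery(self):
        X, Y, W0, V0, active = _lowrank_data()
        lmax = lambda_max(X, Y)
        m = fit_srrr(X, Y, lam=lmax * 1e-4)
        r2 = r2_per_parameter(m, X, Y)
        assert r2.min() > 0.999
        assert set(active) <= set(m.selected)
        assert np.max(subspace_angles(m.W, W0)) < 1e-3

    def test_decoder_is_orthonormal(self):
        X, Y, *_ = _lowrank_data(noise=0.5, seed=1)
        m = fit_srrr(X, Y, lam=0.05)
        assert np.allclose(m.V.T @ m.V, np.eye(2), atol=1e-8)

    def test_objective_monotone_nonincreasing(self):
        X, Y, *_ = _lowrank_data(noise=0.5, seed=2)
        m = fit_srrr(X, Y, lam=0.05)
        assert np.all(np.diff(m.objective_path) <= 1e-10)

    def test_full_shrinkage_above_lambda_max(self):
        X, Y, *_ = _lowrank_data(seed=3)
        m = fit_srrr(X, Y, lam=lambda_max(X, Y) * 1.01)
        assert not m.W.any()
        assert np.allclose(m.predict(X), Y.mean(axis=0))
        assert np.allclose(r2_per_parameter(m, X, Y), 0.0, atol=1e-12)

    def test_pure_ridge_has_no_exact_zero_rows(self):
        X, Y, *_ = _lowrank_data(seed=4)
        m = fit_srrr(X, Y, lam=0.05, alpha=0.0)
        assert np.all(np.linalg.norm(m.W, axis=1) > 0)

    def test_excessive_rank_rejected(self):
        X, Y, *_ = _lowrank_data()
        with pytest.raises(ValueError):
            fit_srrr(X, Y, rank=14)


class TestCrossValidation:
    def test_noiseless_rank2_reaches_r2_one_at_small_lambda(self):
        X, Y, *_ = _lowrank_data(n=150, p=60)
        cv = cv_srrr(X, Y, folds=4, n_lambdas=8, seed=0)
        assert cv.cv_r2_mean.max() > 0.99

    def test_pure_noise_has_no_predictive_power(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(120, 50))
        Y = rng.normal(size=(120, 13))
        cv = cv_srrr(X, Y, folds=4, n_lambdas=6, seed=0)
        assert cv.cv_r2_mean.max() < 0.05

    def test_gene_count_monotone_in_lambda(self):
        X, Y, *_ = _lowrank_data(n=150, p=60, noise=0.3, seed=6)
        cv = cv_srrr(X, Y, folds=4, n_lambdas=10, seed=0)
        # path runs lambda_max -> 0: counts must not decrease
        assert np.all(np.diff(cv.n_genes_mean.values) >= -1e-9)

    def test_fold_assignment_seed_stable(self):
        X, Y, *_ = _lowrank_data(n=100, p=40, noise=0.3, seed=7)
        a = cv_srrr(X, Y, folds=4, n_lambdas=4, seed=3)
        b = cv_srrr(X, Y, folds=4, n_lambdas=4, seed=3)
        pd.testing.assert_frame_equal(a, b)


class TestPerParameterAndLatent:
    def test_permuting_one_column_breaks_only_its_r2(self):
        X, Y, *_ = _lowrank_data(noise=0.05, seed=8)
        m = fit_srrr(X, Y, lam=lambda_max(X, Y) * 1e-3)
        rng = np.random.default_rng(9)
        Yp = Y.copy()
        Yp[:, 4] = rng.permutation(Yp[:, 4])
        r2 = r2_per_parameter(m, X, Yp)
        r2_ref = r2_per_parameter(m, X, Y)
        assert r2[4] < 0.2
        others = np.delete(np.arange(13), 4)
        assert np.allclose(r2[others], r2_ref[others])

    def test_latent_is_two_columns_and_matches_projection(self):
        X, Y, *_ = _lowrank_data(seed=10)
        m = fit_srrr(X, Y, lam=0.02)
        L = latent_coords(m, X)
        assert L.shape == (X.shape[0], 2)
        assert np.allclose(L, (X - m.x_mean) @ m.W)
        X2 = np.vstack([X, X[:1]])
        L2 = latent_coords(m, X2)
        assert np.allclose(L2[-1], L2[0])


class TestGroupCompare:
    def test_identical_matrices_give_zero(self):
        rng = np.random.default_rng(11)
        theta = rng.normal(size=(30, 13))
        labels = np.repeat(["a", "b", "c"], 10)
        _, _, d = group_compare(theta, theta.copy(), labels)
        assert d == pytest.approx(0.0)

    def test_one_sd_perturbation_in_one_parameter_gives_one(self):
        rng = np.random.default_rng(12)
        theta = rng.normal(size=(20, 13))
        pred = theta.copy()
        pred[:, 3] += theta[:, 3].std()
        labels = np.repeat(["only"], 20)
        _, _, d = group_compare(theta, pred, labels)
        assert d == pytest.approx(1.0)

    def test_invariant_to_label_permutation(self):
        rng = np.random.default_rng(13)
        theta = rng.normal(size=(30, 13))
        pred = theta + 0.3 * rng.normal(size=theta.shape)
        labels = np.repeat(["a", "b", "c"], 10)
        _, _, d1 = group_compare(theta, pred, labels)
        mapping = {"a": "z", "b": "y", "c": "x"}
        _, _, d2 = group_compare(theta, pred, np.array([mapping[l] for l in labels]))
        assert d1 == pytest.approx(d2)
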