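"""Unit and property tests for the regularised CCA core."""

import numpy as np
import pytest
import scipy.linalg as sla
from hypothesis import given, settings
from hypothesis import strategies as st

from latentdim.rcca import (
    DegenerateDataError,
    compute_loadings,
    deflate,
    fit_rcca,
    make_deflator,
    project,
)


def cca_eigen_oracle(X, Y):
    """Textbook CCA as a dense generalised eigenproblem (independent of
    the production SVD solver)."""
    n = X.shape[0]
    Xc, Yc = X - X.mean(0), Y - Y.mean(0)
    Cxx, Cyy = Xc.T @ Xc / (n - 1), Yc.T @ Yc / (n - 1)
    Cxy = Xc.T @ Yc / (n - 1)
    p, q = Cxx.shape[0], Cyy.shape[0]
    A = np.block([[np.zeros((p, p)), Cxy], [Cxy.T, np.zeros((q, q))]])
    B = sla.block_diag(Cxx, Cyy)
    w, V = sla.eigh(A, B)
    return w[-1], V[:p, -1], V[p:, -1]


def random_instance(rng, n=20, p=4, q=3):
    X = rng.standard_normal((n, p))
    Y = 0.5 * X[:, : min(p, q)] @ rng.standard_normal((min(p, q), q))
    Y += rng.standard_normal((n, q))
    return X, Y


class TestFitRcca:
    def test_identical_single_column_gives_unit_correlation(self, rng):
        x = rng.standard_normal((30, 1))
        m = fit_rcca(x, x.copy(), 0.0, 0.0)
        assert m.train_corr == pytest.approx(1.0, abs=1e-10)

    def test_matches_cca_eigen_oracle_at_c0(self, rng):
        X, Y = random_instance(rng, n=50, p=3, q=3)
        m = fit_rcca(X, Y, 0.0, 0.0)
        r_oracle, _, _ = cca_eigen_oracle(X, Y)
        assert m.train_corr == pytest.approx(r_oracle, abs=1e-8)

    def test_matches_sklearn_cca_at_c0(self, rng):
        """Independent library cross-check of the unregularised limit."""
        from sklearn.cross_decomposition import CCA

        X, Y = random_instance(rng, n=80, p=4, q=3)
        m = fit_rcca(X, Y, 0.0, 0.0)
        xs, ys = CCA(n_components=1, max_iter=2000).fit(X, Y).transform(X, Y)
        r_sklearn = abs(np.corrcoef(xs[:, 0], ys[:, 0])[0, 1])
        assert m.train_corr == pytest.approx(r_sklearn, abs=1e-6)

    def test_matches_cross_covariance_svd_at_c1(self, rng):
        X, Y = random_instance(rng)
        n = X.shape[0]
        Cxy = (X - X.mean(0)).T @ (Y - Y.mean(0)) / (n - 1)
        U, _, Vt = np.linalg.svd(Cxy)
        m = fit_rcca(X, Y, 1.0, 1.0)
        u = m.u / np.linalg.norm(m.u)
        v = m.v / np.linalg.norm(m.v)
        assert abs(u @ U[:, 0]) == pytest.approx(1.0, abs=1e-8)
        assert abs(v @ Vt[0]) == pytest.approx(1.0, abs=1e-8)

    def test_regularised_variance_constraint_holds(self, rng):
        X, Y = random_instance(rng, n=40, p=6, q=4)
        n = X.shape[0]
        for c in (0.0, 0.3, 0.9, 1.0):
            m = fit_rcca(X, Y, c, c)
            Xc = X - X.mean(0)
            Cxx = Xc.T @ Xc / (n - 1)
            Mx = (1 - c) * Cxx + c * np.eye(X.shape[1])
            assert m.u @ Mx @ m.u == pytest.approx(1.0, abs=1e-8)

    def test_feature_order_invariance_up_to_sign(self, rng):
        X, Y = random_instance(rng)
        perm = rng.permutation(X.shape[1])
        m1 = fit_rcca(X, Y, 0.5, 0.5)
        m2 = fit_rcca(X[:, perm], Y, 0.5, 0.5)
        assert np.allclose(np.abs(m2.u), np.abs(m1.u[perm]), atol=1e-8)
        assert m2.train_corr == pytest.approx(m1.train_corr, abs=1e-10)

    def test_sign_convention_largest_behaviour_loading_positive(self, rng):
        X, Y = random_instance(rng, n=60)
        m = fit_rcca(X, Y, 0.2, 0.2)
        scores = project(m, X, Y)
        loads = compute_loadings(X, Y, scores)
        j = loads.behaviour.abs().idxmax()
        assert loads.behaviour[j] > 0

    def test_rejects_degenerate_input(self, rng):
        X = rng.standard_normal((10, 3))
        with pytest.raises(DegenerateDataError):
            fit_rcca(X, np.zeros((10, 2)), 0.0, 0.0)
        with pytest.raises(DegenerateDataError):
            fit_rcca(X[:2], X[:2, :2], 0.0, 0.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_oracle_equivalence_property(self, seed):
        """c=0 agrees with the dense eigensolver oracle and c=1 with the
        cross-covariance SVD on random small instances."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(12, 40))
        p = int(rng.integers(2, 5))
        q = int(rng.integers(2, 5))
        X, Y = random_instance(rng, n=n, p=p, q=q)
        m0 = fit_rcca(X, Y, 0.0, 0.0)
        r_oracle, _, _ = cca_eigen_oracle(X, Y)
        assert m0.train_corr == pytest.approx(r_oracle, abs=1e-7)
        m1 = fit_rcca(X, Y, 1.0, 1.0)
        Cxy = (X - X.mean(0)).T @ (Y - Y.mean(0)) / (n - 1)
        U, _, Vt = np.linalg.svd(Cxy)
        u = m1.u / np.linalg.norm(m1.u)
        assert abs(u @ U[:, 0]) == pytest.approx(1.0, abs=1e-7)


class TestProject:
    def test_training_projection_reproduces_stored_correlation(self, rng):
        X, Y = random_instance(rng, n=50)
        m = fit_rcca(X, Y, 0.4, 0.1)
        assert project(m, X, Y).corr() == pytest.approx(m.train_corr, abs=1e-12)

    def test_zero_weight_scores_are_flagged(self, rng):
        X, Y = random_instance(rng)
        m = fit_rcca(X, Y, 0.0, 0.0)
        m.u = np.zeros_like(m.u)
        with pytest.raises(DegenerateDataError):
            project(m, X, Y).corr()

    def test_dimension_mismatch_raises(self, rng):
        X, Y = random_instance(rng)
        m = fit_rcca(X, Y, 0.0, 0.0)
        with pytest.raises(ValueError):
            project(m, X[:, :2], Y)

    def test_holdout_correlation_near_planted(self):
        """Out-of-sample projection recovers the planted correlation
        (attenuated by feature noise) within Monte-Carlo tolerance."""
        from tests.conftest import planted_cohort
        from latentdim.framework import apply_preprocess, fit_preprocess

        vals = []
        for seed in range(5):
            c = planted_cohort(seed=seed, n=800, rho=0.6)
            st_x = fit_preprocess(c.X, c.metadata)
            st_y = fit_preprocess(c.Y, c.metadata)
            X = apply_preprocess(st_x, c.X, c.metadata)
            Y = apply_preprocess(st_y, c.Y, c.metadata)
            tr, te = np.arange(0, 600), np.arange(600, 800)
            m = fit_rcca(X[tr], Y[tr], 0.9, 0.9)
            vals.append(project(m, X[te], Y[te]).corr())
        assert abs(np.mean(vals) - 0.6) < 0.1


class TestLoadings:
    def test_variable_identical_to_score_loads_one(self, rng):
        X, Y = random_instance(rng, n=50)
        m = fit_rcca(X, Y, 0.0, 0.0)
        s = project(m, X, Y)
        X2 = np.column_stack([X, s.brain])
        loads = compute_loadings(X2, Y, s)
        assert loads.brain.iloc[-1] == pytest.approx(1.0, abs=1e-10)

    def test_independent_noise_variable_loads_near_zero(self, rng):
        n = 10_000
        X = rng.standard_normal((n, 3))
        Y = X @ rng.standard_normal((3, 2)) + rng.standard_normal((n, 2))
        m = fit_rcca(X, Y, 0.0, 0.0)
        s = project(m, X, Y)
        X2 = np.column_stack([X, rng.standard_normal(n)])
        loads = compute_loadings(X2, Y, s)
        assert abs(loads.brain.iloc[-1]) < 0.05

    def test_zero_variance_variable_marked_undefined(self, rng):
        X, Y = random_instance(rng)
        m = fit_rcca(X, Y, 0.0, 0.0)
        s = project(m, X, Y)
        X2 = np.column_stack([X, np.full(X.shape[0], 3.0)])
        loads = compute_loadings(X2, Y, s)
        assert np.isnan(loads.brain.iloc[-1])
        assert not np.isnan(loads.brain.iloc[:-1]).any()


class TestDeflation:
    def test_deflated_data_orthogonal_to_weights(self, rng):
        X, Y = random_instance(rng, n=40, p=6, q=4)
        m = fit_rcca(X, Y, 0.2, 0.2)
        Xd, Yd = deflate(X, Y, m)
        assert np.abs(Xd @ m.u).max() < 1e-10
        assert np.abs(Yd @ m.v).max() < 1e-10

    def test_frobenius_norm_reduced_by_at_most_rank_one_component(self, rng):
        X, Y = random_instance(rng, n=30)
        m = fit_rcca(X, Y, 0.5, 0.5)
        Xc = X - X.mean(0)
        Xd, _ = deflate(X, Y, m)
        # projection removes a rank-one orthogonal component (Pythagoras)
        assert (
            np.linalg.norm(Xc) ** 2 - np.linalg.norm(Xd) ** 2
            >= -1e-10
        )
        assert np.linalg.norm(Xd) <= np.linalg.norm(Xc) + 1e-12

    def test_second_planted_dimension_recovered_after_deflation(self):
        from tests.conftest import planted_cohort
        from latentdim.framework import apply_preprocess, fit_preprocess

        cos = []
        for seed in range(5):
            c = planted_cohort(
                seed=seed, n=800, rho=0.6, n_dims=2,
                brain_blocks=(("CT", 40),), n_behaviour=10,
            )
            # second dimension is planted at the same rho; patterns are
            # orthogonal by construction
            st_x = fit_preprocess(c.X, c.metadata)
            st_y = fit_preprocess(c.Y, c.metadata)
            X = apply_preprocess(st_x, c.X, c.metadata)
            Y = apply_preprocess(st_y, c.Y, c.metadata)
            m1 = fit_rcca(X, Y, 0.9, 0.9)
            Xd, Yd = deflate(X, Y, m1)
            m2 = fit_rcca(Xd, Yd, 0.9, 0.9)
            s2 = project(m2, Xd, Yd)
            loads = compute_loadings(X, Y, s2)
            lm = loads.brain.to_numpy()
            pats = c.truth.brain_patterns
            sims = [
                abs(lm @ pats[:, d]) / np.linalg.norm(lm) for d in range(2)
            ]
            cos.append(max(sims))
        assert np.mean([c > 0.85 for c in cos]) >= 0.8

    def test_zero_norm_score_raises(self, rng):
        X, Y = random_instance(rng)
        m = fit_rcca(X, Y, 0.0, 0.0)
        m.u = np.zeros_like(m.u)
        with pytest.raises(DegenerateDataError):
            make_deflator(X, Y, m)


def test_training_beats_holdout_on_null_data_on_average(rng):
    """Overfitting direction: with no real association, training
    correlation exceeds holdout correlation in expectation."""
    diffs = []
    for _ in range(30):
        X = rng.standard_normal((60, 8))
        Y = rng.standard_normal((60, 5))
        m = fit_rcca(X[:40], Y[:40], 0.3, 0.3)
        diffs.append(m.train_corr - project(m, X[40:], Y[40:]).corr())
    assert np.mean(diffs) > 0
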