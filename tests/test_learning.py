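"""PCA whitening, score-matching ICA, and submodel assembly."""

import warnings

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from mixsc.learning import (
    assemble_submodel,
    ica_fit_score_matching,
    pca_whiten_fit,
    train_mixture,
)
from mixsc.config import LearningConfig, RunConfig


class TestPCAWhiten:
    def test_identity_covariance_data(self):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((20000, 6))
        data -= data.mean(axis=0)
        d, E = pca_whiten_fit(data, 6)
        assert np.all(np.diff(d) <= 0) and np.all(d > 0)
        assert np.allclose(d, 1.0, atol=0.05)

    def test_line_data_concentrates_variance(self):
        rng = np.random.default_rng(1)
        t = rng.standard_normal(500)
        data = np.outer(t, [3.0, 4.0]) + 1e-3 * rng.standard_normal((500, 2))
        d, _ = pca_whiten_fit(data - data.mean(0), 2)
        assert d[0] / d.sum() > 0.999999

    def test_matches_dense_eigendecomposition_oracle(self):
        rng = np.random.default_rng(2)
        data = rng.standard_normal((300, 5)) @ rng.standard_normal((5, 5))
        data -= data.mean(axis=0)
        d, E = pca_whiten_fit(data, 3)
        cov = data.T @ data / len(data)  # explicit covariance, dense solver
        evals, evecs = np.linalg.eigh(cov)
        assert np.allclose(d, evals[::-1][:3], rtol=1e-10)
        for i in range(3):
            assert abs(E[i] @ evecs[:, -1 - i]) == pytest.approx(1.0, abs=1e-8)

    def test_whitening_contract_on_training_data(self):
        rng = np.random.default_rng(3)
        data = rng.standard_normal((400, 8)) @ rng.standard_normal((8, 8))
        data -= data.mean(axis=0)
        d, E = pca_whiten_fit(data, 5)
        z = data @ E.T / np.sqrt(d)
        cov = z.T @ z / len(z)
        off = cov - np.diag(np.diag(cov))
        assert np.abs(off).max() < 1e-6
        assert np.allclose(np.diag(cov), 1.0, atol=1e-8)

    def test_rank_deficiency_rejected(self):
        data = np.zeros((50, 4))
        data[:, 0] = np.arange(50.0)
        data -= data.mean(0)
        with pytest.raises(ValueError):
            pca_whiten_fit(data, 3)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            pca_whiten_fit(np.ones((5, 10)), 5)


class TestScoreMatchingICA:
    def test_complete_case_recovers_rotation(self):
        """n=M with rotated Laplace sources: unmixing rows align with truth."""
        rng = np.random.default_rng(4)
        S = rng.laplace(size=(8000, 4))
        Q, _ = np.linalg.qr(rng.standard_normal((4, 4)))
        X = S @ Q.T
        X -= X.mean(0)
        d, E = pca_whiten_fit(X, 4)
        z = X @ E.T / np.sqrt(d)
        R, _ = ica_fit_score_matching(z, 4, seed=5)
        # true unmixing rows in whitened coordinates
        B = (E @ Q) / np.sqrt(d)[:, None]
        filt = np.linalg.inv(B)
        filt /= np.linalg.norm(filt, axis=1)[:, None]
        C = np.abs(filt @ R.T)
        ri, ci = linear_sum_assignment(-C)
        assert C[ri, ci].mean() > 0.95

    def test_overcomplete_2d_learns_dual_frame(self):
        """Three directions at 0/60/120 degrees in 2D: the energy model
        converges to the dual (co-sparse) frame — each filter orthogonal to
        one data direction, which for this symmetric geometry is the same
        line set rotated by 30 degrees.  The recovered lines match that
        dual within 10 degrees."""
        rng = np.random.default_rng(6)
        angles = np.deg2rad([0.0, 60.0, 120.0])
        A = np.stack([np.cos(angles), np.sin(angles)])
        S = rng.laplace(size=(20000, 3))
        X = S @ A.T
        X -= X.mean(0)
        d, E = pca_whiten_fit(X, 2)
        z = X @ E.T / np.sqrt(d)
        R, _ = ica_fit_score_matching(z, 3, seed=7, max_iter=2000)
        normals = np.stack([-np.sin(angles), np.cos(angles)]).T  # dual lines
        # map learned whitened filters back to input coordinates
        back = R @ (E / np.sqrt(d)[:, None])
        back /= np.linalg.norm(back, axis=1)[:, None]
        C = np.abs(normals @ back.T)
        ri, ci = linear_sum_assignment(-C)
        degs = np.rad2deg(np.arccos(np.clip(C[ri, ci], 0, 1)))
        assert np.all(degs < 10.0)

    def test_returned_rows_are_unit_norm(self):
        rng = np.random.default_rng(8)
        z = rng.laplace(size=(500, 3))
        R, _ = ica_fit_score_matching(z, 5, seed=9)
        assert np.allclose(np.linalg.norm(R, axis=1), 1.0, atol=1e-8)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(10)
        z = rng.laplace(size=(500, 3))
        R1, _ = ica_fit_score_matching(z, 5, seed=11)
        R2, _ = ica_fit_score_matching(z, 5, seed=11)
        assert np.array_equal(R1, R2)

    def test_undercomplete_rejected(self):
        with pytest.raises(ValueError):
            ica_fit_score_matching(np.ones((50, 4)), 3)

    def test_nonconvergence_flagged(self):
        rng = np.random.default_rng(12)
        z = rng.laplace(size=(2000, 6))
        with pytest.warns(RuntimeWarning):
            R, converged = ica_fit_score_matching(z, 9, seed=13, max_iter=2)
        assert not converged
        assert R.shape == (9, 6)


class TestAssembleSubmodel:
    def test_identity_assembly(self):
        rng = np.random.default_rng(14)
        Q, _ = np.linalg.qr(rng.standard_normal((6, 6)))
        E = Q[:, :3].T
        mean = E.T @ np.ones(3)  # keeps all b components non-negative-ish
        sub = assemble_submodel(np.ones(3), E, np.eye(3), mean)
        flip = np.sign(E @ mean)
        assert np.allclose(sub.W, flip[:, None] * E)

    def test_2x2_worked_example(self):
        """d=(4,1), E=I, R=I with a positive mean: W=diag(1/2,1), A=diag(2,1)."""
        sub = assemble_submodel(np.array([4.0, 1.0]), np.eye(2), np.eye(2), np.ones(2))
        assert np.allclose(sub.W, np.diag([0.5, 1.0]))
        assert np.allclose(sub.A, np.diag([2.0, 1.0]))
        assert np.allclose(sub.A, np.linalg.pinv(sub.W))  # pseudo-inverse oracle
        assert np.allclose(sub.b, [0.5, 1.0])

    def test_moore_penrose_identities_and_sign(self):
        rng = np.random.default_rng(15)
        n, M, D = 4, 7, 10
        Q, _ = np.linalg.qr(rng.standard_normal((D, n)))
        E = Q.T
        d = np.sort(rng.uniform(0.5, 3.0, n))[::-1]
        R = rng.standard_normal((M, n))
        R /= np.linalg.norm(R, axis=1)[:, None]
        mean = rng.standard_normal(D)
        sub = assemble_submodel(d, E, R, mean)
        assert np.allclose(sub.W @ sub.A @ sub.W, sub.W, atol=1e-8)
        assert np.allclose(sub.A @ sub.W @ sub.A, sub.A, atol=1e-8)
        assert np.all(sub.b >= 0)
        assert np.allclose(sub.E @ sub.E.T, np.eye(n), atol=1e-8)

    def test_sign_adjustment_is_canonical(self):
        """Negating any subset of R rows pre-assembly leaves (W, A, b) fixed."""
        rng = np.random.default_rng(16)
        n, M, D = 3, 5, 8
        Q, _ = np.linalg.qr(rng.standard_normal((D, n)))
        E = Q.T
        d = np.array([2.0, 1.5, 1.0])
        R = rng.standard_normal((M, n))
        R /= np.linalg.norm(R, axis=1)[:, None]
        mean = rng.standard_normal(D)
        sub1 = assemble_submodel(d, E, R, mean)
        R2 = R.copy()
        R2[[0, 2]] *= -1.0
        sub2 = assemble_submodel(d, E, R2, mean)
        assert np.allclose(sub1.W, sub2.W)
        assert np.allclose(sub1.A, sub2.A)
        assert np.allclose(sub1.b, sub2.b)

    def test_complete_case_AW_is_subspace_identity(self):
        rng = np.random.default_rng(17)
        n = 4
        Q, _ = np.linalg.qr(rng.standard_normal((9, n)))
        E = Q.T
        d = np.sort(rng.uniform(1, 2, n))[::-1]
        R, _ = np.linalg.qr(rng.standard_normal((n, n)))
        sub = assemble_submodel(d, E, R, E.T @ np.ones(n))
        P = sub.A @ sub.W  # should project onto the PCA subspace
        for _ in range(5):
            v = E.T @ rng.standard_normal(n)
            assert np.allclose(P @ v, v, atol=1e-6)

    def test_singular_d_rejected(self):
        with pytest.raises(ValueError):
            assemble_submodel(np.array([1.0, 0.0]), np.eye(2), np.eye(2), np.ones(2))


class TestTrainMixture:
    @pytest.fixture(scope="class")
    def tiny_setup(self, corpora):
        faces, objects = corpora
        config = RunConfig(learning=LearningConfig(n_reduced=8, n_units=12))
        return faces.images[:80], objects.images[:80], config

    def test_invariants_and_determinism(self, tiny_setup):
        f, o, config = tiny_setup
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            m1 = train_mixture(f, o, config, seed=1)
            m2 = train_mixture(f, o, config, seed=1)
        for s1, s2 in zip(m1.submodels, m2.submodels):
            assert np.array_equal(s1.W, s2.W)
            assert np.array_equal(s1.A, s2.A)
            assert np.array_equal(s1.b, s2.b)
        for sub in m1.submodels:
            assert np.all(sub.d > 0) and np.all(np.diff(sub.d) <= 0)
            assert np.allclose(sub.E @ sub.E.T, np.eye(sub.n_reduced), atol=1e-8)
            expected_W = (sub.R / np.sqrt(sub.d)) @ sub.E
            assert np.allclose(sub.W, expected_W, atol=1e-12)
            assert np.allclose(sub.W @ sub.A @ sub.W, sub.W, atol=1e-8)
            assert np.all(sub.b >= 0)

    def test_empty_class_rejected(self, tiny_setup):
        f, o, config = tiny_setup
        with pytest.raises(ValueError):
            train_mixture(f[:0], o, config, seed=0)

    def test_face_posterior_separation_on_held_out(self, desk_model, corpora, default_bank):
        """Held-out synthetic faces get higher face posteriors than objects."""
        from mixsc.inference import respond

        faces, objects = corpora
        fte, ote = faces.split()[1][:60], objects.split()[1][:60]
        rf = respond(fte, desk_model, bank=default_bank)
        ro = respond(ote, desk_model, bank=default_bank)
        assert rf.posterior[:, 0].mean() > ro.posterior[:, 0].mean()
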