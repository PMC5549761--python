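"""MAP inference, posterior competition, rectification and the sampler."""

from types import SimpleNamespace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mixsc.inference import (
    class_posterior,
    infer_energies,
    map_infer,
    modulate_and_rectify,
    posterior_expectation,
    respond,
    sample_generative,
    softplus,
)
from mixsc.synth import make_synthetic_mixture


def _toy_submodel(A, b):
    """Minimal duck-typed submodel carrying exactly what map_infer reads."""
    return SimpleNamespace(A=A, b=b, W=np.linalg.pinv(A))


class TestMapInfer:
    def test_exact_reconstruction_at_mean(self):
        """x = A b is jointly optimal: y = b, L = 0."""
        rng = np.random.default_rng(0)
        A = rng.standard_normal((6, 3))
        b = np.abs(rng.standard_normal(3))
        sub = _toy_submodel(A, b)
        y, L, _, conv = map_infer(A @ b, sub, 1.0, 1.0)
        assert conv
        assert np.allclose(y, b, atol=1e-8)
        assert L == pytest.approx(0.0, abs=1e-12)

    def test_strong_sparsity_pins_to_mean(self):
        """As lam -> 0+ the penalty dominates and y -> b."""
        rng = np.random.default_rng(1)
        A = rng.standard_normal((5, 3))
        b = np.abs(rng.standard_normal(3))
        x = rng.standard_normal(5)
        sub = _toy_submodel(A, b)
        y, _, _, _ = map_infer(x, sub, 1.0, 1e-7)
        assert np.allclose(y, b, atol=1e-4)

    def test_matches_grid_search_oracle(self):
        """Dense grid search over the objective agrees within resolution."""
        rng = np.random.default_rng(2)
        D, M = 3, 2
        A = rng.standard_normal((D, M))
        b = np.abs(rng.standard_normal(M))
        x = rng.standard_normal(D) * 1.5
        sigma, lam = 1.0, 1.0
        sub = _toy_submodel(A, b)
        y_hat, L_hat, _, _ = map_infer(x, sub, sigma, lam)

        step = 0.02
        grids = [np.arange(b[i] - 4.0, b[i] + 4.0 + step, step) for i in range(M)]
        Y = np.stack([g.ravel() for g in np.meshgrid(*grids, indexing="ij")], axis=1)
        resid = x[None, :] - Y @ A.T
        obj = -0.5 / sigma**2 * (resid**2).sum(1) - np.abs(Y - b).sum(1) / lam
        best = np.argmax(obj)
        assert np.all(np.abs(y_hat - Y[best]) <= step)
        assert L_hat >= obj[best] - 1e-9

    def test_warm_start_invariance(self):
        rng = np.random.default_rng(3)
        A = rng.standard_normal((8, 4))
        b = np.abs(rng.standard_normal(4))
        x = rng.standard_normal(8)
        sub = _toy_submodel(A, b)
        y0, L0, _, _ = map_infer(x, sub, 0.8, 1.2, tol=1e-14, max_iter=50_000)
        y1, L1, _, _ = map_infer(
            x, sub, 0.8, 1.2, tol=1e-14, max_iter=50_000, z0=np.ones((1, 4)) * 2.0
        )
        assert np.allclose(y0, y1, atol=1e-6)
        assert L0 == pytest.approx(L1, abs=1e-9)

    def test_nonfinite_input_rejected(self):
        sub = _toy_submodel(np.eye(2), np.zeros(2))
        with pytest.raises(ValueError):
            map_infer(np.array([np.nan, 0.0]), sub, 1.0, 1.0)

    def test_out_of_subspace_energy_enters_goodness(self):
        """The residual outside span(A) lowers L: this is what lets the
        posterior discriminate classes."""
        A = np.array([[1.0], [0.0]])
        sub = _toy_submodel(A, np.zeros(1))
        _, L_in, _, _ = map_infer(np.array([0.5, 0.0]), sub, 1.0, 1.0)
        _, L_out, _, _ = map_infer(np.array([0.5, 2.0]), sub, 1.0, 1.0)
        assert L_out == pytest.approx(L_in - 2.0, abs=1e-8)


class TestClassPosterior:
    def test_symmetric(self):
        r = class_posterior(np.array([3.3, 3.3]), np.array([0.5, 0.5]))
        assert np.allclose(r, [0.5, 0.5])

    def test_log_odds_nine_to_one(self):
        r = class_posterior(np.array([np.log(9.0), 0.0]), np.array([0.5, 0.5]))
        assert np.allclose(r, [0.9, 0.1], atol=1e-12)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2**31 - 1), st.floats(-500, 500))
    def test_shift_invariance(self, seed, c):
        rng = np.random.default_rng(seed)
        L = rng.uniform(-50, 50, size=3)
        pi = np.array([0.2, 0.3, 0.5])
        assert np.allclose(class_posterior(L, pi), class_posterior(L + c, pi), atol=1e-12)

    def test_extreme_goodness_is_stable(self):
        r = class_posterior(np.array([-1e8, -1e8 + 1.0]), np.array([0.5, 0.5]))
        assert np.isfinite(r).all() and r.sum() == pytest.approx(1.0)

    def test_all_minus_inf_rejected(self):
        with pytest.raises(ValueError):
            class_posterior(np.array([-np.inf, -np.inf]), np.array([0.5, 0.5]))


class TestRectification:
    def test_zero_response_gives_log_two(self):
        resp, _ = modulate_and_rectify([np.zeros((1, 4))], np.array([[1.0]]))
        assert np.allclose(resp[0], np.log(2.0))

    def test_fully_explained_away_sits_at_baseline(self):
        y = [np.full((1, 3), 7.0), np.full((1, 3), -2.0)]
        resp, _ = modulate_and_rectify(y, np.array([[0.0, 1.0]]))
        assert np.allclose(resp[0], np.log(2.0))

    def test_softplus_against_high_precision_oracle(self):
        import sympy

        for a in (-30.0, -5.0, 0.0, 5.0, 30.0, 700.0):
            exact = float(sympy.log(1 + sympy.exp(sympy.Float(a, 60))))
            assert softplus(np.array(a)) == pytest.approx(exact, rel=1e-12)
        assert np.isfinite(softplus(np.array(1e6)))

    def test_strictly_positive_and_monotone(self):
        a = np.linspace(-40, 40, 101)
        s = softplus(a)
        assert np.all(s > 0) and np.all(np.diff(s) > 0)


class TestPosteriorExpectation:
    def test_degenerate_posterior_selects_map(self):
        y = [np.ones((1, 3)), 2.0 * np.ones((1, 2))]
        out = posterior_expectation(y, np.array([[1.0, 0.0]]))
        assert np.allclose(out[0], y[0])
        assert np.allclose(out[1], 0.0)

    def test_reduction_equals_modulation(self):
        rng = np.random.default_rng(4)
        y = [rng.standard_normal((6, 3)), rng.standard_normal((6, 3))]
        r = rng.dirichlet(np.ones(2), size=6)
        _, raw = modulate_and_rectify(y, r)
        exp = posterior_expectation(y, r)
        for a, b in zip(raw, exp):
            assert np.allclose(a, b, atol=1e-12)

    def test_three_class_weighted_sum(self):
        y = [np.array([[2.0]]), np.array([[4.0]]), np.array([[8.0]])]
        r = np.array([[0.5, 0.25, 0.25]])
        out = posterior_expectation(y, r)
        assert out[0][0, 0] == pytest.approx(1.0)  # 0.5 * 2
        assert out[1][0, 0] == pytest.approx(1.0)  # 0.25 * 4
        assert out[2][0, 0] == pytest.approx(2.0)  # 0.25 * 8


class TestGenerativeSampler:
    def test_zero_noise_lies_in_basis_span(self):
        model = make_synthetic_mixture(D=12, n=4, M=6, seed=5, sigma=0.0)
        batch = sample_generative(model, 50, seed=6)
        for i in range(50):
            k = batch.k[i]
            recon = model.submodels[k].A @ batch.y[k][i]
            assert np.allclose(batch.x[i], recon, atol=1e-12)

    def test_laplace_moments(self):
        model = make_synthetic_mixture(D=12, n=4, M=6, seed=7, sigma=0.1, lam=1.3)
        n = 100_000
        batch = sample_generative(model, n, seed=8)
        k0 = batch.k == 0
        y = batch.y[0][k0]
        b = model.submodels[0].b
        lam = model.lam
        se_mean = np.sqrt(2) * lam / np.sqrt(k0.sum())  # Laplace sd = sqrt(2) lam
        assert np.all(np.abs(y.mean(0) - b) < 3 * se_mean)
        mad = np.abs(y - b).mean(0)
        se_mad = lam / np.sqrt(k0.sum())
        assert np.all(np.abs(mad - lam) < 3 * se_mad)
        # non-generating class is centered on zero
        y_off = batch.y[1][k0]
        assert np.all(np.abs(y_off.mean(0)) < 3 * se_mean)

    def test_class_frequencies(self):
        model = make_synthetic_mixture(D=12, n=4, M=6, seed=9)
        n = 50_000
        batch = sample_generative(model, n, seed=10)
        p = (batch.k == 0).mean()
        se = 0.5 / np.sqrt(n)
        assert abs(p - 0.5) < 3 * se

    def test_seed_reproducibility(self):
        model = make_synthetic_mixture(D=12, n=4, M=6, seed=11)
        b1 = sample_generative(model, 20, seed=12)
        b2 = sample_generative(model, 20, seed=12)
        assert np.array_equal(b1.x, b2.x) and np.array_equal(b1.k, b2.k)


class TestRespond:
    def test_composition_contract(self):
        """respond's posterior equals class_posterior over map_infer goodness."""
        model = make_synthetic_mixture(D=16, n=5, M=8, seed=13, sigma=0.5)
        batch = sample_generative(model, 10, seed=14)
        res = infer_energies(batch.x, model)
        good = np.stack(
            [
                map_infer(batch.x, sub, model.sigma, model.lam)[1]
                for sub in model.submodels
            ],
            axis=1,
        )
        assert np.allclose(res.goodness, good, atol=1e-9)
        assert np.allclose(res.posterior, class_posterior(good, model.priors))
        assert np.allclose(res.posterior.sum(axis=1), 1.0, atol=1e-12)

    def test_skip_mixture_agrees_at_saturated_posterior(self):
        model = make_synthetic_mixture(D=20, n=6, M=9, seed=15, sigma=0.05)
        batch = sample_generative(model, 30, seed=16)
        full = infer_energies(batch.x, model)
        ablate = infer_energies(batch.x, model, skip_mixture=True)
        sat = np.nonzero(full.posterior[:, 0] == 1.0)[0]
        assert sat.size > 0
        assert np.allclose(
            full.responses[0][sat], ablate.responses[0][sat], atol=1e-12
        )

    def test_posterior_sharpens_as_noise_shrinks(self):
        """Mean posterior on the true class rises monotonically as sigma drops."""
        mean_r = []
        for sigma in (1.0, 0.3, 0.1):
            model = make_synthetic_mixture(
                D=20, n=10, M=15, seed=17, sigma=sigma, orthogonal=False
            )
            batch = sample_generative(model, 200, seed=18)
            res = infer_energies(batch.x, model)
            mean_r.append(res.posterior[np.arange(len(batch)), batch.k].mean())
        assert mean_r[0] <= mean_r[1] <= mean_r[2]

    def test_blank_image_defines_baseline(self, desk_model, default_bank):
        res = respond(np.zeros((64, 64)), desk_model, bank=default_bank)
        assert np.all(res.responses[0] > 0)
        assert res.posterior.sum() == pytest.approx(1.0)
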