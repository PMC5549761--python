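"""Bayesian inference in the mixture of sparse coding models.

Given an energy vector x (mean-direction-removed), evoked responses are
computed in three steps:

1. each submodel k interprets x on its own by MAP estimation of its feature
   vector, maximizing the sparse coding objective

       L_k(y | x) = -1/(2 sigma^2) ||x - A^k y||^2
                    - 1/lambda * sum_m |y_m - b^k_m| ;

2. the goodnesses L_k are compared as posterior class probabilities
   r_k ∝ pi_k exp(L_k), computed stably by max subtraction;

3. each submodel's MAP responses are multiplicatively modulated by its
   posterior, y_hat^k <- r_k y_hat^k (the explaining-away step: the losing
   submodel's units are pushed toward zero).

Responses are finally passed through the smooth half-wave rectifier
softplus(a) = log(1 + exp(a)).  Because each A^k has rank at most n << D,
the reconstruction term in L_k includes the input's energy outside the
submodel's subspace; this out-of-subspace residual is what lets the
posterior discriminate the classes.

The MAP problem is an L1-penalized least squares (convex).  It is solved by
accelerated proximal gradient (FISTA) on z = y - b after projecting into the
basis' column space via a thin SVD, which makes per-iteration cost O(n M)
instead of O(D M) and is exact: the orthogonal residual is a constant added
back into L_k.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gabor import build_energy_bank, energy_transform
from .learning import MixtureModel, Submodel
from .preprocess import mask_and_standardize, remove_mean_direction

__all__ = [
    "InferenceResult",
    "GenerativeBatch",
    "softplus",
    "map_infer",
    "infer_energies",
    "class_posterior",
    "modulate_and_rectify",
    "posterior_expectation",
    "respond",
    "sample_generative",
]


def softplus(a: np.ndarray) -> np.ndarray:
    """Numerically stable log(1 + exp(a)) (exact for |a| far beyond 30)."""
    return np.logaddexp(0.0, a)


@dataclass
class InferenceResult:
    y_map: list[np.ndarray]  # per class: (N, M_k) MAP features y_hat^k(k)
    goodness: np.ndarray  # (N, K) objective values L_k
    posterior: np.ndarray  # (N, K) class posteriors r, rows sum to 1
    responses: list[np.ndarray]  # per class: softplus(r_k * y_hat^k)
    responses_raw: list[np.ndarray]  # per class: r_k * y_hat^k (pre-rectifier)
    solver_iterations: np.ndarray  # (K,) FISTA iterations used per class
    converged: np.ndarray  # (K,) bool

    def squeeze(self) -> "InferenceResult":
        """Collapse the batch axis for single-input calls."""
        return InferenceResult(
            y_map=[y[0] for y in self.y_map],
            goodness=self.goodness[0],
            posterior=self.posterior[0],
            responses=[r[0] for r in self.responses],
            responses_raw=[r[0] for r in self.responses_raw],
            solver_iterations=self.solver_iterations,
            converged=self.converged,
        )


def _soft_threshold(z: np.ndarray, t: float) -> np.ndarray:
    return np.sign(z) * np.maximum(np.abs(z) - t, 0.0)


def map_infer(
    x: np.ndarray,
    sub: Submodel,
    sigma: float,
    lam: float,
    max_iter: int = 5000,
    tol: float = 1e-10,
    z0: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, int, bool]:
    """MAP features and goodness for one submodel.

    Accepts a single vector (D,) or a batch (N, D).  Returns
    ``(y_hat, L, iterations, converged)`` with y_hat of shape (M,) / (N, M)
    and L scalar / (N,).  Deterministic: the problem is convex and the
    solver is fixed; ``z0`` is an optional warm start in y - b coordinates
    (the solution does not depend on it beyond solver tolerance).
    """
    if sigma <= 0 or lam <= 0:
        raise ValueError("sigma and lam must be positive")
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite input")
    single = x.ndim == 1
    X = x[None] if single else x

    A, b = sub.A, sub.b
    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    keep = s > 1e-12 * s[0]
    U, s, Vt = U[:, keep], s[keep], Vt[keep]
    B = s[:, None] * Vt  # (r, M): A = U B
    Xt = X @ U  # (N, r)
    perp = np.einsum("ij,ij->i", X, X) - np.einsum("ij,ij->i", Xt, Xt)
    c = Xt - B @ b  # target for z = y - b

    inv_s2 = 1.0 / sigma**2
    step = 1.0 / (inv_s2 * s[0] ** 2)  # 1 / Lipschitz constant
    thresh = step / lam

    if z0 is None:
        Z = X @ sub.W.T - b  # warm start at the analysis response y0 = W x
    else:
        Z = np.atleast_2d(np.asarray(z0, dtype=float)).copy()
    Y = Z.copy()
    t_k = 1.0

    def objective(Zc: np.ndarray) -> np.ndarray:
        resid = c - Zc @ B.T
        return 0.5 * inv_s2 * np.einsum("ij,ij->i", resid, resid) + np.abs(
            Zc
        ).sum(axis=1) / lam

    prev_obj = objective(Z)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        grad = -inv_s2 * (c - Y @ B.T) @ B
        Z_new = _soft_threshold(Y - step * grad, thresh)
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_k**2))
        Y = Z_new + ((t_k - 1.0) / t_new) * (Z_new - Z)
        Z, t_k = Z_new, t_new
        if it % 10 == 0 or it == max_iter:
            obj = objective(Z)
            denom = np.maximum(np.abs(prev_obj), 1e-30)
            if np.max(np.abs(obj - prev_obj) / denom) < tol:
                converged = True
                break
            prev_obj = obj

    y_hat = Z + b
    resid = c - Z @ B.T
    L = -0.5 * inv_s2 * (np.einsum("ij,ij->i", resid, resid) + perp) - np.abs(
        Z
    ).sum(axis=1) / lam
    if single:
        return y_hat[0], float(L[0]), it, converged
    return y_hat, L, it, converged


def class_posterior(goodness: np.ndarray, priors: np.ndarray) -> np.ndarray:
    """r_k ∝ pi_k exp(L_k), normalized; stable via max subtraction.

    Accepts (K,) or (N, K) goodness; rows of the result sum to 1.
    """
    goodness = np.asarray(goodness, dtype=float)
    priors = np.asarray(priors, dtype=float)
    if np.any(np.isnan(goodness)) or np.any(goodness == np.inf):
        raise ValueError("goodness values must be finite or -inf")
    single = goodness.ndim == 1
    G = goodness[None] if single else goodness
    if np.any(np.all(G == -np.inf, axis=1)):
        raise ValueError("all goodness values are -inf; posterior undefined")
    logits = G + np.log(priors)
    logits = logits - logits.max(axis=1, keepdims=True)
    r = np.exp(logits)
    r /= r.sum(axis=1, keepdims=True)
    return r[0] if single else r


def modulate_and_rectify(
    y_map: list[np.ndarray], r: np.ndarray
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Step 3 plus rectification: (softplus(r_k y^k), r_k y^k) per class."""
    r = np.atleast_2d(np.asarray(r, dtype=float))
    raw = [np.atleast_2d(y) * r[:, [k]] for k, y in enumerate(y_map)]
    return [softplus(m) for m in raw], raw


def posterior_expectation(y_map: list[np.ndarray], r: np.ndarray) -> list[np.ndarray]:
    """Approximate posterior expectation of each feature variable.

    Since the MAP of y^k conditioned on a non-matching class h != k is
    exactly zero, the expectation sum over classes reduces to r_k *
    y_hat^k(k) — identical to the multiplicative modulation step.
    """
    r = np.atleast_2d(np.asarray(r, dtype=float))
    return [np.atleast_2d(y) * r[:, [k]] for k, y in enumerate(y_map)]


def respond(
    x: np.ndarray,
    model: MixtureModel,
    skip_mixture: bool = False,
    is_image: bool | None = None,
    bank=None,
) -> InferenceResult:
    """Full response pipeline for images or energy vectors.

    ``x`` may be a 64x64 image, a stack (N, 64, 64), an energy vector (D,)
    or a stack (N, D); images are disk-masked, standardized (a blank image
    passes through as the all-zero baseline stimulus) and energy-transformed.
    With ``skip_mixture`` the returned responses are softplus(y_hat^k)
    straight after step 1 — the no-mixture ablation; goodness and posterior
    are still reported.
    """
    x = np.asarray(x, dtype=float)
    size = model.config.frontend.image_size
    if is_image is None:
        is_image = x.ndim == 3 or (x.ndim == 2 and x.shape == (size, size))
    single = x.ndim == (2 if is_image else 1)
    X = x[None] if single else x

    if is_image:
        X = np.stack([mask_and_standardize(im, model.config.preprocess) for im in X])
        if bank is None:
            bank = build_energy_bank(model.config.frontend)
        X = energy_transform(X, bank)
    X = remove_mean_direction(X, model.preprocess)
    result = infer_energies(X, model, skip_mixture=skip_mixture)
    return result.squeeze() if single else result


def infer_energies(
    X: np.ndarray, model: MixtureModel, skip_mixture: bool = False
) -> InferenceResult:
    """Inference steps 1-3 plus rectification on preprocessed vectors (N, D).

    Used directly for generative-model samples, which are already in the
    model's data space and must not be re-preprocessed.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    inf_cfg = model.config.inference
    y_map, goodness, iters, conv = [], [], [], []
    for sub in model.submodels:
        y, L, it, ok = map_infer(
            X, sub, model.sigma, model.lam, max_iter=inf_cfg.max_iter, tol=inf_cfg.tol
        )
        y_map.append(y)
        goodness.append(L)
        iters.append(it)
        conv.append(ok)
    goodness = np.stack(goodness, axis=1)
    r = class_posterior(goodness, model.priors)

    if skip_mixture:
        responses = [softplus(y) for y in y_map]
        raw = [np.array(y) for y in y_map]
    else:
        responses, raw = modulate_and_rectify(y_map, r)

    return InferenceResult(
        y_map=y_map,
        goodness=goodness,
        posterior=np.atleast_2d(r),
        responses=responses,
        responses_raw=raw,
        solver_iterations=np.array(iters),
        converged=np.array(conv),
    )


@dataclass
class GenerativeBatch:
    """Samples from the generative mixture: x, generating class, all y^h."""

    x: np.ndarray  # (N, D)
    k: np.ndarray  # (N,) generating class indices
    y: list[np.ndarray]  # per class h: (N, M_h), the sampled y^h

    def __len__(self) -> int:
        return self.x.shape[0]


def sample_generative(
    model: MixtureModel, n: int, seed: int | np.random.Generator = 0
) -> GenerativeBatch:
    """Draw n samples from the generative model.

    k ~ priors; y^k ~ Laplace(b^k, lam); y^h ~ Laplace(0, lam) for h != k;
    x ~ Normal(A^k y^k, sigma^2 I).  sigma = 0 is allowed and gives
    x = A^k y^k exactly.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    K = model.n_classes
    D = model.submodels[0].A.shape[0]
    k = rng.choice(K, size=n, p=np.asarray(model.priors, dtype=float))
    y = []
    for h, sub in enumerate(model.submodels):
        M = sub.n_units
        loc = np.where((k == h)[:, None], sub.b[None, :], 0.0)
        y.append(rng.laplace(loc=loc, scale=model.lam, size=(n, M)))
    x = np.empty((n, D))
    for h, sub in enumerate(model.submodels):
        idx = k == h
        x[idx] = y[h][idx] @ sub.A.T
    if model.sigma > 0:
        x += rng.normal(scale=model.sigma, size=x.shape)
    return GenerativeBatch(x=x, k=k, y=y)
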