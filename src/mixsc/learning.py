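"""Per-class sparse-code learning: PCA whitening, overcomplete ICA, assembly.

Each class k (face, object) gets its own sparse coding submodel learned in
two steps from mean-direction-removed energy vectors:

1. strong dimension reduction by PCA with whitening (2400 -> n dimensions,
   default n = 100) — the strong reduction acts as spatial pooling and
   yields large basis features;
2. overcomplete ICA estimating M components from the n whitened dimensions
   (default M = 400), fitted by score matching of an energy-based model
   with a smooth L1 log-density.

The filter matrix is assembled as

    W^k = R^k diag(d^k)^(-1/2) E^k

where d^k / E^k are the top PCA eigenvalues / row eigenvectors and R^k the
unit-row ICA weight matrix.  The basis is A^k = pinv(W^k) and the mean
response b^k = W^k xbar^k (class mean of the training energies).  ICA row
signs are arbitrary, so each row whose mean response would be negative is
negated, making every element of b^k non-negative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .config import LearningConfig, RunConfig
from .gabor import build_energy_bank, energy_transform
from .preprocess import (
    PreprocessState,
    fit_preprocess_state,
    mask_and_standardize,
    remove_mean_direction,
)

__all__ = [
    "Submodel",
    "MixtureModel",
    "pca_whiten_fit",
    "ica_fit_score_matching",
    "assemble_submodel",
    "train_mixture",
]


@dataclass
class Submodel:
    """Learned parameters of one class-specific sparse coding model."""

    d: np.ndarray  # (n,) PCA eigenvalues, descending, positive
    E: np.ndarray  # (n, D) orthonormal row eigenvectors
    R: np.ndarray  # (M, n) unit-norm ICA rows (after sign adjustment)
    W: np.ndarray  # (M, D) filter matrix R diag(d)^(-1/2) E
    A: np.ndarray  # (D, M) basis, pseudo-inverse of W
    b: np.ndarray  # (M,) mean response W @ class_mean, elementwise >= 0
    class_mean: np.ndarray  # (D,)
    ica_converged: bool = True

    @property
    def n_reduced(self) -> int:
        return self.d.shape[0]

    @property
    def n_units(self) -> int:
        return self.W.shape[0]


@dataclass
class MixtureModel:
    """K class-specific submodels plus shared globals."""

    submodels: list[Submodel]
    priors: np.ndarray  # (K,) simplex
    sigma: float
    lam: float
    preprocess: PreprocessState
    config: RunConfig
    seed: int | None = None
    class_names: tuple[str, ...] = ("face", "object")

    @property
    def n_classes(self) -> int:
        return len(self.submodels)

    def validate(self) -> None:
        pi = np.asarray(self.priors, dtype=float)
        if pi.shape != (self.n_classes,) or np.any(pi <= 0) or abs(pi.sum() - 1) > 1e-9:
            raise ValueError("priors must be a positive simplex over the submodels")
        # sigma == 0 is allowed for degenerate generative-only models
        if self.sigma < 0 or self.lam <= 0:
            raise ValueError("sigma must be >= 0 and lam > 0")
        dims = {sm.E.shape[1] for sm in self.submodels}
        if len(dims) != 1:
            raise ValueError("all submodels must share the data dimension D")


def pca_whiten_fit(data: np.ndarray, n_reduced: int) -> tuple[np.ndarray, np.ndarray]:
    """Top PCA eigenpairs of already-centered data.

    Parameters
    ----------
    data : (N, D) array, centered (the caller subtracts the class mean).
    n_reduced : number of leading components to retain.

    Returns ``(d, E)``: eigenvalues of the population covariance in
    descending order and the matching orthonormal row eigenvectors, such
    that ``diag(d)**-0.5 @ E @ data.T`` has identity covariance on the
    training set.
    """
    data = np.asarray(data, dtype=float)
    n_samples = data.shape[0]
    if n_samples <= n_reduced:
        raise ValueError(f"need more than {n_reduced} samples, got {n_samples}")
    # SVD route: eigenvalues of data^T data / N are s^2 / N
    _, s, vt = np.linalg.svd(data, full_matrices=False)
    d = s[:n_reduced] ** 2 / n_samples
    if d[-1] <= 1e-12 * max(d[0], 1.0):
        raise ValueError(f"data rank < n_reduced={n_reduced}")
    E = vt[:n_reduced]
    # deterministic sign convention: largest-|.| entry of each row positive
    signs = np.sign(E[np.arange(n_reduced), np.argmax(np.abs(E), axis=1)])
    return d, E * signs[:, None]


def _score_matching_objective(
    w_flat: np.ndarray, z: np.ndarray, shape: tuple[int, int], eps: float
) -> tuple[float, np.ndarray]:
    """Score-matching value and gradient for free-norm filters.

    Model density: log p(z) = -sum_i sqrt((w_i^T z)^2 + eps) + const.  The
    filter norms are free parameters: they set each component's sharpness,
    which the whitened data cannot (its marginals all have unit variance),
    and letting them adapt substantially reduces the direction bias on
    overcomplete data.  The objective is E[1/2 ||psi(z)||^2 + div psi(z)]
    with psi = grad_z log p the model score.
    """
    m, n = shape
    w = w_flat.reshape(m, n)

    u = z @ w.T  # (N, M)
    root = np.sqrt(u**2 + eps)
    g = -u / root
    gp = -eps / root**3
    gpp = 3.0 * eps * u / root**5

    q = g @ w  # (N, n) model score per sample
    n_samples = z.shape[0]
    norms2 = np.einsum("ij,ij->i", w, w)
    value = float(
        0.5 * np.einsum("ij,ij->", q, q) / n_samples + (gp.sum(axis=0) @ norms2) / n_samples
    )

    grad = (g.T @ q + (gp * (q @ w.T)).T @ z) / n_samples
    # divergence term: d/dw_i E[g'(u_i) ||w_i||^2]
    grad += ((gpp * norms2[None, :]).T @ z) / n_samples
    grad += 2.0 * (gp.sum(axis=0) / n_samples)[:, None] * w
    return value, grad.ravel()


def ica_fit_score_matching(
    z: np.ndarray,
    n_components: int,
    seed: int | np.random.Generator = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
    eps: float = 1.0,
) -> tuple[np.ndarray, bool]:
    """Overcomplete ICA of whitened data by score matching.

    Parameters
    ----------
    z : (N, n) whitened data.
    n_components : M >= n, number of components to estimate.

    Returns ``(R, converged)`` where R is (M, n) with unit-norm rows.  On
    hitting the iteration cap a warning is issued and the best iterate is
    returned with ``converged=False``.
    """
    z = np.asarray(z, dtype=float)
    n = z.shape[1]
    if n_components < n:
        raise ValueError("overcomplete ICA requires n_components >= data dimension")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    w0 = rng.standard_normal((n_components, n))
    w0 /= np.linalg.norm(w0, axis=1)[:, None]

    res = minimize(
        _score_matching_objective,
        w0.ravel(),
        args=(z, (n_components, n), eps),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "gtol": tol, "ftol": 1e-14},
    )
    w = res.x.reshape(n_components, n)
    norms = np.maximum(np.linalg.norm(w, axis=1), 1e-12)
    r = w / norms[:, None]
    converged = bool(res.success) or res.status == 0
    if not converged:
        warnings.warn(
            f"score-matching ICA did not converge: {res.message}", RuntimeWarning
        )
    return r, converged


def assemble_submodel(
    d: np.ndarray,
    E: np.ndarray,
    R: np.ndarray,
    class_mean: np.ndarray,
    ica_converged: bool = True,
) -> Submodel:
    """Form (W, A, b) from the learned pieces, with sign canonicalization."""
    d = np.asarray(d, dtype=float)
    E = np.asarray(E, dtype=float)
    R = np.array(R, dtype=float)  # copied: rows may be negated
    class_mean = np.asarray(class_mean, dtype=float)
    if np.any(d <= 0):
        raise ValueError("eigenvalues must be strictly positive")
    if R.shape[1] != d.shape[0] or E.shape[0] != d.shape[0]:
        raise ValueError("inconsistent shapes for d, E, R")

    W = (R / np.sqrt(d)) @ E
    flip = (W @ class_mean) < 0  # rows with b_i == 0 keep their sign
    W[flip] *= -1.0
    R[flip] *= -1.0
    A = np.linalg.pinv(W, rcond=1e-10)
    b = W @ class_mean
    return Submodel(
        d=d, E=E, R=R, W=W, A=A, b=b, class_mean=class_mean, ica_converged=ica_converged
    )


def fit_submodel(
    energies: np.ndarray,
    n_reduced: int,
    n_units: int,
    seed: int | np.random.Generator,
    learning: LearningConfig,
) -> Submodel:
    """PCA + ICA + assembly for one class of (mean-direction-removed) energies."""
    class_mean = energies.mean(axis=0)
    centered = energies - class_mean
    d, E = pca_whiten_fit(centered, n_reduced)
    z = centered @ E.T / np.sqrt(d)
    R, converged = ica_fit_score_matching(
        z,
        n_units,
        seed=seed,
        max_iter=learning.ica_max_iter,
        tol=learning.ica_tol,
        eps=learning.ica_eps,
    )
    return assemble_submodel(d, E, R, class_mean, ica_converged=converged)


def train_mixture(
    face_images: np.ndarray,
    object_images: np.ndarray,
    config: RunConfig | None = None,
    seed: int = 0,
    prepared: bool = False,
) -> MixtureModel:
    """Full training pipeline on stacks of 64x64 images.

    Images are disk-masked and standardized (unless ``prepared``), passed
    through the energy frontend, projected off the global mean direction,
    and each class is fitted with its own sparse coding submodel.
    Reproducible given ``seed``.
    """
    config = config or RunConfig()
    face_images = np.asarray(face_images, dtype=float)
    object_images = np.asarray(object_images, dtype=float)
    if face_images.shape[0] == 0 or object_images.shape[0] == 0:
        raise ValueError("both classes must be non-empty")

    if not prepared:
        face_images = np.stack(
            [mask_and_standardize(im, config.preprocess) for im in face_images]
        )
        object_images = np.stack(
            [mask_and_standardize(im, config.preprocess) for im in object_images]
        )

    bank = build_energy_bank(config.frontend)
    face_e = energy_transform(face_images, bank)
    obj_e = energy_transform(object_images, bank)

    state = fit_preprocess_state(face_e, obj_e, config.preprocess)
    face_e = remove_mean_direction(face_e, state)
    obj_e = remove_mean_direction(obj_e, state)

    lc = config.learning
    child = np.random.SeedSequence(seed).spawn(2)
    submodels = [
        fit_submodel(face_e, lc.n_reduced, lc.n_units, np.random.default_rng(child[0]), lc),
        fit_submodel(obj_e, lc.n_reduced, lc.n_units, np.random.default_rng(child[1]), lc),
    ]
    model = MixtureModel(
        submodels=submodels,
        priors=np.asarray(lc.priors, dtype=float),
        sigma=lc.sigma,
        lam=lc.lam,
        preprocess=state,
        config=config,
        seed=seed,
    )
    model.validate()
    return model
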