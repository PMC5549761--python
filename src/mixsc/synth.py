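"""Synthetic training corpora and synthetic mixture models.

The package is trained on labeled face and object image sets.  The
published experiments used aligned photographic datasets; for desk-scale
training and testing this module generates stand-ins with the properties
that matter to the model: faces that are aligned on average with small
jitter, and centered object composites built from generic geometric
primitives.  Crucially, the object family includes a half-moon "boat hull"
drawn with the same curve primitive as the cartoon mouth, so that isolated
object parts can masquerade as facial parts — the situation the
explaining-away inference is supposed to resolve.

Jitter defaults (translation <= 3 px, scale within 10%, contrast within
20%) keep the face corpus "more or less aligned" in position, size and
upright posture.  Corpora are reproducible from their seed and reserve a
documented held-out fraction for selectivity testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.transform import rescale as _sk_rescale

from .cartoon import (
    SIZE,
    CartoonSpec,
    _bezier_points,
    _fill_ellipse,
    _stroke_ellipse,
    _stroke_polyline,
    random_spec,
    render,
)
from .inference import GenerativeBatch, sample_generative
from .learning import MixtureModel, Submodel, assemble_submodel
from .config import RunConfig, LearningConfig
from .preprocess import PreprocessState

__all__ = [
    "SyntheticCorpus",
    "make_face_corpus",
    "make_object_corpus",
    "make_generative_corpus",
    "make_synthetic_mixture",
    "boat_hull",
]

DEFAULT_TEST_FRACTION = 0.2
MAX_SHIFT = 3  # px
SCALE_JITTER = 0.10
CONTRAST_JITTER = 0.20


@dataclass
class SyntheticCorpus:
    images: np.ndarray  # (N, 64, 64) raw drawings (pre-preprocessing)
    label: str  # "face" | "object"
    manifest: pd.DataFrame  # per-image generation parameters
    seed: int
    test_fraction: float = DEFAULT_TEST_FRACTION

    def __len__(self) -> int:
        return self.images.shape[0]

    def split(self) -> tuple[np.ndarray, np.ndarray]:
        """(train, test) images; the last ``test_fraction`` are held out."""
        n_test = int(round(len(self) * self.test_fraction))
        n_test = min(max(n_test, 1), len(self) - 1) if len(self) > 1 else 0
        cut = len(self) - n_test
        return self.images[:cut], self.images[cut:]


def _jitter(img: np.ndarray, rng: np.random.Generator) -> tuple[np.ndarray, dict]:
    scale = 1.0 + rng.uniform(-SCALE_JITTER, SCALE_JITTER)
    contrast = 1.0 + rng.uniform(-CONTRAST_JITTER, CONTRAST_JITTER)
    dx = int(rng.integers(-MAX_SHIFT, MAX_SHIFT + 1))
    dy = int(rng.integers(-MAX_SHIFT, MAX_SHIFT + 1))

    z = _sk_rescale(img, scale, order=1, anti_aliasing=False)
    out = np.zeros((SIZE, SIZE))
    # center the rescaled canvas, then translate by (dx, dy)
    offy = (SIZE - z.shape[0]) // 2 + dy
    offx = (SIZE - z.shape[1]) // 2 + dx
    ys0, xs0 = max(0, offy), max(0, offx)
    ys1, xs1 = min(SIZE, offy + z.shape[0]), min(SIZE, offx + z.shape[1])
    zy0, zx0 = ys0 - offy, xs0 - offx
    out[ys0:ys1, xs0:xs1] = z[zy0 : zy0 + (ys1 - ys0), zx0 : zx0 + (xs1 - xs0)]
    return out * contrast, {"scale": scale, "contrast": contrast, "dx": dx, "dy": dy}


def make_face_corpus(
    n: int, seed: int = 0, test_fraction: float = DEFAULT_TEST_FRACTION
) -> SyntheticCorpus:
    """n cartoon faces with random feature parameters plus small jitter."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    images, rows = [], []
    for i in range(n):
        spec = random_spec(rng)
        img, jit = _jitter(render(spec).pixels, rng)
        images.append(img)
        rows.append({"index": i, "params": list(spec.params), **jit})
    return SyntheticCorpus(
        images=np.stack(images),
        label="face",
        manifest=pd.DataFrame(rows),
        seed=seed,
        test_fraction=test_fraction,
    )


def boat_hull(
    cx: float, cy: float, half_width: float, bow: float, gap: float
) -> np.ndarray:
    """Half-moon hull: the same two-Bezier primitive as the cartoon mouth."""
    p0, p1 = (cx - half_width, cy), (cx + half_width, cy)
    top = _stroke_polyline(_bezier_points(p0, p1, bow), 1.2)
    bot = _stroke_polyline(_bezier_points(p0, p1, bow + gap), 1.2)
    return np.maximum(top, bot)


_PRIMITIVES = ("ellipse", "blob", "box", "bar", "triangle", "hull")


def _draw_primitive(kind: str, rng: np.random.Generator) -> np.ndarray:
    cx = 31.5 + rng.uniform(-12, 12)
    cy = 31.5 + rng.uniform(-12, 12)
    if kind == "ellipse":
        return _stroke_ellipse(cx, cy, rng.uniform(4, 16), rng.uniform(4, 16))
    if kind == "blob":
        return _fill_ellipse(cx, cy, rng.uniform(2, 7), rng.uniform(2, 7))
    if kind == "box":
        w, h = rng.uniform(5, 16), rng.uniform(5, 16)
        pts = [(cx - w, cy - h), (cx + w, cy - h), (cx + w, cy + h), (cx - w, cy + h), (cx - w, cy - h)]
        return _stroke_polyline(pts, 1.2)
    if kind == "bar":
        a = rng.uniform(0, np.pi)
        L = rng.uniform(8, 22)
        d = (L * np.cos(a), L * np.sin(a))
        return _stroke_polyline([(cx - d[0], cy - d[1]), (cx + d[0], cy + d[1])], rng.uniform(1, 3))
    if kind == "triangle":
        pts = [(cx + rng.uniform(-14, 14), cy + rng.uniform(-14, 14)) for _ in range(3)]
        return _stroke_polyline(pts + [pts[0]], 1.2)
    if kind == "hull":
        return boat_hull(cx, cy, rng.uniform(4, 10), rng.uniform(0.5, 2.5), rng.uniform(0.5, 3.0))
    raise ValueError(kind)


def make_object_corpus(
    n: int, seed: int = 0, test_fraction: float = DEFAULT_TEST_FRACTION
) -> SyntheticCorpus:
    """n centered composites of 2-6 random geometric primitives."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    images, rows = [], []
    for i in range(n):
        k = int(rng.integers(2, 7))
        kinds = [str(rng.choice(_PRIMITIVES)) for _ in range(k)]
        img = np.zeros((SIZE, SIZE))
        for kind in kinds:
            img = img + _draw_primitive(kind, rng)
        images.append(img)
        rows.append({"index": i, "n_primitives": k, "kinds": kinds})
    return SyntheticCorpus(
        images=np.stack(images),
        label="object",
        manifest=pd.DataFrame(rows),
        seed=seed,
        test_fraction=test_fraction,
    )


def make_generative_corpus(
    model: MixtureModel, n: int, seed: int = 0
) -> GenerativeBatch:
    """Labeled (x, k, y) samples from the model's generative process."""
    return sample_generative(model, n, seed)


def _low_coherence_rows(M: int, n: int, rng: np.random.Generator, iters: int = 200) -> np.ndarray:
    """M unit rows in R^n with low mutual coherence (frame-potential descent).

    Overcomplete component directions are only identifiable when they are
    well separated; ground-truth filters for recovery tests are therefore
    drawn as an approximately equiangular frame rather than i.i.d. rows.
    """
    R = rng.standard_normal((M, n))
    R /= np.linalg.norm(R, axis=1)[:, None]
    step = 0.1
    for _ in range(iters):
        G = R @ R.T
        np.fill_diagonal(G, 0.0)
        grad = 4.0 * (G**3) @ R  # d/dR of sum_{i!=j} (r_i . r_j)^4
        R -= step * grad
        R /= np.linalg.norm(R, axis=1)[:, None]
    return R


def make_synthetic_mixture(
    D: int = 20,
    n: int = 10,
    M: int = 15,
    K: int = 2,
    seed: int = 0,
    sigma: float = 0.3,
    lam: float = 1.0,
    orthogonal: bool = True,
) -> MixtureModel:
    """A small mixture model with known ground-truth parameters.

    Each submodel gets orthonormal eigenvector rows E (on disjoint,
    mutually orthogonal subspaces when ``orthogonal`` and D >= K*n),
    descending eigenvalues, random unit ICA rows, and a class mean inside
    its subspace so the assembled b is non-negative.  Used for generative
    sampling, posterior-consistency and parameter-recovery tests.
    """
    if orthogonal and D < K * n:
        raise ValueError("need D >= K*n for orthogonal submodel subspaces")
    rng = np.random.default_rng(seed)
    Q, _ = np.linalg.qr(rng.standard_normal((D, D)))
    submodels = []
    for k in range(K):
        if orthogonal:
            E = Q[:, k * n : (k + 1) * n].T
        else:
            Ek, _ = np.linalg.qr(rng.standard_normal((D, n)))
            E = Ek.T
        d = np.sort(rng.uniform(1.0, 4.0, size=n))[::-1]
        R = _low_coherence_rows(M, n, rng)
        class_mean = E.T @ (np.sqrt(d) * rng.standard_normal(n))
        submodels.append(assemble_submodel(d, E, R, class_mean))

    config = RunConfig(learning=LearningConfig(n_reduced=n, n_units=M, sigma=sigma, lam=lam))
    model = MixtureModel(
        submodels=submodels,
        priors=np.full(K, 1.0 / K),
        sigma=sigma,
        lam=lam,
        preprocess=PreprocessState(global_mean=np.ones(D)),
        config=config,
        seed=seed,
        class_names=tuple(f"class{k}" for k in range(K)),
    )
    model.validate()
    return model
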