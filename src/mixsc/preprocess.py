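"""Image standardization and mean-direction removal.

Raw images of any size are converted to the canonical 64x64 inputs by:
grayscale -> center crop to square -> bilinear resize -> disk mask
(raised-cosine fade from radius 30 to 32) -> per-image standardization to
zero mean and unit (population) variance.  Rendered cartoon stimuli go
through the same mask + standardization so stimuli and training images share
preprocessing; an exactly blank stimulus is passed through as all zeros
instead of raising (it is the baseline stimulus, and dividing by its zero
variance would be meaningless).

Energy vectors are additionally projected off the direction of the global
mean over all (face and object) training data,

    x  <-  x - x_bar (x_bar^T x) / ||x_bar||^2,

a linear form of contrast normalization that prevents the learned mean
response vectors from blowing up along the dominant energy direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize as _sk_resize

__all__ = [
    "PreprocessConfig",
    "PreprocessState",
    "prepare_image",
    "mask_and_standardize",
    "disk_fade",
    "fit_preprocess_state",
    "remove_mean_direction",
]


@dataclass(frozen=True)
class PreprocessConfig:
    image_size: int = 64
    disk_radius: float = 30.0
    fade_width: float = 2.0  # raised-cosine rolloff, radius 30 -> 32


@dataclass
class PreprocessState:
    """Fitted preprocessing state: the global energy mean over both classes."""

    global_mean: np.ndarray
    config: PreprocessConfig = field(default_factory=PreprocessConfig)


def disk_fade(config: PreprocessConfig | None = None) -> np.ndarray:
    """The radial fade mask: 1 inside disk_radius, raised-cosine to 0."""
    config = config or PreprocessConfig()
    s = config.image_size
    c = (s - 1) / 2.0
    y, x = np.mgrid[0:s, 0:s].astype(float)
    r = np.hypot(x - c, y - c)
    t = np.clip((r - config.disk_radius) / config.fade_width, 0.0, 1.0)
    return 0.5 * (1.0 + np.cos(np.pi * t))


def _to_gray(raw: np.ndarray) -> np.ndarray:
    raw = np.asarray(raw, dtype=float)
    if raw.ndim == 3:  # RGB(A): ITU-R 601 luma on the first three channels
        raw = raw[..., :3] @ np.array([0.299, 0.587, 0.114])
    if raw.ndim != 2:
        raise ValueError(f"expected a 2D or 3D image array, got ndim={raw.ndim}")
    return raw


def _center_crop_square(img: np.ndarray) -> np.ndarray:
    h, w = img.shape
    m = min(h, w)
    top, left = (h - m) // 2, (w - m) // 2  # extra pixel dropped at right/bottom
    return img[top : top + m, left : left + m]


def prepare_image(raw: np.ndarray, config: PreprocessConfig | None = None) -> np.ndarray:
    """Standardized 64x64 image from a raw raster of any size."""
    config = config or PreprocessConfig()
    img = _center_crop_square(_to_gray(raw))
    if img.size == 0:
        raise ValueError("empty image")
    if img.shape != (config.image_size, config.image_size):
        img = _sk_resize(
            img,
            (config.image_size, config.image_size),
            order=1,
            anti_aliasing=False,
            preserve_range=True,
        )
    if img.std() == 0.0:  # constant input; the fade ring would fake structure
        raise ValueError("degenerate image: zero variance")
    return mask_and_standardize(img, config, allow_blank=False)


def mask_and_standardize(
    img: np.ndarray, config: PreprocessConfig | None = None, allow_blank: bool = True
) -> np.ndarray:
    """Disk mask then per-image standardization (population variance).

    With ``allow_blank`` an all-zero input (the baseline stimulus) is returned
    unchanged; otherwise zero variance after masking raises ValueError.
    """
    config = config or PreprocessConfig()
    img = np.asarray(img, dtype=float)
    if img.shape != (config.image_size, config.image_size):
        raise ValueError(f"expected {config.image_size}x{config.image_size} image")
    masked = img * disk_fade(config)
    std = masked.std()  # population (divide by N)
    if std == 0.0:
        if allow_blank and np.all(masked == 0.0):
            return masked
        raise ValueError("degenerate image: zero variance after disk masking")
    return (masked - masked.mean()) / std


def fit_preprocess_state(
    face_energies: np.ndarray,
    object_energies: np.ndarray,
    config: PreprocessConfig | None = None,
) -> PreprocessState:
    """Global mean over the pooled face + object energy vectors."""
    face_energies = np.atleast_2d(np.asarray(face_energies, dtype=float))
    object_energies = np.atleast_2d(np.asarray(object_energies, dtype=float))
    if face_energies.shape[0] == 0 or object_energies.shape[0] == 0:
        raise ValueError("need at least one energy vector per class")
    pooled = np.vstack([face_energies, object_energies])
    return PreprocessState(global_mean=pooled.mean(axis=0), config=config or PreprocessConfig())


def remove_mean_direction(x: np.ndarray, state: PreprocessState) -> np.ndarray:
    """Project energy vector(s) off the global-mean direction.

    Accepts a single vector (D,) or a stack (N, D).  The output is exactly
    orthogonal to the global mean; applying the operation twice equals
    applying it once.
    """
    xbar = state.global_mean
    n2 = float(xbar @ xbar)
    if n2 == 0.0:
        raise ValueError("global mean is zero; preprocess state is unusable")
    x = np.asarray(x, dtype=float)
    coef = x @ xbar / n2
    return x - np.multiply.outer(coef, xbar) if x.ndim == 2 else x - coef * xbar
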