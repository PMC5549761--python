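"""Fixed Gabor energy-detector bank (complex-cell frontend).

The frontend maps a 64x64 grayscale image to a vector of oriented-contrast
energies.  Each detector is a quadrature pair of Gabor filters (phases 0 and
90 degrees) sharing a center position, orientation and spatial frequency; its
output is the sum of the squared inner products of the image with the two
filters, which makes the response invariant to the spatial phase of a matched
grating.  The default bank tiles a 10x10 grid of centers with 8 orientations
(22.5 degree spacing) and 3 frequencies (0.25, 0.17, 0.13 cycles/pixel),
giving a 2400-dimensional energy representation.

Conventions frozen here (serialized models depend on them):

* detector ordering is position-major: index = (row*grid + col) * n_orient
  * n_freq + orient_idx * n_freq + freq_idx, with grid centers scanned in
  raster order (top-left to bottom-right);
* grid centers sit at the centers of a uniform partition of the frame,
  pixel coordinate (i + 0.5) * image_size/grid - 0.5 (0-based);
* the Gaussian envelope is isotropic with standard deviation 0.4/f and is
  truncated at the image border without renormalization;
* the cosine-phase filter is mean-subtracted (DC correction) so a constant
  image yields exactly zero energy;
* after DC correction each filter is rescaled to Euclidean norm f**1.15
  (an approximate match to the 1/f amplitude spectrum of natural images).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GaborFilter",
    "EnergyBank",
    "FrontendConfig",
    "build_energy_bank",
    "energy_transform",
]

DEFAULT_FREQUENCIES = (0.25, 0.17, 0.13)


@dataclass(frozen=True)
class FrontendConfig:
    """Configuration of the energy frontend (reconstructable from YAML)."""

    grid: int = 10
    n_orientations: int = 8
    frequencies: tuple[float, ...] = DEFAULT_FREQUENCIES
    image_size: int = 64

    def validate(self) -> None:
        if self.grid < 1 or self.image_size < 1:
            raise ValueError("grid and image_size must be >= 1")
        if self.n_orientations < 1:
            raise ValueError("need at least one orientation")
        if len(self.frequencies) == 0 or any(f <= 0 for f in self.frequencies):
            raise ValueError("frequencies must be a non-empty list of positive values")


@dataclass(frozen=True)
class GaborFilter:
    center: tuple[float, float]  # (x, y), 0-based pixel coordinates
    orientation: float  # radians
    frequency: float  # cycles/pixel
    phase: float  # radians
    envelope_width: float  # pixels (isotropic Gaussian sigma)
    weights: np.ndarray  # image_size x image_size


@dataclass(frozen=True)
class EnergyBank:
    config: FrontendConfig
    centers: np.ndarray  # (dim, 2) float, (x, y) per detector
    orientations: np.ndarray  # (dim,) radians
    frequencies: np.ndarray  # (dim,) cycles/pixel
    weights0: np.ndarray  # (dim, image_size**2) cosine-phase filters, flattened
    weights90: np.ndarray  # (dim, image_size**2) sine-phase filters

    @property
    def dim(self) -> int:
        return self.weights0.shape[0]

    def filters(self, i: int) -> tuple[GaborFilter, GaborFilter]:
        """The quadrature pair of detector ``i`` as GaborFilter objects."""
        s = self.config.image_size
        f = float(self.frequencies[i])
        mk = lambda w, ph: GaborFilter(  # noqa: E731
            center=(float(self.centers[i, 0]), float(self.centers[i, 1])),
            orientation=float(self.orientations[i]),
            frequency=f,
            phase=ph,
            envelope_width=0.4 / f,
            weights=w.reshape(s, s),
        )
        return mk(self.weights0[i], 0.0), mk(self.weights90[i], np.pi / 2)


def _gabor_weights(
    size: int, cx: float, cy: float, theta: float, f: float, phase: float
) -> np.ndarray:
    """One Gabor filter on a size x size grid, norm f**1.15, DC-corrected."""
    y, x = np.mgrid[0:size, 0:size].astype(float)
    u = (x - cx) * np.cos(theta) + (y - cy) * np.sin(theta)
    v = -(x - cx) * np.sin(theta) + (y - cy) * np.cos(theta)
    sigma = 0.4 / f
    envelope = np.exp(-(u**2 + v**2) / (2.0 * sigma**2))
    w = envelope * np.cos(2.0 * np.pi * f * u + phase)
    w -= w.mean()  # constant images must yield zero energy
    norm = np.linalg.norm(w)
    if norm == 0.0:
        raise ValueError("degenerate Gabor filter (zero after DC correction)")
    return w * (f**1.15 / norm)


def build_energy_bank(config: FrontendConfig | None = None) -> EnergyBank:
    """Construct the fixed energy-detector bank. Deterministic."""
    config = config or FrontendConfig()
    config.validate()
    size, grid = config.image_size, config.grid
    step = size / grid
    grid_pos = (np.arange(grid) + 0.5) * step - 0.5
    thetas = np.arange(config.n_orientations) * np.pi / config.n_orientations

    centers, oris, freqs, w0, w90 = [], [], [], [], []
    for gy in grid_pos:  # raster order: rows (y), then columns (x)
        for gx in grid_pos:
            for theta in thetas:
                for f in config.frequencies:
                    centers.append((gx, gy))
                    oris.append(theta)
                    freqs.append(f)
                    w0.append(_gabor_weights(size, gx, gy, theta, f, 0.0).ravel())
                    w90.append(
                        _gabor_weights(size, gx, gy, theta, f, np.pi / 2).ravel()
                    )
    return EnergyBank(
        config=config,
        centers=np.asarray(centers, dtype=float),
        orientations=np.asarray(oris, dtype=float),
        frequencies=np.asarray(freqs, dtype=float),
        weights0=np.asarray(w0),
        weights90=np.asarray(w90),
    )


def energy_transform(images: np.ndarray, bank: EnergyBank) -> np.ndarray:
    """Energy vector(s) for one image (H, W) or a stack (N, H, W).

    Returns shape (dim,) for a single image and (N, dim) for a stack; all
    entries are >= 0.
    """
    images = np.asarray(images, dtype=float)
    single = images.ndim == 2
    if single:
        images = images[None]
    s = bank.config.image_size
    if images.shape[1:] != (s, s):
        raise ValueError(
            f"image shape {images.shape[1:]} does not match bank size ({s}, {s})"
        )
    flat = images.reshape(images.shape[0], -1)
    e = (flat @ bank.weights0.T) ** 2 + (flat @ bank.weights90.T) ** 2
    return e[0] if single else e
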