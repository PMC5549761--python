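"""Tuning-curve estimation and the face-neuron analysis battery.

Protocols
---------
* **full variation** — many cartoon faces with all 19 parameters random;
  the curve for a feature is the mean response at each of its 11 levels,
  then smoothed with a unit-variance Gaussian kernel (truncated and
  renormalized at the boundaries).
* **single variation** — 11 stimuli per feature: the standard face with
  only that feature swept; one response per level, unsmoothed.
* **partial face** — like single variation but only the feature's owning
  part is rendered (global features 1-3 are swept on the outline).
* **inverted** — full variation on vertically flipped renders.

Significance of a (smoothed) full-variation curve is assessed against
surrogate curves built from label-shuffled responses: a curve counts as
significantly tuned if its maximum is at least 25% greater than its minimum
and its heterogeneity exceeds 99.9% of the surrogate heterogeneities, where
heterogeneity is the negative entropy sum(p log p) of the curve normalized
to sum 1 (responses are strictly positive post-softplus, so this is well
defined).

Population statistics mirror the face-patch literature: the
face-selectivity index, extremity (anti-)preference indices of peak/trough
locations, gain ratios between tuning protocols, and additive /
multiplicative predictors of 2D tuning maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cartoon import (
    N_FEATURES,
    PART_OF_FEATURE,
    CartoonSpec,
    render,
    render_partial,
    standard_spec,
)

__all__ = [
    "TuningCurve",
    "gaussian_smooth_curve",
    "tuning_curve_means",
    "full_variation_tuning",
    "heterogeneity",
    "significance_test",
    "sweep_specs",
    "single_variation_stimuli",
    "partial_face_stimuli",
    "face_selectivity_index",
    "extremity_indices",
    "gain_ratio",
    "population_gain_ratio",
    "tuning_2d",
    "predict_2d",
    "predictor_correlation",
]

N_LEVELS = 11
LEVELS = np.arange(-5, 6)


@dataclass
class TuningCurve:
    unit_id: int
    feature_id: int  # 1-based
    values: np.ndarray  # (11,) smoothed (or raw for single/partial protocols)
    raw: np.ndarray | None = None
    smoothed: bool = True
    significant: bool | None = None
    surrogate_percentile: float | None = None

    @property
    def peak_level(self) -> int:
        return int(LEVELS[int(np.argmax(self.values))])

    @property
    def trough_level(self) -> int:
        return int(LEVELS[int(np.argmin(self.values))])

    @property
    def heterogeneity(self) -> float:
        return heterogeneity(self.values)


def _smoothing_matrix(n: int = N_LEVELS, sigma: float = 1.0) -> np.ndarray:
    """Row-stochastic Gaussian kernel, truncated and renormalized at edges."""
    idx = np.arange(n)
    K = np.exp(-((idx[:, None] - idx[None, :]) ** 2) / (2.0 * sigma**2))
    return K / K.sum(axis=1, keepdims=True)


_SMOOTH = _smoothing_matrix()


def gaussian_smooth_curve(values: np.ndarray) -> np.ndarray:
    """Unit-variance Gaussian smoothing over the 11 levels (constant-preserving)."""
    values = np.asarray(values, dtype=float)
    return values @ _SMOOTH.T


def tuning_curve_means(responses: np.ndarray, levels: np.ndarray) -> np.ndarray:
    """Per-level mean responses.

    responses: (N,) or (N, U); levels: (N,) integers in [-5, 5].
    Returns (11,) or (11, U).  Raises naming the level if a bin is empty.
    """
    responses = np.asarray(responses, dtype=float)
    levels = np.asarray(levels)
    single = responses.ndim == 1
    R = responses[:, None] if single else responses
    out = np.empty((N_LEVELS, R.shape[1]))
    for i, lev in enumerate(LEVELS):
        mask = levels == lev
        if not mask.any():
            raise ValueError(f"no stimulus at level {lev}")
        out[i] = R[mask].mean(axis=0)
    return out[:, 0] if single else out


def full_variation_tuning(
    responses: np.ndarray, specs: list[CartoonSpec], feature_id: int
) -> tuple[np.ndarray, np.ndarray]:
    """(raw, smoothed) full-variation curves, each (11, U)."""
    levels = np.array([s.params[feature_id - 1] for s in specs])
    raw = tuning_curve_means(responses, levels)
    return raw, gaussian_smooth_curve(raw.T).T


def heterogeneity(values: np.ndarray) -> np.ndarray:
    """Negative entropy of the curve taken as relative probabilities.

    Accepts (11,) or (..., 11); more peaked curves score higher.
    """
    v = np.asarray(values, dtype=float)
    total = v.sum(axis=-1, keepdims=True)
    if np.any(total <= 0):
        raise ValueError("curve sum must be positive to normalize")
    p = v / total
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    return plogp.sum(axis=-1)


def significance_test(
    responses: np.ndarray,
    levels: np.ndarray,
    n_surrogates: int = 5000,
    seed: int | np.random.Generator = 0,
    min_max_ratio: float = 1.25,
    percentile: float = 99.9,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Surrogate significance of full-variation tuning for U units at once.

    responses: (N, U) strictly positive; levels: (N,) stimulus levels of one
    feature.  Surrogate curves destroy the stimulus-response correspondence
    by permuting responses (one shared permutation per surrogate across
    units, which preserves each unit's null distribution), and are smoothed
    identically to the real curves.  Returns ``(significant, percentile_rank,
    smoothed_curves)`` with shapes (U,), (U,), (11, U).
    """
    responses = np.asarray(responses, dtype=float)
    if responses.ndim == 1:
        responses = responses[:, None]
    if np.any(responses <= 0):
        raise ValueError("responses must be strictly positive")
    levels = np.asarray(levels)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = responses.shape[0]

    # level-indicator matrix for grouped means: (N, 11) / counts
    ind = (levels[:, None] == LEVELS[None, :]).astype(float)
    counts = ind.sum(axis=0)
    if np.any(counts == 0):
        missing = int(LEVELS[np.argmin(counts)])
        raise ValueError(f"no stimulus at level {missing}")
    ind /= counts[None, :]

    raw = ind.T @ responses  # (11, U)
    smoothed = _SMOOTH @ raw
    het = heterogeneity(smoothed.T)  # (U,)

    exceed = np.zeros(responses.shape[1])
    for _ in range(n_surrogates):
        perm = rng.permutation(n)
        sur = _SMOOTH @ (ind.T @ responses[perm])
        exceed += het > heterogeneity(sur.T)
    pct = 100.0 * exceed / n_surrogates

    ratio_ok = smoothed.max(axis=0) >= min_max_ratio * smoothed.min(axis=0)
    significant = ratio_ok & (pct > percentile)
    return significant, pct, smoothed


def sweep_specs(feature_id: int, base: CartoonSpec | None = None) -> list[CartoonSpec]:
    """The 11 single-variation specs for one feature (others at standard)."""
    base = base or standard_spec()
    return [base.with_param(feature_id, lev) for lev in LEVELS]


def single_variation_stimuli(feature_id: int, inverted: bool = False) -> np.ndarray:
    """(11, 64, 64) stack: standard face with one feature swept."""
    specs = sweep_specs(feature_id)
    if inverted:
        specs = [CartoonSpec(s.params, s.visible_parts, True) for s in specs]
    return np.stack([render(s).pixels for s in specs])


def partial_face_stimuli(feature_id: int) -> np.ndarray:
    """(11, 64, 64) stack: only the feature's owning part, swept."""
    part = PART_OF_FEATURE[feature_id]
    return np.stack(
        [render_partial(s, part).pixels for s in sweep_specs(feature_id)]
    )


def face_selectivity_index(
    mean_face: float | np.ndarray,
    mean_object: float | np.ndarray,
    baseline: float | np.ndarray,
) -> np.ndarray:
    """((f-b) - (o-b)) / ((f-b) + (o-b)); NaN where the denominator vanishes."""
    f = np.asarray(mean_face, dtype=float) - baseline
    o = np.asarray(mean_object, dtype=float) - baseline
    denom = f + o
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(np.abs(denom) < 1e-12, np.nan, (f - o) / denom)
    return out


def extremity_indices(
    peak_levels: np.ndarray, trough_levels: np.ndarray
) -> tuple[float, float]:
    """Extremity preference / anti-preference indices of significant curves.

    Each index is the mean count per extreme level (-5, +5) divided by the
    mean count per non-extreme level; all peaks at the extremes gives inf.
    """
    def _index(levels: np.ndarray) -> float:
        levels = np.asarray(levels)
        if levels.size == 0:
            raise ValueError("need at least one significant curve")
        extreme = np.isin(levels, (-5, 5)).sum() / 2.0
        non_extreme = (~np.isin(levels, (-5, 5))).sum() / 9.0
        return float(extreme / non_extreme) if non_extreme > 0 else float("inf")

    return _index(peak_levels), _index(trough_levels)


def gain_ratio(curve_ref: np.ndarray, curve_test: np.ndarray) -> float:
    """Reference-over-test gain: 1 / slope of test regressed on reference."""
    x = np.asarray(curve_ref, dtype=float)
    y = np.asarray(curve_test, dtype=float)
    if x.shape != y.shape:
        raise ValueError("curves must have the same length")
    xc = x - x.mean()
    var = xc @ xc
    if var < 1e-24:
        raise ValueError("constant reference curve: gain undefined")
    slope = float(xc @ (y - y.mean()) / var)
    return 1.0 / slope


def population_gain_ratio(
    ref_curves: np.ndarray,
    test_curves: np.ndarray,
    mask: np.ndarray,
    min_slope: float = 1e-8,
) -> float:
    """Mean gain ratio over selected unit-feature pairs.

    ``ref_curves`` / ``test_curves``: (..., 11) stacked curves; ``mask``
    selects the (significant) pairs.  Pairs with a non-positive or
    near-zero slope are flagged and excluded from the mean, since their
    reciprocal gain is unbounded.
    """
    refs = np.asarray(ref_curves, dtype=float)[mask]
    tests = np.asarray(test_curves, dtype=float)[mask]
    ratios = []
    for r, t in zip(refs, tests):
        rc = r - r.mean()
        var = rc @ rc
        if var < 1e-24:
            continue
        slope = rc @ (t - t.mean()) / var
        if slope > min_slope:
            ratios.append(1.0 / slope)
    if not ratios:
        raise ValueError("no usable unit-feature pairs for the gain ratio")
    return float(np.mean(ratios))


def tuning_2d(
    responses: np.ndarray, specs: list[CartoonSpec], feat_i: int, feat_j: int
) -> np.ndarray:
    """11x11 map of mean responses per (level_i, level_j) cell; (11, 11) or
    (11, 11, U) for multi-unit responses.  Raises naming an empty cell."""
    responses = np.asarray(responses, dtype=float)
    li = np.array([s.params[feat_i - 1] for s in specs])
    lj = np.array([s.params[feat_j - 1] for s in specs])
    single = responses.ndim == 1
    R = responses[:, None] if single else responses
    out = np.empty((N_LEVELS, N_LEVELS, R.shape[1]))
    for a, u in enumerate(LEVELS):
        for bidx, v in enumerate(LEVELS):
            m = (li == u) & (lj == v)
            if not m.any():
                raise ValueError(f"no stimulus in cell (level {u}, level {v})")
            out[a, bidx] = R[m].mean(axis=0)
    return out[..., 0] if single else out


def predict_2d(curve_i: np.ndarray, curve_j: np.ndarray, mode: str) -> np.ndarray:
    """Additive or multiplicative 2D prediction from two 1D curves."""
    ci = np.asarray(curve_i, dtype=float)
    cj = np.asarray(curve_j, dtype=float)
    if mode == "additive":
        return ci[:, None] + cj[None, :]
    if mode == "multiplicative":
        return ci[:, None] * cj[None, :]
    raise ValueError(f"unknown mode: {mode!r}")


def predictor_correlation(map_2d: np.ndarray, predicted: np.ndarray) -> float:
    """Pearson correlation over the 121 cells."""
    a = np.asarray(map_2d, dtype=float).ravel()
    b = np.asarray(predicted, dtype=float).ravel()
    return float(np.corrcoef(a, b)[0, 1])
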