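"""High-level experiment protocols on a trained mixture model.

These functions wire stimuli through the response pipeline and the tuning
analyses: full-variation (random cartoon faces), single-variation and
partial-face sweeps, the inverted-face variant, and the face/object
selectivity measurement with its blank-image baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cartoon import CartoonSpec, N_FEATURES, random_spec, render
from .gabor import build_energy_bank
from .inference import respond
from .learning import MixtureModel
from .tuning import (
    LEVELS,
    face_selectivity_index,
    full_variation_tuning,
    partial_face_stimuli,
    significance_test,
    single_variation_stimuli,
)

__all__ = [
    "FullVariationResult",
    "baseline_response",
    "full_variation_protocol",
    "sweep_protocol",
    "selectivity_protocol",
    "inverted_tuning_correlations",
]

FACE = 0  # submodel index conventions
OBJECT = 1


@dataclass
class FullVariationResult:
    specs: list[CartoonSpec]
    responses: np.ndarray  # (N, U) face-submodel responses, post-softplus
    posterior: np.ndarray  # (N, K)
    curves_raw: np.ndarray  # (19, 11, U)
    curves: np.ndarray  # (19, 11, U) smoothed
    significant: np.ndarray  # (19, U) bool
    percentile: np.ndarray  # (19, U)

    @property
    def n_tuned_per_unit(self) -> np.ndarray:
        return self.significant.sum(axis=0)

    @property
    def n_tuned_per_feature(self) -> np.ndarray:
        return self.significant.sum(axis=1)

    def peak_trough_levels(self) -> tuple[np.ndarray, np.ndarray]:
        """Peak and trough levels of all significant curves (flattened)."""
        f, u = np.nonzero(self.significant)
        sel = self.curves[f, :, u]  # (n_sig, 11)
        return LEVELS[np.argmax(sel, axis=1)], LEVELS[np.argmin(sel, axis=1)]


def baseline_response(model: MixtureModel, bank=None, submodel: int = FACE) -> np.ndarray:
    """Per-unit response to the blank image (the selectivity baseline)."""
    size = model.config.frontend.image_size
    blank = np.zeros((size, size))
    res = respond(blank, model, bank=bank)
    return res.responses[submodel]


def full_variation_protocol(
    model: MixtureModel,
    n_stimuli: int = 5000,
    n_surrogates: int = 5000,
    seed: int = 0,
    inverted: bool = False,
    skip_mixture: bool = False,
    bank=None,
    submodel: int = FACE,
) -> FullVariationResult:
    """Random cartoon faces, responses, tuning curves and significance."""
    rng = np.random.default_rng(seed)
    specs = [random_spec(rng) for _ in range(n_stimuli)]
    if inverted:
        specs = [CartoonSpec(s.params, s.visible_parts, True) for s in specs]
    stimuli = np.stack([render(s).pixels for s in specs])
    if bank is None:
        bank = build_energy_bank(model.config.frontend)
    res = respond(stimuli, model, skip_mixture=skip_mixture, bank=bank)
    responses = res.responses[submodel]

    U = responses.shape[1]
    curves_raw = np.empty((N_FEATURES, 11, U))
    curves = np.empty((N_FEATURES, 11, U))
    sig = np.empty((N_FEATURES, U), dtype=bool)
    pct = np.empty((N_FEATURES, U))
    ana = model.config.analysis
    for fid in range(1, N_FEATURES + 1):
        levels = np.array([s.params[fid - 1] for s in specs])
        raw, smooth = full_variation_tuning(responses, specs, fid)
        s_flags, s_pct, _ = significance_test(
            responses,
            levels,
            n_surrogates=n_surrogates,
            seed=rng,
            min_max_ratio=ana.min_max_ratio,
            percentile=ana.percentile,
        )
        curves_raw[fid - 1] = raw
        curves[fid - 1] = smooth
        sig[fid - 1] = s_flags
        pct[fid - 1] = s_pct
    return FullVariationResult(
        specs=specs,
        responses=responses,
        posterior=res.posterior,
        curves_raw=curves_raw,
        curves=curves,
        significant=sig,
        percentile=pct,
    )


def sweep_protocol(
    model: MixtureModel,
    kind: str = "single",
    skip_mixture: bool = False,
    bank=None,
    submodel: int = FACE,
) -> tuple[np.ndarray, np.ndarray]:
    """Single-variation or partial-face tuning curves for all 19 features.

    Returns ``(curves, posterior)``: curves (19, 11, U), unsmoothed (one
    stimulus per level); posterior (19, 11, K).
    """
    if bank is None:
        bank = build_energy_bank(model.config.frontend)
    curves, posts = [], []
    for fid in range(1, N_FEATURES + 1):
        if kind == "single":
            stimuli = single_variation_stimuli(fid)
        elif kind == "partial":
            stimuli = partial_face_stimuli(fid)
        else:
            raise ValueError(f"unknown sweep kind: {kind!r}")
        res = respond(stimuli, model, skip_mixture=skip_mixture, bank=bank)
        curves.append(res.responses[submodel])
        posts.append(res.posterior)
    return np.stack(curves), np.stack(posts)


def selectivity_protocol(
    model: MixtureModel,
    face_images: np.ndarray,
    object_images: np.ndarray,
    skip_mixture: bool = False,
    bank=None,
    submodel: int = FACE,
) -> dict:
    """Face-selectivity indices of the face units on held-out images."""
    if bank is None:
        bank = build_energy_bank(model.config.frontend)
    rf = respond(face_images, model, skip_mixture=skip_mixture, bank=bank)
    ro = respond(object_images, model, skip_mixture=skip_mixture, bank=bank)
    base = baseline_response(model, bank=bank, submodel=submodel)
    if skip_mixture:
        # ablation baseline: same pipeline without steps 2-3
        size = model.config.frontend.image_size
        base = respond(
            np.zeros((size, size)), model, skip_mixture=True, bank=bank
        ).responses[submodel]
    mean_face = rf.responses[submodel].mean(axis=0)
    mean_obj = ro.responses[submodel].mean(axis=0)
    fsi = face_selectivity_index(mean_face, mean_obj, base)
    return {
        "fsi": fsi,
        "mean_face": mean_face,
        "mean_object": mean_obj,
        "baseline": base,
        "posterior_face": rf.posterior,
        "posterior_object": ro.posterior,
    }


def inverted_tuning_correlations(
    upright: FullVariationResult, inverted: FullVariationResult
) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature tuned-unit counts (inverted) and mean upright/inverted
    tuning correlation over units significant in both conditions."""
    counts = inverted.significant.sum(axis=1)
    corr = np.full(N_FEATURES, np.nan)
    for f in range(N_FEATURES):
        both = upright.significant[f] & inverted.significant[f]
        if not both.any():
            continue
        cs = []
        for u in np.nonzero(both)[0]:
            a, b = upright.curves[f, :, u], inverted.curves[f, :, u]
            if a.std() > 0 and b.std() > 0:
                cs.append(np.corrcoef(a, b)[0, 1])
        if cs:
            corr[f] = float(np.mean(cs))
    return counts, corr
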