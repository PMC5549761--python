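# Methods

This note records the modeling assumptions, parameter choices and numerical
decisions behind `mixsc`, in the spirit of a methods appendix.  Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Energy frontend

Each detector is a quadrature pair of Gabor filters sharing center,
orientation and frequency, with phases 0° and 90°; its output is the sum of
squared filter responses, the standard complex-cell energy model.  The
default bank covers 10×10 grid centers × 8 orientations (22.5° apart) × 3
frequencies (0.25, 0.17, 0.13 cycles/px) = 2400 detectors.

Choices the energy-model literature leaves open, frozen here:

* **Grid placement** — centers of a uniform partition of the 64×64 frame,
  i.e. pixel coordinate (i + 0.5)·6.4 − 0.5; symmetric coverage with no
  border bias.
* **Envelope** — isotropic Gaussian, σ = 0.4/f, truncated at the image
  border without renormalization.
* **DC correction** — the cosine-phase filter is mean-subtracted so blank
  and constant images give exactly zero energy; the blank stimulus is used
  as the response baseline, so it must be a true baseline.
* **Norm** — after DC correction each filter is rescaled to ‖g‖ = f^1.15,
  approximating the 1/f amplitude spectrum of natural images.
* **Ordering** — detectors are position-major (raster order), then
  orientation, then frequency; serialized models depend on this.

Consequence of truncation: quadrature phase invariance is excellent (<1%
energy variation across grating phase) for interior detectors but degrades
to ~15% for corner detectors whose envelopes are clipped by the frame.  This
is measured in the test suite and accepted; renormalizing truncated
envelopes would instead distort the norm law.

## Preprocessing

Raw images: grayscale → center crop to square (extra pixel dropped at the
right/bottom) → bilinear resize to 64×64 → disk mask → per-image
standardization (zero mean, unit population variance).  The disk mask keeps
radius ≤ 30 px and fades with a raised cosine to zero at radius 32; "fade
gradually" is under-determined, and the raised cosine is the standard
smooth, parameter-free choice (width exposed in config).  Rendered cartoon
stimuli pass through the same mask + standardization so stimuli and training
images share a pipeline; the all-zero blank stimulus bypasses
standardization (dividing by its zero variance is undefined) and proceeds as
zeros, defining the baseline response.  Constant inputs are rejected by a
variance check *before* masking, because the fade rim would otherwise
manufacture spurious variance.

Energy vectors are projected off the direction of the global mean x̄ over
all face and object training data, x ← x − x̄ (x̄ᵀx)/‖x̄‖².  This linear
contrast normalization prevents elements of the learned mean responses
b^k from growing uncontrolled along the dominant energy direction.  The
operation is idempotent and norm-non-increasing (both property-tested).

## Learning

Per class: center by the class mean, PCA to n dimensions with whitening,
then overcomplete ICA estimating M components.  Strong reduction (2400 →
100 at full scale) acts as spatial pooling and produces large, parts-like
basis patterns; the desk-scale configuration used throughout the tests is
n = 30, M = 60 on 400 + 400 training images.

ICA is fitted by score matching of an energy-based model
log p(z) = −Σᵢ G(wᵢᵀz) + const with G(u) = √(u² + ε):

* **Free filter norms.** The norms ‖wᵢ‖ are free parameters of the
  optimization: whitened data has unit variance along every direction, so
  the norms are the only way the model can set each component's sharpness.
  Constraining them to 1 during optimization biases the estimated
  *directions* on overcomplete data; the returned weight matrix R is
  row-normalized after fitting, so downstream assembly always sees unit
  rows.
* **ε = 1.0 by default.** ε is a shape parameter, not merely a numerical
  smoothing: data generated by *dense* Laplace mixtures (every component
  active in every sample, as in this model's generative process) has
  marginals that are smooth near zero, and a pseudo-Huber G matches them
  far better than a near-L1 one.  Empirically (the recovery test and the
  acceptance script), ε of order 1 recovers a known overcomplete basis at
  mean matched |cosine| ≈ 0.98, while ε = 10⁻³ plateaus near 0.65
  regardless of sample size.  ε is config-exposed for sparser data.
* **Optimizer** — L-BFGS with analytic gradients (finite-difference
  verified in tests), random Gaussian row initialization from the seed,
  500 iterations / gradient tolerance 1e−6 by default; hitting the cap
  emits a warning and returns the best iterate, flagged on the submodel.
* **Known limitation: analysis/synthesis duality.** In low dimensions with
  mild overcompleteness (the 3-directions-in-2D configuration), the energy
  model's optimum is the *dual* frame — filters orthogonal to data
  directions, which have maximally sparse responses.  For the symmetric
  0°/60°/120° frame this is the same line set rotated 30°.  The test suite
  asserts this behavior explicitly.  At realistic sizes (15 components in
  10 dimensions and up, quasi-orthogonal directions) the synthesis
  directions are recovered correctly.

Assembly: W^k = R^k diag(d^k)^(−1/2) E^k; every row whose mean response
(W x̄^k)ᵢ would be negative is negated together with its R row (rows with
exactly zero mean response keep their sign); A^k is the SVD pseudo-inverse
of W^k with singular values below 1e−10 of the maximum discarded; and
b^k = W^k x̄^k ≥ 0 elementwise.  Sign canonicalization makes the assembled
triple invariant to ICA sign indeterminacy (property-tested).

## Inference

The MAP problem per submodel is convex.  With z = y − b^k it is an
L1-penalized least squares solved by FISTA, with the step size set by the
Lipschitz constant σ_max(A)²/σ², warm-started at the analysis response
W x − b, stopping when the relative objective change falls below 1e−10
(checked every 10 iterations) or at 5000 iterations.  The quadratic term is
evaluated in the rank-r column space of A via a thin SVD; the input's energy
orthogonal to that subspace is added back to L_k as a constant.  That
out-of-subspace residual is deliberate and essential: it is what makes L_k
class-discriminative, and it is why strong dimension reduction (small n)
helps the posterior separate faces from objects.

Posteriors use log-domain softmax with max subtraction; exact goodness ties
return the priors.  Softplus is computed as logaddexp(0, a), exact over the
full float range.  Responses are reported both before and after softplus
(`responses_raw` / `responses`), since reported "response" conventions vary.

σ and λ have no canonical published values; both default to 1.0 and are
config-exposed.  All acceptance measurements use these defaults.

## Cartoon stimuli

The renderer draws a face as the *sum* of 7 parts (outline, hair, eye pair,
iris pair, eyebrows, nose, mouth) controlled by 19 integer parameters on 11
levels (−5…+5).  Parameters 1–3 (aspect ratio, direction, assembly height)
set the global geometry every part inherits; 4–19 are local to one part.
The exact stroke geometry (ellipse outlines, segments, quadratic Bezier
lips, a polar hair band) is this package's own design, frozen by regression
tests; the parameter *semantics* (round-to-long, smily-to-frowny, …) follow
the face-patch stimulus convention.  Two deliberate decoupling choices keep
locality exact: eyebrows are anchored to the face frame (not the eye
positions), and the mouth is anchored to the face frame (not the nose tip),
so sweeping eye- or nose-owned parameters cannot move other parts.  Gaze
direction maps its 11 levels onto a raster path inside the eye (4 upper, 3
middle, 4 lower positions, left-to-right).  Inversion is a vertical flip of
the finished render.  The "standard" face is all parameters at level 0.

For the partial-face protocol each feature is swept with only its owning
part rendered; the global parameters 1–3, which own no single part, are
swept on the outline.

## Synthetic corpora

The face corpus renders random cartoon specs with small jitter (≤3 px
translation, ≤10% scale, ≤20% contrast) — aligned on average, like the
face photographs the full-scale model trains on.  The object corpus
composes 2–6 centered geometric primitives; one family (the "boat hull") is
drawn with the same two-Bezier primitive as the cartoon mouth, so isolated
object parts can masquerade as facial parts — the ambiguity that
explaining-away is supposed to resolve, exercised directly in the tests.
Corpora reserve a held-out fraction (default 20%) for selectivity testing.

Synthetic ground-truth mixtures for recovery/consistency tests draw their
ICA rows as low-coherence frames (frame-potential descent) because
overcomplete directions are only identifiable when well separated; i.i.d.
rows at M = 15, n = 10 routinely contain near-parallel pairs.

## Tuning analysis

Full-variation curves average responses per feature level over random
stimuli (2000 at desk scale; 5000 at full scale) and are smoothed with a
unit-variance Gaussian kernel truncated and renormalized at the boundary
(so constants are preserved).  Significance requires (1) smoothed maximum ≥
1.25 × minimum and (2) heterogeneity — Σ p log p of the curve normalized to
sum 1 — above the 99.9th percentile of label-permuted surrogates (1000 at
desk scale; 5000 at full scale), smoothed identically.  One permutation per
surrogate is shared across units; each unit's null distribution is
unaffected, and the acceptance suite verifies the joint criterion's
false-positive rate ≤ 0.005 on feature-independent responses.

Single-variation and partial-face curves use one stimulus per level and are
not smoothed.  Gain ratios regress the test curve on the reference curve
and report 1/slope; pairs with non-positive or vanishing slope are excluded
from the population mean (their reciprocal gain is unbounded), with the
single-variation (reference) vs partial-face (test) pairing as the default.
The face-selectivity index is ((f−b) − (o−b))/((f−b) + (o−b)) with b the
blank-image response; a vanishing denominator yields NaN rather than an
exception.  2D tuning maps are compared with additive and multiplicative
predictors built from the 1D curves via Pearson correlation over the 121
cells.

## Desk-scale study conditions

The test suite and acceptance script run everything at sizes chosen for a
single CPU: 500 + 500 synthetic training images, n = 30, M = 60, 2000
full-variation stimuli, 1000–2000 surrogates, 100 + 100 held-out test
images.  What passing shows: the inference machinery is exact (oracle
checks), the learning pipeline recovers known generative structure, the
statistics are calibrated, and the qualitative face-patch signatures
(category selectivity from explaining-away, sparse feature tuning, gain
reduction for partial faces) emerge end to end.  What it does not show:
quantitative match to electrophysiology at the published scale, which
requires the full photographic training corpora; and the synthetic corpora
lack the background clutter, lighting and texture statistics of real
images, so absolute index values here are not comparable to those measured
on natural-image-trained models.
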