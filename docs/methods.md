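# Methods

This note records the models, parameter choices and numerical decisions
behind `pyloruskit`, and what the synthetic evaluation does and does not
establish.

## Colour-saliency valid region

Frames are converted sRGB → CIE Lab under the D65 white point with L in
[0, 100] (the dominant convention; `skimage.color.rgb2lab`). The chroma
channels are smoothed with a Gaussian of σ₁ = 1 px before the saliency
score; a difference-of-Gaussians variant with σ₂ = 1.6 σ₁ (the classic
band-pass ratio) is exposed via `SaliencyParams(use_dog=True)` but is not
the default, because the mean-deviation score needs the DC component that a
band-pass removes.

The score itself is

    S = (a − a_u)^α + |b − b_u|^β,    α = 3, β = 1.5.

Two sign conventions were possible for the `a` term; the signed odd power
was chosen so that tissue — which reflects more strongly in `a` than any
disturbance — scores positive, while bright achromatic disturbances
(specular blobs, bubbles, fluid) fall far below the image mean and score
strongly negative. The absolute value on the `b` term keeps the fractional
power real. `α` must be odd (the sign carries information) and
1 < β < α. Positivity is tested with a 1e-9 absolute tolerance: a nominally
constant frame carries conversion round-off of order 1e-16 which the
absolute-valued `b` term would otherwise promote into "valid" pixels.

**Degenerate masks.** Downstream statistics divide by the valid-pixel count,
so if fewer than 1% of pixels are positive the mask falls back to the full
frame and is flagged. This happens on constant frames (S ≡ 0) and protects
the window statistics rather than expressing any confidence in the frame.

## Monitor

Windows are consecutive, non-overlapping blocks of `window_size = 100`
frames, paired with stride one window: (W₁, W₂), (W₂, W₃), …. Within a
window, every `sample_interval = 5`-th frame is analysed — the capsule
advances slowly enough that adjacent frames are nearly identical, so denser
sampling buys noise averaging, not information. Only the `a` and `b`
channel means enter the dissimilarity; luminance is excluded because
capsule illumination varies with pose, not with organ.

The running reference MDC is the arithmetic mean of all dissimilarities
seen so far, initialized to DC₁ (the printed running-mean denominator
`k − 2` is undefined for the first pairs; the chosen rule is well defined
from the first pair and agrees with the stated initialization). The mean is
computed with `math.fsum`, with an exact shortcut for constant histories so
the invariant "MDC of n equal DCs is exactly that DC" holds in floating
point.

The trigger fires when `DC_k / MDC > 0.2 + 0.3·t`. Consequences worth
stating explicitly:

* The first pair always triggers (ratio 1 > 0.2), so the Judge vets the
  start of the stream once; on a pure-stomach span its predictions are
  single-class, the verdict is rejected, and `t` escalates.
* A stationary stream triggers exactly while `0.2 + 0.3·t < 1`, i.e. three
  times, then never again.
* `t` increments only on a Judge rejection and never resets; an accepted
  verdict terminates the run, so whether the accepting trigger "also"
  increments `t` is unobservable.
* A zero MDC with a non-zero DC triggers: any change from perfect
  constancy is suspicious.

## CTVP descriptor

**Phase congruency.** Computed per orientation from a log-Gabor bank
(4 scales, 6 orientations spaced 30°, minimum wavelength 3 px, scale
multiplier 2.1, bandwidth ratio σ_onf = 0.55, 15th-order Butterworth
low-pass at 0.45 of Nyquist to keep the widest scale inside the band). The
noise threshold T_o follows the Rayleigh model: the smallest-scale
amplitude's median estimates the noise scale τ, extended over the geometric
scale ladder, with k = 2 standard deviations of compensation. A sigmoid
weight (cutoff 0.5, gain 10) down-weights pixels whose response is
concentrated in few scales. Values are clipped to [0, 1]. Because both the
energy and the noise estimate scale linearly with image intensity, the
measure is contrast-invariant up to the ε = 1e-4 denominator guard
(measured mean deviation under intensity doubling is ~1e-5).

**Maximum moment.** The orientation covariance sums use the standard form
a = Σ(PC cos o)², b = 2 Σ PC² sin o cos o, c = Σ(PC sin o)², and
M = (a + c + √(b² + (a − c)²))/2 — the larger principal value. (A printed
source formulation repeats the cosine sum where the sine sum belongs; the
covariance form is the only one that makes M the orientation-free structure
strength, and it reproduces the hand-checkable cases M = p² for a single
orientation and for two equal orthogonal ones.)

**GLCM.** The M map is min–max quantized to G = 16 levels (a balance of
resolution against sparsity at the 256×240 clinical frame size; the map's
observed range is used because M has no fixed scale). Co-occurrence
matrices are accumulated at displacement δ = 1 for θ ∈ {0°, 45°, 90°, 135°},
symmetric, normalized to sum 1, and the four statistics are averaged over
orientations — the standard rotation-robust practice. Displacements are
exact integer offsets ((0,d), (−d,d), (−d,0), (−d,−d)), so a diagonal
displacement at δ = 2 really is a 2-step diagonal. Homogeneity uses the
inverse-difference form Σ C/(1 + |i − j|); a variant that inserts
mean-centred factors into the numerator exists in some formulations and is
available as `homogeneity_variant="printed"`, but it is not bounded by
[0, 1] and is not the default. Correlation of a zero-variance matrix is
reported as 0 with a `correlation_defined = False` flag. Texture is
computed on the full frame by default (co-occurrence needs spatial
continuity); pair counting can be restricted to the valid region.

**Colour histograms.** Hue and saturation from the classical HSI
decomposition (I = (R+G+B)/3, S = 1 − 3·min/(R+G+B), H via the arccos
form), each uniformly binned into 16 bins over its full range and
normalized by the valid-pixel count. Intensity is discarded as
illumination-dependent. Saturation — not intensity — is the second channel:
it is the one the histogram formulas act on.

**Layout.** [contrast, correlation, energy, homogeneity, 16 hue bins,
16 saturation bins] — 36 values, fixed order, named in `CTVP_LAYOUT`.

## Judge

Features are standardized to zero mean / unit variance with training-set
statistics (RBF kernels are scale-sensitive) before an SVC with RBF kernel,
C = 10, γ = "scale". The judged span is the triggered pair plus the
preceding window — three windows, giving stomach-side context whichever
window edge the boundary sits near — sampled at the Monitor stride, with
the Monitor's cached masks reused rather than re-extracted.

The boundary estimator is the minimum-misclassification step split:
s minimizing (ones before s) + (zeros at/after s) over s ∈ [1, n−1],
earliest index on ties (so the estimate is the first frame called
intestinal). It equals exhaustive brute force by construction and is tested
against one. A verdict is accepted when both classes appear among the
predictions and the split cost is at most 20% of the judged frames; the
20% ceiling is configurable and exists to give the Monitor's escalation
loop a rejection path with a concrete criterion.

## Synthetic data

The generator emulates exactly the features the method consumes: a reddish
mean colour for stomach (RGB (165, 75, 60)) vs a yellower one for intestine
((175, 140, 70)), i.i.d. Gaussian pixel noise (σ = 3), a villi texture on
the intestinal phase realized as thresholded band-pass noise bumps
(amplitude 25) — fixed per sequence seed, since mucosal pattern persists
across frames while photometric noise does not — and four disturbance
primitives (overexposed blob, near-black shadow, bright bubble ring with
washed-out interior, low-chroma fluid patch) each injected per frame with
probability 0.1 at seeded positions, with their exact pixel footprints
recorded so mask tests can assert exclusion directly. Frames are rendered
lazily from per-frame child seeds, so sequences are bit-reproducible, can
be accessed out of order, and expose how many frames a run actually
decoded.

What the generator deliberately does not model: capsule optics and vignette,
illumination gradients, peristaltic motion blur, gradual (rather than
abrupt) organ transitions, food debris with tissue-like chroma, and the
long-range nonstationarity of real recordings. Passing tests therefore
establish the pipeline's correctness and its behaviour under the stated
regime — not clinical performance.

## Problem sizes

The end-to-end evaluation runs 20 sequences of 2,000 frames (boundary
uniform in the middle half, window 100, stride 5) at 128×120 pixels, and
the classifier cross-validation uses 200 descriptors (100 per class) at the
same size; the generator's default frame size remains the clinical 256×240.
These sizes keep a full evaluation at about two minutes on one CPU while
leaving every algorithmic parameter at its stated value.

## Known limitations

* A sequence whose boundary falls inside the first window pair offers the
  Monitor no stationary reference; the first-trigger Judge call usually
  still resolves it, but MDC is then not a noise estimate.
* The Judge assumes a single boundary in the judged span; multiple
  transitions (e.g. reflux) would be reduced to the best single step.
* The acceptance threshold and the escalation rule interact: a very noisy
  classifier can exhaust all triggers and return no estimate, which callers
  must handle (`LocateResult.boundary_frame is None`).
* Eq-style confusion metrics are offered in two conventions; the default
  ("printed") sensitivity/specificity read as precision-like quantities
  unless class 1 is interpreted in a specific way — the `standard`
  convention is the textbook one.
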