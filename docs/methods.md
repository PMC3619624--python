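# Methods

This note documents the models implemented in `fadsync`, the choices made
where the method's description leaves room, and what the synthetic
phantom does and does not establish.

## Factor analysis of the TAC matrix

The TAC matrix `X` holds one row per selected ventricular pixel, ordered
by the 1-based row-major linearization `p = (i − 1)·M + j`, and one
column per gated frame. The decomposition is

- **Centering** — per-pixel temporal mean removal. This makes the
  autocorrelation a covariance of TAC *shapes*: the factors cluster
  temporal behaviors rather than baseline intensities.
- **Autocorrelation** — `C = X_mᵀ X_m / P`. The `1/P` normalization
  makes the eigenvalue scale independent of how many pixels the ROI
  contains, so dilated ventricles are not penalized for their size.
- **Scaling `D`** — default `diag(λ)^(−1/2)` (whitening): the factor
  coordinates of every subject then have unit second moment per retained
  factor, which is what makes clouds from different subjects poolable
  into one density model. `sqrt` and `none` scalings are available for
  exploratory use.
- **Sign convention** — an eigenvector's sign is arbitrary but must be
  fixed consistently across subjects before pooling. Each eigenvector is
  oriented so its inner product with the subject's mean centered
  ventricular TAC is non-negative; if that projection is numerically
  zero (< 1e-12), the largest-magnitude component is made positive.
  Eigenvalue ties (exactly degenerate spectra) keep `eigh`'s deterministic
  ordering, stabilized by a stable descending sort.
- **Degenerate input** — an all-constant TAC matrix yields a valid
  all-zero decomposition with a `RuntimeWarning` rather than an error;
  eigenvalues below `1e-12 × λ_max` are treated as zero and produce zero
  factor columns.

With per-pixel centering, a pure raised-cosine TAC population spans at
most two temporal dimensions, so the third factor of a noiseless
single-harmonic phantom is identically zero; on real (and Poisson-noisy
simulated) data the third factor carries the residual structure that
distinguishes abnormal contraction.

## Gaussian-mixture reference model

The pooled 3-MSF cloud of a control group is modeled as
`p(f) = Σ_r w_r N(f | μ_r, Σ_r)` with `Σ w_r = 1`. EM fitting supports
five covariance families in the volume/shape/orientation coding:
EII and VII (spherical, shared or per-component volume), EEE (one shared
full covariance), VEV (`λ_r D_r A D_rᵀ` — shared shape `A` with
`det A = 1`, free volumes and orientations) and VVV (unconstrained). The
VEV M-step has no closed form; it alternates the shape and volume
updates given the per-component scatter eigendecompositions (orientation
is optimal at the scatter eigenvectors regardless of the shape), to a
relative tolerance of 1e-8 with at most 100 inner iterations.

Numerical choices:

- **Initialization** — k-means++-style center seeding from the supplied
  seed, five restarts. Each restart runs a 25-iteration EM burn-in and
  only the best burn-in log-likelihood is continued to convergence
  (relative log-likelihood change < 1e-6, at most 500 iterations). This
  "short-runs" strategy gives near-identical fits to running every
  restart to convergence at a fraction of the cost.
- **Covariance floor** — whenever a component's smallest eigenvalue
  falls below `1e-6 · tr(S)/3` (`S` the data covariance), that floor is
  added to the diagonal; if all restarts still collapse, the fit retries
  with a fresh sub-seed up to three times before raising.
- **Density evaluation** — log-sum-exp throughout; points hundreds of
  sigma from every component yield finite large-negative log-densities.

**Model selection** fits every (R, family) candidate with R in 1..9 and
all five families, and keeps the minimum of
`BIC = −2 log L + m ln n`, where the free-parameter count `m` is
`R−1` weights plus `3R` means plus a family-dependent covariance count
(1 for EII, R for VII, 6 for EEE, `4R + 2` for VEV, `6R` for VVV).
Mixture software in the wild also reports the negated, maximized
convention `2 log L − m ln n`; selection tables carry both columns so the
two sign conventions cannot be confused. Ties break toward fewer
components, then family order (EII, VII, EEE, VEV, VVV).

## Training and scoring

Training draws `group_count` groups of `group_size` control subjects
(defaults 6 × 10), each group sampled uniformly *without* replacement
within the group and independently across groups — subjects recur across
groups, in the spirit of bootstrap resampling of a small control pool.
Each group's pooled factor cloud goes through BIC selection and the
overall minimum-BIC group model becomes the reference. Subjects are
canonically ordered by their id before group assembly, so training
depends only on the id set and the seed, not on input order.

The normality index is implemented literally as the mean natural-log
likelihood of the subject's ventricular factor points — typically a
negative number, higher (closer to zero) meaning more normal. Published
clinical tables sometimes quote positive indices that *increase* with
abnormality; since no transformation of the literal definition reproduces
such a scale unambiguously, the package exposes an explicit
`orientation` switch (`literal` | `abnormality`, the latter the negated
value) and every report records which was used. Scoring pools the
LV ∪ RV pixels by default (per-region scoring is available through the
`regions` argument); each subject is decomposed with its own FADS under
the fixed sign/scale conventions above.

Cohorts are compared with a two-sided independent-samples t-test at
α = 0.01. Welch's unequal-variance form is the default (the group
variances differ strongly between normal and pathological cohorts); the
pooled-variance form is available as `variant="pooled"`.

## The phantom

The generator emulates the target acquisition: 64 × 64 grid, 16 gated
frames, ~300 Kcounts/frame, two elliptical ventricular pools on a flat
background (10 % of the brightest region's peak). Ventricular pixels
follow `b + a·cos(2πk/K − φ)` with per-pixel phases drawn once
(wrapped-normal around the region phase with dispersion σ_φ — phase
structure is anatomy, not noise), and Poisson counting noise applied per
pixel and frame. The noiseless series is scaled so the *mean* expected
frame total equals the count target; individual frame totals modulate
around it with the cardiac cycle, as in a real gated study.

Preset parameter ranges (uniform per-subject jitter):

| preset | interventricular delay | σ_φ | amplitude scale | dilation |
| --- | --- | --- | --- | --- |
| normal | 0° | 5–10° | 0.9–1.1 | 1.0 |
| lbbb_like | 30–50° | 8–15° | 0.9–1.1 | 1.0 |
| dcm_like | 10–30° | 35–55° | 0.25–0.45 | 1.15–1.35 |

The LBBB delay range sits above the 25.5° interventricular-dyssynchrony
cut-off used clinically; the DCM preset combines dilation, large phase
dispersion and reduced pulsation amplitude (a proxy for severely reduced
ejection fraction — the package does not compute EF itself). These
ranges are this package's own calibration: no published generative model
for these populations exists, so passing tests demonstrate that the
pipeline separates cohorts *with the qualitative contrasts described
clinically*, not that it reproduces any particular patient population.
The phantom omits photon transport, collimator blur, attenuation,
scatter, gating errors and arrhythmia; its single-harmonic TACs are
kinder to Fourier phase analysis than real data would be.

## Phase analysis baseline

Per-pixel phase is the first DFT harmonic of the count curve in cosine
form, degrees in [0, 360), zero-referenced to frame 1, so the phantom's
configured delay is returned verbatim. A vanishing first harmonic
(relative amplitude < 1e-12) marks the pixel's phase undefined. ROI mean
and SD are linear statistics computed after unwrapping the ROI's phases
into a 360° window centered on their circular mean (naive linear
statistics break at the 0/360 seam); SD uses the sample (n−1) form, and
a single-pixel ROI reports SD 0. The mode is the center of the tallest
histogram bin (default width 1°; ties take the lowest bin). The
interventricular index is the absolute circular difference of the two
ROI means, in [0, 180].

## Problem sizes and shipped data

The unit-test phantoms run at 32 × 32 / 60 Kcounts with proportionally
shrunken ventricles — the same generative structure as the default
acquisition at a fraction of the cost; the acceptance-level checks and
`scripts/acceptance.py` use the full 64 × 64 / 300 Kcounts defaults with
cohort sizes 23 (training), 8 (normal test) and 13 (DCM-like test), and
the published-model recovery check uses 5,000 sampled points. All
fixtures are generated programmatically; the only shipped data file is
the published reference mixture (`fadsync/data/control_3msf_gmm.json`),
whose printed weights sum to 0.999 (renormalized on load, tolerance
1e-3) and whose second covariance is stored symmetrized, as the printed
matrix differs between its lower and upper triangles in the last digit.

## Known limitations

- The NIfTI/NPZ/JSON on-disk formats are this package's choices; the
  method itself prescribes none.
- Whether clinical practice pools per-subject factor decompositions (as
  done here) or decomposes subjects jointly is not standardized; joint
  decomposition is not implemented.
- Oblique rotation of factors to non-negative "physiological" TACs —
  common elsewhere in the FADS literature — is out of scope; the method
  uses the orthogonal decomposition only.
- Only the five covariance families listed are implemented; d ≠ 3 data
  is handled correctly but not optimized.
- Beat-rejection gating, DICOM I/O and ejection-fraction computation are
  out of scope.

## Mixture-model JSON schema

`save_model`/`load_model` use a flat JSON document:

```json
{
 "format": "fadsync-mixture", "version": 1,
 "family": "VVV", "R": 5,
 "weights": [...],            // length R, sums to 1 within 1e-3 on load
 "means": [[...], ...],       // R x 3
 "covariances": [[[...]]],    // R x 3 x 3, each symmetric positive definite
 "fit": {"n": ..., "d": 3, "log_likelihood": ..., "bic": ...,
         "converged": ..., "n_iter": ..., "seed": ...}  // or null
}
```

Loading validates SPD covariances and the weight sum (renormalizing the
printed-rounding residual); floats round-trip losslessly at double
precision.
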