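# Methods

This note documents the models, numerical choices and synthetic-data design
behind `hsidry`, in the spirit of a package methods appendix. It states no
empirical numbers beyond what the test suite and `scripts/acceptance.py`
compute.

## Reflectance calibration and ROI extraction

Raw pushbroom digital numbers are converted to relative reflectance by the
black/white correction R = (R_o − R_d)/(R_w − R_d) against a whiteboard frame
R_w and a dark-current frame R_d. Reference frames may be full images,
per-column scan lines (the pushbroom case), or per-band vectors. Cells where
R_w = R_d are unreconstructable; they are set to 0 and flagged in an
`invalid` mask that all downstream statistics honor, rather than propagating
NaN.

Manual region-of-interest drawing is replaced by a deterministic stand-in:
Otsu thresholding at the band nearest 550 nm, largest connected component,
then removal of 15 % of the object's extent at each end of its longer axis
(configurable `trim_fraction`) to exclude head and tail. The trim fraction is
a declared convention — there is no quantitative rule to infer it from — and
the synthetic generator builds its ground-truth masks with the same
convention, so segmentation accuracy is testable (Jaccard overlap against
truth). Mean spectra are per-band arithmetic means over ROI pixels.

## Spectral preprocessing

Savitzky–Golay smoothing (default window 11, polynomial order 2 — a common
chemometrics default at 224 bands; the edge polynomials are re-evaluated so
length is preserved) followed by the standard normal variate transform,
(x − mean)/sd with the n−1 denominator. SNV removes multiplicative scatter
and additive offsets per spectrum. The SG→SNV order is a package convention;
both transforms can be toggled in `PreprocessConfig`.

## CARS wavelength selection

Competitive adaptive reweighted sampling runs M Monte-Carlo iterations
(default config 1000; the orchestrated pipeline and the acceptance script use
60, which is sufficient for the synthetic studies because the exponential
schedule, not the iteration count, controls how aggressively bands are
culled). Iteration i:

1. draw 80 % of the calibration samples without replacement;
2. fit PLS1 with the component count chosen by 5-fold CV on that subset
   (capped at min(10, rank); the coefficient path makes this one fit per
   fold);
3. keep the top r_i·N bands by |coefficient| (ties to the lower band index),
   where the exponentially decreasing function r_i = a·e^(−k·i) is pinned by
   r_1 = 1 and r_M = 2/N;
4. adaptive reweighted sampling: r_i·N weighted draws with replacement,
   p ∝ |coefficient|, duplicates collapsed — survivors only ever shrink;
5. record the 10-fold cross-validated RMSE of the survivor set on all
   calibration samples.

The subset at the argmin of the RMSECV curve is returned. All randomness
flows from one seed, so reruns reproduce selections exactly.

## Regression models and evaluation

**PLS1 (NIPALS)** with mean centering (no variance scaling by default, the
chemometric convention for spectra). The per-component coefficient path
β_a = Σ_j q_j r_j (with r_j the X-side rotation built from weights and
loadings) lets one fit score every component count, which keeps
cross-validated component selection (10-fold by default) and the inner CARS
loop cheap. At full rank PLS1 reproduces ordinary least squares, which the
tests use as an oracle, and predictions agree with scikit-learn's
`PLSRegression` at matched component counts.

**LSSVM** with RBF kernel K(x,x′) = exp(−‖x−x′‖²/σ²) solves
[[0, 1ᵀ],[1, Ω + I/γ]]·[b; α] = [0; y] by a dense symmetric solve; the
residual of that system is checked to 1e−8. Hyperparameters come from a 7×7
log grid (γ ∈ 10⁰…10⁶, σ² ∈ 10⁻²…10⁴) by 10-fold CV, ties resolved toward
smaller γ then larger σ². Because RBF distances are scale-sensitive, the
pipeline standardizes feature columns on calibration statistics before LSSVM
fits; PLSR handles centering internally.

The 104 samples are split 3:1 into calibration and prediction sets,
stratified by drying level (6 + 2 per level) with a seeded draw. Models are
reported as Pearson R and RMSE per partition plus RPD =
sd(y_prediction-set, n−1)/RMSEP; R is a correlation, not R², and a zero
RMSEP reports RPD = ∞ rather than failing.

**Feature-level fusion** z-scores each column of [CARS-selected bands | 13
image features] using calibration means/sds (zero-variance columns dropped
with a warning) and concatenates. Plain z-scoring is the declared reading of
"normalization" for fusion.

## Image color and texture features

RGB images are synthesized from the bands nearest 647/550/460 nm and clipped
to [0,1]. The nine color features are per-channel ROI means (first moments),
per-channel population standard deviations (second moments; the sd scale is
the documented convention for "color variance"), and the arithmetic ROI
means of H, S, V (hue on [0,1); the arithmetic hue mean is the default, a
circular mean is available where hue wraps matter).

Texture comes from a mask-aware GLCM: the image is quantized to 64 gray
levels over the ROI min–max range (so constant offsets cancel), and pairs at
distance 1 in the 0/45/90/135° orientations are counted only when **both**
pixels are inside the ROI — a requirement a rectangular-image co-occurrence
routine cannot express, hence the in-package implementation (cross-checked
against scikit-image on rectangular ROIs and against exhaustive pair
enumeration). Matrices are symmetrized and normalized; contrast, correlation,
energy and homogeneity are averaged over the four orientations **and** over
the top three principal-component images of the cube (pixels as
observations, bands as variables), yielding exactly four texture values —
the only reading consistent with a 13-feature fused vector. A constant image
has undefined GLCM correlation: direct calls raise, batch extraction reports
0 with a warning so one degenerate sample cannot abort a study.

## CPMG inversion and water pools

The decay is modeled as s(t_i) = Σ_j f_j exp(−t_i/T2_j) on a 128-point
log-spaced grid over 0.01–10 000 ms and inverted by non-negative least
squares with penalty λ‖L f‖². Two penalty operators are provided:

* `ridge` (L = I), the textbook Tikhonov form — used for the
  regularization-monotonicity property (‖f‖² never increases with λ);
* `curvature` (default): second differences over the log grid plus a small
  (0.1-weighted) ridge. The pure ridge form systematically inflates
  short-T2 pool areas, because grid points left of the first echo have
  low-norm design columns and absorb mass cheaply; the curvature form
  reduces that bias markedly while the embedded ridge pins the
  otherwise-unconstrained sub-echo columns (a linear ramp there has zero
  curvature).

λ defaults to the discrepancy principle — the largest ladder value whose
residual stays below √n·σ̂, with σ̂ estimated from first differences of the
decay; the residual is monotone in λ, so a bisection over the ladder
suffices. The discrepancy principle is deliberately conservative and
over-smooths small fast pools (their apparent times shift left by up to
~20 %); a fixed-λ override exists, and the orchestrated pipeline uses
λ = 0.01, which preserves the per-sample pool-time trends at the generator's
signal-to-noise level. λ = 0 (unregularized) is appropriate only for
noiseless, grid-representable signals, where it reproduces the forward model
to ~machine precision.

Pools follow the conventional windows — bound 0.01–10 ms, immobilized
10–100 ms, free 100–10 000 ms. Pool area is the summed amplitude in the
window; pool time is the amplitude-weighted geometric mean of the grid
points (the natural statistic on a log grid; mode-of-peak is available). A
window holding < 10⁻³ of total mass reports time 0 and area 0, matching how
a vanished free-water pool is conventionally tabulated. Correlations between
pool times and quality indicators are plain Pearson r, per-sample by default
(per-level means optional).

## Quality maps

Spectral models are applied pixel-wise: each ROI pixel's spectrum passes
through the identical preprocessing used in training (per-pixel SNV when the
model was trained with SNV) and is scored; background pixels hold NaN, never
a prediction. Rendering uses a linear blue→red scale with the 1st/99th
percentile clip applied to hues only — stored values are never clipped.
Fusion models cannot be applied per pixel (image features are per-sample);
maps for fusion-selected indicators fall back to the spectral-only sibling
model, recorded in the run metadata.

## The synthetic study generator

The generator emulates the drying-study design: 13 levels × 8 replicates =
104 samples, 64×96×224 cubes over 400–1000 nm, per-column white/dark
references, one CPMG decay and one quality record per sample. What it
emulates, and what it does not, determines what a passing test means.

**Quality tables.** Level means are piecewise-linear through three printed
anchors (fresh at level 0, boiled at level 1, the 12 h endpoint at level
12); elasticity additionally peaks at level 7, reproducing its
rise-then-fall. Replicates scatter around the level means with the anchors'
interpolated standard deviations; the moisture replicate sd, not printed
anywhere, is set to 1.2 % (typical gravimetric repeatability). Moisture runs
75.87 % → 35.02 % and is monotone by construction. ΔE is computed per sample
against the fresh mean Lab.

**Reflectance model.** Foreground pixels follow
g·b(px)·[1 + slope·x + 0.15·x² − d_a·G(480,40) − d₄₅₅·G(455,20) −
d₅₃₀·G(530,25) − d_w(px)·G(960,35)] with x the centered wavelength. The
planted links are: baseline level decreasing with drying level, slope affine
in the sample's L\* deviation, the 480 nm (astaxanthin) depth affine in a\*,
and the 960 nm (water) depth affine in moisture with a mild left-to-right
spatial gradient (wet → dry) for map tests. The fixed x² curvature keeps the
spectral family non-affine so SNV remains injective in the latent
parameters. Nuisances are chosen to mirror why full spectra beat 3-band
color readouts in practice: a per-sample multiplicative scatter (sd 0.04,
removed by SNV but corrupting image brightness), two independent secondary
pigment bands at 455 and 530 nm (spectrally separable at 224 bands, but
confounding for RGB/HSV ratios, which have only two scatter-free degrees of
freedom), small depth jitters (sd 0.0015), and a drying-dependent
multiplicative speckle whose amplitude rises then falls over the drying
course with strong (±25 %) sample-to-sample variability — texture is a noisy
proxy, as real GLCM features are. Band-wise pixel noise has sd `noise_sd`
(default 0.01 reflectance units).

`noise_sd = 0` is the **deterministic oracle mode**: it disables every
stochastic component (pixel noise, scatter, pigment nuisances, depth jitter,
replicate scatter, decay noise), so replicates are bit-identical and an
end-to-end extract→fit run must achieve essentially perfect calibration —
the pipeline's smoke oracle.

**Decays.** Tri-exponential with per-level pool times shrinking over drying
(bound 3.05 → 1.52 ms, immobilized 28.48 → 14.17 ms, free ~320 → 140 ms),
the free-pool amplitude reaching 0 for levels past 9, and total amplitude
proportional to the sample's moisture. Echo spacing 0.4 ms (2τ with
τ = 200 µs), 2500 echoes. Decay noise sd defaults to 0.001: the study's T2
spectra show three cleanly resolved pools with stable fast-pool trends,
which implies scan-averaged SNR of order 10³ — at substantially higher noise
the 10 %-amplitude bound pool is unrecoverable by any inversion, which would
contradict the data the generator emulates.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: no radiative transfer or tissue optics (depths are
affine in quality values by fiat), no wavelength-dependent instrument noise,
no spatial autocorrelation beyond the planted gradient and speckle, no MRI
imaging, and no biochemical covariance between indicators beyond their
shared level trends. Recovery results demonstrate algorithmic correctness
and the qualitative information ordering (spectra > images for internal
indicators), not instrument-level accuracy claims.

**Seeding.** One global seed spawns per-sample substreams
(`numpy.random.SeedSequence`), so datasets are bit-reproducible and
replicate-level draws are independent.

## Problem sizes and determinism

The default study (104 cubes of 64×96×224) extracts in tens of seconds; the
test suite and the acceptance script run the full design, with CARS at 60
Monte-Carlo iterations and T2 inversions on 2500-echo decays — sizes chosen
so the complete analysis remains a single-machine, single-process run. All
splits, CARS runs, tuning grids and generator draws are seeded; rerunning
any stage with the same seed reproduces its outputs byte-for-byte.

## Known limitations

* Pool times from regularized inversion carry a smoothing-dependent downward
  bias for small fast pools; areas are much better determined than times.
* The arithmetic hue mean is used by default; for hue distributions near the
  red wrap point the circular mean flag should be used.
* CARS selected-band counts are data- and seed-dependent outcomes, not
  targets; only the planted-recovery property is asserted.
* The generator's endpoint-anchored linear level trends ignore the
  mid-drying fluctuations a real study records between its anchor rows.
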