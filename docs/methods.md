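# Methods

This note records the models, the operational definitions behind the image
measurements, the synthetic-data generator, and the numerical choices —
including the places where the design was genuinely open and what was
decided.

## Image measurements

All analysis happens on maximum Z-projections of three-channel stacks
(Collagen IV, α-SMA, Aβ), in (row, column) pixel coordinates at a lateral
calibration of field-width/matrix-size; the shipped default is
581.25 μm / 1024 px = 0.5676 μm/px.  Calibration precedence: an explicit
value overrides file metadata; absence of both is an error.  Intensities
are processed in float regardless of the stored dtype.

**Binarisation.**  The protocol this package emulates does not name its
binarisation method, so each channel is thresholded by Otsu's method by
default, with a fixed-value override per channel.  A constant image under
Otsu yields an empty mask rather than an error.

**Complete ring.**  "A complete ring of α-SMA" is operationalised as: the
connected component, after morphological hole-filling, gains at least
`min_lumen_px` (default 1) enclosed pixels; the gained pixels are reported
as the lumen.  Consequences users should know: a ring cut by a gap of any
width fails; a solid disk fails (no hole); and a ring truncated by the
image border fails, because no hole is enclosed on the open side.  The
flag is invariant to translation and 90° rotation.

**Arteriole rule.**  An arteriole is a complete-ring SMA component with
(a) at least `copositivity_fraction` (default 0.5) of its pixels also
Collagen-IV-positive — "positive for both" is not pixel-defined in the
protocol; a majority criterion is robust to ~1-px registration jitter —
and (b) stained wall area ≥ 150 px, lumen excluded.  Only the applied
150-px threshold is implemented; the theoretical ~155-px wall area quoted
alongside it presumes an unstated wall thickness and is not reproduced.

**Capillary rule.**  Capillaries are the Collagen IV mask minus the
arteriole wall mask dilated by 4 px (disk element — the protocol says "4
pixels" without a shape; a disk gives an isotropic margin), keeping
components ≥ 29 px.  Components are 8-connected throughout (the common
particle-analysis convention), configurable to 4.

**Aβ detection.**  The three listed operations are ordered top-hat →
Mexican-hat → threshold: background removal must precede band-pass
filtering.  The structuring-element radius (10 px ≈ 5.7 μm, larger than
expected aggregates, smaller than vessels) and the Mexican-hat σ (2 px)
are not stated by the original protocol; they are exposed in the
configuration and not claimed to match the original macro.  The Mexican
hat is the negated, σ²-normalised Laplacian of Gaussian, computed with a
wide kernel (truncate = 8σ) so flat regions map to ≈ 0.  Thresholding is
applied to the filtered response (Otsu default; fixed and quantile
overrides); component sizes, centroids and mean intensities are recorded,
the mean intensity from the raw Aβ channel.  Adding a constant offset to
the input leaves detections unchanged (the top-hat removes it).

**Measures and preprocessing.**  Coverage is the percentage of wall pixels
overlapped by the detected Aβ mask.  Compartment assignment uses a strict
pixel majority (ties → extramural); the original report does not define
the boundary case, and an any-overlap rule is available.  The 20-fold
outlier rule is implemented iteratively — remove the largest value while it
strictly exceeds 20× the next largest — which is deterministic, idempotent,
and reduces to single removal when only one extreme exists.  Images with
zero detected arterioles are excluded from arteriole-level analyses (their
intramural/extramural split is untrustworthy); exclusions are logged.

## The two mixed models

Let y_i be the response of unit i in image j(i) of mouse m(i), with group
x_i ∈ {0, 1}, and u_m ~ N(0, σ²_mouse), v_j ~ N(0, σ²_image) independent.

*Zero-inflated Beta* (coverage as a proportion): with probability
π = logistic(γ₀) the response is exactly 0; otherwise
y ~ Beta(μφ, (1−μ)φ) with logit μ = β₀ + β₁x + u + v.  The zero part is
intercept-only by default (whether group enters it is not stated in the
design this mirrors; a group term is available by option).  Nonzero
responses are mapped into (0, 1) by the Smithson–Verkuilen squeeze
y′ = (y(n−1) + 0.5)/n with n the number of nonzero responses, so full
coverage has finite likelihood; at the sample sizes involved this moves
values by < 0.5%.

*Tweedie* (aggregate size): y follows the compound Poisson–gamma law with
mean μ, dispersion φ and power p ∈ (1, 2) (variance φμᵖ), log μ = β₀ +
β₁x + u + v.  The density at y > 0 is the standard series over the Poisson
count, summed in log space over a window around the dominant index
y^(2−p)/(φ(2−p)) wide enough for double precision (capped at 5000 terms, a
region far outside any fit optimum).  In exponential-dispersion form the
series factor is mean-free, so it is computed once per outer parameter
value rather than per inner Newton step.

**Marginal likelihood.**  The likelihood factorises over mice; per mouse
the (1 + J)-dimensional integral over (u, v₁..v_J) is approximated by
Laplace expansion at the penalised-likelihood mode, found by damped Newton
iterations batched across mice (unbalanced designs are padded with empty
image slots, whose Gaussian factors integrate to one exactly, so padding
is lossless).  Newton stops when the gradient infinity-norm falls below
1e−8 or the step/decrement reach solver precision.  When both random-
effect SDs are zero the likelihood is evaluated exactly with no integral.
Accuracy: against nested adaptive Gauss–Hermite quadrature on small
fixtures the Laplace value agrees to ~1e−4 relative at σ ≈ 0.1; the
approximation error grows with σ² and with non-Gaussianity of the
per-cluster likelihood, reaching ~1e−2 relative in weakly-informative
Beta regimes (few observations, small φ).  That is a property of the
Laplace approximation itself, shared by the standard mixed-model tools
for these families, not of this implementation.

**Optimisation and inference.**  Variance components are parameterised as
log-SD and the Tweedie power by logit(p−1), hard-bounded to (1.05, 1.95):
toward p → 1 the compound law degenerates to a lattice and the series
likelihood of continuous data turns rugged.  The power is initialised by a
coarse profile over {1.2, 1.4, 1.6, 1.8} and refined jointly.  The outer
maximiser is L-BFGS-B from moment-based starts with optional random
restarts (default 3; the simulation studies use 1, where the moment
initialisation is reliable).  Standard errors come from the inverse of a
central finite-difference observed information evaluated with cold inner
starts (warm-started evaluations are path-dependent at the 1e−9 level,
enough to corrupt second differences).  Bound-pinned nuisance parameters
and collapsed variance components (σ̂ < 0.01) span flat or one-sided
directions and are profiled out of the information and out of the
gradient-norm convergence diagnostic; the gradient tolerance scales with
|log L| since gradient magnitudes grow with the data size.  A fit that
fails these diagnostics is still returned, flagged `converged=False`, and
refuses to produce marginal means.

**Estimated marginal means.**  Random effects at zero; for the Tweedie
model the group mean is exp(β₀ + β₁g) with a log-scale delta CI.  For the
zero-inflated Beta the default is the overall mean (1−π)μ with the delta
CI on its log (the conditional Beta mean with a logit-scale CI is an
option); whether published marginal means for such models are conditional
or overall is often unstated — overall is this package's default.  Wald
p-values are two-sided with no multiplicity correction (α = 0.05), matching
the analysis convention emulated here.

## Synthetic data

*Tabular.*  `simulate_zib_dataset` / `simulate_tweedie_dataset` draw
mouse and image intercepts from their Gaussians and responses exactly from
the families above, at the study design (2 groups × 5 mice × ~10
images/mouse).  Default generative values: coverage β₀ = −2.0 (mean
≈ 12%), β₁ = −0.24, φ = 3, γ₀ = −0.4 (≈ 40% zeros); intramural size β₀ = 3.0
(≈ 20 px), β₁ = −0.56, φ = 2, p = 1.6; extramural β₀ = 1.6, β₁ = −0.48.
The group effects sit at the magnitudes the emulated study reported — they
make the synthetic studies resemble the real one, not reproduce it.  The
random-intercept SDs (σ_mouse = 0.35, σ_image = 0.3) were set by matching
the information content implied by the published group-effect SE (≈ 0.23
with 5 mice per group); φ = 3 reflects the very large per-vessel dispersion
implied by a 3.38% median with a 14.9% IQR.

*Scenes.*  `render_synthetic_image` draws arterioles as annuli co-positive
in both stains with unstained lumina (outer diameter 12–40 μm, wall 2–5
μm — every qualifying annulus rasterises to ≥ 150 px so threshold tests are
meaningful), capillaries as constant-width tubes along smoothed random
walks (3.5 μm wide), and aggregates as Gaussian blobs whose ground-truth
extent is the half-maximum footprint (differentiable size control).
Structures are placed without overlap by rejection sampling; optional
distractors (gap-cut rings, solid disks, sub-150-px ringlets) exercise the
classifier's rejection rules.  Axial structure is a triangular intensity
profile across 5 planes peaking at 1, so the pre-noise maximum projection
equals the 2-D scene exactly; Gaussian background and photon-like Poisson
noise are added last, after the truth masks are frozen.  In pipeline
studies the treatment group's scenes scale aggregate sizes by
exp(β₁,intramural), carrying a group effect through the full image chain.

*What the scenes do not emulate:* optical point-spread blur, tissue
autofluorescence, photobleaching, staining heterogeneity, or touching
vessels.  Passing the zero-noise recovery suite therefore demonstrates the
correctness of the classification logic and thresholds, not robustness to
real acquisition artefacts.

## Simulation studies and their scale

The recovery study simulates 2 × 5 mice × 5 images × 10 units (500
observations), refits with one quasi-Newton start, and summarises
group-effect bias, 95% Wald CI coverage and (under β₁ = 0) type-I error.
The shipped test and acceptance runs use 50 replicates per condition; the
per-replicate tables are written so larger runs are a one-line change.

A finding worth stating plainly: at this design scale the Wald intervals
undercover (≈ 0.82–0.92 observed instead of 0.95) and the null rejection
rate runs above 0.05.  The cause is visible in the replicate tables —
with 5 mice per group and a mouse-level SD comparable to the per-mouse
standard error, the ML variance components are often estimated at zero,
and the Wald SE then omits real between-mouse variance.  glmmTMB fitted to
the same replicates shows the same behaviour, with per-dataset agreement
of estimates and SEs to ≥ 4 decimals; it is a small-sample property of
Laplace-ML Wald inference in this regime, not an implementation artefact.
Bias of the group-effect estimate itself is small (|bias| ≲ 0.05 for the
coverage model, ≲ 0.03 for the size model).

## Known limitations

* 2-D analysis of maximum projections; no 3-D vessel tracing or blob
  detection, no spectral unmixing, no sub-pixel localisation.
* Veins are not distinguished; leptomeningeal vessels are out of scope.
* The Tweedie power is restricted to (1.05, 1.95); data that genuinely
  prefer quasi-Poisson behaviour stop at the lower bound (reported in the
  fit's variance components).
* Wald inference with ≤ 5 clusters per group should be read with the
  undercoverage caveat above; a parametric bootstrap would be the natural
  extension.
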