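# Methods

This note documents the models, parameter choices, and numerical decisions
behind octmorph, and what the synthetic validation does and does not
establish about real data.

## Synthetic cohort generator

The generator is the package's study-conditions module: its defaults are the
cohort the analyses are validated on, not tuning knobs.

**Demographics.** 444 subjects; ages drawn uniformly within four buckets
([21,40), [40,60), [60,80), [80,88]) with weights 51:212:161:8; sex
Bernoulli with 281/444 female; each subject contributes both eyes with
probability 411/444 (expected 855 eyes, one eye otherwise, laterality
random); scan focus ~ N(0, 1.5 D) as an axial-length proxy covariate;
fixation offset uniform in a 0.3 mm disc, so fovea localization is always
exercised without leaving the scanned raster.

**Layer effect models.** Each layer's whole-macula mean follows
μ + b₁(age−40) + b₂(age−40)² + β_sex·isMale + β_sf·scanFocus + γ·μ/μ_TRT.
Reference means μ are derived as (absolute coefficient)/(percent
coefficient) ratios of the encoded effect table (the study prints both
scales but not the group means); the five layer means are renormalized by a
common factor (0.9970) so they sum exactly to the TRT reference mean
309.52 μm. Age effects per decade: RNFL +0.22 (linear), GCIPL −1.77 (quad),
INL −0.45 (quad), ONPL −0.66 (linear), ELM-BM −0.45 (quad); sex effects
−0.03 / +0.57 / +0.87 / +1.80 / +0.93 μm. For quadratic layers the
curvature is fixed at 10% of the combined effect (b₂ = c/400 per yr²,
b₁ = 0.9c with c the combined per-year change over ages 40–80), so the
yearly slope varies ±10% around the combined value across that range. The
generated TRT effects are the layer sums: age −3.11 μm/decade
(≈ −1.00%/decade) and sex +4.14 μm — the printed per-layer coefficients do
not sum exactly to the printed TRT age coefficient (−3.25) because of table
rounding; layer additivity wins, and both values sit well inside the TRT
CI. Because the curvature is small relative to the calibrated noise, the
AIC step usually selects the linear form at n = 444; the combined-effect
reporting makes linear and quadratic fits directly comparable, so this has
no practical consequence.

**Noise calibration.** Subject random intercept sd 14 μm and eye-level
residual sd 6 μm on the TRT scale, chosen so the TRT marginal R² lands near
8%; both are applied proportionally (× μ_layer/μ_TRT) to the five layers
through one shared draw per subject/eye, which preserves additivity exactly.
The other layers' R² are then whatever proportionality implies (GCIPL ≈
30–40%): only TRT is calibrated, by design.

**Radial layer templates.** The five layers are fixed radial shapes scaled
per eye so the whole-macula mean matches the effect model. Shapes are
synthetic but anatomically structured: inner layers (RNFL, GCIPL, INL) rise
sigmoidally from near zero (< 1 μm inside r < 0.3 mm) to annular maxima
around 0.8–1 mm with mild exponential decay; ONPL carries a flat-topped
central peak (1 + 0.8·exp(−(r/1.15)⁶)); ELM-BM is near-flat. The flat ONPL
top keeps the template TRT's minimum at the foveal center to within
~0.01 μm, which the σ = 0.15 mm localization smoothing resolves correctly.
Templates are normalized to mean 1 over the 3 mm disc (20 000-point radial
quadrature, ~1e−8 accurate).

**Pit mode.** For foveal analyses the TRT is a parametric pit surface
T(r,θ) = CFT + (RH(θ) − CFT)·g(r/RR(θ)), g(u) = u^a·exp(a(1−u)) with shape
a = 2 (g(0) = 0, g(1) = 1, unique maximum at the rim). Rim radius and rim
height carry cos(2θ) modulations (+10% and +2% horizontally), making the
pit broader in the horizontal plane. Per-eye CFT, rim height and rim radius
follow their own effect models (reference 230.26 / 350.81 μm, 1133.6 μm;
age −1.44 / −3.42 μm/decade quadratic, −7.66 linear; sex +7.99 / +8.63 /
−59.4 μm) with noise sds (subject/eye) 18/9, 15/7.4, 90/42 μm calibrated so
the marginal R² and CI widths of the fitted models match the encoded table.
The subject-level components share one standard-normal draw with the
thickness intercept — a thicker retina raises CFT and rim height together —
which also keeps the emergent mean-slope dispersion realistic (~0.8°). The
mean slope is *not* injected directly: it emerges from the geometry; with
the default parameters the implied sex difference is ≈ +0.3°, inside the
encoded CI. Layer fields in pit mode are the template shares of the pit TRT
(so TRT = Σ layers holds identically); pit-mode cohorts are used only for
foveal analyses. Degenerate draws are guarded: rim height is kept ≥ CFT +
20 μm and rim radius clipped to [0.2, 2.0] mm (both ~1e−5 probability at
default noise).

**Generation modes.** *Raster mode* evaluates the truth on the device
raster (25 × 512 standard, 97 × 1024 high-resolution over 6 × 6 mm) with
the fixation offset and OS x-mirroring applied in the device frame — the
full-fidelity path, used by the sensitivity analysis and small-n tests.
*Grid mode* evaluates the truth directly on the analysis grid extended by
15 nodes per side with the offset snapped to the grid lattice; recentring is
then an exact crop, and template normalization uses the discrete node mean
over the analysis disc so whole-macula means recover the targets exactly in
the noiseless limit. Grid mode makes full-cohort runs cheap (~1 min for 855
eyes including model fits) and is used for the large parameter-recovery
experiments.

## Mapping and sectorization

The analysis grid covers the 6 × 6 mm scanned field with 300 × 300 nodes
(0.0201 mm spacing): the nominal description "300 × 300 at 0.1 mm" is
internally inconsistent (it would span 30 mm), and the field extent wins
over the nominal spacing; the run manifest records this deviation.
Interpolation is piecewise-linear on the Delaunay triangulation (exact on
affine fields, no overshoot, no extrapolation outside the convex hull); one
triangulation per scan serves both fovea localization and mapping.
Fovea localization interpolates TRT to a coarse 0.05 mm grid, smooths with
an isotropic Gaussian (σ = 0.15 mm, truncated at 3σ, mask-normalized around
missing nodes), and takes the arg-min in the central 2 × 2 mm window; ties
break by distance to the raster center, then lexicographically. On grid-mode
scans a 3-point parabolic refinement per axis precedes snapping to the
offset lattice (the 300-node axis has no node at 0, so the arg-min node
alone is ambiguous by half a spacing).

Sector conventions: ring boundaries belong to the inner region; diagonal
boundary nodes are assigned with priority nasal > superior > inferior >
temporal; ETDRS outer sectors use only nodes within the 3 mm circle (the
map is a 6 mm square); a 20 × 20 cell is retained iff its center lies within
the 3 mm circle (316 cells; 300 for RNFL/GCIPL/INL after excluding the
central 1.2 × 1.2 mm block, where near-zero inner-layer thickness makes
means segmentation-noise-dominated). The node-weighted mean of retained TRT
cells equals the whole-macula mean on the same node mask exactly — a
conservation identity the tests assert at 1e−12.

## Foveal pit morphometry

LOESS uses the nearest ⌈span·n⌉ = 11 of 21 points, tricube weights on
distance scaled by the window radius (the farthest neighbour gets weight 0),
and a local quadratic — chosen because the rim is a curvature feature, so
smooth peaks are reproduced with O(h⁴) bias; on exactly quadratic profiles
smoothing is an identity to 1e−9. With fixed radii and no missing data the
smoother is linear, so a cached 21 × 21 matrix serves all directions; a
brute-force per-point weighted-least-squares oracle verifies it to 1e−9.
The rim is the arg-max of the smoothed profile over r > 0 with ties broken
toward the center (nearest anatomical rim); an arg-max at r = 2.0 mm flags
the result `rim_at_boundary`. CFT is the *raw* center value, and the mean
slope averages pointwise atan(ΔT/Δr) forward differences of the *raw*
profile between center and rim: degree units imply per-step angles, and
with the default geometry this yields ≈ 6.2°, consistent with the encoded
percent normalization. Rim radius is quantized to the 0.1 mm radial step;
across a noisy cohort the quantization dithers out and regression recovers
sub-step effects (e.g. the −59 μm sex difference), but a single noiseless
eye cannot resolve it — which is why the noiseless-exactness guarantee is
stated at the parameter level (below).

## Effects estimation

All fits are ML, not REML: AIC comparisons and likelihood-ratio tests
across fixed-effect structures require it. Age is centered at 40 before
fitting (de-correlates linear and quadratic terms); coefficients are mapped
back to the raw scale for reporting. The combined age effect is the mean
yearly change between 40 and 80 (β_age + 120·β_age2, = b₁ + 40·b₂
centered), reported × 10; its CI is Wald with normal quantiles on the
linear combination. The combined age p-value for quadratic fits is a 2-df
likelihood-ratio χ² against a no-age model — used in place of an exact
F-test, whose denominator df are ill-defined for mixed models; a
20 000-replicate null study puts its type-I error at 0.052–0.054 for
150–450 subjects. Percent transforms divide by young-group (age ≤ 40)
means — the boundary is inclusive — and rescale the CI bounds by the same
factor. Holm corrects the whole-macula families (6 layers × 2 factors;
4 pit parameters × 2); Benjamini–Hochberg corrects sector maps, where tests
are many and spatially dependent.

Two fitting engines expose the identical model: statsmodels MixedLM (the
default) and an exact profiled-ML path that exploits the single-random-
intercept structure (V = σ²(I + θJ) lets both the GLS coefficients and σ²
profile out, leaving a 1-d likelihood in θ). The profiled engine is ~50×
faster and powers large simulation studies (the 1000-replicate calibration
test runs in seconds); a test pins the two engines together to ~1e−6 on
coefficients and log-likelihood.

## Sensitivity analysis

Both eyes of 12 subjects are imaged under both protocols from the same true
surface and fixation offset, with independent eye-level measurement noise
per acquisition (no session drift or re-registration is modelled); the bias
model is y = β₀ + β_bias·isStandard + γ_subject with a Wald CI, and percent
bias = β_bias/β₀. With the default pit geometry the standard protocol
inflates CFT by ≈ +3% and depresses the mean slope by ≈ −5 to −7% while
whole-macula layer means stay within ±0.5% — the interpolation-across-the-
minimum signature. The *magnitudes* depend on the true foveal sharpness,
which the parametric pit only stands in for; they are treated as
sign/robustness properties, not numeric targets.

## Validation design and problem sizes

- Parameter recovery runs the full pipeline on default-size cohorts
  (444 subjects, ~855 eyes) in grid mode; the test suite uses 3 seeds and
  requires each headline estimate inside its reference 95% CI in ≥ 2 of 3.
- Noiseless-limit exactness (< 1e−3 on every injected coefficient) is
  asserted on the generator's true parameter table (120 subjects), which is
  the correct reference given the imaging quantizations above.
- The type-I calibration study uses 1000 replicates of 200-subject null
  cohorts; the sensitivity suite uses one 12-subject paired run.

## What passing does and does not show

The generator emulates scattered raster sampling, fixation error, eye
laterality, inter-eye correlation, and realistic radial thickness
structure. It does not model speckle or per-A-scan measurement noise,
segmentation errors, nasal–temporal asymmetry (fields are radially
symmetric up to the cos 2θ pit modulation), ocular magnification / lateral
scaling, or session-to-session drift. Passing therefore demonstrates that
the pipeline's geometry, smoothing, and statistics are correct and
well-calibrated under known ground truth — not that segmentation-driven or
optics-driven biases in real scans are absent. Known limitations: the ETDRS
quadrant boundary rule introduces sub-0.05 μm asymmetries between quadrants
of symmetric fields; duplicated-eye fits agree with single-eye fits to
~1e−5 (optimizer tolerance at the zero-residual-variance boundary); rim
radius is measured on a 0.1 mm lattice.
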