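# octmorph

Spatial morphometry of the macula from segmented OCT: layer thickness maps
with whole-macula / ETDRS / 20 × 20-grid sectorization, radial foveal-pit
geometry, and mixed-effects normative modelling of age and sex effects —
exercised end to end on a synthetic segmented-OCT cohort generator whose
defaults encode a published normative study's demographic structure (444
subjects, 855 eyes, ages 21–88, 63% female) and effect sizes, so every
effect estimate is a parameter-recovery experiment with known ground truth.

## Who it is for

Researchers building or validating macular normative pipelines: the package
provides the full analysis chain (alignment → interpolation → sectorization
→ pit morphometry → regression) plus a ground-truth generator, so each stage
can be tested against closed-form oracles and the whole pipeline against the
coefficients it was fed.

## The model

Per eye, six thickness fields are analyzed: total retinal thickness (TRT)
and five layers (RNFL, GCIPL, INL, ONPL, ELM-BM), with TRT ≡ the layer sum
at every sample. Scans are aligned on the foveal center (arg-min of a
Gaussian-smoothed TRT map, σ = 0.15 mm), left eyes are mirrored into the
right-eye frame (+x nasal, +y superior), and scattered A-scan samples
(25 × 512 or 97 × 1024 over 6 × 6 mm) are triangulated and linearly
interpolated to a 300 × 300 grid.

Foveal pit geometry comes from the TRT on a radial grid (24 directions ×
21 radii, 0–2 mm): per direction, LOESS smoothing (span 50%, local
quadratic, tricube weights) precedes the rim search; the pit descriptors are

- CFT — raw TRT at r = 0 (μm);
- rim height — max of the smoothed profile over r > 0 (μm);
- rim radius — its radial position (mm);
- mean slope — mean of atan(ΔT/Δr) over the raw profile from center to rim
  (degrees, ΔT converted μm → mm).

Every parameter y (layer × sector mean or pit metric) is modelled with
eye-level observations and a subject random intercept γ:

    y = β₀ + β_sex·isMale + β_age·age [+ β_age2·age²] + β_sf·scanFocus + γ + ε

fitted by maximum likelihood; AIC picks linear vs quadratic age. Results are
reported as the combined age effect — the mean yearly change between ages 40
and 80, β_age + 120·β_age2, × 10 per decade — with Wald CIs; the quadratic
model's age p-value is a 2-df likelihood-ratio test against a no-age model.
Percent effects divide by young-group (age ≤ 40) means (young females for
sex effects). Whole-macula families use Holm correction (12 thickness tests,
8 foveal tests); sector maps use Benjamini–Hochberg. Marginal R² =
var(Xβ) / (var(Xβ) + σ²_γ + σ²_ε).

A paired sensitivity analysis re-images the same true surfaces under both
raster protocols and fits y = β₀ + β_bias·isStandard + γ, exposing the
undersampling bias of the 25-B-scan raster (inflated CFT, flattened slope).

## Worked example

`examples/03_foveal_pit_morphometry.py` builds a noiseless parametric pit
(CFT 230.3 μm, rim height 350.8 μm, rim radius 1.134 mm, broader
horizontally), samples it radially and extracts the pit descriptors:

```
per-direction rim geometry (0 deg = nasal, counterclockwise):
      0 deg: rim height  357.6 um at 1.20 mm, slope 6.03 deg
     90 deg: rim height  343.7 um at 1.00 mm, slope 6.44 deg
    180 deg: rim height  357.6 um at 1.20 mm, slope 6.03 deg
    270 deg: rim height  343.7 um at 1.00 mm, slope 6.44 deg

whole-macula aggregate (mean of 24 directions):
  CFT         230.44 um   (true 230.3)
  rim height  350.70 um   (true 350.8)
  rim radius   1.117 mm   (true 1.134)
  mean slope    6.14 deg
```

The aggregate recovers the generator's geometry to a fraction of a μm
(rim radius to the 0.1 mm radial step), and the horizontal directions show
the broader rim the generator injects. `examples/04_age_sex_effects.py`
continues to the regression stage on a 120-subject cohort:

```
parameter model_form  beta_age_pct_per10y  beta_sex_abs  p_age  p_sex_adjusted
    GCIPL     linear               -2.684         1.209  0.000           0.160
      INL     linear               -1.640         1.168  0.000           0.001
      TRT     linear               -1.358         6.828  0.000           0.048
...
```

i.e. a GCIPL loss of ≈ 2.4%/decade driving a TRT loss of ≈ 1%/decade, and a
thicker male retina — the effects the generator encodes.

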