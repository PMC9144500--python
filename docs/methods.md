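# Methods

## Measurement model

### Particle sizing

Dispersion micrographs (polarized light, 3.3 px/µm at 200×
magnification) are converted to 8-bit grey with the BT.601 luma weights
(`round(0.299R + 0.587G + 0.114B)`), thresholded at ≥ 80 grey values
(inclusive), and labelled with 8-connectivity.  The Feret diameter of a
component is the maximum caliper width of its pixel-corner polygon:
every foreground pixel contributes its four corners, and the diameter
is the largest pairwise corner distance (computed over the convex
hull; a single pixel measures √2 px).  This matches the de-facto
convention of common particle-analysis tooling; a pixel-centre
convention is available via `corner_polygon=False`.  Components whose
area-equivalent diameter `2·√(area/π)` is below 0.4 µm are excluded as
optical artefacts — the filter is deliberately applied to the
area-equivalent diameter, not the Feret, so elongated single-pixel
noise cannot survive on caliper length alone.  Mean Feret is reported
both pooled over all particles and as a mean of per-image means; the
two coincide for balanced designs.

The two printed pixel scales (3.3 for dispersions, 2.84 for skin
sections, both at 200×) are interpreted uniformly as px/µm.  Under the
inverse reading (µm/px) a single pixel would already span 3.3 µm and
the 0.4 µm artefact filter could never exclude anything, so the px/µm
reading is the only self-consistent one.  Scale is always a parameter,
never hard-coded.

### Penetration read-outs

The skin surface is detected per column as the topmost row whose grey
value exceeds the background level (estimated from the top 30 rows)
plus 5 estimated noise SDs, then median-smoothed over 15 columns.  All
depths are referenced to this line, which makes every read-out
invariant to vertical placement of the section in the frame.

The dye mask implements autofluorescence subtraction as green
dominance: a pixel belongs to the fluorescein signal iff `G ≥ g_min`
(default 50) **and** `G − max(R, B) ≥ margin` (default 20).  Skin
autofluorescence is broadband (here modelled bluish with weak green),
so it never satisfies the margin; fluorescein emission is strongly
green-dominant.  Both parameters are exposed in `RunConfig`.

* **ART** (MGV/px) = sum of green values over `mask ∧ tissue` divided
  by the tissue-ROI pixel count.  Unstained tissue pixels count in the
  denominator, so ART grows with both stained area and intensity — the
  behaviour required of a penetrated-amount surrogate.  The ROI is the
  tissue (below-surface) region; a full-frame denominator is available
  by passing a different ROI.
* **Depth** (µm) = maximum surface-referenced depth over the dye mask
  after removing components smaller than 3 px (despeckle).  The
  maximum emulates a manual "deepest visible signal" reading; a
  99th-percentile mode is provided for speck-heavy material.  MPD is
  the mean of per-image depths ± SD.
* **SCT** (µm) = per column, the contiguous run of rows from the
  surface whose brightness stays above a threshold midway between the
  SC-band median (sampled 1–8 px below the surface) and the
  deeper-tissue median (sampled at 70–90 % of the tissue extent);
  image SCT is the column median.  Relative SCT = 100 ×
  mean(treated)/mean(control).
* **QC**: sections with TEWL strictly above 15 g/cm²/h are excluded
  from summaries and statistics but still quantified and reported.
  The unit is used exactly as printed by the source instrument
  convention.

### Statistics

Per measure, groups pass Shapiro–Wilk (per group, matching the
sequential test protocol; not on pooled residuals) and mean-centred
Levene.  All normal + homoscedastic → one-way ANOVA with Tukey HSD;
normal + heteroscedastic → Welch ANOVA with Games–Howell; otherwise
Kruskal–Wallis with Dunn's rank test.  Dunn is implemented in-package
(pairwise z on mean ranks with tie correction); for two groups its z²
equals the Kruskal–Wallis H, which the tests use as an independent
cross-check.  Dunn's raw p-values get Holm adjustment by default
(Bonferroni or none are selectable); Tukey and Games–Howell are
inherently multiplicity-adjusted.  With exactly two groups the omnibus
test is the two-sample test itself (t / Welch-t / Mann–Whitney), so
omnibus and pairwise p coincide.  Significance is inclusive at the
boundary (p ≤ 0.05), following the star convention
(\*\*\* ≤ 0.001, \*\* ≤ 0.01, \* ≤ 0.05); type-I calibration of the
full route is verified by simulation (≈ 5 % on three identical normal
groups, 1000 studies).  Formulation clusters are the connected
components of the graph joining pairs with p > α.

## Synthetic micrographs

The generator emulates the features the pipeline keys on, with
bit-exact reproducibility from `(inputs, seed)`.

**Skin sections** (default 768 × 1024 px at 2.84 px/µm): dark
background (level 8); a surface row uniform in rows 40 … H/4; a bright
SC band (RGB ≈ (110, 90, 90), times a smooth multiplicative texture
field) of thickness 40 µm × `sct_factor`; textured tissue
autofluorescence below (channel fractions 0.9/0.5/1.0 of
`autofluor_level` = 40, i.e. bluish with weak green); additive green
dye; Gaussian noise (σ = 6) per channel.  The SC band's green channel
is constructed with the *same* green deficit (−0.5 × autofluor level)
as the deeper tissue, so the dye mask behaves identically inside and
below the band — without this the masked area would depend
discontinuously on the dye amplitude.

The dye amplitude ramps linearly from a calibrated surface value `D₀`
to a fixed edge value (60 grey units) and then falls to zero across a
front transition of width 5 µm **centred on the programmed depth**.
Centring is deliberate: a transition placed entirely beyond the
programmed front would bias every thresholded depth read deep by a
fixed amount, leaving the ground-truth depth ill-defined under
thresholding.  With the centred front the deepest above-threshold
pixel is unbiased around the programmed depth for any mask cut near
half the edge amplitude.

`D₀` is solved in closed form so that the expected masked green
integral — ramp, masked-tissue autofluorescence, and the SC band's
green excess — is proportional to the preset's relative amount
(`ART_GAIN` = 6885 grey·µm per amount unit, fixing the control preset
at `D₀` = 90).  Fold changes measured by ART therefore recover the
programmed amount ratios on expectation.  Presets whose amount/depth
combination would push `D₀` below the edge amplitude are rejected
rather than silently mis-calibrated.

Between-replicate biological variability is modelled as Gaussian CVs
(depth 8 %, amount 10 %, SCT 4 %, truncated at ±3 SD), applied per
image: the realized depth stretches the profile, the realized amount
scales it, and the realized per-image truth is returned alongside the
image.  The study-style spread (MPD ± SD) and non-degenerate
normality tests both depend on this spread; the CVs were fixed once at
values typical for ex vivo porcine-skin work.

**Particle dispersions**: bright convex blobs (grey 200 on background
10, σ = 5 noise) placed without contact; a blob is a single ellipse
(aspect 0.6–0.95, random orientation) or, with probability
`agglomeration`, a chain of 2–3 overlapping ellipses spanning the
target extent.  Target diameters are lognormal with the preset's
mean/SD, floored at 0.6 µm so the generated population and the
post-filter measurement describe the same particles.  Because a
continuous ellipse rasterized by pixel centres and measured over pixel
corners gains ≈ 0.7 px of caliper, the continuous geometry is shrunk
by that amount; the returned truth is the exact pixel-corner Feret of
each rendered blob.  The two registered dispersion presets encode the
study arms: water (mean 3.84 µm, SD 2.3, agglomeration 0.30) and
surfactant (mean 2.98 µm, SD 1.3, agglomeration 0.05).

**Studies**: a design of `(label, preset, n)` arms; per-record child
seeds derive from one master seed; synthetic TEWL values are drawn so
a configured fraction (default 10 %) violates the 15 g/cm²/h limit,
with a bookkeeping flag for QC cross-checks.

### What the generator does not model

No hair shafts, cryotome chatter, folds, or uneven illumination; no
follicular pathway; no 3-D tissue structure; no absolute
concentration-to-intensity calibration (the linear amplitude model is
a stand-in, not a claim about fluorescein photophysics).  Passing
recovery tests therefore demonstrates that the *measurement chain* is
correct and internally consistent, not that it is robust to every real
histology artefact.

## Problem sizes and numerical choices

Unit tests run on 576 × 640 px frames (tall enough for the deepest
front with 3-SD jitter); recovery checks use 20 replicates per arm at
the default 768 × 1024 px frame, and the end-to-end study uses the
six-arm design (20 images per arm) across 20 master seeds on the
smaller frame.  Degenerate arms (zero variance, e.g. untreated depth
≡ 0) are summarised but omitted from omnibus statistics, where
normality tests are undefined; the reference arm for fold changes and
relative SCT defaults to the first arm of the design.  Ties in
Mann–Whitney/Dunn use mid-ranks with tie-corrected variances; empty
dye masks yield depth 0 and ART 0; an empty tissue ROI, a missing SC
band, or an undetectable surface raise errors rather than returning
placeholders.
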