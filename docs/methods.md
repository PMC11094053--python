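# Methods

## Phantom model

A scan is a stack of `n_slices` parallel short-axis slices imaged over
`n_phases` cardiac phases (default 30) on an `N x N` grid with isotropic
in-plane spacing (default 0.4 mm) and slice thickness 6 mm. Each labeled
slice carries a circular blood pool of end-diastolic radius `r_s` (pixels,
per slice; a mild apical taper is used in the study cohort) surrounded by a
myocardial annulus of constant thickness `w`. The cavity radius follows a
piecewise-cosine contraction profile: phase 0 is end-diastole, the minimum
sits at `floor(0.4 * n_phases)`, and the radius at end-systole is
`r_s * (1 - f)` for contraction fraction `f`. The profile has a single
minimum, so extremum-based ED/ES selection is well posed, and the analytic
volumes follow in closed form (`V = sum_s pi r_s^2 dz`), giving
`EF = 100 * (1 - (1 - f)^2)` independent of slice radii.

Rasterization rule: a pixel belongs to a region when its center lies inside
the continuous boundary. `empty_slice_margin` slices at each end of the
stack are emitted with empty masks, emulating basal/apical slices without a
labelable ventricle. Papillary muscles, when enabled, are rendered as
intensity features inside the cavity but never labeled — they belong to the
blood pool by the segmentation convention adopted here.

Infarct morphology is sector wall thinning: inside an angular sector the
wall thickness becomes `w * (1 - thinning)` on the affected slices, the
cavity untouched. The analytic mass correction uses the continuous sector
geometry.

### Image degradation

The three-criterion quality rating (artefacts, noise, general image
quality; each 1 = best to 4 = worst, total 3–12) drives three degradation
channels; a score of 1 leaves its channel off and each step increases the
strength monotonically:

- noise: additive Gaussian, SD `0.03 * (score - 1)` in intensity units;
- artefacts: multiplicative low-frequency sinusoidal shading bands
  (amplitude `0.10 * (score - 1)`, random orientation/frequency/phase),
  a stand-in for the B0/B1 field-inhomogeneity patterns seen at ultra-high
  field — the shading model is not a claim of physical fidelity;
- general: Gaussian blur, `sigma = 0.35 * (score - 1)` px. The step is
  deliberately small relative to the phantom wall (~4–7 px): on this grid a
  real-scale blur would render score-3 images nondiagnostic, whereas the
  rating defines score 3 as "affects delineation" and reserves
  nondiagnostic for score 4.

Degradation acts on intensities only; ground-truth masks are untouched by
construction.

### Synthetic observers

Repeat readings and a second observer are synthesized by perturbing the
ground-truth boundaries: the signed distance to each boundary is offset by a
smooth Gaussian random field (correlation length ~4 px) scaled to an SD of
`magnitude` pixels and re-thresholded. Local over- and under-segmentation
partially cancel across the boundary, as they do between human readings.
Defaults: 0.5 px for the repeat reading, 1.0 px for the second observer,
which reproduce the expected ordering (intra-observer agreement tighter than
inter-observer) with ICCs and CoVs in plausible ranges.

What the generator does **not** emulate: k-space acquisition or MR physics,
ECG gating and arrhythmia effects, through-plane motion, anatomical
asymmetry of the ventricle, trabeculation, or systematic observer bias
(synthetic observers are unbiased by construction). Passing tests therefore
demonstrate the correctness of the measurement and statistics machinery on
controlled geometry, not segmentation performance on real animals.

## Segmentation network and transfer schedule

Because the package targets a CPU-only desk scale, the network is a small
encoder–decoder written directly in numpy: conv3x3(1→c) → avgpool2 →
conv3x3(c→2c) → nearest-upsample2 → skip-concat → conv3x3(3c→c) → conv1x1
head over 3 classes, ReLU activations, He initialization (default c = 8,
input 64 px in the study; the preprocessing operation scales arbitrary
frames to the model size, masks by nearest-neighbor). Forward and backward
passes are explicit and verified against finite differences in the tests.

Training minimizes a soft Dice loss (per-class soft overlap of the softmax
maps, summed over the batch, averaged over the three classes; empty-mask
frames participate exactly as labeled) with Adam under a one-cycle
learning-rate policy capped at the schedule's `max_lr` (linear warmup over
the first 30% of steps to the cap, then cosine decay — any monotone warmup
satisfying the cap would do; this one is fixed and documented).

The transfer schedule is two-step: a *frozen* phase trains only the final
parameter group (the 1×1 head) for `frozen_epochs` at `frozen_max_lr`;
the checkpoint with the highest validation Dice seeds the *unfrozen* phase,
which trains all parameters at `unfrozen_max_lr`. Checkpoints are recorded
every `checkpoint_every` epochs with their validation Dice; the selected
model is the checkpoint with the overall highest validation Dice.
Validation Dice is the mean over the two foreground classes per image, with
(image, class) pairs empty in both reference and prediction excluded.
Schedule defaults on the `TrainSchedule` type are the full-scale values
(100 + 100 epochs, max rates 1e-4 / 1e-5, checkpoints every 10); the study
configuration scales them down to 10 frozen + 30 unfrozen epochs at
1e-2 / 1e-2 with checkpoints every 10, sized for a single CPU.

"Transfer" is emulated by pretraining the same architecture on a clean
phantom distribution and fine-tuning on the study's degraded cohort; no
pretrained third-party weights are involved.

Intensity normalization is a config option. The study uses `"center"`
(per-frame mean shift only): per-frame contrast stretching ("minmax",
"zscore") would amplify the noise of empty basal/apical frames to full
scale and make the model hallucinate tissue there, while a common shift
keeps all frames on one intensity scale. On clean phantoms (no noise)
min-max works equally well and is the preprocessing default. Batch size
defaults to 8.

## Contours and the CON-TXT dialect

Boundary extraction traces the 0.5 iso-contour of the binary region
indicator (cavity for the endocardium, cavity ∪ myocardium for the
epicardium) after hole filling; with multiple connected components the
largest is kept and the event logged. Rasterization marks pixels whose
centers fall inside the polygon (a tiny positive containment radius keeps
centers lying exactly on the traced boundary inside, which makes
mask → contour → mask pixel-exact for simply-connected regions).
Coordinates are 0-based pixel indices, vertices `(x = column, y = row)` at
pixel centers.

Clinical software stores contours in proprietary binary containers; none is
reverse-engineered here. Instead CON-TXT v1 is a documented plain-text
dialect (header `#CONTXT 1`, `scan`, `spacing`, then per-contour vertex
blocks ordered by slice, phase, endo-before-epi) with a bit-exact round
trip (`%.17g` floats).

## Volumetry conventions

Volumes are computed by voxel counting, not by disk summation from contour
areas; contour input is rasterized first. No inter-slice gap is modeled.
ED/ES default to the blood-pool volume extrema (ties broken by the earliest
phase, a constant curve warns); the pipeline pins all readers to the same
ED/ES phases so observers and model are compared on identical frames.
Slices with absent labels contribute zero volume and their count is
reported, since missing labels artificially reduce volumes; `EDV = 0`
leaves EF undefined and flagged, never silently zero. Myocardial density is
fixed at 1.05 g/ml unless overridden.

## Agreement statistics

- CoV divides the SD of the paired differences by the *grand mean* of all
  values of both series (the per-pair-means variant is available by
  option; the two coincide for complete pairs). The grand-mean reading
  makes identical series score exactly 0%.
- ICC is the single-measure two-way absolute-agreement form ICC(A,1) by
  default (the conservative choice with two raters; ICC(A,2) by option),
  computed from the two-way mean squares and interpreted on the
  poor/moderate/good/excellent bands at 0.5 / 0.75 / 0.9. Zero total
  variance leaves the ICC undefined (flagged), not 1.
- Shapiro–Wilk failures warn but do not block the paired t-test; at the
  sample sizes used here the t-test is treated as robust. Significance uses
  the Bonferroni-adjusted threshold `overall_alpha / m` (default
  0.05 / 4 = 0.0125).
- Hausdorff distances are reported in pixels of the analysis grid by
  default (millimeters by option via the pixel spacing); infinite values
  participate in the median as +∞, and the display cap at 100 used for
  plots never enters any computed statistic.
- The prediction tally classifies each evaluated frame as correct /
  incorrect / missing; frames without a manual reference are excluded. The
  correct/incorrect boundary uses a Dice threshold `tau` (default 0.5) on
  the myocardium — an operational proxy for a visual judgement, always
  reported alongside results.

## Study configuration (desk scale)

The `analysis/` scripts and the pipeline default `RunConfig` use: 11
animals (7 infarct, 4 sham), one scan each, split 6/2/3 animal-wise with
group stratification; 6 slices × 30 phases at 64 px and 0.4 mm spacing;
infarct animals draw contraction fractions 0.18–0.26 (EF ≈ 33–44%) and a
70–110° thinning sector, sham animals 0.30–0.38 (EF ≈ 51–62%); quality
scores are drawn so component means approximate a moderately degraded
cohort (artefacts ≈ 2.6, noise ≈ 1.9, general ≈ 2.0). Problem sizes were
chosen so the full study runs in about a minute on one CPU; every number in
the report tables is recomputed at run time from these conditions.

## Known limitations

- Circular cross-sections make volumetry easier than on real anatomy; the
  recovery tolerances (2 EF points, 5% volumes) are specific to the default
  resolution.
- The network is intentionally tiny; its absolute Dice scores on degraded
  phantoms vary by a few points across seeds and carry no claim about any
  full-scale architecture.
- Agreement statistics on the 3-animal test subset (n = 3 paired scans) are
  reported for completeness but are dominated by sampling noise, as any
  n = 3 ICC is.
- The ICC assumes the two-way model without subject–rater interaction;
  with k = 2 raters the interaction is not identifiable anyway.
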