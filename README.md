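# cinefunc

Cardiac cine-MRI volumetry and segmentation-agreement analysis on synthetic
short-axis phantoms.

## The problem

Quantifying left-ventricular (LV) function from short-axis cine MRI requires
segmenting the LV cavity and myocardium on end-diastolic (ED) and
end-systolic (ES) frames of every slice. Manual delineation is slow and
observer-dependent; automatic segmentation promises perfectly repeatable
readings, but its agreement with human observers has to be demonstrated with
the same statistics used for inter-observer studies. This package implements
that whole workflow as a tested pipeline — aimed at preclinical imaging
groups who want to validate a segmentation method's effect on *derived
cardiac function*, not just on overlap scores — and runs it end to end on
synthetic cine phantoms whose ground truth is known in closed form.

Given 3-class label masks (background 0, cavity 1, myocardium 2) over a
stack of `n_slices x n_phases` frames with pixel spacing `dx, dy` and slice
thickness `dz`:

- **Volumetry** (voxel counting): `EDV` and `ESV` are the cavity voxel
  counts at the phases of largest / smallest blood-pool volume times the
  voxel volume; `SV = EDV − ESV`; `EF = 100 · SV / EDV`; LV mass is the
  myocardial shell volume at ED (epicardial minus endocardial volume) times
  the myocardial density 1.05 g/ml.
- **Overlap**: Dice `2|A∩B| / (|A|+|B|)` on filled regions; Hausdorff
  distance `max{max_a min_b d(a,b), max_b min_a d(b,a)}` on boundary point
  sets. An absent label against a present one scores Dice 0 and HD +∞; Dice
  aggregates by the mean, HD by the median.
- **Reproducibility**: Bland–Altman bias and ±1.96·SD limits of agreement,
  single-measure two-way mixed-effects ICC with absolute agreement
  `(MSR − MSE) / (MSR + (k−1)MSE + k(MSC − MSE)/n)`, coefficient of
  variability `CoV = 100 · SD(a−b) / mean(all values)`, Pearson r, and
  paired t-tests with a Shapiro–Wilk gate at a Bonferroni-adjusted threshold
  (0.05 / 4 = 0.0125).
- **Segmentation model**: a small numpy encoder–decoder (U-Net-style skip
  connection, 1×1 classification head) trained with Adam on a soft Dice
  loss under the two-step transfer schedule — a *frozen* phase that trains
  only the head, then an *unfrozen* phase over all parameters, with
  checkpoints every k epochs and selection of the checkpoint with the
  highest validation Dice.
- **Phantoms**: annular myocardium around a blood pool, cosine contraction
  over 30 phases, empty basal/apical slices, sector wall thinning for
  infarcted animals, and image degradation (noise / shading bands / blur)
  graded by a 3-criterion quality score summing to 3–12.

## Worked example

```python
import numpy as np
from cinefunc import phantom as ph, volumetry as vol, stats as st

cfg = ph.PhantomConfig(n_slices=5, n_phases=10, image_size=64,
                       endo_radius_px=10, wall_thickness_px=5,
                       contraction_fraction=0.3, empty_slice_margin=1, seed=1)
stack, gt = ph.generate_phantom_stack(cfg)
f = vol.compute_function(gt.masks, vol.VolumetryConfig((0.4, 0.4), 6.0))
print(f"EDV {f.edv_ml:.3f} ml  ESV {f.esv_ml:.3f} ml  EF {f.ef_percent:.1f}%"
      f"  (analytic EF {gt.analytic_ef_percent:.1f}%)")
```

prints

```
EDV 0.896 ml  ESV 0.438 ml  EF 51.1%  (analytic EF 51.0%)
```

i.e. voxel counting on the rasterized masks recovers the closed-form
ejection fraction of the continuous phantom (here `100·(1−(1−0.3)²) = 51%`)
to within a tenth of an EF point at this resolution.

The full study lives in `analysis/` as numbered scripts — simulate the
11-animal cohort, split it animal-wise (6/2/3, group-stratified), transfer-
train the network, predict the test animals, and compute agreement and
reproducibility tables under `results/`:

```sh
cd analysis
python 01_simulate_cohort.py
python 02_split_and_train.py
python 03_predict_and_agreement.py
python 04_cardiac_function.py
python 05_reproducibility_stats.py
```

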