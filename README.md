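# segunc

Ensemble segmentation uncertainty maps and observer-study analysis for
manual contour editing.

Deep-learning models now produce near-clinical prostate CTV and rectum
segmentations, but clinicians still review and edit every contour.  Does
showing them *where the model is unsure* change how they edit?  `segunc`
provides the full quantitative toolchain for that question, aimed at
medical-physics and radiotherapy researchers running two-condition
(without/with uncertainty map) editing studies:

- **Uncertainty maps** — voxel-wise sample standard deviation
  `u(x) = sqrt( Σ_k (p_k(x) − p̄(x))² / (K−1) )` of K cross-validation
  SoftMax volumes (bounded by `sqrt(K/(4(K−1)))` ≈ 0.527 for K = 10),
  ensemble segmentation `p̄(x) ≥ 0.5`, a fixed-scale calibration block,
  and export as a PET-encoded DICOM series that overlays on the planning
  MRI in clinical software.
- **Contour comparison** — Dice, surface Dice (NSD, τ = 1 mm), Hausdorff,
  average surface distance, signed volume difference/ratio, and slice-wise
  total added path length (τ = 1 mm).
- **Edit analysis** — ±1 edited-voxel maps and histograms of edited voxels
  by uncertainty value in 0.1 bins, with per-bin percent change between
  conditions.
- **Observer-study statistics** — visual grading characteristics (VGC)
  AUC for paired ordinal ratings with case-level bootstrap (percentile
  95% CI) and paired permutation test (fixed-reader), paired two-sided
  Wilcoxon signed-rank tests, Fligner–Killeen inter-observer variance
  comparison, and volume-ratio outlier flags.
- **A synthetic study generator** — phantom anatomy, perturbed ensembles,
  uncertainty-dependent simulated edits, Likert ratings and editing times
  with known effect parameters, so every stage is testable end to end.

See `docs/methods.md` for the models, assumptions and design choices.

## Worked example

```python
import numpy as np
import segunc as su
from segunc.synthetic_study import StudyConfig, simulate_case

cfg = StudyConfig(seed=7)
prostate, rectum = simulate_case(cfg, case_index=0)

# how much did the observer change in each condition?
for step in (1, 2):
    edited = prostate.edits[("obsE", step)]
    panel = su.metric_panel(prostate.dl, edited, organ="prostate_ctv")
    em = su.edit_map(prostate.dl, edited)
    h = su.uncertainty_histogram(em, prostate.umap)
    print(f"step {step}: dice={panel.dice:.4f} apl={panel.apl_mm:.1f} mm "
          f"edits/bin={h.counts.tolist()}")

# paired ordinal ratings under two conditions
res = su.VGCModel([1, 2, 3, 2, 1] * 7, [2, 3, 3, 3, 2] * 7, scale_size=4).fit(seed=1)
print(res.summary())
```

Output:

```
step 1: dice=0.9950 apl=179.1 mm edits/bin=[10, 19, 25, 91, 36]
step 2: dice=0.9956 apl=140.4 mm edits/bin=[5, 15, 25, 76, 39]
VGC analysis
----------------------------------------------------
pairs: 35   cases: 35   scale: 1..4
AUC               0.780
bootstrap SD      0.031   (2000 resamples)
95% CI         [ 0.720,  0.837] (percentile)
p (two-sided)     0.000   (2000 permutations)
AUC > 0.5 means condition 2 rated higher than condition 1.
```

The first block shows one simulated observer editing the DL prostate
contour: with the uncertainty map (step 2) they edit less — the largest
relative reduction in the low-uncertainty bins — and the added path
length drops accordingly.  The second block is a VGC analysis of 35 paired
ratings: AUC 0.78 means the second condition was rated decisively higher
(a permutation p below 1/2000 prints as 0.000).

A command-line interface mirrors the library:

```bash
segunc simulate --out study/ --seed 1234
segunc build --members m01.nii.gz ... m10.nii.gz --out product/
segunc metrics --ref dl.nii.gz --test edited.nii.gz --out panel.json
segunc edits --dl dl.nii.gz --edited edited.nii.gz --unc product/uncertainty.nii.gz --out hist.csv
segunc vgc --ratings study/ratings.csv --question Q3 --organ prostate_ctv --out vgc.csv
segunc stats --times study/ratings.csv
```

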