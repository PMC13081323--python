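# lungwater

Quantitative-CT extravascular lung water index (EVLWI) pipeline with an
extracorporeal-blood-flow (ECBF) correction for bedside thermodilution
estimates, plus the method-agreement and study-design statistics used to
validate it. Everything is testable end-to-end on synthetic CT phantoms and
synthetic patient cohorts with known ground truth.

## What it does

- **`lungwater.ct_quant`** — computes EVLWI_CT from a 3-D Hounsfield-unit
  volume plus an aligned binary lung mask: voxels inside the edema HU window
  (default −700 to 200 HU, inclusive; HU > 200 treated as contrast and
  excluded) are integrated with tissue-weight fraction `1 + HU/1000`; the
  height-predicted expected lung weight (`−1806.1 + 1633.7 × height(m)` g) is
  subtracted and the excess normalized to ideal body weight (sex-specific
  predicted body weight, configurable rule). Also provides the DICE overlap
  coefficient for comparing segmentations.
- **`lungwater.correction`** — ordinary-least-squares fit of
  `evlwi_tptd ~ 1 + evlwi_ct + ecbf`; the ECBF coefficient is the correction
  factor, applied at the bedside as `evlwi_tptd − factor × ecbf` (intercept
  and CT slope are reported but not applied).
- **`lungwater.agreement`** — Bland–Altman bias and 95% limits of agreement
  (differences fixed as reference − test), LoA precision (Var ≈ 3σ²/n),
  precision-based and power-based paired sample sizes (normal-approximation
  z quantiles), Shapiro–Wilk-gated paired t / Wilcoxon comparison, Spearman
  correlation, normality-gated descriptive summaries.
- **`lungwater.synthetic`** — ellipsoid-lung CT phantoms with analytic truth
  records (computed from realized post-noise voxels, so recovery tests are
  exact), optional contrast-like and effusion-like compartments, mask
  degradation by erosion/boundary flips, and paired cohorts drawn from a
  three-parameter linear generative model with gamma EVLWI_CT, truncated
  normal ECBF and normal heights. All generators are seed-deterministic.
- **`lungwater.io` / `lungwater.cli`** — NIfTI volumes/masks, cohort CSV,
  flat key=value model/config files, and a `lungwater` command.

## CLI

```sh
# generate a synthetic phantom and quantify it
lungwater simulate phantom --seed 1 --noise-sd 50 \
    --out vol.nii.gz --mask mask.nii.gz --truth truth.json
lungwater quantify --volume vol.nii.gz --mask mask.nii.gz \
    --height 1.77 --sex male

# simulate a cohort, fit the ECBF correction, apply it, report agreement
lungwater simulate cohort --n 64 --seed 1 --out cohort.csv
lungwater fit-correction --cohort cohort.csv --model model.txt
lungwater correct --cohort cohort.csv --model model.txt --out corrected.csv
lungwater agree --cohort corrected.csv --test-column evlwi_tptd_corr \
    --out report.json --plot ba.png
```

Results go to stdout or `--out` (existing files are never overwritten
without `--force`); logs go to stderr. Exit codes: 2 usage, 3 format,
4 validation, 5 numeric. `lungwater --show-config` prints the defaults.

## Notes

- The per-voxel weight uses `1 + HU/1000`, the only form consistent with the
  mean-HU closed form `(1 − meanHU/(−1000)) × volume`; a sometimes-quoted
  variant `(1 − (HU − 1000)/1000)` would give water a density of 2 g/ml and
  is not used.
- Lung volume and weight are integrated over windowed voxels only by
  default; `quantify_scan(..., window_only=False)` (CLI `--full-mask-volume`)
  integrates volume over the whole mask for sensitivity analysis.
- Negative EVLWI_CT (drier-than-expected lung) is returned, not clipped.
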