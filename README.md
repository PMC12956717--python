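# ctquant

Quantitative cardiothoracic CT biomarkers, implemented as a deterministic,
testable toolkit and exercised on seeded synthetic thorax phantoms with
analytically known ground truth.

Chest CT carries simultaneous information on four organ systems that matter
in cardiopulmonary comorbidity (e.g. COPD with coronary disease): lung
parenchyma, airways, pulmonary vasculature, and the heart. `ctquant`
implements the standard quantitative indices for each branch, the evaluation
metrics used to validate automated segmentation against references, and the
trial-design statistics (sample size, GOLD stratification, randomization,
multiplicity control) of an imaging-endpoint rehabilitation trial. It is
aimed at researchers who need reference implementations of these biomarkers
with exact, voxel-count-level ground truth to test pipelines against.

## The quantities

| Branch | Index | Definition |
|---|---|---|
| Lung | LAV% | `100·|{x ∈ lung : HU(x) < −950}| / |lung|` (low-attenuation volume) |
| Lung | Perc15 | HU at the 15th percentile of the lung density histogram |
| Lung | MLD | mean HU over the lung mask |
| Airway | WA%, WA/LA | wall area as % of wall+lumen area; wall/lumen ratio (circular model, FWHM ray casting) |
| Airway | Pi10 | predicted √WA at internal perimeter 10 mm, from OLS of √WA on Pi |
| Vessel | BV5% | % of vessel volume with local cross-sectional area < 5 mm² (skeleton + distance transform) |
| Vessel | D | 3D box-counting fractal dimension, −slope of log N(ε) vs log ε |
| Cardiac | CACS | Agatston: Σ lesion area × peak-HU weight (1–4) × slice-spacing/3 mm |
| Cardiac | LVM, EDV, ESV, SV, EF | voxel-summation volumes; SV = EDV−ESV; EF = 100·SV/EDV; mass at 1.05 g/mL |
| Trial | n/group | `n = 2σ²(Z₁₋α/₂+Z₁₋β)²/δ²`, ceiling |

All quantification reads **raw HU**; the `[−1000, 400]` HU truncation and
[0, 1] normalization in `ctquant.core.preprocess` exist only to prepare
model input (truncating at 400 HU would destroy the ≥400 HU Agatston
density class).

Conventions: arrays are `(z, y, x)` with spacing `(dz, dy, dx)` in mm,
0-based coordinates; NIfTI I/O via nibabel.

## Worked example

Generate a seeded thorax phantom (two emphysematous lungs, three airways,
a small/large vessel population, a 120/48 mL two-phase left ventricle, two
calcified plaques) and quantify it against its own truth masks:

```bash
ctquant phantom --seed 7 --out-dir phantom7
ctquant quantify lung --volume phantom7/volume.nii.gz \
    --lung-mask phantom7/mask_lung.nii.gz --out phantom7/lung_report
```

prints

```json
{
  "laa_threshold_hu": -950.0,
  "n_lung_voxels": 255372,
  "lav_percent": 25.0,
  "perc15_hu": -980.0,
  "mld_hu": -882.5
}
```

i.e. exactly the generator's target: 25% of lung voxels were painted as
emphysema pockets at −980 HU inside −850 HU lung, so LAV% is 25.0, the 15th
percentile sits inside the emphysema block (−980 HU) and the mean lung
density is the two-point mixture 0.25·(−980) + 0.75·(−850) = −882.5 HU.
Similarly `ctquant quantify cardiac ...` on the same phantom reports
EDV 120.0 mL, ESV 48.0 mL, SV 72.0 mL, EF 60.0% and CACS 14.67 (a 4 mm²
weight-2 lesion and a 9 mm² weight-4 lesion on 1 mm slices), matching
`phantom7/truth.json`. The trial-design worked example:

```bash
ctquant stats samplesize --sigma 5 --delta 3 --alpha 0.05 --power 0.8
# -> n_per_group: 44 (raw 43.56)
```

## Layout

- `ctquant.core` — `CTVolume`/`LabelMask` data model, NIfTI I/O, preprocessing, reports
- `ctquant.phantom` — seeded synthetic thorax generator with voxel-count ground truth
- `ctquant.lung`, `.airway`, `.vessel`, `.cardiac` — the four biomarker branches
- `ctquant.evaluation` — Dice/IoU, agreement statistics, losses, splits, augmentation
- `ctquant.trial` — sample size, GOLD grading, randomization, BH adjustment, correlations
- `ctquant.cli` — `ctquant` command-line entry point

See `docs/methods.md` for the modeling choices, numerical conventions and
known limitations.
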