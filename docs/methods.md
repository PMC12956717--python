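# Methods

## Scope and data model

`ctquant` quantifies four families of cardiothoracic CT biomarkers on 3D HU
volumes with anisotropic voxel spacing, evaluated against binary/label masks
aligned to the volume. No automatic segmentation is performed: masks come
from the phantom generator's ground truth or from the user (in a real
pipeline, from a segmentation model whose quality is assessed with
`ctquant.evaluation`). Every quantification operates on raw HU. The
preprocessing chain (Gaussian denoising at σ = 1.0 voxels by default, HU
truncation to [−1000, 400], linear normalization to [0, 1]) produces a
separate model-input copy only: the 400 HU ceiling would make the ≥400 HU
Agatston density class unreachable, so quantifying the truncated copy is a
bug the test suite guards against. σ is interpreted in voxel units by
default because the alternative (mm) is equally defensible; both are
supported via `PreprocessConfig.sigma_units`, and 1.0 — the low end of the
conventional 1–1.5 denoising range — is chosen to minimally blur thin airway
walls.

## The phantom: what it emulates and what it does not

The generator paints a thorax-like scene: soft-tissue background (40 HU),
two ellipsoidal lungs (−850 HU) containing spherical emphysema pockets
(−980 HU) grown until they occupy an exact target fraction of the lung
mask, tubular airways (lumen −1000 HU, wall 0 HU), hard-edged vessel
cylinders (optionally a recursive bifurcating tree), a two-phase spherical
left-ventricular blood pool with a concentric myocardial shell, and
single-slice calcified plaques of known area and peak HU. Optional Gaussian
noise is seeded; generation is pure — (spec, seed) determines every voxel.

Ground truth is defined on the **voxelized** geometry, not the continuous
solids: LAV% is literally the emphysema/lung voxel-count ratio, EDV is the
ED blood voxel count × voxel volume, and so on. Two constructions make
exact recovery possible:

- the LV blood pools are digital balls whose outermost voxels are trimmed
  (largest center distance first, ties by flat index) until the count
  matches the volume target exactly, so EDV/ESV/SV/EF recover to the last
  digit rather than "close to 4πr³/3";
- the lung truth mask excludes a one-voxel margin around every airway, the
  vessel voxels and the cardiac region, so lung HU is an exact two-point
  mixture of lung and emphysema values and LAV%/MLD/Perc15 recovery is
  exact on noiseless phantoms.

Airway walls are painted with a one-voxel linear partial-volume ramp at the
lumen and outer boundaries — a crude stand-in for the scanner point-spread
function — so that half-maximum edge localization finds the true radii.
The phantom does **not** model CT physics (beam hardening, reconstruction
kernels, dose-dependent noise texture), respiratory or cardiac motion,
contrast dynamics, or anatomically realistic airway/vessel trees. Passing
tests therefore demonstrate correctness of the quantification operators on
known geometry, not robustness to clinical image quality.

## Branch-specific choices

**Lung.** The low-attenuation threshold defaults to −950 HU, the field
standard for inspiratory CT emphysema quantification; it is a required,
visible parameter. Perc15 uses a fixed lower-value order statistic
(`sorted[⌈0.15·n⌉]`, 1-based) so tests can assert exact equality; this is
implemented directly because common interpolating quantile conventions
(including numpy's `lower`, which indexes `⌊0.15·(n−1)⌋`) differ on small
samples. Metrics on an empty mask are flagged absent, never zero.

**Airway.** The wall operator casts 64 equiangular rays in the plane normal
to the supplied centerline direction, samples HU trilinearly every 0.1 mm,
and places the inner edge at the half-rise from lumen HU to the per-ray peak
and the outer edge at the half-fall from the peak to the post-peak minimum
(FWHM). A measurement is rejected — with a reason — when more than 25% of
rays find no wall peak (≥100 HU contrast), which also catches centers placed
outside a closed lumen. Areas use the circular model LA = πr_l²,
WA = π(r_o²−r_l²), Pi = 2πr_l; elliptical fitting was rejected as
unverifiable here. FWHM needs roughly three in-plane samples across the
wall: at 0.5–0.6 mm in-plane spacing (typical HRCT) a 1 mm wall is recovered
within ~3% of the closed forms, while at 1.0 mm the partial-volume effect
halves the observed wall peak and FWHM overestimates wall area by ~50%
regardless of interpolation — at that resolution the mask-based path
(per-slice voxel counts × pixel area) is the appropriate oracle and is what
the 1 mm phantom tests assert. Pi10 is the OLS fit of √WA on internal
perimeter evaluated at Pi = 10 mm (the standard airway-remodeling summary);
degenerate inputs (fewer than two airways, all perimeters equal) raise
rather than returning NaN. Whether WA% should be averaged per airway or
pooled over cross-sections is not standardized; this package averages
per-airway measurements, then across airways.

**Vessel.** The local cross-sectional area map skeletonizes the vessel mask,
takes the Euclidean distance transform (anisotropic sampling respected) at
skeleton voxels as the local radius, and propagates CSA = πr² to each vessel
voxel from its nearest skeleton voxel. Two numerical corrections matter:
(i) the digital boundary sits half a voxel beyond the last foreground
center, so half the smallest spacing is subtracted from the EDT — without
this a radius-1 mm cylinder reads CSA ≈ 6.3 mm² instead of ≈π and the 5 mm²
threshold misclassifies it; (ii) a ±2-voxel rolling maximum of the EDT along
the skeleton removes the end-cap artifact of finite tubes, where endpoint
EDT values collapse toward the cap distance. The rolling maximum can bridge
distinct vessels closer than ~2 voxels; the phantom keeps vessels farther
apart, and real masks with touching vessels would need component-wise
treatment. BV5% uses total vessel volume as the denominator (matching
"percentage of blood vessels"), and the 5 mm² threshold is configurable.
Box counting anchors the grid at the array origin with no offset averaging,
making counts deterministic and exactly log-linear for digital lines,
planes and solid cubes (D = 1, 2, 3 to machine precision); box sizes
default to powers of two up to a quarter of the shortest axis. Reported
clinical fractal dimensions depend on segmentation protocol and are not
comparable targets for phantom values.

**Cardiac.** Classic Agatston: per-slice 8-connected components of
{HU ≥ 130} within the coronary search region, lesions under 1 mm² dropped,
peak-HU weights 1/2/3/4 at 130/200/300/400 HU, and a slice-spacing/3 mm
normalization (on by default, configurable) because the original protocol
assumes 3 mm slices while thin-slice CTA is common. 2D connectivity per
slice is deliberate (the classic protocol), not 3D. Myocardial density is
the standard 1.05 g/mL. LV function reduces gated multi-phase imaging to
two static masks (ED, ES); inconsistent phases (ESV ≥ EDV) are an error,
not a silent negative stroke volume.

**Evaluation harness.** Dice and IoU define the both-empty pair as perfect
agreement with a flag (the main alternative — undefined — is noted here;
callers can branch on the flag). Soft-Dice loss uses ε = 1e−7. The
70/15/15 split and five-fold assignment shuffle within each stratum under a
seeded generator; folds are dealt round-robin so strata are represented
evenly, and a stratum smaller than k is an error. Augmentation samples one
geometric transform (±10° in-plane rotation, in-plane flips, random crop at
scale 0.8–1.0 resized back) applied to volume (linear) and mask (nearest),
plus a uniform additive HU offset on the volume only; a fully collapsed
config is the exact identity. A full multi-task training loop is out of
scope: no deep-learning framework is a dependency, and the harness above is
what the package's validation story needs.

**Trial statistics.** The per-group sample size is the two-sample-means
formula with the ceiling taken (43.56 → 44 on the σ=5, δ=3, 1.96/0.84
example); both rounded and exact normal quantiles are supported and give
the same 44 here. The dropout inflation ⌈n/(1−0.15)⌉ = 52 does not produce
the convenient 50-per-subgroup enrollment figure some designs quote — the
function therefore reports the formula value and accepts a fixed
per-stratum target as an explicit design input (50 × 4 strata × 2 arms =
400) rather than inventing a rounding rule. GOLD grades partition FEV₁
percent-predicted with boundaries inclusive on the milder side (80.0 → I),
and a respiratory-failure flag forces grade IV. Randomization permutes each
stratum under a seeded generator and splits 1:1, flagging odd strata (±1).
BH adjustment delegates to `statsmodels.stats.multitest` and is tested
against a hand-written min-over-suffix brute force; the correlation matrix
is pairwise-complete, flags constant columns as undefined rather than r=0,
and BH-adjusts across all defined cells.

## Problem sizes

The default phantom is 104×128×128 voxels at 1 mm isotropic spacing —
large enough that every branch has realistic structure counts (≈255k lung
voxels, three airways, ≈680 vessel voxels, 120 mL LV) while generating in
seconds. Oracle-equivalence suites use 1000 random instances each; the
correlation recovery uses n = 500 subjects, giving a sampling error
comfortably inside its ±0.08 assertion band.

## Known limitations

- Airway measurement assumes a locally straight, circular airway and a
  user-supplied centerline; no automatic tree extraction or generation
  labeling.
- The FWHM operator degrades predictably when the wall is under ~3 in-plane
  samples thick (see above) and when wall contrast is below the 100 HU
  rejection threshold.
- BV5% end-cap handling trades a small over-smoothing of radii near true
  vessel endpoints for removal of the cap artifact.
- Phantom realism is geometric, not physical; results on clinical data
  additionally depend on segmentation quality, which this package measures
  but does not produce.
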