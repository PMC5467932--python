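# Methods

## Measurement model

All volumes live on one fixed lattice convention: axes (x, y, z) =
left→right, posterior→anterior, inferior→superior; 0-based voxel
indices at voxel centers; spacing and origin in mm. Activity volumes
are assumed decay-corrected scanner output (standard for reconstructed
clinical images), so SUV conversion applies no decay correction:
`SUV = C[kBq/mL] · weight[kg] / dose[MBq]`, body-weight normalisation
(the most common clinical convention; lean-mass or BSA normalisation is
out of scope).

### Lung quantification

Each lung voxel is modelled as a three-compartment mixture of air
(fraction `a`), blood (`f`) and tissue (`1 − a − f`). CT gives
`HU = a·(−1000) + (1 − a)·0`, hence `1 + HU/1000` estimates the non-air
fraction. The three lung measures follow:

* `SUV_M` — the raw regional mean;
* `SUV_L = SUV_M / (1 + HU/1000)` — uptake of bulk (non-air) lung
  material;
* `SUV_T = (SUV_M − f·SUV_B) / (1 + HU/1000 − f)` — uptake of lung
  tissue proper, subtracting the blood signal `f·SUV_B`.

`f` defaults to 0.16 (a literature estimate of lung blood volume
fraction from dog measurements) and is a configuration parameter, never
hard-coded. `SUV_B` is the pooled voxel-weighted mean over the LA
cavity and descending-aorta masks; pooling the union was chosen over
averaging two per-structure means because the clinical description is
ambiguous — the alternative is a one-line change at the call site.
Corrections are applied to *region means* (mean HU and mean SUV are
recorded per region, then corrected), matching the clinical recording
convention; the correction functions also accept arrays for per-voxel
use. Negative `SUV_T` (possible when measured uptake falls below the
blood contribution) is returned as computed with a warning — truncation
would bias cohort means.

The 24 regions are built per lung from the mask alone: the z-extent is
cut into three equal-thickness levels (upper/mid/lower — no anatomical
lobe definition is attempted), each level is sampled as two equal z
sub-slabs, and everything is split at that lung's own mid-coronal plane
into anterior/posterior. That yields 12 regions per lung, 24 per
subject, forming an exact partition of the mask. "Excluding the lower
lobes" removes the lower level of both lungs — 8 of the 24 regions —
leaving 16.

### Cardiac quantification

Gated convention: frame 1 starts at the R wave. ED is the combination
of frames {1, 8}, ES of frames {4, 5}; these frame numbers are fixed
pipeline constants, not inferred from the volume curve. Frames are
combined by **mean**, not raw sum: for SUV-calibrated images the mean
preserves the calibration while averaging noise; a `sum_mode` flag
exists for count-space data.

Manual cavity contouring is replaced by a deterministic algorithm:
seeded region growing over voxels below `threshold_fraction` (default
0.5) times the maximum uptake in an analysis box around the seed, the
hot myocardial wall acting as the boundary. Face connectivity (6
neighbours) is used. Failure modes mirror the non-contourable clinical
scans: a seed at or above threshold (no cavity/wall contrast) and a
grown region reaching the analysis box (wall does not enclose the
cavity) both raise a contourability error; the subject-level driver
records the subject as non-contourable with NaN volumes rather than
aborting. Cavity volume is voxel counting (`n · voxel volume / 1000`
mL); EF and SV follow from EDV/ESV. Wall max SUVs are read on the
static (frame-averaged) SUV image; the RA max is reported but feeds no
derived ratio.

## Synthetic phantom

The thorax is deliberately schematic so every truth is analytic:
ellipsoidal lungs in an elliptic-cylinder body, LV and RV as
ellipsoidal shells with a planar septum band between the cavities, an
RA shell, an LA ellipsoid and a cylindrical descending aorta.
Compartments are painted onto a label grid in a fixed priority order,
so masks are disjoint by construction and the activity/HU of every
voxel is exactly the labelled compartment's value.

* Lung activity = `f·SUV_blood + (1 − a − f)·SUV_tissue` (air
  contributes nothing); lung HU = `a·(−1000)`; defaults `a = 0.70`,
  `f = 0.16`, tissue SUV 2.0 (a PH-like value), blood SUV 1.0.
* The RV cavity is an ellipsoid (axis ratio 1 : 1.3 : 2) whose volume
  follows a cosine-like 8-frame cycle normalised so frames 1/8 sit
  exactly at EDV and frames 4/5 exactly at ESV; the wall is a
  constant-thickness shell around the instantaneous cavity. Default
  EDV/ESV 120/78 mL (EF 35%, a typical impaired RV).
* Wall uptake defaults: LV 3.0, RV 4.2 (RV/LV ratio 1.4,
  pressure-overloaded), septum 3.0, RA 2.0 SUV.
* Acquisition defaults: 370 MBq dose, 74 kg weight, 90 min uptake.
* Noise is additive i.i.d. Gaussian on activity, with σ specified in
  SUV units (converted by dose/weight) — a proxy for post-
  reconstruction image noise, which is approximately Gaussian; Poisson
  count noise, scatter, attenuation, respiratory motion and PSF
  blurring are *not* modelled. Same spec + seed ⇒ bit-identical output.

Two grids are provided: the full thorax (116×92×100 at 2 mm) and a
compact heart-only window (`PhantomSpec.cardiac`) used for EF-recovery
studies down to 1 mm spacing. Lungs are homogeneous by default (the
clinical data showed no regional differences); per-region perturbation
can be added through the uptake configuration.

What passing phantom tests shows — and does not: the quantification
chain exactly inverts the generator's mixing/geometry model, and EF
recovery tolerates voxelization and moderate Gaussian noise. It does
not certify performance on real scans, where PSF blur, scatter,
respiratory motion and anatomy violate the phantom's assumptions.

## Cohort generator

Per-group marginals (normal or lognormal, parameterised by mean and SD)
are coupled through a Gaussian copula. Requested *rank* correlations
`ρ_s` are mapped to latent Gaussian correlations via
`ρ = 2·sin(π·ρ_s/6)`, so sample Spearman correlations converge to the
request. The latent matrix must be positive semidefinite (checked;
eigen-decomposition square root, tiny negative eigenvalues clipped at
−1e−8 tolerance).

Printed group summaries that exist in text form (lung SUV_M 0.50 ± 0.15
PH vs 0.37 ± 0.09 control; subgroup SUV_T 2.13 ± 0.63 idiopathic,
1.98 ± 0.81 hereditary, 1.59 ± 0.38 control; subgroup RV/LV ratios;
group sizes 8/9/12/9) are the defaults. Measures whose published
values appear only in figure-rendered tables (SUV_L, RV volumes/EF,
echo parameters, NT-proBNP, 6MWD, CAMPHOR) use plausible clinical
values for a PH cohort vs healthy controls, chosen once and kept.
NT-proBNP, CAMPHOR and the RV/LV ratio use lognormal marginals
(nonnegative, heavy-tailed — the data contained unusually high
NT-proBNP values). Echo inputs are generated by *inverting* the derived
formulas from latent draws (RVSP→TRV given RAP, FS→ESA given EDA,
Tei→TCO given ET, HRR→HR at 1 min), so deriving them back round-trips
to numerical precision; RVES volume is derived from drawn EDV and EF,
keeping EF/SV identities exact within each record. Mild truncations
keep draws physiologic (e.g. FS clipped to (1, 99)%, RVSP floored at
RAP + 1 mmHg); they are rare events with negligible effect on moments.
Two PH subjects are generated without strain values, exercising the
pairwise-complete statistics path.

Convergence checking: normal marginals are verified on the natural
scale (mean and SD within 2% at n = 10⁴). Heavy-tailed lognormal
marginals are verified on the log scale — the sample SD of a lognormal
with σ ≈ 1 has ~5% sampling error even at n = 10⁴, so the log-scale
moments are the statistically meaningful 2% check of the same
parameters.

## Statistics

Summary-statistic t-tests implement Welch (default) and pooled formulas
directly from (mean, SD, n), with Welch–Satterthwaite df and a 95% CI
for the mean difference; they agree with raw-sample tests on
moment-matched samples to 1e−10. Welch is the default because it is
safe under unequal variances and reproduces the published p-values for
the summary comparisons checked. Zero variance in both groups with
equal means returns p = 1 by convention; with unequal means it is an
error. Spearman uses average ranks and the t approximation for p
(|ρ| = 1 ⇒ p = 0); constant vectors raise rather than returning silent
NaN; missing values are dropped pairwise. Bland–Altman reports the mean
difference, SD (n−1), mean ± 1.96·SD limits and the Pearson r of the
paired readings. P-values are reported at full precision plus a
display-rounded value (one decimal at/above 0.1, two below, one
significant figure when two decimals would show 0.00). No
multiple-comparison correction is applied anywhere, by design.

## Pipeline

`run_study` is deterministic given (config, seed): the root seed is
split into named substreams (phantom, cohort) with
`numpy.random.SeedSequence`; tables are written with a fixed float
format so reruns are byte-identical; the manifest records versions,
seed, config hash, per-stage record counts and aggregated warnings
(negative SUV_T regions, non-contourable subjects, negative heart-rate
recovery). Stage failures propagate as `StageError` carrying the stage
name and subject id.

## Known limitations

Schematic anatomy (no lobes, trabeculation, valves or great vessels);
no reconstruction physics; region-growing segmentation assumes a
closed hot wall, which fasting scans with minimal RV uptake will not
provide (this is surfaced as the contourability flag, not solved); the
partition's level boundaries are geometric thirds, not anatomical
lobes; echo pass-through measures (TAPSE, S′, RA volume, strain, RV
thickness) are validated for range only.
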