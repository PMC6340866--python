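# Methods

## Problem and model

Bone metastases of prostate cancer are imaged with two complementary PET
tracers: a bone-remodeling agent (¹⁸F-NaF, taken up where osteoblasts lay
down new bone) and a tumor-cell agent targeting prostate-specific membrane
antigen (PSMA). The two signals need not coincide inside a single lesion,
and the degree of intra-lesion discordance is itself biologically
informative: tumor growing independently of the osteoblastic reaction shows
PSMA uptake displaced from the sclerotic, NaF-avid bone. `petcoloc`
quantifies that discordance per lesion and tests whether it differs between
castration-sensitive (CSPC) and castration-resistant (CRPC) disease.

The analysis chain is:

1. **Registration.** Each tracer session carries its own low-dose CT in the
   session's frame. Session B (PSMA) is aligned to session A (NaF) by a
   global rigid CT-to-CT registration followed by a per-lesion rigid
   refinement restricted to a world-aligned box around the lesion. The
   session-A CT grid is the reference frame for everything downstream; one
   fixed convention is required for reproducibility and this is ours.
2. **Segmentation.** Per lesion and tracer, a gradient-based ROI is the
   primary contour; nested 60/70/80 %-of-SUVmax ROIs capture the uptake
   core; a CT threshold ROI captures radiographic sclerosis.
3. **Concordance.** Overlap volume OV = |A∩B| / min(|A|,|B|) at each
   segmentation level; seven-way voxel concordance categories over the
   PSMA/NaF/CT ROI triplet; three distances between the regions of highest
   uptake (SUVmax-to-SUVmax, f80 centroids, mean pairwise f80 distance).
4. **Statistics.** All inference respects the lesion-within-patient
   clustering: a clustered Wilcoxon signed-rank test across segmentation
   levels, patient-level permutation tests between disease groups,
   patient-level bootstrap CIs, a nested mixed model of voxel HU by
   concordance category, and a paired-scan ICC as a registration-quality
   surrogate.

## Key algorithms and numerical choices

### Gradient segmentation

Edge-seeking PET segmentation places the contour where the spatial gradient
of uptake is steepest. Our implementation casts rays from the lesion's
local uptake maximum (reached by greedy hill-climbing from the seed on a
smoothed copy; smoothing σ = 1 voxel stabilizes both the climb and the
gradient under noise). Along each of 62 directions (the 26 cube-neighbor
directions plus a once-subdivided icosahedron) the profile is sampled at
0.8 mm steps to a 25 mm cap, and the boundary radius is the peak of the
along-ray gradient magnitude. The search stops where the profile re-rises
by more than 5 % of its drop from the center — without this, a neighboring
lesion's rising flank would capture the boundary. Rays without a usable
peak inherit the median radius of valid rays; if more than half the rays
fail, the lesion is declared indistinct and excluded. The boundary surface
is voxelized by blending the four angularly nearest rays per voxel, closed
morphologically, and reduced to the component containing the center.

For an isotropic Gaussian blob of scale σ the radial gradient
A·r/σ²·exp(−r²/2σ²) peaks exactly at r = σ, giving an analytic oracle: on a
noiseless σ = 4 mm blob at 2.5 mm spacing the recovered equivalent-sphere
radius is within one voxel of σ (the 1-voxel smoothing inflates the
boundary to √(σ² + (2.5 mm)²) ≈ 4.7 mm, well inside that tolerance).

Fractional ROIs keep parent voxels with SUV ≥ f·SUVmax, f ∈ {0.60, 0.70,
0.80}, where SUVmax is the maximum inside the gradient ROI (ties broken at
the lowest (z,y,x) index). Nesting f80 ⊆ f70 ⊆ f60 ⊆ gradient is
structural and asserted on every lesion.

### CT ROI

Sclerosis is thresholded at Δ = 150 HU above the median HU of bone voxels
(HU > 100) in the lesion box, keeping the largest connected component. The
bone-median reference makes the rule invariant to the soft-tissue fraction
of the box. Lesions with nothing above threshold (osteolytic /
radiographically invisible) yield an ROI flagged empty and are carried
through with missing CT-derived quantities rather than dropped.

### Registration

Mean squared HU difference on fixed-image voxels with HU > 100, optimized
over a 6-DOF Euler transform by regular-step gradient descent at three
resolutions (shrink 4/2/1, smoothing 4/2/0 mm), full deterministic
sampling, identity initialization (global) or the global transform
(local). Both scans are CT of the same subject days apart, so a mono-modal
metric suffices. On noiseless phantoms, misalignments up to 10 mm / 5° are
recovered to ≤ 0.1 mm and ≤ 0.1° at lesion positions — against the
0.5 mm / 0.25° contract. One geometric caveat: phantom lesions are
spheres, so a phantom with fewer than three non-collinear lesions leaves a
rotation axis unobservable by the bone-masked metric; recovery checks use
three lesions.

### Clustered statistics

*Signed-rank:* ranks of |d| are pooled over all non-zero paired
differences; T = Σ sign(d)·rank; Var(T) is estimated as Σ over patients of
the squared within-patient signed-rank sum, which reduces to the classical
n(n+1)(2n+1)/6 for singleton clusters; z = T/√Var is normal-referenced.
Empirical size at α = 0.05 over 2000 correlated-null replicates (10
clusters × 5 exchangeable pairs) is ≈ 0.04.

*Permutation:* whole patients swap group labels; the statistic is the
difference of group medians of lesion-level values (the group median is
what the study reports; the statistic choice is ours); p = (1 + #{|perm| ≥
|obs|})/(n_perm + 1) with n_perm = 2000 by default. Patient ids are sorted
internally so the result is exactly invariant to input ordering.

*Bootstrap:* patients resampled with replacement, lesions carried along,
percentile CI. At 19 patients × 5 lesions the 95 % percentile CI for a
patient-mean covers truth ≈ 93 % of the time — the familiar mild
anticonservatism of the percentile method at modest cluster counts.

*HU mixed model:* HU ~ category (treatment-coded against the
triple-overlap "all matching" reference) + region + cohort, with random
intercepts for patient and lesion-within-patient; ML fits; category tested
by likelihood ratio. Region and tracer cohort enter as fixed covariates:
with a handful of levels each, variance components for them are not
estimable with useful stability. The paired-scan ICC uses the balanced
two-replicate one-way ANOVA estimator ICC = (MSB − MSW)/(MSB + MSW), which
is exactly the REML variance-ratio of a random-intercept-per-voxel model
of the two scans' HU.

## The phantom generator

Each simulated patient carries four volumes on a 96×96×64 grid at 2.5 mm
isotropic spacing (sizes chosen so a 19-patient cohort analyzes in
minutes). A lesion is: a bone-density sphere (250 HU, radius 3σ) in soft
tissue (40 HU), a sclerotic core (+400 HU, radius 1.6σ, raised-cosine edge
of ±2 mm), a tracer-A Gaussian uptake blob (σ ∈ [3.5, 5.5] mm, peak SUV
8–15) centered on the sclerosis, and a tracer-B blob (peak SUV 6–12)
displaced by |N(μ, sd)| in a uniformly random direction with μ = 1.5 mm
(CSPC) or 7 mm (CRPC) — small offsets mean concordant lesions, large
offsets discordant ones. Uptake is blurred by a 6 mm FWHM Gaussian PSF
(typical whole-body PET resolution), then carries additive Gaussian SUV
noise (sd 0.1); CT carries 5 HU noise. Session B is the patient-frame
field resampled through a random rigid transform (±3 mm, ±2°) before
noise, emulating repositioning between sessions; PET and CT of a session
share the frame as on a PET/CT scanner. Per-patient RNG streams are
spawned from the master seed, so enlarging a cohort never reshuffles
earlier patients.

What the phantom does **not** emulate: real anatomy and its registration
ambiguities, attenuation/scatter and Poisson count noise, intra-lesion
uptake texture (blobs are unimodal Gaussians), osteolytic lesions, and
respiratory/positioning motion beyond a global rigid move. Passing tests
therefore demonstrate that the measurement chain is correct and calibrated
under its stated assumptions — not that it would segment every clinical
lesion; the gradient ROI in particular sees an easier edge on a Gaussian
blob than on textured clinical uptake.

## Degenerate inputs and tie rules

- SUVmax ties: lowest (z, y, x) voxel index wins, deterministically.
- Seeds in background (smoothed SUV below the 1.0 floor at the climbed
  maximum) and indistinct lesions raise a segmentation error; the pipeline
  logs the lesion as excluded rather than failing the run.
- All-zero paired differences: z = 0, p = 1. A single cluster is an error.
- Constant input to Spearman correlation is an error (undefined ranks).
- Pairwise-distance pair counts above 10⁶ are subsampled with a fixed
  seed.
- Empty CT ROIs propagate as missing CT-derived quantities (NaN), and the
  mixed model falls back to the largest category if the triple-overlap
  reference is absent.

## Known limitations

- The pipeline analyzes one lesion per manifest seed; merging/splitting
  uptake foci is out of scope.
- The gradient boundary is star-shaped around the uptake maximum by
  construction; strongly concave lesions would be truncated.
- The permutation test assumes exchangeability of patients across groups
  under the null; covariate imbalance is not adjusted.
- With default phantom parameters the CRPC group's f80 cores are often
  fully disjoint (median f80 OV near 0), a harsher contrast than clinical
  cohorts show; group comparisons remain directional, not calibrated to
  clinical effect sizes.
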