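# Methods

## The problem

Semiquantitative FDG-PET parameters — SUVmax, SUVmean, metabolic tumour
volume (MTV) and total lesion glycolysis (TLG) — drive staging and response
assessment in oncology, yet different analysis workstations return
measurably different numbers for the same scan. `petquant` implements the
complete measurement chain so that the sources of disagreement can be
studied in a controlled, fully synthetic setting: a sphere-phantom
calibration of size-dependent delineation thresholds, threshold-based VOI
segmentation with SUV/MTV/TLG extraction under three unit conventions, and
a statistical layer comparing measurements across simulated software
variants.

## SUV arithmetic

SUV is the tissue activity concentration normalized by administered
activity per unit mass, dimensionless under the g/mL convention:

    SUV = C [kBq/mL] / (A [MBq] / m [kg])

with `m` either total body weight (SUV-BW) or lean body mass (SUV-LBM),
the latter from the sex-specific James formula

    men:   LBM = 1.10·BW − 128·BW²/h²
    women: LBM = 1.07·BW − 148·BW²/h²

(BW in kg, h in cm). The administered activity is decay-corrected from
injection to scan start with the ¹⁸F half-life (109.771 min default;
configurable per radionuclide). Decaying the activity forward and decaying
the concentration backward to injection time give identical SUV, so only
the first convention is implemented. The raw Bq/mL readout bypasses
normalization entirely. Images are stored in Bq/mL; the kBq conversion
happens inside the SUV routines.

## Delineation and lesion metrics

A lesion VOI is every voxel in a search region with value ≥ T% of the
region's maximum, reduced to the face-connected (6-neighbour) component
containing the maximum voxel. Design choices, each of which flips boundary
voxels and is therefore fixed and documented:

- threshold comparison is inclusive (≥);
- max ties break to the lowest linear index (z-major order);
- connectivity is 6-face — the most conservative standard choice,
  preventing diagonal leakage into adjacent hot structures;
- negative post-noise values are clamped to 0 before any statistic;
- voxel volume always comes from header spacing (never assumed isotropic).

MTV is voxel count × voxel volume (cm³); TLG is SUVmean × MTV per unit
system, stored as the exact product so the identity is bit-level.

## Phantom calibration

The volume-recovering %-of-max threshold depends on object size through the
partial-volume effect, so it is calibrated on a simulated body phantom with
hot spheres of 13/17/22/28/37 mm diameter (volumes 1.150–26.522 cm³; the
10 mm sphere of the physical phantom is supported but off by default).
Per sphere and per software variant, all integer thresholds 1–99% are
scanned exhaustively and the one minimizing |MTV − true volume| is kept
(ties → smallest threshold, favouring inclusive volumes and making
regressions stable). The selection metric is volume recovery because the
sphere volumes are the only ground truth a phantom provides. Per sphere
size, the per-variant optima are averaged with equal weight — a variant
reporting two equally good thresholds contributes two terms — and rounded
half-up to an integer consensus (the published calibration's 63.75 → 64 and
43.75 → 44 rule out round-half-even).

Applying the consensus table to a lesion whose size is not yet known is
circular: the threshold picks the volume and the volume picks the
threshold. It is resolved by fixed-point iteration: segment at the middle
bin's threshold, measure MTV, reassign to the bin nearest in log-volume,
repeat (≤ 5 iterations); a two-bin oscillation resolves to the
larger-volume bin. Idempotence (restarting from the returned bin changes
nothing) is tested on simulated lesions across sizes.

## Synthetic data

**Phantom.** Spheres are voxelized analytically (voxel-centre-in-sphere) on
a uniform warm background, blurred with an isotropic Gaussian, then
degraded with additive Gaussian noise of SD proportional to the background
concentration and clamped at 0 (a simple, reproducible stand-in for
reconstruction noise). Truth masks are the unblurred voxelized spheres.
Defaults: 2 mm isotropic voxels on a 40×96×96 grid, spheres on a 57.2 mm
transaxial ring, background 5 kBq/mL, sphere fill 8:1 over background.

The blur parameter models the *effective reconstructed-image resolution*
(intrinsic PSF plus reconstruction smoothing), default **11 mm FWHM**, not
the detector resolution. This is a deliberate design decision: under
Gaussian blur the volume-recovering threshold for a 13 mm sphere only
exceeds the 37 mm sphere's once the blur is ≳ 8 mm — below that the small
sphere sits past the partial-volume crossover and the published
small-needs-higher-threshold pattern cannot arise at all. At 11 mm / 8:1
the simulated calibration lands close to published multi-workstation values
(e.g. ~63–65% for the smallest sphere vs ~46–48% for the largest). Both
parameters are configurable.

**Cohort.** Each patient carries one sphere-like lesion on a uniform
SUV ≈ 1 background in a 48³ × 2 mm volume. True SUVmax is log-normal with
arithmetic mean 9.9 and SD 4.7; true volume is log-normal with mean 20 cm³
and SD 15 cm³ (mean matches typical NSCLC staging cohorts; the SD is chosen
to give a realistic right-skewed spread while keeping lesions inside the
grid, clipped to [0.8, 80] cm³). Injected activity is normal 364 ± 75 MBq
truncated at 0; uptake time uniform on 50–70 min; sex ratio 42F:56M with
sex-specific weight/height normals (M 80±12 kg, 176±7 cm; F 68±12 kg,
163±6 cm — ordinary adult anthropometrics). The lesion plateau
concentration is chosen so the pre-blur peak encodes the true SUVmax
exactly given that patient's decayed activity and weight. All draws flow
from one seed through per-patient spawned substreams, so any record is a
pure function of (spec, seed).

**Software variants.** Three simulated readers differ in small conventions:
LBM support (one variant lacks it, mirroring workstations without an LBM
workflow), a smoothed-maximum reference (the threshold is a percentage of a
4 mm-smoothed max rather than the raw hottest voxel), a threshold grid step
(2% vs 1%), and a small multiplicative calibration offset (0.97 / 1.03).
A pure scale offset cancels in %-of-max segmentation, so it shifts SUV and
TLG but not MTV; the smoothing and grid conventions shift MTV — the same
dissociation seen between real packages.

What the generator does **not** emulate: reconstruction (OSEM/TOF),
attenuation/scatter, spatially correlated noise, respiratory motion,
heterogeneous lesion uptake and irregular shapes, multiple lesions per
patient, and observer variability. Passing tests therefore demonstrate
correctness of the measurement chain and statistical calibration under an
idealized imaging model — not that real inter-software discrepancies are
fully reproduced.

## Comparison statistics

Pearson correlation per parameter × unit system for every variant pair,
labelled with the conventional bands on |r| (0.7–1 very strong, 0.5–0.7
strong, 0.3–0.5 moderate, 0–0.3 low; boundaries assigned to the higher
band). Paired differences are tested with a normality-gated choice:
Shapiro–Wilk on the differences at α = 0.05, then paired t-test (normal) or
Wilcoxon signed-rank (otherwise), with the chosen test reported — the
gating is reproducible and defensible whichever test the original analysts
used. Summaries are mean ± sample SD (n−1; population SD is a switch).
Identical vectors make the difference test degenerate; such cells carry the
label "degenerate (identical)" and a NaN p-value rather than a fabricated
1.0. No multiple-testing correction by default; Holm is available but off.
Shapiro–Wilk and the difference tests are delegated to SciPy and
cross-checked in the test suite against R's implementations on frozen
samples.

## Numerical choices and edge cases

- Threshold grid is integer 1–99% (published calibrations quote integers).
- The brute-force optimum re-scan is kept as a regression oracle in tests.
- An all-zero or empty search region is a segmentation error, not an empty
  mask; an empty mask is MTV 0 but rejects metric extraction.
- `optimal_threshold` on a flat objective (noise-free binary sphere)
  returns 1 by the tie-break, by contract.
- Log-space bin assignment is used because sphere volumes are
  geometrically spaced.

## Problem sizes

Default test and acceptance runs use the 2 mm phantom grid (≈ 3.7×10⁵
voxels), cohorts of 8–98 patients at 48³ voxels, 200 null repetitions for
type-I calibration and 20 seeded cohort runs for offset-detection power;
these sizes give stable statistics while keeping a full run in minutes on
one CPU.
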