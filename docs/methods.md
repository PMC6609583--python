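# Methods

## The measurement model

WS-TLG quantifies skeletal tumour burden on a co-registered FDG-PET/CT
study as the summed total lesion glycolysis of every FDG-avid focus inside
the CT-defined bone compartment:

* **Bone segmentation.** A voxel belongs to the skeleton iff its CT
  attenuation is *strictly* greater than the HU threshold (default 152 HU).
  The strict comparison is a deliberate convention (the boundary value is
  excluded); the threshold is configurable. CT and PET grids are
  harmonised by interpolating the HU values trilinearly onto the PET voxel
  centres *before* thresholding, which gives smooth partial-volume
  behaviour at bone edges; transporting a pre-thresholded mask with
  nearest-neighbour sampling was rejected as blockier. Voxels outside the
  CT field of view are non-bone by definition. Manual clean-up (metal
  artefacts, extra-skeletal calcification) is expressed as an exclusion
  mask subtracted from the bone mask, with every operation recorded in the
  mask's provenance trail.
* **Lesion extraction.** Candidate voxels are bone voxels with SUV
  strictly above the cutoff (default 4.0). Lesions are connected
  components of the candidate set; 26-connectivity is the default (the
  usual convention for hot-spot labelling), with 6/18 available because no
  published rule fixes lesion separation. No minimum lesion size is
  imposed; single-voxel lesions are kept but flagged in reports so noise
  sensitivity can be audited.
* **Summation.** Each lesion contributes TLG = volume(mL) × SUVmean, with
  SUVmean taken over the supra-cutoff voxels only; WS-TLG is the sum.
  Since volume × mean = voxel_volume × Σ SUV, the total is invariant to how
  the candidate set is partitioned into components, and is monotone
  non-increasing in both the SUV cutoff and the HU threshold. Positivity
  is defined as WS-TLG > 0.

### Lytic cavities and `fill_bone_cavities`

A purely HU-thresholded mask excludes the interior of an osteolytic lesion
whose trabecular bone has been destroyed, even though that territory is
unambiguously skeletal; clinically such lesions remain enclosed by residual
cortical bone. `RunConfig.fill_bone_cavities` (and the `fill_holes` keyword
of `resample_mask_to_grid`) applies binary hole filling so cavities fully
enclosed by supra-threshold bone count as bone. The default is **off**,
keeping the plain threshold rule; the phantom validations of lytic and
mixed lesions enable it, and real-data users measuring lytic disease
should too. Hole filling preserves the mask's monotonicity in the HU
threshold (filling is inclusion-monotone).

## SUV and SUL

SUV(v) = calibration × activity(v) / (decayed_dose_Bq / body_mass_g), with
the injected dose decayed once from injection to scan start
(2^(−Δt/half-life); F-18 half-life 109.77 min; per-bed-position decay is
out of scope). Tissue density is taken as 1 g/mL. SUL replaces total body
weight with Janmahasatian lean body mass —
male 9270·W/(6680 + 216·BMI), female 9270·W/(8780 + 244·BMI) — the form
recommended for PERCIST; vendor workstations do not always document their
LBM formula, so SUL-based comparisons across software carry that caveat,
and the formula is isolated in one function should a different convention
be needed. The dimensionless `calibration_factor` (default 1) rescales
SUVs between scanners that read a reference phantom differently (older
systems can read 20–30% low); it is a single scalar, not a harmonisation
model. Volumes already exported in SUV units are passed through unchanged.

## Response criteria (bone-restricted)

Up to two osseous target lesions with the highest uptake are followed;
ties in the selection metric break deterministically by larger volume,
then lowest voxel index. PERCIST is evaluated on the **sum** of the
target SULpeaks (mirroring the EORTC "sum of SUVmax" usage; a
hottest-single mode is available), in this order: new lesion ⇒ PMD;
increase ≥ 30% and ≥ 0.8 SUL units ⇒ PMD; follow-up at or below the
background reference ⇒ CMR; decrease ≥ 30% and ≥ 0.8 SUL units ⇒ PMR;
otherwise SMD. The background reference for CMR is user-supplied (a
mean + 2SD of a normal-bone ROI is the suggested convention); published
practice leaves "background level" undefined. A baseline SULpeak of 0
cannot anchor a percent change: those cases are classified with EORTC
(new lesion or Δ ≥ +25% ⇒ PMD; complete resolution ⇒ CMR; Δ ≤ −25% ⇒ PMR;
else SMD; uptake appearing from a zero baseline ⇒ PMD). A change of
therapeutic regimen resets the baseline and re-selects targets. New-lesion
status is an input flag, not computed by spatial matching — in practice it
is a visual call.

SULpeak is the maximum, over spheres centred at every lesion voxel, of the
mean SUL across all voxels whose centres fall within a 1 mL sphere
(radius 6.20 mm); at image borders the mean is over in-grid voxels. If
the sphere covers only one voxel centre the measure degenerates to SUVmax
with a warning.

**Trajectory grouping.** A longitudinal WS-TLG series is *favorable* if no
successive difference is positive, *progressive* if none is negative and
at least one is positive, *fluctuating* otherwise. The strict-sign rule
with zero tolerance reproduces the published 4/5/6 grouping of all 15
reference series; a tolerance parameter exists for noisy series but
defaults to 0.

## Cutoff selection and cohort summaries

A study is test-positive iff WS-TLG > 0. Specificity is the negative rate
among patients without skeletal metastasis, sensitivity the positive rate
among those with it; both are reported unrounded and rounded half-up to
integers (printed style). "Comparing specificity and sensitivity" is
operationalised as maximising Youden's J = sens + spec − 100 with ties to
the lowest cutoff — the only standard rule that reproduces the published
choice of 4.0 from the reference scan (3.5: 81/97, 4.0: 91/97, 4.5:
94/91); a minimum-specificity rule is available. SD conventions: CT-type
stratification defaults to population SD (ddof = 0), normal-bone site
summaries to sample SD (ddof = 1); both are parameters, since the
reference tables do not state their convention.

## The phantom generator

The generator emulates exactly the features the pipeline consumes: a
soft-tissue CT compartment (40 HU) with spherical bone sites (700 HU)
carrying physiologic marrow uptake at published normal-site means
(sternum 1.43, rib 1.27, Th7 2.29, L3 2.33, ilium 1.66), spherical focal
lesions with the four CT morphologies (lytic carves HU to soft tissue,
blastic raises it above bone, intertrabecular leaves CT unchanged —
the "invisible type" — and mixed does both in halves split at the
equatorial plane), then optional isotropic Gaussian PSF blur of the PET
only (CT stays sharp; mask partial-volume behaviour is exercised by
resampling) and additive Gaussian noise, clipped at 0. Geometry is
deterministic; the seed drives only the noise. The default grid is
128×128×160 at 2.6×2.6×3.0 mm, approximating clinical PET sampling at a
tractable extent; tests use smaller grids of the same voxel scale.

Lesions must not overlap each other, so every lesion's volume (4πr³/3) and
TLG are closed-form and `truth_wstlg` is exact for unblurred, noiseless
phantoms; for blurred or noisy phantoms it refuses and a relative
tolerance band is offered instead. Sphere centres placed on voxel centres
keep voxelized volumes within ~2% of analytic; arbitrary alignment can
reach ~5% at radii near 4 voxels, which is the tolerance used in the
pipeline-recovery tests.

What the phantom does **not** model: realistic skeletal anatomy, scanner
reconstruction (OSEM/PSF) noise texture and correlations, respiratory
motion, marrow heterogeneity, or CT artefacts. Passing phantom tests
therefore demonstrates the correctness of the measurement chain
(geometry, masking, labelling, arithmetic), not clinical detectability or
inter-scanner robustness on patient data.

## Numerical conventions and degenerate inputs

* Strict comparisons at both thresholds (HU > 152, SUV > cutoff); boundary
  values are excluded.
* A voxel is a point sample at its centre; world space is right-handed
  axis-aligned millimetres; oblique NIfTI affines are rejected rather than
  silently approximated.
* Empty bone mask or all-subthreshold volume ⇒ empty lesion list and
  WS-TLG 0 (not an error); an empty ROI for SUVmax ⇒ error.
* Half-up rounding for printed percentages; unrounded values retained.
* SUV/SUL volumes must be non-negative; interpolation jitter above −1e−6
  is clipped to 0.
* Reports serialise with sorted keys and are byte-identical across reruns
  of identical inputs and configuration; inputs are identified by SHA-256
  hashes of the raw voxel data.

## Problem sizes

Test and acceptance phantoms use grids of 40³–56³ voxels at 2.0–2.6 mm
spacing — the same voxel scale as clinical PET at a smaller extent, chosen
to exercise every pipeline stage with sub-second studies. The monotonicity
suite runs 50 seeded random phantoms; the brute-force oracle comparisons
use ≤ 20³ volumes where a pure-Python flood fill is exact and fast.

## Known limitations

* The 152 HU bone rule misses osteopenic trabecular bone and marrow-space
  disease unless it is enclosed (see `fill_bone_cavities`) or FDG-avid
  within supra-threshold bone.
* WS-TLG is blind to FDG-non-avid metastases by construction; a WS-TLG of
  0 does not exclude disease.
* Absolute WS-TLG values are scanner-dependent through SUV; the scalar
  calibration factor is a coarse correction only.
* Response concordance between WS-TLG trajectories and PERCIST/EORTC
  categories is reported but not asserted numerically; no published
  concordance rule exists.
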