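# Methods

This note documents the models, numerical rules and design choices behind
`intralobe`, in the spirit of a statistical-methods appendix.

## Study design being emulated

A within-patient randomized comparison of intra-arterial versus systemic
exposure of liver metastases to a radiolabelled somatostatin analogue.
Each eligible patient has at least one metastasis ≥ 3 cm in each liver
lobe; one lobe (left or right hepatic artery) is randomized to receive the
activity intra-arterially over four treatment cycles, and uptake is
quantified on the post-treatment emission scan of every cycle. Because
both arms live in the same patient, between-patient heterogeneity in
receptor expression, tumour burden and pharmacokinetics cancels in the
within-patient contrast.

## Phantom model

The synthetic patient is deliberately minimal — it carries exactly the
features the quantification and inference chain consumes and no more:

* **Geometry.** The liver is an axis-aligned ellipsoid (default semi-axes
  110 × 85 × 75 mm on a 64³ grid of 4 mm isotropic voxels), split by a
  plane into a left lobe holding one third of the volume and a right lobe
  holding two thirds, the approximate anatomical ratio. The plane offset
  solves the ellipsoid-cap volume equation exactly. Lesions are spheres
  with diameters drawn from 30–50 mm, 1–3 per lobe; overlapping (confluent)
  lesions are allowed. A spherical healthy-liver reference VOI (radius
  16 mm → ≈ 17 mL, above the 15 mL floor) is placed first in the control
  lobe and lesions keep clear of it. Placement is rejection sampling with
  cheap analytic pre-filters; the accepted position is the one whose
  *voxelized* sphere lies fully inside the voxelized lobe, which is the
  invariant downstream code relies on. An infeasible configuration raises
  a placement error after a bounded number of attempts.
* **Counts.** Expected counts per voxel are: 0 outside the liver, `b`
  (default 20) in normal liver, `b·m` in lesion voxels of the control
  lobe and `b·m·ρ` in lesion voxels of the treated lobe on post-cycle
  volumes, where `m` is the patient's lesion-to-background multiplier and
  `ρ` the intra-arterial enhancement. Observed volumes are independent
  Poisson draws of these expectations (switchable off for exact tests).
  All of a patient's lesions share one multiplier so that in the
  noise-free limit the measured `T/N_IA / T/N_control` equals `ρ`
  exactly; lesion-to-lesion uptake heterogeneity would make the
  volume-weighted lobe means differ by construction, not by treatment.
* **Truth distributions.** `m ~ LogNormal(ln 16.2, 0.8)` and
  `ρ ~ LogNormal(ln 1.17, 0.39)`. The medians reproduce the scale of a
  real trial of this design (control-lobe T/N ≈ 16, enhancement ≈ +17 %);
  0.39 is the within-patient log-ratio SD obtained by inverting a
  two-sided one-sample *t* p-value of 0.045 at n = 27 for a mean log-ratio
  of ln 1.17; 0.8 makes the raw between-patient SD of T/N roughly equal to
  its mean, matching the wide dispersion such trials report. The
  multiplier is floored at 2.5: a lesion-to-background ratio below
  1/0.42 cannot be isolated by the 42 %-of-max threshold (background would
  cross it), and such faint lesions would not be selected as targets.
* **Misalignment.** The baseline (receptor image) grid and each
  post-cycle grid may differ by a rigid transform (default identity;
  optionally a bounded random translation). Cycle volumes are rendered by
  evaluating the analytic geometry at inverse-transformed voxel centers,
  so the recorded transform is the true registration and VOI transfer can
  be tested against known ground truth. Estimating the registration is
  out of scope.
* **Follow-up diameters.** One trajectory per lobe is drawn from a joint
  3/6-month mixture (default weights 25 % early response, 10 % late
  response, 4 % late progression, 61 % stable), identical for both lobes —
  the no-differential-response null. Trajectories are drawn jointly, not
  per timepoint, so that a deep 3-month response cannot be followed by an
  uncorrelated rebound that would spuriously read as progression from the
  nadir. The default weights reproduce response tables with ≈ 25 % partial
  response at 3 months and ≈ 35 % / 4 % partial response / progression at
  6 months.
* **Laboratory panel.** Fifteen analytes (hepatic, haematological, renal)
  with baseline values drawn inside normal ranges, an 8 % chance per
  patient-analyte of an abnormal (grade 1–3) baseline, multiplicative
  visit-to-visit noise (log-SD 0.06) and a 12 % chance of one follow-up
  visit one grade above baseline — a treatment-emergent event under the
  delta rule.

What the phantom does **not** model: acquisition and reconstruction
physics (collimator response, attenuation, scatter, partial-volume
blur), anatomical realism beyond lobe/lesion topology, receptor-binding
pharmacology, and lesion-level uptake heterogeneity. Passing tests
therefore validate the *computational chain* under its stated assumptions,
not the physics of any scanner.

## Quantification rules

* **Segmentation**: rough VOI → keep voxels ≥ 0.42 × the maximum voxel
  value inside the rough VOI, computed on the baseline receptor image;
  restrict to the 26-connected component containing the maximum voxel
  (standard for blob-like lesions). The maximum voxel is always retained;
  a rough VOI with maximum 0 is an error.
* **VOI transfer**: each source voxel center is mapped through the rigid
  transform and assigned to the nearest target voxel; duplicates collapse,
  out-of-grid points are dropped with a logged count, an empty result is
  an error. No partial-volume weighting — errors are bounded by a
  one-voxel surface shell.
* **Peak uptake**: mean counts in a 10 mm-diameter sphere centred on the
  hottest VOI voxel, using the voxel-center-in-sphere rule in world
  coordinates; the sphere may leave the VOI but is clipped at the grid
  edge. Ties at the maximum break to the lowest lexicographic (i, j, k)
  index. The sphere radius must be at least half the largest voxel
  dimension.
* **T/N**: volume-weighted (VOI mL) mean of lesion uptake divided by the
  control-lobe reference mean. Volume weighting makes the numerator the
  aggregate concentration over all target tissue. Uptake stays in raw
  counts per voxel: T/N is scale-free, so no SUV calibration is applied,
  and a global rescaling of a volume provably leaves every T/N unchanged.

## Inference

* Primary contrast: paired *t* on cycle-1 `(T/N_IA − T/N_control)`;
  equivalently a one-sample *t* on the differences. Secondary: the same
  test on natural-log T/N with point estimate and CI exponentiated (a
  geometric ratio). All p-values are two-sided; no multiplicity
  adjustment. Pairs with a missing side are dropped per cycle
  (available-case analysis). Zero-variance differences are reported with
  their exact point estimate, a zero-width CI and an undefined (NaN)
  p-value flagged `degenerate` — except the all-zero case, where p = 1 is
  exact. The numeric zero-variance threshold is relative (10⁻¹² of the
  data scale) so that mathematically constant ratios computed in floating
  point are recognized.
* All-cycle model: `tn = β₀ + β·arm + u_patient + v_patient:cycle + ε`
  with independent random intercepts per patient and per cycle within
  patient, fitted by REML (statsmodels `MixedLM`; REML because n is small
  and variance components are the point). With a single cycle the two
  grouping levels coincide, so the cycle component is dropped and
  reported as 0 — this also makes the balanced single-cycle β identical
  to the paired-*t* mean difference, which is tested to 10⁻⁶ relative.
  Boundary (singular) variance estimates are reported, not hidden;
  non-convergence raises.
* Covariates (hypervascularity, treated lobe, tumour burden) are tested
  as covariate × arm effect-modification terms in the same model.
* Response tables are compared with an exact conditional Fisher test for
  r × c tables by complete enumeration of tables with the observed
  margins, summing the probabilities of tables no more probable than the
  observed one (ties included with a 10⁻⁹ relative tolerance). The sum is
  normalized by the enumerated total, which removes floating-point drift
  and makes identical-column tables return exactly 1.0. Complexity grows
  quickly with the margins; response-table sizes (total ≲ 50, 2–4
  categories) enumerate in milliseconds. A table with a single observed
  category carries no contrast and is reported as p = 1 by the pipeline.
* Power: exact noncentral-*t* power of the paired test, noncentrality
  `d_z·√n`, df `n − 1`. At d_z = 0.65, α = 0.05 two-sided, the exact
  answer first reaches 90 % power at n = 27 (power 0.9015; n = 26 gives
  0.8896). Designs computed with one-sided tests or normal approximations
  quote 26; the package returns the exact two-sided result and documents
  the difference rather than forcing agreement.

## Response and toxicity rules

* RECIST 1.1 on per-lobe sums of target-lesion diameters (each lobe is a
  lesion set, because the lobes are the randomized arms): CR when the sum
  is 0; PD when the sum grew ≥ 20 % from the nadir **and** ≥ 5 mm
  absolute; PR when the sum shrank ≥ 30 % from baseline; SD otherwise; PD
  takes precedence over PR. The nadir is the minimum of all prior sums
  including baseline. All bounds are closed. CR is unreachable with
  ≥ 30 mm baseline lesions but implemented for completeness. A patient
  missing an assessment is excluded at that timepoint only.
* Laboratory toxicity grading is table-driven: per analyte a direction
  (high/low) and up to four monotone thresholds, compared with closed
  bounds (≥ for high, ≤ for low). The shipped default table is an
  **approximate** CTCAE-v5-style table in SI units and should be replaced
  by a site-verified table for real analyses. An event is
  treatment-emergent only when the worst follow-up grade exceeds the
  baseline grade (the baseline-delta rule); worst ≤ baseline never emits
  an event, by construction of the event type.

## Randomization

Permuted blocks with sizes drawn uniformly from {1, 2}: a size-2 block
contains one left and one right in random order, a size-1 block is a fair
coin. Size-1 blocks weaken strict balance — the design is implemented as
specified rather than "improved". The sequence is deterministic given the
seed, and the trailing block is truncated to the cohort size.

## Problem sizes and determinism

The test and acceptance suites run at sizes chosen to make Monte-Carlo
bands tight while keeping a desk-scale footprint: oracle equivalence on
100 random 8³ volumes; enhancement recovery on 200 single-patient 64³
phantoms with Poisson noise (the between-patient truth SDs are set to 0
there, isolating measurement noise — between-patient variation is the
subject of the tabular recovery study instead); parameter recovery and CI
coverage on 200 tabular cohorts of n = 27; type-I error on 1000 null
cohorts. Replicate studies at the statistical level use the tabular
simulators (`simulate_paired_tn`, `simulate_tn_long`), which draw directly
from the model the analyses assume; image rendering is exercised where the
voxel chain itself is under test. Every stochastic component takes a
`numpy` seed, identical seeds reproduce byte-identical manifests, and the
pipeline records the seed and a config hash in every report.

## Known limitations

* The phantom's lesions are homogeneous spheres; no partial-volume effect
  exists, so the quantification chain is validated under conditions more
  benign than clinical SPECT.
* The peak statistic on a noise-free uniform lesion ties at every lesion
  voxel and resolves to an edge voxel whose sphere includes background;
  peak-based T/N is therefore only approximately ρ even without noise.
  With noise the maximum is interior and the statistic behaves as
  intended.
* `MixedLM` Wald p-values are asymptotic; at n ≲ 10 patients they are
  anticonservative, and the paired tests are the primary inference at
  small n.
* The default CTCAE-style thresholds are approximations; grading output
  should not be interpreted clinically.
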