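# Methods

## Problem and model

The package detects the epileptogenic zone (EZ) in focal, MR-negative
epilepsy from three diffusion parametric maps per subject — mean
diffusivity (MD, µm²/ms), fractional anisotropy (FA, dimensionless in
[0, 1]) and mean kurtosis (MK, dimensionless ≥ 0) — assumed co-registered
on one grid.  Epileptogenic tissue is modelled as carrying the signature
↑MD, ↓FA, ↓MK, at two spatial scales: a widespread deep white-matter
change over the affected lobe (captured by asymmetry of the WM skeleton)
and a focal cortical/juxtacortical change (captured by a voxel-wise
three-way overlap).  Detection is single-subject inference: one patient
against a control cohort.

## Step 1: skeleton asymmetry and lobar index

*Skeleton.*  The cohort-mean FA (patient plus controls) is thresholded at
`fa_skeleton_threshold` (default 0.2, excluding partial-volume superficial
WM) and thinned to a medial surface: a supra-threshold voxel is kept when
its Euclidean distance to the thresholded boundary is ≥ 2 voxels and a
local maximum along at least one grid axis.  The result is symmetrized by
intersection with its own mirror image about the midsagittal plane (the
plane between the two central sagittal slices; grids must have an even
left-right extent).  This replaces the TBSS perpendicular-projection
search with direct voxel sampling — adequate for smooth co-registered
maps; for real data a precomputed skeleton mask can be supplied and is
then symmetrized and thresholded the same way.  Right-hemisphere skeleton
voxels are paired with their mirror voxels; pair order is lexicographic in
the right member, so outputs are deterministic.

*Asymmetry.*  Per pair, `AI = (R − L)/(R + L)`.  AI is antisymmetric under
hemisphere swap, bounded in (−1, 1) for positive inputs and invariant
under common rescaling.  A zero denominator aborts (physical maps are
positive on WM; a zero indicates a masking bug), rather than silently
emitting 0.

*Inference.*  Per pair, an OLS fit of AI on [intercept, patient-indicator,
sex, age(centered)] gives the group-coefficient t (df = n − 4; equal to
the unequal-n two-sample t with n₁ = 1 when covariates are absent).  The
positive part of the one-tailed t map is TFCE-enhanced
(E = 0.5, H = 2, dh = max/100, 26-connectivity — the standard published
defaults) and compared with the permutation distribution of the maximum
enhanced statistic.  With a single patient, the permutation universe is
which subject carries the patient label; the group column of the design
is reassigned to each other subject in turn while data and covariates stay
attached to their subjects, so each null statistic is the covariate-
adjusted deviation of one subject.  We initially implemented Freedman–Lane
residual permutation here, but direct measurement on iid-Gaussian nulls
(400 runs, 20 controls + 1 patient, sex/age covariates) showed it
anticonservative for this design (family-wise error ≈ 0.09 at nominal
1/21 ≈ 0.048, driven by the reduced-model leverage at small n), while
direct relabeling measured 0.040–0.043; the package therefore uses direct
relabeling.  At cohort sizes like 100 controls the two schemes coincide in
practice.  p-values use the +1 correction, `p = (1 + #{max_perm ≥
obs})/(1 + n_perm)`, so the smallest attainable p with N subjects is 1/N —
with 101 subjects ≈ 0.0099, comfortably below the 0.05 level; cohorts of
fewer than 20 controls cannot reach significance at 0.05.

*Lobar aggregation.*  Both one-tailed tests are always run, since either
direction is diagnostically meaningful: increased MD asymmetry implicates
the right hemisphere and increased FA/MK asymmetry the left (and vice
versa), because AI is signed right-minus-left and pathology raises MD but
lowers FA/MK.  Significant pairs are mapped to the implicated hemisphere's
voxel coordinates, connected components (26-neighborhood restricted to the
skeleton; stricter connectivity fragments thin sheets) below
`min_cluster_voxels` (default 20) are discarded per (lobe, hemisphere,
tail), and `LAI = surviving / N_vx(lobe)`.  The argmax (ties broken by
higher surviving count, then lobe name) is the detected lobe; a subject
with no surviving voxel has no significant lobar detection.  Lobe
membership of a skeleton pair is the atlas label at the voxel (nearest
nonzero label as fallback); the parcellation itself is an input, since no
canonical lobe atlas is assumed.

## Step 2: iDrArK overlap

Within the analysis brain mask, per metric a parametric one-tailed t-map
(same GLM; MD tail "greater", FA/MK tail "less") is thresholded at
`voxelwise_p` (default 0.001, uncorrected, strict inequality).  The three
binary maps are intersected; 26-connected components smaller than
`min_cluster_voxels` are removed.  The same constructor with one or two
masks yields the single-metric and pairwise comparison maps (MD, FA, MK,
MD_MK, MD_FA, FA_MK).  If step 1 was significant, voxels outside the
selected lobe are removed and the size filter re-applied (a cluster split
by the lobe boundary may leave a sub-threshold remnant); restriction is
idempotent and never adds voxels.  Subjects without a significant lobar
result keep the unrestricted map.

## Evaluation

The resection zone is dilated by a Euclidean ball of `erz_dilation_mm`
(default 10 mm) in world units (per-axis scaling handles anisotropic
voxels), implemented via the sampled distance transform.  A cluster counts
as inside the eRZ when a strict majority (> 50%) of its voxels is inside —
a deliberate middle ground between any-overlap (inflates hits) and full
containment (punishes boundary clusters).  `PPV = NC_eRZ / NC`; SD iff
PPV ≥ `ppv_success_threshold` (default 0.5, boundary inclusive), NS iff no
clusters, UD otherwise; `accuracy = SD/(SD+UD)` (undefined and reported as
null when no subject is significant) and `DR = (SD+UD)/total`.  Reported
percentages are rounded to the conventional reporting precision (one
decimal, or integer where customary).

## Synthetic cohorts

The generator emulates what the pipeline assumes about preprocessed,
smoothed, co-registered maps — not raw DWI, k-space, cortical folding or
registration error:

- ellipsoidal brain on a 40×48×40 grid at 2 mm isotropic by default (so
  the 10 mm dilation is a 5-voxel ball), mirror-symmetric across the
  midsagittal plane; lobes are mirror-symmetric anterior–posterior slabs
  per hemisphere; WM is a 3-voxel interior erosion;
- mean fields: MD 0.8 µm²/ms, MK 1.0, FA 0.45 in deep WM tapering below
  0.2 toward the edge (linear in boundary distance over 4 voxels);
- per subject, a smooth multiplicative random field (Gaussian-filtered
  white noise, σ = 2 voxels, rescaled to CV 3% inside the brain — the low
  end of the 3–5% band plausible for smoothed, registered maps; chosen a
  priori so that a 15% lesion effect is detectable at p < 0.001 with
  realistic control-group sizes) plus 1% unsmoothed voxel noise; FA
  clipped to [0, 1], MD/MK to ≥ 0;
- lesions: a ball with the ↑MD/↓FA/↓MK signature at full strength over
  the inner 75% of its radius and a linear partial-volume ramp on the
  outer quarter; the resection zone is the un-tapered ball.  Optionally a
  fractional MK reduction over one lobe's deep WM (the widespread change
  step 1 targets);
- demographics: sex balanced, age uniform 20–45 (bracketing typical
  adult cohort medians); they carry no planted effect and only exercise
  the covariate path;
- all per-subject randomness derives from independent child seeds of one
  root seed, so cohorts are reproducible and order-independent.

Passing tests on these phantoms demonstrates the pipeline's logic
(symmetry handling, inference calibration, aggregation and scoring
arithmetic), not clinical performance: real maps have anatomy-dependent
variance, registration error, and correlated metric noise from a shared
tensor fit, none of which are modelled.

## Numerical choices and problem sizes

- TFCE integrates from dh to the map maximum with a Riemann sum; the
  constant-map value n^E·h^(H+1)/(H+1) is matched within the first-order
  dh bound, and halving dh halves the error.
- Grid mismatches are hard errors everywhere; nothing is resampled
  silently, because the pairing and overlap logic require exact voxel
  correspondence.
- Default experiment sizes in the test-suite/acceptance demonstrations:
  30 controls for lobar recovery, 60 for voxel-wise recovery (a scaled-
  down version of a 100-control clinical cohort), 20 for null calibration
  on a 20×24×20 phantom — sizes at which each property is comfortably
  decidable on a single CPU in minutes.

## Known limitations

- The skeleton thinning is a medial-surface ridge, not the TBSS
  projection; on strongly folded real WM the two differ, which is why an
  external skeleton mask can be supplied.
- Single-metric/pairwise maps share the step-1 restriction logic, so
  comparisons between map families are like-for-like, but no attempt is
  made to reproduce any particular clinical cohort's per-patient results.
- The permutation test's resolution is limited by cohort size (min
  p = 1/N); covariate handling assumes linear age/sex effects.
- MD units only need to be internally consistent; all statistics are
  comparisons or ratios of like quantities.
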