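# Methods

## Scope

`icvkit` evaluates *measurement protocols* for intracranial volume (ICV),
not images: every analysis runs on binary cavity masks with known voxel
spacing. Its pipeline mirrors a two-phase rater/tool study: reference
manual tracing (operator 1, phase I), repeat tracing (operator 1, phase II)
for intra-operator variation, a second operator (reported under phase I in
the measurement table) for inter-operator variation, simulated automated
tools in both phases, a randomized slice-subsampling reliability analysis
on the reference tracings, and an agreement/ANOVA battery.

## Phantom model

A subject's cranial cavity is a voxelized perturbed ellipsoid. In
spherical coordinates about the grid center, the surface is

    r(θ, φ) = r_ell(θ, φ) + A · P(θ, φ),

with `r_ell` the radius of an ellipsoid with semi-axes (a, b, c) mm and
`P` a seeded band-limited field normalized to max |P| = 1, scaled by the
roughness amplitude `A` (mm). A voxel is occupied iff its **center** lies
inside the surface — the same convention as voxel-count volumetry, which
keeps the estimator chain exactly self-consistent. The constraint
`A < min(a,b,c)/2` keeps the surface star-shaped, so the mask is one
26-connected component (checked at generation).

`P` is a separable sinusoidal expansion with two parts:

* a **zonal corrugation** `Σ_{j=1..order} z_j cos(jθ + ψ_j)` whose
  azimuthal mean survives integration over each slice. This is the only
  part that materially perturbs the slice-area profile `a(z)`, and its
  axial wavelength (≈ 2πc/order near the equator) is what interacts with
  the sampling period: once the period approaches half that wavelength,
  interleaved sampling aliases the corrugation and the estimate degrades.
* a low-order **azimuthal texture**, damped by sin θ so the surface stays
  single-valued at the poles; it adds 3D irregularity without affecting
  subsampling much (purely azimuthal structure cancels within a slice).

This design is a deliberate choice, not a neutral one. Smooth band-limited
bumps (e.g. low-degree spherical harmonics) make a cavity look rough while
leaving the axial profile easy to sample — in experiments, subsampling
error *fell* slightly with such perturbations, because they disrupt the
systematic end-cap error pattern of a pure ellipsoid. What makes sparse
slice sampling genuinely harder is axial structure at the sampling scale,
so that is what the roughness knob controls.

Whether real AD cavities differ from controls by anything like axial
corrugation is unknown — the group contrast attributes the difference in
safe sampling period entirely to surface geometry, with roughness as the
single controllable surrogate. Passing tests show the *pipeline* resolves
such differences in the stated direction; they do not validate the
anatomical mechanism.

### Cohort presets

| parameter | AC-like | AD-like | note |
|---|---|---|---|
| target ICV mean ± SD (L) | 1.4609 ± 0.14444 | 1.4870 ± 0.16418 | group distributions the cohorts emulate |
| semi-axes template (mm) | (76, 68, 62) | (76, 68, 62) | rescaled per subject to the volume draw |
| roughness amplitude (mm) | 1.5 | 4.5 | AD rougher |
| roughness order | 4 | 18 | AD corrugation wavelength ≈ 22 mm axially, at the sampling scale |
| n per group | 11 | 11 | study design default |

Per-subject volumes are N(mean, SD) draws truncated at ±3 SD (truncation is
symmetric, so the mean is exact and the SD shrinks < 3%; it also guarantees
every subject fits its grid with the required 2-voxel margin). Semi-axes
scale isotropically as the cube root of the drawn volume. Default geometry
is a 192³ grid at 1 mm in-plane, 1.5 mm slice spacing along axis 2; tests
and the acceptance script use coarser grids (2.5 mm in-plane) because
center-rule voxelization is nearly unbiased, so statistics about volumes
and sampling periods survive coarsening while phantom generation stays
fast. Demographics (age ~ N(81, 9.31) with 6F/5M for AD-like; N(71, 6.21)
with 9F/2M for AC-like) feed only the GLM.

## Measurement-noise models

**Operator tracing.** Within each 2D slice, each voxel near the in-plane
cavity boundary receives an independent radial error δ ~ N(0, sd) (mm) and
is included iff its signed distance to the boundary is ≤ δ. Zero jitter
reproduces the input bit-exactly. The noise is per boundary voxel, not a
rigid per-slice shift: manual contouring errs point by point along the
contour, the errors largely cancel within a slice, and only such
cancellation can produce the observed whole-volume error scale (MRPA of
order 10⁻²–10⁻³ %) — a rigid sub-voxel slice shift is simply erased by
binarization. `calibrate_operator_jitter` bisects the SD against a
Monte-Carlo MRPAD estimate to hit a target error scale.
`simulate_tracing_icvs` evaluates the same flip model without
materializing masks (the per-voxel flip probabilities depend only on the
precomputed signed distances), which makes 10⁴-draw null simulations cheap.

**Automated tools.** `output = true × bias × (1 + ε)`, ε ~ N(0, cv).
Presets: `fs_like` (bias 1.08, cv 0.04) — mildly overestimating
atlas-based tool; `fsl_like` (2.77, 0.08) — grossly overestimating
affine-scaling tool (MRPAD ≈ 177% at zero noise); `spm_like` (0.90, 0.05)
— mildly underestimating tissue-segmentation tool. These reproduce
magnitudes, not any particular software's behavior.

## Reliability analysis

For each sampling period `m` (default grid 2…40) and each of `n_reps`
(default 5000) repetitions, a start offset is drawn uniformly from
{0, …, m−1} **independently per subject** (a shared-start mode exists;
independent starts model raters who each pick their own starting slice).
Each subject's estimate is `m ×` (sum of sampled slice volumes), anchored
at the first occupied slice and stopping at the last. The draw records

* ICC(2,1) between estimates and references — absolute agreement, so a
  systematic subsampling bias is penalized; the consistency variant is
  available as an option;
* MPE — the maximum over subjects of |est − ref|/ref × 100 (aggregation
  over subjects per repetition; the across-repetition [p5, p95] of MPE is
  reported as its 90% interval).

Implementation note: for a given `m` there are only `m` distinct estimates
per subject, so they are tabulated once and repetitions index into the
table; the two-way ANOVA decomposition is vectorized across repetitions.
Results are identical to the naive loop, draw for draw.

Percentiles use linear interpolation between order statistics (NumPy's
default inclusive rule) — with 5000 draws the estimator choice is minor,
but determinism requires fixing one.

### Guidelines

* `confidence_icc`: period `m` qualifies iff the 5th percentile of its ICC
  draws ≥ 0.99 (i.e. ICC above threshold with 95% probability). Other
  confidences map onto the tabulated percentiles.
* `tight_spread`: `m` qualifies iff ICC p95 − p5 ≤ 0.005.

The reported maximum safe period is the largest `m` such that **every**
smaller tested period also qualifies. The ICC becomes erratic at large
periods, and an isolated pass beyond a failure is not a safe protocol
recommendation. "No period qualifies" is a result, not an error. Periods
are also reported in mm (`m ×` slice spacing) because slice counts do not
transfer across acquisitions; slice spacing is therefore an explicit input
everywhere.

## Agreement battery and GLM

MRPAD, paired two-sided t (p from the t distribution with n−1 df), and
Pearson r are computed per method against the reference (operator 1,
phase I) within each group, and per method between phases (intra-method
consistency). Zero-variance differences with nonzero mean are flagged
degenerate (t = ±inf, p = NaN) rather than silently approximated; identical
samples give t = 0, p = 1.

The factor analysis is one ordinary least-squares GLM of ICV on Group,
Sex, Age (mean-centered) and Method with interactions up to the four-way
term, reported as Type III F/p with sum-to-zero contrasts. Method is
physically within-subject, but the battery follows the single
between-style GLM layout; the Method F therefore ignores within-subject
correlation, which is conservative about nothing in particular and is
flagged here rather than fixed (a mixed model is out of scope). Post-hoc
method-vs-reference contrasts are plain paired t-tests, which test the
same nulls without contrast-machinery dependencies. Rank-deficient designs
fail loudly, naming the aliased term; the study driver falls back to the
largest estimable interaction order and records it in the report. Tests
are two-sided at α = 0.05 with no multiplicity correction.

## Determinism

Every stochastic step derives its generator from explicit integer seeds
(`numpy` `SeedSequence`); stage seeds hash the master seed with a stage
label. Two runs of `run_study` with one seed produce byte-identical
report JSON (no timestamps; sorted keys; the config hash excludes output
location).

## Problem sizes

Defaults mirror the study design (n = 11 per group, 5000 repetitions,
periods 2–40). The test suite and acceptance script use the sizes chosen
for this package's own verification runs: 2.5 mm in-plane grids, 500
repetitions, periods 2–30, 20 cohort replicates for the group-contrast
check, and 10,000 simulations for the type-I calibration.

## Known limitations

* No intensity simulation, bias fields, tissue classes, skull/dura
  rendering, or registration — masks only, by design.
* The roughness surrogate is an assumption (see above); magnitudes of the
  group difference in safe sampling period depend on preset choices, only
  the direction is a tested claim.
* Tracing noise is spatially white along the contour; real raters make
  correlated errors (consistent over- or under-inclusion of dura), which
  would shift MRPA for the same jitter SD.
* The estimator-error bound `|est − ref| ≤ m × max slice volume` holds for
  near-unimodal cavity profiles, and is tested there; it is not a theorem
  for arbitrary occupancy profiles.
* Guideline percentile estimates at 500 repetitions carry Monte-Carlo
  noise of a slice or two; the 5000-repetition default tightens them.
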