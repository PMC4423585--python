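# icvkit

Protocol evaluation for intracranial volume (ICV) estimation on synthetic
cranial-cavity phantoms.

ICV — the volume of the cranial cavity bounded by the dura — is the
standard head-size normalizer in brain morphometry, and especially in
Alzheimer's disease (AD) studies, where regional atrophy measures are
meaningless without it. Measuring ICV manually means tracing the cavity in
every MRI slice, which is so slow that practitioners trace only every
*m*-th slice and scale up (a Cavalieri estimator). That raises two protocol
questions this package answers quantitatively:

1. **How sparse may the slice sampling be** before the estimate stops being
   reliable — and does the answer differ between patient groups (rougher,
   atrophic cavities) and controls?
2. **How much can automated tools be trusted**, given their biases differ
   across groups?

Because suitable MRI cohorts cannot be shipped, the package generates
voxelized phantoms with known ground truth: radially perturbed ellipsoids
whose surface roughness, cohort volume distribution (AD-like:
1.4870 ± 0.16418 L; AC-like: 1.4609 ± 0.14444 L), operator tracing noise
and automated-tool bias/noise are all controllable and seeded.

## The statistics at its core

* **Cavalieri subsampling estimator.** With slice areas `a_i` (mm²), slice
  spacing `t` (mm), sampling period `m` and start offset `s` relative to
  the first occupied slice, `ICV_hat = m · t · Σ_j a_{f+s+jm}`. For `m = 1`
  this equals voxel-count volumetry exactly, and the average over all `m`
  start offsets recovers the full volume identically.
* **Reliability via randomized resampling.** For each `m`, start offsets
  are redrawn per subject and the intraclass correlation between estimates
  and the every-slice reference is recorded; the default 5000 repetitions
  give an empirical ICC distribution per period. The ICC is the
  single-measure absolute-agreement two-way random-effects coefficient
  ICC(2,1) = (MS_R − MS_E) / (MS_R + MS_E + 2(MS_C − MS_E)/n).
* **Guidelines.** The maximum safe period under (a) the confidence
  criterion — 5th percentile of the ICC draws ≥ 0.99, i.e. reliability
  above 0.99 with 95% probability — and (b) the tight-spread criterion —
  ICC p95 − p5 ≤ 0.005 — using a contiguous-from-smallest rule, reported in
  mm (`m` × slice spacing) so it transfers across acquisitions.
* **Agreement battery.** MRPAD = (1/n) Σ |est_i − ref_i| / ref_i × 100,
  paired t-tests, Pearson r, maximum percentage error (MPE), and a
  four-factor Type III GLM of ICV on Group, Sex, Age and Method with
  sum-to-zero contrasts.

## Worked example

```python
import icvkit as ik

spec = ik.ac_like_spec((80, 80, 128), (2.5, 2.5, 1.5))   # control-like preset
cohort = ik.generate_cohort(spec, 11, "AC", master_seed=42)
masks = [m for _, m, _ in cohort]
refs  = [t for _, _, t in cohort]        # every-slice reference ICVs (L)

est = ik.subsample_icv(masks[0], m=10, start_offset=3)
print(refs[0], est.icv_l, est.period_mm)  # 1.5008  1.5067  15.0

draws = ik.run_randomized_reliability(masks, refs, range(2, 31), n_reps=500, seed=1)
curve = ik.summarize_curve(draws)
print(curve.loc[[5, 10, 15], ["icc_p5", "spread", "mpe_max"]])
#      icc_p5   spread  mpe_max
# 5   0.99986  0.00009  0.24167
# 10  0.99807  0.00109  1.07265
# 15  0.98719  0.00792  2.09057

res = ik.guideline_max_period(curve, "confidence_icc", slice_spacing=1.5)
print(res.max_period_slices, res.max_period_mm)   # 13 slices = 19.5 mm
```

Reading: tracing every 10th slice (15 mm) of this control-like cohort keeps
the ICC above 0.99 in ≥95% of random starts with at most ~1.1% error in the
worst subject; the guideline says sampling may not exceed 19.5 mm. Rough
AD-like cohorts (`ik.ad_like_spec`) come out stricter — typically 15–18 mm.

The same pipeline runs end to end from a config:

```bash
icvkit report --seed 7 --out study_out --n 11 --reps 5000
```

writing cohort manifests, the measurement table, reliability curves,
guideline JSONs, agreement batteries, the ANOVA table and a deterministic
`report.json`. Individual stages (`simulate`, `trace`, `tools`,
`subsample`, `reliability`, `guideline`, `compare`, `fixtures`) can be run
and re-run in isolation from their persisted files.

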