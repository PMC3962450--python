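# Methods

## Signal model and tensor fitting

Diffusion-weighted signal follows the mono-exponential Stejskal-Tanner
model, S_i = S0·exp(−b_i·gᵢᵀ D gᵢ), with D a symmetric 3×3 diffusion
tensor in mm²/s, b in s/mm², and g a unit gradient direction. Fitting is a
two-stage chain per voxel:

1. **Log-linear initializer.** Ordinary least squares of ln S on the
   7-column design [1, −b·gx², −2b·gx·gy, −2b·gx·gz, −b·gy², −2b·gy·gz,
   −b·gz²], requiring ≥ 7 measurements including ≥ 1 b = 0 and a
   full-rank direction set. Because magnitude data can hit zero under
   noise, signals are floored before the log transform at 1e-6 of the
   voxel's b0-mean S0 estimate (absolute 1e-12 if that is non-positive).
2. **Nonlinear least squares.** Levenberg–Marquardt on (S0, D) jointly — S0
   is estimated, not fixed from the b0 mean — minimizing Σ(S_i − Ŝ_i)², with
   analytic Jacobian, gradient tolerance 1e-10 (scaled by 1 + SSE), relative
   step tolerance 1e-12, and at most 200 iterations. Only strictly improving
   steps are accepted, so the NLLS objective provably never exceeds the
   initializer's. Damping decreases ×0.3 on success and increases ×10 on
   rejection (capped at 1e12; a rejection at the cap terminates as a local
   minimum). Non-convergence returns the best iterate flagged, never raises.
   The implementation is batched over voxels, so a whole volume is fitted
   with a handful of vectorized linear solves per iteration.

Eigendecomposition sorts eigenvalues descending, with a deterministic
eigenvector sign convention (first nonzero component ≥ 0) so repeated runs
are bit-identical. Negative eigenvalues from noisy fits are retained in the
stored tensor field but clamped to 0 for metric derivation only, keeping
FA ∈ [0, 1] and diffusivities non-negative without biasing the stored fit.
FA of the all-zero tensor is defined as 0.

The default foreground mask keeps voxels whose mean b0 signal exceeds 10%
of the volume's 99th-percentile b0 signal; the pipeline passes the phantom's
exact label mask instead, since the simulator knows its own geometry.

## The synthetic cohort

The phantom emulates the *statistical design* of a back-to-back test-retest
study, not brain anatomy. Regions are non-overlapping axis-aligned boxes in
a small grid (default 20×20×10 at nominal 2 mm isotropic, RAS+ affine),
each with a homogeneous ground-truth tensor: anisotropic "white-matter"
regions with distinct principal directions and near-isotropic "grey-matter"
regions, bilateral structures as separate left/right labels. Background has
zero signal (air).

Variability is multiplicative and log-normal with mean exactly 1:

- per subject and region, an eigenvalue scale factor with coefficient of
  variation `between_subject_cv` (default 0.10);
- per scan and region, an independent factor with CV `within_subject_cv`
  (default 0.02, a plausible scan-rescan magnitude; the true physiological/
  scanner split is unknown, so it is a free parameter);
- Rician noise |(s + n₁) + i·n₂| with σ = `rician_sigma` (default 1.0
  against S0 = 100, i.e. b0 SNR 100 — comfortable, so that reliability is
  dominated by the configured variance structure rather than by noise).

Scalar scaling of eigenvalues preserves positive-definiteness by
construction and makes region-mean MD inherit the configured structure
exactly: the raw-scale true ICC is cv_b²/(cv_b² + (1+cv_b²)·cv_w²), and
`cv_between_for_icc` inverts this so cohorts can be simulated at an exact
target ICC. The deliberate flip side: FA is invariant under scalar
eigenvalue scaling, so the phantom gives FA essentially no true
between-subject variability and its ICC is noise-driven and low. Passing
tests therefore validate the estimators, not a claim that FA is unreliable
in real brains — real FA varies between subjects anatomically, which this
phantom does not model. Other unmodelled features: motion, eddy currents,
susceptibility distortion, crossing fibres, spatially varying noise,
registration error.

The disease group ("hd") receives a deterministic mean shift: +10%
diffusivity in all regions and an eigenvalue flattening toward isotropy
(−10% of the anisotropic excess) in white-matter regions, lowering FA —
a stylized early-Huntington's profile that gives the patient group larger
between-subject spread. Cohort metadata (age, CAG repeat length, total
functional capacity) are simulated per group, and disease burden is
age × (CAG − 35.5).

Randomness derives from one global seed with substreams keyed by
(seed, subject index, repeat), so adding subjects never changes existing
ones, and everything — volumes, tables, maps — is bit-reproducible.

## Reliability statistics

The reliability model is one-way random effects with k = 2 exchangeable
repeats: x_ij = μ + b_i + e_ij. Estimators are the ANOVA method of moments,
σ̂²_w = MSW and σ̂²_b = max(0, (MSB − MSW)/2); the negative-part truncation
keeps ICC(1,1) = σ²_b/(σ²_b + σ²_w) in [0, 1]. ICC(1,1) (absolute
agreement, single measurement) is the right variant because back-to-back
scans have no rater structure. If both components are zero the ICC is
undefined and carried as an explicit flag (file output writes "NA", never
0). Groups are never pooled for ICC; Bland-Altman pools them.

**Confidence intervals.** The 95% CI uses the delta method with Fisher's
large-sample variance V(ρ) = 2(1−ρ)²(1+(k−1)ρ)²/(k(k−1)(n−1)). The default
construction applies the delta method on the variance-stabilized arctanh
scale — where for k = 2 the standard error is exactly 1/√(n−1),
independent of ρ — and back-transforms, truncating to [0, 1]. The plain
interval ρ̂ ± z·√V(ρ̂) (`transform="identity"`) is also provided; it was
not chosen as the default because evaluating V at the point estimate makes
it anti-conservative in small samples (Monte-Carlo coverage ≈ 0.906 at
ρ = 0.8, n = 12, versus ≈ 0.942 for the transformed interval — the
acceptance script recomputes this coverage at run time). CIs require n ≥ 3;
smaller groups get a point estimate with the CI omitted.

Voxelwise ICC maps apply the identical decomposition per voxel, vectorized
with the same floating-point operation order as the scalar routine, so map
values equal a per-voxel loop bit for bit. Zero-total-variance voxels are
written as 0 and counted. Bland-Altman uses differences repeat1 − repeat2,
SD with the n−1 denominator, and limits of agreement mean ± 1.96·SD;
per-pair (mean, difference) coordinates are exported as TSV for external
plotting. Outlier sensitivity recomputes the full reliability result with
one subject removed (requires n ≥ 4). No multiple-testing correction is
applied anywhere: the outputs are estimates with CIs, not hypothesis tests.

The regional summary reports, per metric and group, the number and
percentage of regions with ICC ≥ 0.8 and the unweighted mean ICC across
regions (undefined ICCs count toward the region total but not the mean).

## Pipeline design

Each subject's two scans are randomly assigned to analysis streams A and B
by a seeded fair coin per subject (in sorted subject order), each stream
receiving exactly one scan per subject; all downstream statistics pair
stream A against stream B. Atlas-style regions are measured under a
per-stream FA template (the voxelwise mean FA over that stream's subjects)
thresholded strictly at FA > 0.2; T1-style regions (here: the grey-matter
boxes and cerebral white matter) are measured unthresholded, and a config
key can exclude a subset of controls from the T1-ROI path to reproduce a
reduced-sample analysis. The run manifest records the config echo, seeds,
library versions, per-stage wall times, non-convergence and
undefined-voxel counts, and the output file list; since wall times are
inherently non-deterministic, reproducibility is asserted over all TSV
outputs except the manifest.

## Problem sizes

The default desk-scale study is 22 subjects × 2 repeats × 49 volumes on a
20×20×10 grid and runs in a few seconds. Calibration experiments use
image-level cohorts of 200 subjects on a 4×4×2 single-region grid (10
cohorts per target ICC) and measurement-level simulation — the same
log-normal scaling model without image formation — for the n = 500 bias
check (200 replicates) and the CI coverage experiment (1000 cohorts of
n = 12). Measurement-level simulation is used exactly where image formation
adds nothing: with zero noise the fitted region mean equals the scaled
truth, which the image-level round-trip tests verify independently.

## Known limitations

- The phantom's FA carries no true between-subject variability (see above).
- Region homogeneity means region means have zero spatial averaging error;
  partial-volume effects exist only through the template-FA threshold.
- The delta-method CI is a large-sample construction; at n ≪ 10 its
  coverage degrades and an exact or bootstrap interval would be preferable.
- The two-stream design here consumes scans that are already in voxelwise
  correspondence; with real data, stream independence would also cover
  registration and template construction, which this package does not
  implement.
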