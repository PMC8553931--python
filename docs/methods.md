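# Methods

This note documents the models, algorithms and parameter choices behind
`dynfc`: what each stage computes, what the synthetic data generator does and
does not emulate, and the numerical conventions that make the pipeline's
results reproducible and testable.

## Synthetic cohort model

The generator produces three groups (FOG, NFOG, HC; default 25
subjects/group) of 4D BOLD-like grids (default 16×16×16 voxels at 3 mm, 185
volumes at TR = 2 s).

**Signals.** Every voxel series is Gaussian noise restricted by an ideal
frequency mask to the resting-state band (0.01–0.1 Hz) and standardized to
unit variance. A *planted effect* links a seed region to a target region
through a latent unit-variance signal *u(t)* and a coupling series *c(t)*:

- seed voxels: `u + σ·noise`
- target voxels: `c(t)·u + sqrt(1 − c(t)²)·v_i + σ·noise`

where `v_i` is an independent band-limited series *per target voxel* and
σ = 0.5 is the voxel-noise scale. With this construction the expected
windowed correlation of a target voxel with the seed tracks *c(t)* (up to an
attenuation from voxel noise), while the correlation *sampling* noise is
independent across target voxels — as it is for real cortical voxels, whose
fluctuations beyond the shared coupled component are local. That
independence is what lets cluster-extent inference accumulate evidence over
a region; a shared `v` would make every target voxel's window-correlation
estimate rise and fall together and reduce the cluster test to a single
effective voxel.

**Coupling dynamics.** `c(t) = b + a·sin(2π·t·TR/P + φ)` with random phase
φ per subject. A sinusoid keeps the window-SD analytically predictable: a
window of length *W* attenuates the modulation by |sinc(W/P)| and the SD of
the windowed coupling approaches `a·sinc(W/P)/√2`. The default period
P = 180 s is slower than both analysis windows (60 s and 100 s), so a
planted variability effect survives the 50 TR validation window
(attenuation ≈ 0.56 at 100 s vs ≈ 0.83 at 60 s). An optional reflected
random-walk modulation with matched RMS is provided for robustness checks.
Per-subject modulation amplitudes are drawn around the group value with
coefficient of variation 0.25 (clipped to keep |c| < 1): subjects genuinely
differ in effect strength, which is what the clinical-correlation stage
estimates.

**Atlas.** 28 compact 2×2×2 seed boxes (14 nuclei × 2 hemispheres, labels
1–28, reuniens excluded) on a lattice with one-voxel gaps, plus two reserved
boxes for the WM and CSF masks and, on grids of ≥12 voxels per side, four
4×4×4 "cortical target" regions (labels 101–104) in the free half of the
grid. Planted effects project a nucleus seed onto a cortical target,
mirroring the asymmetry of seed-to-voxel analyses (a nucleus is small; the
coupled cortical patch is not). Real anatomical geometry is out of scope.

**Clinical table.** Ages, MMSE, illness duration, UPDRS III, LEDD and
Hoehn-Yahr stages are drawn from normal distributions matching the published
group summaries (NA outside the patient groups). NFOGQ scores
(20.52 ± 5.54, clipped to [1, 28], FOG only) are generated with a
configurable correlation ρ (default 0.6) to each subject's true modulation
amplitude, giving the association analysis a recoverable ground truth.

**Motion.** Translations/rotations are cumulative random walks with
per-volume steps of 0.02 mm and 2·10⁻⁴ rad — gentle drift that exercises
the Friston-24 regression and FD computation without triggering motion QC.

**What the generator does not emulate** — hemodynamic response, physiological
noise, scanner artifacts, spatial autocorrelation at generation (smoothing
induces it downstream), 1/f spectra, anatomical geometry. Passing recovery
tests therefore show the *pipeline* is correct and well calibrated under its
own assumptions, not that in-vivo effects of this size would be detectable.

## Preprocessing

Fixed stage order: volume discard (first 10) → slice timing (a no-op for
synthetic data, kept in the stage list for fidelity) → nuisance regression →
band-pass → smoothing. All stages are pure functions.

- **Nuisance design (28 columns):** the 24-parameter motion expansion
  [p, p one-step-back, p², (back)²] with zero-padding at the first time
  point, a linear trend, WM and CSF mean signals, and an intercept.
  Residuals are exact OLS residuals computed via QR on unit-RMS-scaled
  columns (scaling preserves the column space, so results equal the raw
  normal equations); rank-deficient designs drop dependent columns with a
  warning rather than failing silently.
- **Framewise displacement:** the Power formulation — sum of absolute
  backward differences of the three translations plus 50 mm × the absolute
  rotation differences — reported with a leading zero. Motion QC fails a
  subject if any excursion from the first volume exceeds 3 mm or 3°.
- **Band-pass:** an ideal DFT-mask filter retaining bins with
  0.01 ≤ f ≤ 0.1 Hz (DC removed as a consequence). The frequency-mask
  approach matches the common resting-state toolboxes and is exactly
  testable: on-bin sinusoids pass unchanged, out-of-band ones are
  annihilated to rounding error.
- **Smoothing:** per-volume 3D Gaussian, σ = FWHM/(2√(2 ln 2)) converted to
  voxels, reflect padding (stated so the delta-kernel test is well defined);
  FWHM = 0 is the identity. Smoothing is applied to the time series before
  FC (the data-level reading of "before statistical analysis"); a config
  switch (`smooth_domain="maps"`) exposes the map-level alternative.

## FC measures

Seed series are unweighted means over ROI voxels. Static FC is voxel-wise
Pearson *r* with the seed, Fisher-transformed with |r| clipped at 1 − 10⁻⁷
to keep maps finite (clipped voxels remain flagged); zero-variance voxels
get z = 0 plus a mask flag. Windows follow
`floor((T − length)/step) + 1` bookkeeping (30 TR/1 step on 175 volumes →
146 windows; 50 TR → 126). The Hamming taper is applied as weights inside
the correlation (weighted means, variances and covariance); the rectangular
taper reduces exactly to the unweighted correlation. Dynamic FC variability
is the per-voxel sample SD (denominator n − 1, stated because conventions
differ) of *r* across windows, computed on r values per the source wording;
a `z_domain` switch enables Fisher-z-domain SD.

## Group inference

Voxel-wise one-way fixed-effects ANOVA, df = (k−1, N−k). Voxels constant
across all subjects are defined as F = 0 (the 0/0 case). The
cluster-defining threshold is the F-scale upper-tail quantile of
F(k−1, N−k) at voxel p < 0.001. Clusters are connected components under
26-connectivity (6/18 available), and their family-wise error is controlled
by max-cluster-size permutation: group labels are permuted across subjects
(exchangeable under the one-way null), the maximal supra-threshold cluster
size is recorded per permutation, and each observed cluster gets
`p = (1 + #{perm max ≥ size}) / (n_perm + 1)`, significant at p < 0.05.
Permutation replaces parametric random-field theory deliberately: it is
assumption-light and its calibration is itself testable. Post-hoc tests are
pooled-variance two-sample *t* per pair, uncorrected at p < 0.001; clinical
association is the Pearson correlation of FOG cluster means with NFOGQ,
with p from `t = r√(n−2)/√(1−r²)`. By default the correlation stage
considers dynamic clusters whose FOG-vs-NFOG post-hoc contrast is
significant (`correlate_mode="all_significant"` lifts the gate). The
window-length validation recomputes dynamic FC at 50 TR on the same
preprocessed data and compares cluster-mean values across groups ROI-wise,
reporting the group ordering so directional concordance with the 30 TR
analysis can be read off.

## Summary statistics

Pooled-variance (Student) *t* from (mean, SD, n) rows — pooled rather than
Welch because it reproduces the published statistics exactly for unequal
SDs; Welch is available by flag. One-way ANOVA from summaries via
`F = MS_between/MS_within`. Pearson χ² without continuity correction
(again matching the published value). Mann-Whitney U uses the tie-corrected
normal approximation without continuity correction, signed so a
lower-ranked first sample gives Z < 0. Two of the published table's values
are not recomputable from printed data: the FD ANOVA (printed F = 1.132;
the rounded summaries give 1.241 — a rounding artifact of the three
decimals shown) and the Hoehn-Yahr Z (needs the raw ordinal data). Both are
excluded from exact-reproduction checks; the implementations are instead
validated against enumeration and permutation oracles.

## Operating-characteristic experiments

`dynfc.experiments` measures the pipeline on replicate cohorts; the same
code backs the acceptance tests and `scripts/acceptance.py`.

- **FWE calibration:** 200 no-effect cohorts of 8 subjects/group, 12³
  voxels, 120 volumes; one seed's static maps run through the cluster test
  with 199 permutations. The fraction of cohorts with any significant
  cluster should sit in the binomial neighbourhood of the nominal 0.05.
  Cohort and permutation counts are sized so the whole study runs in a few
  minutes on one CPU while leaving the band's resolution (1/200 per
  permutation) well below the tolerance checked.
- **Effect recovery:** 20 replicate cohorts of 25 subjects/group (12³ grid,
  185 volumes) with a single FOG-only dynamic-variability effect: base
  coupling 0.6, modulation amplitude 0.35, cortical target region,
  other parameters at generator defaults; inference with 499 permutations.
  Measured: the fraction of replicates with a corrected-significant cluster
  overlapping the target; among detected replicates, the fraction with a
  positive FOG correlation between cluster-mean SD and NFOGQ (scores
  generated at ρ = 0.6); and the fraction whose 50 TR recomputation keeps
  the FOG group highest at the detected cluster. The base coupling is set
  high deliberately: the sampling SD of a windowed correlation scales with
  (1 − r²), and a weakly coupled pair would bury a 0.35-amplitude
  modulation under estimator noise at this record length — the planted
  effect emulates a strongly connected nucleus–cortex pair.

## Numerical conventions and edge cases

- All randomness flows through explicit seeds (`numpy` `SeedSequence`
  spawning); identical seeds give bit-identical cohorts, maps and reports.
- Exactly constant series are detected with relative (not absolute)
  tolerance before correlation/ANOVA to keep rounding residue from leaking
  through equality checks.
- Correlations are clipped to [−1, 1] before the Fisher transform; the
  transform rejects |r| > 1 inputs outright.
- Empty supra-threshold sets, empty cluster lists, and cohorts with no
  significant clusters are all legal, empty results — not errors.
- NIfTI round-trips preserve data bit-exactly (float64) with voxel size and
  TR in the header; motion traces use the 6-column realignment-parameter
  text convention (mm, mm, mm, rad, rad, rad).

## Known limitations

- The synthetic generator's simplifications (above) mean absolute effect
  sizes do not translate to in-vivo detectability claims.
- The permutation test controls FWE for one seed's map; analysing 28 seeds
  multiplies the family, as it does in the emulated design.
- The Hamming taper is interpreted as correlation weights; toolboxes that
  use "Hamming window" purely as window-length terminology correspond to
  the rectangular setting.
- Slice-timing correction, EPI distortion correction, co-registration and
  nonlinear normalization are out of scope: synthetic volumes are generated
  already aligned.
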