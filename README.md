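# dynfc

Seed-to-voxel **static** and **sliding-window dynamic** functional
connectivity (FC) analysis for resting-state fMRI, with cluster-level
permutation inference and a synthetic BOLD cohort generator.

The package re-implements, as a fully tested pipeline, the analysis used to
compare thalamic-nuclei-to-cortex coupling across three groups — Parkinson's
disease with freezing of gait (FOG), without freezing (NFOG), and healthy
controls (HC). It is aimed at researchers who want a transparent, scriptable
version of this analysis whose every stage can be validated against planted
ground truth, without access to patient scans.

## The analysis

For each of 28 thalamic seeds (14 nuclei × 2 hemispheres, reuniens
excluded), after preprocessing (drop the first 10 volumes; regress out the
24-parameter motion expansion, a linear trend, and white-matter/CSF mean
signals; ideal band-pass 0.01–0.1 Hz; 6 mm FWHM Gaussian smoothing):

- **Static FC**: the voxel-wise Pearson correlation *r* of each voxel's
  series with the seed ROI's mean series, Fisher-transformed,
  *z* = atanh(*r*).
- **Dynamic FC variability**: seed-to-voxel correlation computed in sliding
  windows (30 TR length, 1 TR step, Hamming taper; TR = 2 s), summarized per
  voxel by the standard deviation of *r* across windows. A larger SD marks
  greater temporal fluctuation of coupling strength.
- **Group inference**: a voxel-wise one-way ANOVA (*F* with df = 2, N−3)
  across the three groups; clusters defined at voxel *p* < 0.001 are
  assessed with cluster-level family-wise error control by the
  max-cluster-size permutation distribution under group relabeling
  (significance at corrected *p* < 0.05); significant clusters get
  pooled-variance post-hoc pairwise *t*-tests (*p* < 0.001) and, in FOG, a
  Pearson correlation of cluster-mean FC with the NFOGQ severity score.
- **Window-length validation**: dynamic FC recomputed at 50 TR and compared
  ROI-wise at the clusters found at 30 TR.
- **Summary statistics**: the demographics table's tests (χ², one-way ANOVA,
  pooled *t*, tie-corrected Mann-Whitney *Z*) computed in closed form from
  printed mean ± SD rows.

Because the source study deposited no scans, the `synthdata` module
generates cohorts with known structure — band-limited BOLD-like signals, a
seed whose coupling *c(t)* to a target region is constant or sinusoidally
modulated with group-dependent amplitude, motion traces, tissue masks and a
clinical table — so recovery of planted effects is the test bed.

## Worked example

```python
import numpy as np
import dynfc
from dynfc import SummaryRow as S, inference

# closed-form statistics from printed summary rows
res = dynfc.anova_from_summary(
    [S(65.320, 8.385, 25), S(65.240, 6.796, 25), S(63.880, 8.212, 25)])
print(f"age ANOVA: F = {res.statistic:.3f}, p = {res.p:.3f}")
print(f"p for r=0.414 at n=25: {dynfc.pearson_p_from_r(0.414, 25):.3f}")

# simulate a cohort with a FOG-only dynamic-variability effect and run
# the dynamic FC group analysis at the planted seed
spec = dynfc.dynamic_effect_spec(rng_seed=7, n_per_group=25)
subjects, atlas, clinical = dynfc.generate_cohort(spec)
pre = [dynfc.preprocess_subject(s)[0] for s in subjects]
design = inference.GroupDesign(tuple(s.group for s in pre))
maps = []
for ds in pre:
    ts = dynfc.roi_mean_timeseries(ds.bold, atlas, 11, ds.brain_mask)
    stack = dynfc.windowed_fc(np.asarray(ds.bold, float), ts, dynfc.WindowSpec())
    maps.append(dynfc.dynamic_fc_map(stack).sd)
clusters, posthoc = inference.seed_group_analysis(
    np.asarray(maps), design, n_perm=499, rng=1)
for c in clusters:
    if c.significant:
        print(f"cluster: size = {c.size} voxels, "
              f"peak F = {c.peak_f:.3f}, p_FWE = {c.p_fwe:.3f}")
```

prints

```
age ANOVA: F = 0.267, p = 0.766
p for r=0.414 at n=25: 0.040
cluster: size = 48 voxels, peak F = 25.735, p_FWE = 0.002
```

The ANOVA and correlation lines reproduce the published demographics
statistics exactly from their printed summaries. The cluster line shows the
pipeline recovering the planted FOG-specific variability effect: a
48-voxel cluster at the planted cortical target survives cluster-level FWE
correction, its post-hoc tests isolate the FOG group (FOG vs NFOG
t = 6.059, FOG vs HC t = 4.908, NFOG vs HC n.s.), and the cluster-mean SD
correlates with the planted NFOGQ-like scores (r = 0.489, p = 0.013 in this
cohort).

## Command line

Each stage is independently invokable on the previous stage's outputs:

```sh
dynfc simulate   --config cohort.yaml --out cohort/
dynfc preprocess --input cohort/ --out pre/
dynfc fc         --input pre/ --cohort cohort/ --out maps/ --seeds 11
dynfc group      --maps maps/ --out grp/
dynfc table1     --clinical cohort/clinical.tsv --fd pre/fd.tsv
dynfc run        --config full_run.yaml        # whole pipeline
```

Exit codes: 0 success, 2 configuration error, 3 data error.

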