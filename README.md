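# methtraject

Longitudinal DNA-methylation trajectory analysis for two-phase
repeated-measures intervention studies — for example a cognitive
behavioral therapy course with an embedded acute fear-exposure session,
where blood methylomes are sampled at three timepoints around the acute
event and four across the weeks of treatment.

The package answers three questions epigenome-wide:

1. **Does immune-cell composition change?**  Leukocyte fractions are
   estimated from beta values by reference-based constrained projection
   (non-negative least squares onto cell-type profiles, renormalized to
   the simplex), and each fraction — plus the granulocyte-to-lymphocyte
   ratio GLR = Gran/(CD4T+CD8T+NK+B) — is tested for a time trend.
2. **Which CpGs change, and how?**  Per CpG, four linear mixed models
   are fit by maximum likelihood — fixed linear or quadratic time ×
   random intercept or intercept+slope, with age, sex, smoking, cell
   fractions and surrogate variables as covariates — and compared by
   likelihood-ratio tests (boundary χ² mixture for the variance
   component) and AIC.  The selected model's time-effect p (LRT against
   the model without time terms) feeds a dual ranking: statistical rank
   by p, biological rank by the maximum absolute difference between
   timepoint mean methylations on the raw beta scale, summed and
   sliced to a top-k candidate list.  Paired first-vs-last t tests with
   Benjamini-Hochberg correction screen for long-lasting changes, and a
   remission × time model probes outcome interactions.
3. **Do neighboring CpGs move together?**  A spatial DMR caller combines
   probit-transformed p-values with a distance-binned autocorrelation
   estimate (Stouffer–Liptak–Kechris), smooths each probe over a 750 bp
   window, calls seed-and-extend regions of ≥ 2 sub-threshold probes,
   and Šidák-corrects region p-values by covered extent over region
   width.

Because studies of this kind rarely deposit raw patient methylomes, the
package ships a first-class synthetic cohort generator
(`methtraject.synth`): beta values as cell-type mixtures with
time-varying proportions, CpGs with null/linear/transient subject-level
trajectories, covariate effects, remitter/non-remitter interactions and
spatially clustered probe runs — all with recorded ground truth, so
every stage is testable end to end.  See `docs/methods.md` for models,
defaults and limitations.

## Worked example

```python
import pandas as pd
from methtraject import synth, deconv
from methtraject.trajectories import cell_type_trajectory_scan

design = synth.StudyDesign(n_subjects=30, seed=7)
effects = synth.EffectSpec(n_cpgs=800, n_linear=40, n_quadratic=40,
                           n_clusters=4, cluster_size=5)
study = synth.generate_study(design, effects=effects)

props = deconv.deconvolve(study.beta, study.reference.profile_matrix)
scan = cell_type_trajectory_scan(props, study.phenotypes, "exposure")
with pd.option_context("display.float_format", lambda v: f"{v:.3g}"):
    print(scan[["selected_model", "p_time", "q_time"]])
```

```
          selected_model   p_time   q_time
cell_type
CD8T                  M1    0.252    0.294
CD4T                  M2 3.41e-07 5.98e-07
NK                    M2 2.58e-07 5.98e-07
Bcell                 M1    0.648    0.648
Mono                  M2  0.00094  0.00132
Gran                  M2  1.3e-24 9.12e-24
GLR                   M2 5.88e-22 2.06e-21
```

The generator plants an acute granulocyte surge balanced by CD4T/NK/Mono
dips at the middle exposure timepoint.  The scan recovers exactly that:
the pulsed fractions and the GLR select the quadratic model (M2) with
small FDR-corrected q-values — a transient response that returns to
baseline by 24 h — while the flat cell types (CD8T, B cells) select the
linear model with null p-values.

## Command line

```sh
methtraject simulate --config sim.yaml --out data/ --seed 1
methtraject run --config pipeline.yaml --out results/
```

`run` executes deconvolution → cell-type scan → inverse-normal transform
+ surrogate variables → per-CpG model fits → ranking and screens →
candidate-gene subset → DMR calling, writing fixed-column TSVs, a BED
per phase and a JSON run manifest.  Individual stages are available as
`deconvolve`, `preprocess`, `fit`, `rank`, `screen` and `dmr`
subcommands.  Outputs are byte-reproducible given config + seed.

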