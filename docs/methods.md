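# Methods

`methtraject` analyzes DNA-methylation trajectories in a two-phase
repeated-measures intervention design: a short acute phase sampled at
three timepoints around a provocation (before, 1 h after the peak, 24 h
after) and a gradual treatment course sampled at four (baseline,
mid-treatment, end, follow-up).  This note records the models, the
synthetic-data assumptions, the numerical choices, and the known
limitations.

## Cell-type deconvolution

Leukocyte composition is estimated per sample by constrained projection
of the beta vector onto a CpG × cell-type reference-profile matrix
(CD8T, CD4T, NK, B cells, monocytes, granulocytes): non-negative least
squares followed by renormalization to sum one.  This reproduces the
standard reference-based (Houseman-type) projection without an external
reference-library dependency; the reference matrix is a user input.  The
residual norm of the constrained fit is reported per sample as a
diagnostic.  The granulocyte-to-lymphocyte ratio is Gran / (CD4T + CD8T
+ NK + B); monocytes are excluded from the denominator, and a zero
lymphocyte sum yields a flagged missing value.  On noiseless mixtures
the projection is exactly invertible (recovery error < 1e-8), and on
logit-noise sd 0.05 mixtures with 500 discriminating CpGs the per-type
mean absolute error stays below 0.05.

## Preprocessing

Beta values are inverse-normal transformed per CpG before linear
modeling: Φ⁻¹((rank − c)/(n − 2c + 1)) with the Blom offset c = 3/8
(configurable to 0 or 1/2), average ranks at ties, missing values passed
through.  Features with under 80% complete samples or zero variance are
dropped with a logged count.

Surrogate variables are principal components of the feature × sample
residual matrix after regressing out the known covariates plus an
intercept ("SVA-lite"); they are orthogonal to the known-covariate
column space by construction.  The number of components is either set
directly (pipeline default: 2) or chosen by permutation-based parallel
analysis with 19 permutations.

Residualization (used where covariates cannot enter the model, e.g. the
paired screen) is per-feature OLS on covariates + intercept.  Because
the six estimated cell fractions sum to one, exactly one (granulocytes)
is dropped from every design that also contains an intercept.

## Candidate mixed models and selection

Per feature, four linear mixed models are fit by maximum likelihood
(never REML, so log-likelihoods are comparable across fixed-effect
structures), all sharing the covariates age, sex, cigarettes/day, five
cell-type fractions and the surrogate variables:

| model | fixed time terms | random effects |
|---|---|---|
| M1 | t | subject intercept |
| M2 | t, t² | subject intercept |
| M3 | t | intercept + independent slope |
| M4 | t, t² | intercept + independent slope |

Time is coded as the ordinal within-phase index centered at mid-phase;
the quadratic term is the squared centered index (reduces collinearity;
raw coding is available).  The two phases are always analyzed
separately.

Selection: within each random-effect family the quadratic term is kept
iff the χ²(1) LRT p < α (default 0.05); between the two family winners,
the random slope is kept iff the boundary 0.5·χ²(0) + 0.5·χ²(1) mixture
LRT p < α (the slope adds a single variance component, hence one
boundary df).  If the two family winners differ in fixed structure they
are not nested and the smaller AIC wins, with AIC = −2·logLik +
2·(fixed + residual + variance-component parameters).  Non-converged
fits are flagged and excluded; if none converge the feature is skipped
with a logged reason.

The time-effect p-value is the LRT of the selected model against the
same model with all time fixed effects removed (df 1 or 2); when the
reduced model fails, a Wald test on the time coefficients is used and
flagged.  Under the generator's null, the select-then-test p-value is
approximately uniform (Wald 95% intervals for a planted slope cover at
~93–95%), but not exactly so: the ~5% of null features for which the
quadratic model wins selection carry that already-significant quadratic
term into the df-2 time test, producing a mild excess of small p-values
— the usual post-selection-inference footprint of selecting and testing
on the same data.  A KS test at 500 features sits near the detection
boundary of this effect (p typically 0.03–0.3).

### The fitting engine

Fits use a profiled-ML engine specialized to this structure: one
grouping factor, random intercept, optional independent random slope.
The likelihood is profiled over the fixed effects and residual variance,
leaving only the variance ratios γ₀ = σ₀²/σ², γ₁ = σ₁²/σ² to optimize
(bounded 1-D search for intercept-only; L-BFGS-B with a Nelder-Mead
fallback for the two-ratio case, seeded from the matching intercept-only
fit).  Subjects with identical time vectors share one small Cholesky per
likelihood evaluation, so a genome-wide scan over thousands of CpGs is
tractable.  The engine agrees with statsmodels MixedLM (ML) to ~1e-5 in
log-likelihood and fixed effects on balanced and unbalanced data; that
cross-check is part of the test suite.

### Cell-type scan and interaction models

Each of the six cell fractions and the GLR is run through the same
candidate family (covariates: age, sex, cigarettes/day), with
Benjamini-Hochberg correction across the 7 outcomes per phase.  For the
treatment phase a remission × time model is fitted on the first and last
timepoints only (fixed: time, remission, interaction; random intercept)
and the interaction Wald p is reported.  The expression model for the
acute phase is value ~ t + t² + remission + t²×remission with a random
intercept, supporting pre-averaging of probe sets; it reports Wald p for
t² and the interaction.

## Ranking and screens

The statistical rank orders features by the selected model's time-effect
p (ascending); the biological rank by the maximum absolute difference
between timepoint mean methylations on the raw beta scale (descending).
Average ranks at ties; the sum of the two ranks orders the table, ties
broken by statistical rank then feature id, and the top k (default 100)
are marked.  p-values come from INT values while the biological
difference uses raw beta — an interpretable methylation difference.

The long-lasting-change screen runs two-sided paired t tests of last vs
first timepoint within subjects on residualized values, BH-corrected per
screen per phase; zero-variance differences are flagged missing and
excluded from the FDR family.  The candidate-gene screen recomputes
ranks and the FDR family within the annotated subset.

## DMR calling

The spatial caller combines per-probe p-values comb-p style.  The probit
transform z = Φ⁻¹(1−p) is used throughout (one-sided small-p
enrichment); p = 0 inputs are floored at 1e-300.  The autocorrelation of
z is estimated in contiguous distance bins (default 150 bp) up to the
window (default 750 bp); bins with under 10 pairs are interpolated from
neighbors, and correlations are clipped to [0, 1] when used in the
combination variance (negative noisy estimates would be
anti-conservative).  Each probe's p is replaced by the
Stouffer-Liptak-Kechris combination of the probes within ±window/2;
regions are maximal runs of sub-threshold smoothed probes (seed p <
0.05) with inter-probe gaps ≤ window and at least 2 probes.  The region
p combines the original (unsmoothed) member p-values with ACF
correlations; the Šidák correction raises it by total covered track
extent (summed per chromosome) over region width, computed via
log1p/expm1.

Known property: because the search spans several region sizes while the
Šidák exponent counts windows of the observed size only, the expected
number of Šidák-significant regions on i.i.d. uniform tracks is ~2–3×
the single-size nominal rate (~0.14 vs 0.05 per 2000-probe track).  The
brute-force oracle in the test suite reproduces the caller exactly, so
this is a property of the algorithm itself, consistent with published
reports of mild anti-conservatism for this family of callers.  Planted
5-probe clusters (z shift +3) are recovered in ≥ 90% of replicates.

## Synthetic cohort generator

The generator defines the study conditions for every test: a default
cohort of 50 subjects observed in both phases (arbitrary
exposure-only/both/therapy-only partitions are supported, including the
4/17/21 split of the motivating design), 5,000 CpGs, a remitter fraction
of 1/3, age ~ N(32, 10²) truncated to [18, 65], 64% female, 30% smokers.

Beta values are cell-type mixtures: per-sample compositions follow
baseline + linear drift + quadratic pulse per cell type with truncated
subject-level intercepts (sd 0.01), renormalized to the simplex.  The
default acute-phase pulses (+0.08 granulocytes, −0.04 CD4T, −0.03 NK,
−0.01 monocytes) sum to zero so the remaining types stay flat; the
treatment-phase drifts are an order of magnitude smaller, matching the
qualitative contrast between an acute response and a gradual shift.  On
top of the mixture, CpGs carry null / linear / transient trajectories
(default 150 + 150 effect CpGs of 5,000, amplitude 0.05 on the beta
scale, random sign), covariate effects, and 7 spatially clustered
5-probe runs (6 transient + 1 linear, spacing U[50, 400] bp) sharing a
latent per-sample effect (sd 0.15 logit) for DMR testing.  Noise (sd
0.30) and subject intercepts (sd 0.20) are added on the logit-beta scale
and back-transformed, keeping values in (0, 1) with clipping counted and
reported.  Remission enters as a multiplier (1 + interaction) on the
time terms for remitters, mirroring the downstream interaction models.
Expression is simulated as Gaussian intensities with subject intercepts;
the remitter and non-remitter mean curves differ exactly by the
specified interaction times the pulse shape.

Because composition itself moves over time, even null CpGs whose
reference profiles differ across cell types shift with the mixture term
— the confounding that motivates including cell fractions as covariates.
Closed-form mean checks in the tests therefore either use
time-constant compositions or reconstruct the mixture term explicitly.

What the generator does not emulate: array chemistry (probe types,
detection p-values), batch structure, genotype effects, realistic
genome-wide beta distributions, or the variance components of any real
cohort (none are published for the motivating study).  Passing tests
demonstrate the statistical machinery's operating characteristics under
these stated conditions, not performance on real arrays.

## Determinism and problem sizes

A single integer seed drives every random stream (split into fixed
substreams per stage); identical config + seed reproduce every output
byte, with wall-clock timings confined to the log file.  The shipped
operating-characteristic checks use 500 features for calibration and
coverage, 200 replicates per class for selection fidelity, 400 features
(80 shifted) at n = 38 for the screen, 100 replicates each for DMR
recovery and null calibration, and the full default cohort (50 subjects,
5,000 CpGs, both phases) run twice for the determinism check.

## Open choices made here

- The four-model family and the LRT-then-AIC order were fixed as
  {linear, quadratic} × {random intercept, +independent slope}; the
  slope enters as a single variance component so the boundary mixture
  has one df.
- FDR families are per phase and per screen.
- The statistical rank uses the selected model's time-effect p (not the
  minimum over candidates).
- The DMR input track uses a fixed model per phase — quadratic
  (M2-type) p-values for the acute phase, linear (M1-type) for the
  treatment phase — because per-CpG model selection would disturb the
  spatial correlation structure of the p-value track; the per-CpG
  selected-model track is also available.
- GLR denominator fixed to CD4T + CD8T + NK + B.
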