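# Methods

## Data model

A `CtMatrix` holds genes × samples cycle-threshold values (PCR cycles,
typically 10–40; lower Ct = more template) with per-sample metadata:
treatment ∈ {Control, SA, MeJA, ETH, ABA}, sampling time in hours, and
biological replicate. Technical replicates of the same (sample, gene)
well are averaged at read time, so every downstream n is the biological
n. Missing cells are explicit NaN; because all four stability
estimators assume complete matrices, a sample missing any gene in the
analyzed group is dropped with a warning rather than imputed — imputing
Ct would manufacture the very signal the estimators measure.

Sample groups follow the usual design: each hormone group is that
treatment across all time points; `Control` is every time-0 biological
replicate across treatment batches (the pre-induction state is shared,
and pooling time-0 replicates is the only grouping that gives the
Control group a usable n); `Total` is all samples.

## Relative quantities

GeNorm and NormFinder operate on relative quantities
Q = 2^−ΔCT with ΔCT taken per gene against that gene's minimum Ct, so
0 < Q ≤ 1. The calibrator choice is arbitrary — every statistic these
methods compute is invariant to per-gene rescaling of Q — and this one
bounds Q conveniently. Base 2 exactly, with no per-assay efficiency
correction, matching the standard ΔCT/ΔΔCT formulation; quantities and
ΔΔCT with measured efficiencies are deliberately out of scope of the
default path.

## The four estimators

**GeNorm.** For genes j, k let A_jk be the per-sample log2(Q_j/Q_k) and
V_jk its sample SD (n−1). M_j is the mean of V_jk over k ≠ j. The gene
with the largest M is excluded and M recomputed until two genes remain;
a gene's reported M is the value at its exclusion step, and the final
pair shares one M and rank 1 (their mutual log-ratio SD cannot
discriminate them). Exclusion ties are broken toward the later gene in
input order, logged, for determinism. Normalization factors NF_n are
per-sample geometric means of Q over the n most stable genes;
V(n/n+1) = SD(log2 NF_n/NF_{n+1}); the recommended reference count is
the smallest n with V < 0.15 (cutoff configurable), falling back to all
G genes with a warning when no V passes.

**NormFinder (basic variant).** On x = log2 Q, each sample's gene-mean
is subtracted (removing loading), giving z. With subgroups g of sizes
n_g: d_ig = mean_g(z_i) − size-weighted grand mean, v_ig the subgroup
sample variance, and

    stability_i = mean over g of ( |d_ig| + sqrt(v_ig / n_g) )

With a single subgroup the score is the sample SD of z_i. This additive
form keeps the intended behavior — penalize systematic between-group
shifts plus within-group noise — without the original small-sample
shrinkage corrections, which affect absolute values far more than
rankings; rankings are what the consensus consumes. Subgroups default
to time points within a hormone group, treatments within Total, and
single-subgroup mode for Control (a time-0-only group has no natural
split).

**BestKeeper.** Descriptive dispersion of *raw* Ct: "SD" is the mean
absolute deviation from the arithmetic mean Ct (the original tool's
convention; the n−1 sample SD is available behind a flag) and
CV% = 100·SD/mean. Ranking is ascending by SD with CV% as tiebreak.
BestKeeper is intentionally not loading-invariant — that contrast with
the ratio-based methods is asserted in the tests.

**Comparative ΔCT.** score_i = mean over j ≠ i of SD_samples(Ct_i −
Ct_j). Since log2(Q_i/Q_j) = Ct_j − Ct_i + const, this equals the
full-set GeNorm M exactly; the identity is exploited as a cross-method
oracle in the test suite.

All rankings break score ties by input order after the unrounded score.

## Consensus

The comprehensive stability value is the geometric mean of the four
per-method rank positions. GeNorm's tied final pair both contribute
rank 1; this convention (rather than ranks 1 and 2, or 1.5 each) is the
one that reproduces published comprehensive values exactly, which the
bundled six-group, ten-gene worked example verifies cell by cell.
Display rounds to 2 decimals; ordering uses unrounded values. If a
method is unavailable for a group the geometric mean adjusts to the
methods present (logged).

## Standard curves

Ct is regressed on log10 relative input (dilution step s of an f-fold
series sits at −s·log10 f) by ordinary least squares;
E% = (10^(−1/k) − 1) × 100 from the slope k, with R² from the same fit.
A slope of −3.32 is perfect doubling (100%). Positive slopes are
flagged as assay anomalies but still produce a (meaningless) E so the
batch report stays complete. All replicate points are fit, not
per-step means — with equal replication per step the OLS slope is
identical either way, and the residual spread then informs R².
Published efficiencies recomputed from 2-decimal printed slopes can
differ by ±0.1–0.2 because slopes were evidently rounded after E was
computed; only self-consistent rows are used as exact expectations.

## Relative expression

ΔCT = Ct_target − arithmetic mean of reference Ct (equivalently the
geometric mean of reference quantities, the standard multi-reference
normalization factor); ΔΔCT subtracts the calibrator-mean ΔCT (default
calibrator: the 0 h samples of the analyzed group), so RQ = 2^−ΔΔCT is
1 at the calibrator by construction. Per-time summaries are replicate
mean ± SD. Significance vs the calibrator is Welch's t on log2 RQ
(log2 because RQ is log-normal under the additive-on-Ct error model)
with stars at p < 0.05/0.01/0.001; no multiple-testing correction is
applied across time points, matching common practice in validation
figures — consumers doing formal inference should correct downstream.
`reference_choice_sensitivity` runs the same series under a stable and
an unstable reference set and reports the per-sample log2 ratio (max
and mean absolute), which is exactly the artifact an unstable reference
injects.

## Co-expression screening

*Tissue screen*: candidates plus the metabolite tissue profile are
clustered with average linkage on 1 − Pearson r (scale-free, so
candidates on different expression scales are comparable). A candidate
is selected when it falls on the metabolite's side of a two-branch cut,
correlates positively with the metabolite, and is expressed in the leaf
above a user threshold (the time-course tissue); selection is ordered
by cophenetic proximity. When no quantitative metabolite tissue
contents are available the qualitative ordering root > flower > stem >
leaf is encoded as rank weights (4, 3, 2, 1 respectively) — only the
ordering matters to a correlation distance. Constant profiles are
dropped (undefined correlation).

*Time-course correlation*: Pearson r between per-time replicate means
of gene RQ and metabolite content over the shared time points (six per
treatment in the standard design), two-sided p from t with n−2 df,
star classes as above. Means rather than all replicate pairs are the
default because replicate pairing across assays is artificial; a
replicate-level mode exists behind a flag. Pearson is the default
(continuous, roughly log-linear quantities); Spearman is available.
At n = 6 the p < 0.05 boundary sits at |r| ≈ 0.811 — the tests assert
the class transitions at the analytic boundaries.

## Synthetic data generator

Ct[i, s] = baseline_i + L_s + A_i·profile_i(treatment_s, time_s) + ε,
with L_s ~ N(0, σ_load²) shared by all genes of sample s, ε ~ N(0,
σ_rep²), and profile values in [−1, 1], 0 at time 0. Gaussian noise on
the Ct (log2) scale is the standard qPCR error model. Defaults: 10
candidate genes with designed amplitudes {0,0,0,0,1,1,2,2,3,3} cycles,
σ_load = 0.5, σ_rep = 0.2, 3 biological replicates, 4 hormones × 6
time points (72 samples), baselines spanning 17–28 cycles. Profiles
are explicit per-(treatment, time) tables (human-readable in the JSON
config), built from cyclic shifts of one base shape so genes respond
differently; the metabolite-coupled pathway trio shares a dedicated
sustained-suppression shape chosen to be nearly uncorrelated with every
cyclic shift, so uncoupled genes do not track content by accident.

Metabolite content is log2-linear in the coupled genes' expression
signal: log2 c = log2 c₀ + Σ w_i·(−A_i·profile_i) + noise, so positive
w means expression and content rise together. With a single coupled
gene at w = 1 and no noise, content is exactly proportional to the
gene's RQ series (r = 1); mixed couplings give strong but imperfect
correlation.

What the generator does *not* emulate: amplification-efficiency
differences between samples, pipetting outliers and non-Gaussian heavy
tails, inter-plate batch effects, Ct censoring at the cycle limit, and
biological autocorrelation between adjacent time points. Passing tests
therefore demonstrate correctness of the estimators and pipeline on
the stated error model, not robustness to every real-world artifact.

## Problem sizes and numerics

The bundled analyses run at the design scale of the motivating study
(10 + 15 genes, 72 samples, 5-point dilution series), which keeps the
full test suite in seconds. Cross-method identities are asserted to
1e−10; exact worked-example reproductions to the published 2-decimal
precision; stochastic parameter-recovery checks use fixed seeds with
Spearman ≥ 0.8 against the designed instability order. Degenerate
inputs (constant genes, zero-variance dilutions, single replicates,
subgroups of one) raise or warn as documented rather than returning
NaN silently.

## Known limitations

* NormFinder is the basic variant: rankings are faithful; absolute
  stability values will differ from the original implementation's
  bias-corrected estimates.
* Whether published BestKeeper "SD" columns are MAD or sample SD is
  not always decidable from tables alone; both are provided.
* Efficiency-corrected (Pfaffl-style) quantification is not
  implemented; the base-2 model is used throughout.
* The tissue screen's two-branch cut is a deliberate simplification of
  dendrogram inspection; unusual topologies may warrant manual review
  of the returned linkage.
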