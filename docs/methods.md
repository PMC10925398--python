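# Methods

This note documents the statistical model behind each pipeline stage, the
defaults and why they were chosen, what the synthetic generators do and do
not emulate, and the numerical choices that affect results.

## Data model

Abundance matrices are protein × sample with `nan` as the only missing
marker — zeros in exported intensity tables are treated as missing, never as
measurements. Protein identity is two-layered: the UniProt accession in
`UniProtID|GeneSymbol` keys matrix joins; the upper-cased gene symbol is the
identity for network-module, cell-type and gene-set matching, because
reference networks and marker lists are published as symbol lists.

## Preprocessing chain (TMT)

1. **Channel-sum normalization.** Each observed value is scaled by
   `max_k(S_k) / S_j`, where `S_j` is the sum of observed intensities in
   sample *j*. This equalizes total reporter-ion load across channels while
   keeping values on the intensity scale.
2. **Missingness filter.** Proteins missing in *more than* half the samples
   are removed (a protein missing in exactly 50% is retained). The default
   threshold 0.5 is a config key.
3. **TAMPOR.** For each protein and batch, a denominator `d_ib` is the
   median over the batch's denominator samples — the pooled
   global-internal-standard (GIS) channels by default, or all samples of
   the batch (`denominator: all_samples`); this choice is the "tunable"
   part. Log2 ratios `R_ij = log2(A_ij) − log2(d_ib)` are two-way median
   polished (alternately subtracting row then column medians until the
   largest adjustment < `tol = 1e-8`, at most 250 sweeps), and the
   per-protein log2 median abundance over all samples is added back.
   Because the GIS channels are the denominator of their own batch, their
   ratios are identically zero and the polished GIS profiles agree exactly
   across batches — the batch effect is removed, not merely shrunk.

   *Numerical choice*: all medians are computed on the log2 scale. With an
   even number of samples the median interpolates between the two central
   values, and linear-space interpolation differs from log-space
   interpolation by ~10⁻³ log2 units; log-space medians make
   `tampor(tampor(M)) == tampor(M)` exact. Missing cells are ignored by
   every median and stay missing; the chain never imputes TMT data.
4. **Bootstrap covariate regression.** Per protein, log2 abundance is
   regressed (OLS) on protected terms (diagnosis by default) plus nuisance
   covariates (batch by default; age/sex/PMI if present) over its complete
   cases; coefficients are averaged over `n_boot = 100` batch-stratified
   bootstrap resamples of the samples (rank-deficient resamples are skipped
   and replaced from a pre-drawn spare pool, so the resample sequence is
   deterministic given the seed). The corrected value subtracts only the
   covariate contributions, centred at the covariate means; protected
   effects pass through untouched. `n_boot = 0` degenerates to a single
   plain-OLS fit. Proteins with fewer complete cases than parameters are
   left uncorrected with a logged warning.

   *Known property*: removing fitted covariate effects in-sample slightly
   deflates residual variance (≈ q/n for q covariate parameters), so the
   downstream t-test is mildly anticonservative — measured ≈ 0.061 at
   α = 0.05 on null data through the full chain with five batches. This is
   inherent to correct-then-test designs, not to the bootstrap.

## LFQ fraction workflow

Fraction comparisons (input / flow-through / heparin-enriched triplicates)
use the 2-of-3 detection filter per fraction, the same channel-sum scaling,
log2 transform, and downshifted Gaussian imputation: missing cells in
sample *j* draw from `N(m_j − 1.8·s_j, (0.3·s_j)²)` with `m_j`, `s_j` the
observed column mean and SD — the standard left-censored treatment for
below-detection-limit intensities. Width 0 is the deterministic limit
(every imputed cell lands at `m_j − 1.8 s_j`). Fraction t-tests run on log2
intensities; enrichment/depletion calls use strict `p < 0.05` and
fold > 2 thresholds. Three-group spectral-count comparisons use one-way
ANOVA with Tukey HSD.

## Differential abundance and FDR

The two-group test is the classical pooled-variance Student t on log2
values (Welch is deliberately not the default; the pooled form is exposed
as the only path because group variances are comparable after variance
correction). Proteins with fewer than 2 observed values in either group are
excluded from testing and from the BH family. BH is the step-up
`q_(i) = min_{j≥i}(p_(j)·m/j)` capped at 1, with the family = all tested
proteins in the contrast. Log2 fold-change is the difference of group
means; fold thresholds are interpreted on the linear scale (fold 2 ⇔
|log2FC| > 1) with strict inequalities at every published threshold.

## Meta-analysis and traits

Per-set differential tables are combined over the union of proteins:
`mean_log2fc` averages the sets where the protein was measured and
`meta_p` is Fisher's combination `X = −2Σ ln pᵢ ~ χ²(2k)`; a protein
quantified in one set keeps that set's statistics, so set-unique proteins
survive the meta-analysis. Exact zero p-values are an error unless
explicitly clamped (the pipeline clamps to the smallest positive float,
since extreme t-tests can underflow). Note Fisher's combination only
sharpens concordant small p-values; two p = 0.5 combine to 0.597.

Sample inclusion for the combined analysis retains an AD sample iff its
CSF tTau/Aβ₁₋₄₂ ratio > 0.226 **and** MoCA < 24, and a Control iff
ratio ≤ 0.226 **and** MoCA > 26 (AND-combination chosen where the source
description was ambiguous; both thresholds are config keys). Explicitly
exempted samples (e.g. cases measured in both sets) and GIS channels always
pass.

Z-transformation standardizes each protein row over its observed samples
(n−1 SD) across the pooled, inclusion-filtered samples of both sets.
Protein–trait association is the Pearson correlation over
pairwise-complete pairs with the two-sided Student p from
`t = r√(n−2)/√(1−r²)` (≥3 complete pairs required; the protein × trait
grid is reported unadjusted, with BH available downstream). The
multi-trait selection keeps proteins with p < 0.05 in at least three of the
six traits (MoCA, CSF Aβ₁₋₄₂, CSF tTau, CSF pTau181, tTau/Aβ ratio,
plasma pTau181).

## Network projection

**bicor.** Observations are weighted by `(1−u²)²` with
`u = (x − median)/(9·MAD)` and zero weight beyond 9 MADs; if MAD is zero
(or all weights vanish) the vector falls back to plain mean-centering,
reducing bicor to Pearson for that vector. Pairwise-complete evaluation;
≥3 pairs required.

**Eigenproteins.** The first right singular vector of the standardized
member × sample matrix (missing member values filled with the protein's row
mean first), returned standardized (mean 0, SD 1 with n−1) and signed to
correlate positively with the mean standardized member profile. At modest
sample counts the kME of a module's *own* members against a recomputed
eigenprotein is biased upward (the PC1 of even pure noise absorbs
~`(1+√(p/n))²/p` of the variance), so cross-tissue projections in
`recompute` mode over-assign relative to `shared` mode; this is a known
property of kME-based assignment, not an implementation artifact.

**Assignment.** kME = bicor of a protein against every module eigenprotein;
the protein joins the module with the highest positive kME if that value is
≥ 0.30 (inclusive), otherwise grey; ties break to the lowest module index.
`shared` mode correlates against the reference eigenproteins on the shared
sample space (used when re-assigning the reference proteome to its own
network); `recompute` mode rebuilds eigenproteins from reference membership
on the query matrix (used to project plasma onto a brain network).

**Overrepresentation.** One-tailed p = P(X ≥ k) for
X ~ Hypergeometric(N, K, n) plus the standardized deviate
`z = (k − nK/N)/σ` with the hypergeometric σ (z = 0 when σ = 0). Module
overlap runs per direction (up/down) with BH across modules within a
direction; cell-type enrichment BH-corrects across all module × cell-type
cells; GO-style GMT enrichment BH-corrects across all tested sets and
applies the pruning flag Z > 1.96, q < 0.05, and ≥ 5 genes — counted on the
overlap by default (`min_size_on: overlap`), since pruning aims at
supported hits; counting the background-intersected set size is available.
An alternative significance convention (Z > 1.3 ⇔ p < 0.05 one-tailed) is
reachable by setting `z_min: 1.3`. Backgrounds are always explicit
arguments, never implicit.

## Synthetic generators

`simulate_tmt_plasma` draws raw abundance
`2^(base_i + δ_i·I(AD) + γ_{set,batch,i} + λ_j + ε_ij)` with per-protein
baselines `N(10, 3²)` (log2), batch offsets `γ ~ N(0, σ_batch²)` centred
per protein within each set, channel loadings `λ ~ N(0, σ_channel²)` and
noise `ε ~ N(0, σ_noise²)`. Planted effects have magnitude `delta_log2`
with balanced random signs — real differential sets contain both
directions, and inter-set concordance is only measurable when effects vary
in sign. GIS channels read out a fixed virtual pool (baseline + batch +
loading terms, no diagnosis effect, no ε), which makes internal-standard
batch correction exactly testable. Missingness hits non-GIS channels with
probability `2·rate·sigmoid(steepness·(0.5 − rank))` of the within-sample
abundance rank — a left-censored mechanism matching downshifted imputation;
steepness 0 gives missing-completely-at-random for null experiments. GIS
channels are exempt (pooled standards are high-input and nearly complete in
practice, and an exact GIS denominator keeps TAMPOR's invariant testable).

Traits derive from a latent severity (`N(0,1)`, +1 SD for AD):
MoCA = 28 − 6·severity (clamped to [0, 30], noise SD 1.5), CSF Aβ₁₋₄₂ =
1200 − 300·severity pg/ml, CSF tTau = 180 + 150·severity pg/ml, CSF
pTau181 = 18 + 15·severity pg/ml, plasma pTau181 = 2 + 1.2·severity pg/ml,
with the tTau/Aβ ratio computed from its components. The intercepts and
slopes were fixed once so that the 0.226 ratio threshold separates the
groups the way the clinical assays do (controls ≈ 0.15, AD ≈ 0.37).

`simulate_reference_brain` builds each member row as
`kme_target·e_m + √(1−kme_target²)·noise` around a standardized latent
`e_m`, plus pure-noise grey proteins; CERAD-, Braak- and MMSE-like traits
are linear in the designated matrisome-like module's latent. Gene symbols
are shared with the plasma generator so cross-proteome symbol matching is
exercised. `simulate_lfq_fractions` multiplies designated heparin-binding
proteins by the enrichment fold and divides designated abundant proteins by
the depletion fold in the HP columns, and hides a fraction of low-abundance
proteins from the input/flow-through columns to emulate fraction-unique
detections.

**What the generators do not emulate**: peptide/PSM-level structure, TMT
isotope-impurity ratio compression, batch-level (all-channels-at-once)
missingness, correlated protein–protein co-expression in plasma beyond the
shared diagnosis effect, longitudinal or covariate-driven trait structure,
and non-Gaussian heavy-tailed noise. Passing tests therefore demonstrate
correctness of the statistical machinery under the stated model, not
robustness to every pathology of real plasma data.

All randomness flows from one integer seed; each generator and each
stochastic stage derives its own `numpy` Generator from a fixed stage
offset plus the seed, so stages are independently reproducible and the CLI
is byte-deterministic.

## Study conditions and problem sizes

The packaged defaults mirror a two-set design: a discovery set of 3 batches
× 13 channels and a replication set of 5 batches × 18 channels, one GIS
channel per batch, 2000 proteins with planted ±1 log2 effects on 10%, batch
SD 0.5, channel SD 0.1, noise SD 0.2, 20% abundance-dependent missingness.
Tests and the acceptance script use these sizes (or smaller fixtures for
unit tests); they were chosen as representative desk-scale conditions under
which every recovery property is identifiable.

## Known limitations

- Bottleneck/centrality-aware module assignment is out of scope; assignment
  is purely kME-based.
- No moderated (limma-style) statistics, no random-effects meta-analysis,
  no surrogate-variable batch correction.
- Trait correlations are not adjusted for age or sex.
- The t-test after covariate regression inherits the mild anticonservatism
  described above; interpret borderline p-values accordingly.
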