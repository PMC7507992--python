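# Methods

This note documents the statistical models implemented in `triprot`, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical decisions that were genuinely open.

## Pattern classification

A matched triplet (normal, pre, post) of log2 abundances yields two ternary
transition calls at threshold τ = log2(1.5) ≈ 0.585 (a 1.5-fold change on
the linear scale, the conventional cutoff for calling a protein-level
change between matched FFPE samples). The mapping from call pairs to the
eight pattern codes lives in a single table constant
(`triprot.patterns.PATTERN_TRANSITIONS`), so the numbering of the rarer
classes 5–8 can be re-keyed in one place if a different convention is
preferred; the mapping used here is 1 (UP, DOWN), 2 (DOWN, UP),
3 (UP, NONE), 4 (DOWN, NONE), 5 (NONE, UP), 6 (NONE, DOWN), 7 (UP, UP),
8 (DOWN, DOWN), with (NONE, NONE) = FLAT. Thresholding is inclusive
(≥ τ), and negating the data provably swaps 1↔2, 3↔4, 5↔6, 7↔8.

Patient-wise pattern percentages use all classifiable (non-missing)
proteins of that patient as the denominator, FLAT included, so the eight
percentages sum to at most 100. The association of each pattern's
percentage with survival time is a Spearman rank correlation across
patients, p from the t approximation, Benjamini–Hochberg over the eight
patterns.

## Moderated paired tests and permutation FDR

The cohort-level ("global") variant replaces per-patient thresholding by a
moderated paired statistic per protein and contrast:

    d = mean(diffs) / (SE(diffs) + S0),  SE = sd/√n,  S0 = 0.3

The additive S0 damps proteins whose tiny standard error would otherwise
make trivial fold changes significant — the standard background-variance
trick in proteomics differential analysis. Significance is controlled by
sign-flip permutations of each patient's difference vector: for a symmetric
cutoff t, FDR(t) = (mean permuted count of |d| ≥ t) / (observed count);
proteins are flagged at the smallest cutoff with FDR ≤ q (default
q = 0.05, 250 permutations). A protein's reported q-value is the smallest
FDR estimate among cutoffs it passes, which is monotone in |d| by
construction. Under a dense global null the procedure is conservative
(realized false-positive fraction near zero in the calibration tests) —
the permuted and observed distributions coincide, so no cutoff attains the
nominal level.

Global pattern assignment uses the normal↔pre and pre↔post contrasts for
the two ternary calls (UP/DOWN by the sign of the mean difference when the
contrast passes FDR, NONE otherwise); the normal↔post contrast is computed
and reported but does not enter the assignment, since there is no canonical
rule for folding three pairwise tests into one two-transition pattern.

In the grouped (supervised) contrast, each response group's permutation
seed is derived from the sorted member list, so results attach to the set
of patients rather than to the group label. "Unaltered in the other group"
means not passing FDR there — no additional effect-size criterion. The
single M&P-4 patient class is pooled with M&P 3 as "better responders".

## Preprocessing

* 2-of-3 rule: within each patient's triplet, proteins with fewer than two
  quantified values are dropped for that patient; a single missing value is
  imputed from N(μ − 1.2 σ, (0.3 σ)²) with μ, σ the observed mean and SD of
  the sample column holding the gap. Per-column statistics (rather than
  per-matrix) follow the convention of mainstream proteomics software;
  left-shifted imputation reflects that single dropouts in an otherwise
  quantified triplet are predominantly below-detection values.
* 70% filter: proteins quantified in at least 70% of samples are kept
  (boundary inclusive).
* Batch correction removes one principal component of the sample-space PCA
  (samples are observations, proteins variables, components 1-indexed,
  default the 3rd): the matrix is protein-centered, the rank-1 SVD
  contribution of the chosen component subtracted, and the means restored.
  This is a blunt but transparent instrument; it assumes the batch effect
  is concentrated in a single direction of sample space.

## Co-expression modules

Signed adjacency a_ij = ((1 + r_ij)/2)^β with Pearson r and β = 10; the
signed transform keeps anti-correlated proteins apart (r = −1 → a = 0).
Module detection cuts an average-linkage tree of the topological-overlap
dissimilarity (raw adjacency dissimilarity is also supported) at a fixed
height (static cut, default 0.95) and discards clusters below the minimum
size (default 20) as "unassigned". A static cut is simpler than dynamic
tree cutting and reproducible; it is a known fidelity gap relative to the
dynamic default of the reference WGCNA implementation, and the cut height
is exposed for that reason. No post-hoc merging of modules by eigengene
similarity is performed. Module labels are ordered by size with a
lexicographic tie-break, so they do not depend on protein input order.

The module eigengene is the first right singular vector (sample space) of
the row-standardized member matrix, unit norm, sign-aligned to correlate
non-negatively with the mean member profile; variance explained is the
first squared singular value over the total. Module–trait statistics are
Pearson correlations with two-sided t-approximation p-values; binary
traits are coded 0/1 and ordinal scores (M&P, grade, Ki67, size) enter as
integers. GS and MM are plain correlations of each protein with the trait
and with its own module's eigengene.

## Bootstrap co-clustering

Samples are clustered with distance 1 − Spearman ρ and average linkage.
Cluster support uses multiscale bootstrap: at scale r ∈ {0.5, 0.6, …, 1.4}
(the conventional grid), ⌈r·P⌉ of the P proteins are resampled with
replacement n_boot times, the tree is rebuilt, and each observed node's
BP_r is the fraction of bootstrap trees containing its exact leaf set.
Fitting Φ⁻¹(1 − BP_r) = v√r + c/√r by weighted least squares (binomial
weights) gives the signed-distance and curvature coefficients, and
AU = 1 − Φ(v − c). Nodes with BP pinned at 0 or 1 across all scales get
AU 0 or 1 with a degenerate-fit flag. Desk-scale default is n_boot = 1,000
per scale; 10,000 matches publication practice.

A patient's matched pre/post tumors "co-cluster" when the smallest
internal node containing both leaves has AU ≥ 0.95 (i.e. approximately
unbiased P < 0.05 for the cluster). Two deliberate choices: the statistic
is AU (BP is reported alongside), and a pair whose smallest joint node is
the tree root never co-clusters, because the root contains every leaf in
every bootstrap tree and its support is vacuous.

## Survival, enrichment, centrality

Kaplan–Meier curves, global and pairwise log-rank (pairwise BH-corrected)
and Cox proportional-hazards models are fitted with standard maximum
partial likelihood; tie handling defaults to Efron, with Breslow
selectable (Breslow is also what makes the subject-duplication invariance
exact). Protein strata come from a median split: strictly above the
median is "high", ties go to "low". Ordinal clinical covariates enter Cox
models as integers by default.

Set enrichment is the one-sided hypergeometric tail over a fixed
background universe (identical to the one-sided Fisher exact p), BH over
terms, with a configurable q cutoff (2% or 5% typical). Betweenness
centrality is exact (Brandes accumulation via networkx, unnormalized);
"top" flags mark nodes at or above the 90th percentile of scores.

## The synthetic cohort

The generator emulates the statistical structure the pipeline assumes:

* **Protein archetypes + patient tilt.** Each protein draws an archetype
  class from the pattern mixture (defaults dominated by patterns 1–4 with
  67% FLAT). In a given patient, the protein follows its archetype with
  probability `pattern_fidelity` (default 0.5); otherwise its class is
  drawn from the mixture tilted along a per-patient resistance axis —
  exp(+η) on the persistent patterns 3/4, exp(−η) on the reverting
  patterns 1/2, η ~ N(0, `resistance_sd` = 1.5). Archetypes give the
  cross-patient consistency that cohort-level tests need; the tilt gives
  patients genuinely different pattern-3 burdens, as real response
  heterogeneity does. With these defaults the patient-wise pipeline
  recovers a pattern-3 vs RFS Spearman ρ around −0.35 to −0.45 — the
  magnitude class of interest — at both n = 35 and n = 200.
* **Effects and noise.** Planted transition shifts are |N(2τ, 0.25)| log2
  units, truncated below at τ + 0.05 so the planted class is recoverable
  in the noise-free limit; measurement noise is i.i.d. N(0, 0.25) per
  value. Baselines are N(0, 1) per protein; batch 1 (patients alternate
  between two batches) gets a +0.3 log2 offset.
* **Modules.** The first `n_modules × module_size` proteins form blocks
  sharing an additive per-(block, patient) latent factor of amplitude
  `module_strength` = 1 log2 unit. The factor is a property of the
  patient's tumor, identical across that patient's three samples — so it
  cancels out of within-patient transitions (pattern calls are unaffected)
  while driving protein–protein correlation across samples, which is what
  the module stage and the co-clustering stage see. A separate pure
  block-correlation generator (`simulate_block_matrix`, exact within-block
  correlation) drives the module-recovery acceptance gate.
* **Missingness.** Cells are masked with probability
  logistic(a − steepness·z) of their global z-score, the intercept a found
  by bisection so the overall rate hits `missing_target_rate` (default
  10%): monotone left-censored MNAR, the mechanism that motivates
  downshifted imputation.
* **Survival.** RFS is exponential with hazard
  `hazard_baseline`·exp(`log_hr_per_unit`·f3), f3 the patient's true
  pattern-3 fraction (defaults 0.12/year and 12 per unit fraction);
  censoring replaces the event time by a uniform fraction of itself with
  probability `censor_rate` = 0.3. OS adds an independent exponential tail
  to RFS. The M&P score is a noisy quartile of −f3, so response grade and
  pattern burden are linked as they are in real cohorts. Healthy-duct
  reference samples are generated by the same model as adjacent-normal
  tissue (the two are statistically exchangeable here, and the pipeline's
  normal-vs-healthy utility verifies it finds nothing).

What the generator does **not** emulate: peptide-level quantification and
protein inference, ratio compression, sample-quality gradients, non-left
missingness (e.g. interference), correlated clinical covariates beyond the
M&P–f3 link, and competing risks. Passing tests therefore certify the
statistics on data with the assumed structure, not robustness to every
artifact of real FFPE proteomics.

## Problem sizes and numerical notes

The test suite and the acceptance script run at desk scale, chosen so each
check has clear statistical resolution: FDR calibration on 2,000 × 20 null
matrices over 20 seeds; survival recovery on 200-patient cohorts with 400
proteins over 20 seeds; module recovery on 5 × 60-protein blocks over 40
samples; Cox recovery at n = 600 with > 50% events over 20 seeds and CI
coverage over 200 null replicates; bootstrap support with 500 resamples
per scale. All randomness flows through `numpy.random.default_rng` seeds;
identical config + seed is bit-reproducible.

Degenerate inputs fail loudly rather than silently: zero-variance
difference vectors with S0 = 0, constant proteins in correlation networks,
constant samples in Spearman distances, all-identical values at a median
split, perfect separation in Cox fits, and 2×2 tables with an empty margin
all raise typed errors. Bootstrap resamples that happen to produce a
constant sample column fall back to zero correlation for that pair rather
than aborting the resample.

## Known limitations

* The static tree cut can fragment or merge modules that dynamic tree
  cutting would resolve; cut height and minimum size are configurable.
* The moderated statistic's permutation null is exchangeable only under
  symmetric paired differences; heavy asymmetry under the null would bias
  the FDR estimate.
* AU p-values inherit the usual multiscale-bootstrap small-sample bias for
  nodes with very few leaves or BP near the boundaries.
* The per-patient imputation never fills triplets with two or three
  missing values; downstream complete-matrix stages (PCA correction,
  adjacency) therefore work on the listwise-complete protein subset.
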