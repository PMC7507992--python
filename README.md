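# triprot

Matched-triplet longitudinal proteomics analysis for neoadjuvant-treatment
cohorts.

## The problem

Neoadjuvant chemotherapy (NAT) is given before surgery, which makes a rare
study design possible: from each patient one can profile three matched
specimens — tumor-adjacent **normal** tissue, the **pre**-treatment biopsy,
and the **post**-treatment residual tumor. Pathological response is a
*change* between two tumor states, not a snapshot of either, so the
informative quantity is the trajectory of each protein's abundance across
the triplet. `triprot` implements the statistical pipeline for such
cohorts, for proteomics/bioinformatics analysts working with SILAC-style
ratio matrices (e.g. a MaxQuant proteinGroups export) plus per-patient
clinical outcomes.

## The model

For protein *g* in patient *i*, write the log2(L/H) abundances of the
triplet as (xN, xP, xQ) for normal, pre, post. Each of the two transitions
gets a ternary call against a fold-change threshold τ = log2(1.5):

    c1 = UP if xP − xN ≥ τ, DOWN if ≤ −τ, else NONE   (normal → pre)
    c2 = UP if xQ − xP ≥ τ, DOWN if ≤ −τ, else NONE   (pre → post)

The 3 × 3 combinations map onto **eight patterns** plus FLAT:
1 (UP, DOWN), 2 (DOWN, UP), 3 (UP, NONE), 4 (DOWN, NONE), 5 (NONE, UP),
6 (NONE, DOWN), 7 (UP, UP), 8 (DOWN, DOWN). Pattern 3 — elevated in the
tumor and untouched by treatment — is the resistance-linked class; a
patient's *pattern-3 percentage* is tested against relapse-free survival by
Spearman rank correlation with Benjamini–Hochberg correction.

Around this core the package provides:

* **preprocessing** — patient-wise 2-of-3 filtering with left-shifted
  imputation (downshift 1.2 SD, width 0.3 SD), a ≥ 70% valid-values filter,
  and batch correction by removing one sample-space principal component;
* **global patterns** — cohort-level moderated paired statistics
  d = mean / (SE + S0) with S0 = 0.3 and sign-flip permutation FDR (5%),
  one test per contrast, combined into per-protein pattern assignments;
* **supervised contrasts** — pre/post paired tests stratified by response
  group (Miller & Payne 3–4 vs 1–2) or relapse, with "significant in one
  group, unaltered in the other" selection;
* **co-expression modules** — signed weighted adjacency
  a_ij = ((1 + cor)/2)^β with β = 10, topological overlap, average-linkage
  modules, eigengenes (first PC of the standardized module) and
  module–trait / GS / MM statistics;
* **bootstrap co-clustering** — sample dendrograms on 1 − Spearman ρ with
  average linkage, multiscale bootstrap (AU/BP) cluster support, and
  per-patient calls of whether matched pre/post tumors co-cluster;
* **survival & networks** — median-dichotomized Kaplan–Meier and log-rank,
  univariate/multivariate Cox proportional hazards (Efron or Breslow ties),
  Fisher/hypergeometric set enrichment, and exact betweenness centrality;
* **a synthetic-cohort generator** with planted pattern archetypes,
  patient-level resistance tilt, block co-expression modules, left-censored
  missingness and survival times whose hazard grows with the true pattern-3
  burden — every stage of the pipeline is testable against known truth.

## Worked example

Simulate a 35-patient cohort, preprocess it, and run the pattern stage:

```sh
triprot simulate --n-patients 35 --n-proteins 2000 --missing-rate 0.1 \
    --seed 7 --out demo/cohort
triprot preprocess --matrix demo/cohort/matrix.tsv \
    --samples demo/cohort/samples.tsv --out demo/prep
triprot patterns --matrix demo/prep/filtered.tsv \
    --samples demo/prep/samples.tsv \
    --clinical demo/cohort/clinical.csv --out demo/patterns
```

which prints

```
wrote synthetic cohort to demo/cohort (seed 7)
retained 1968 proteins after filtering; 949 complete proteins batch-corrected
classified 1968 proteins x 35 patients
```

and writes `demo/patterns/pattern_rfs_correlation.tsv`, whose pattern-3 row
in this run is

```
pattern  rho      p       q       n
3        -0.358   0.035   0.092   35
```

i.e. patients dominated by pattern-3 proteins (tumor-elevated, persisting
after chemotherapy) relapse earlier — the planted resistance signal, at
desk scale, with the expected sign and magnitude. The co-clustering and
survival stages run the same way:

```sh
triprot coclust --matrix demo/prep/corrected.tsv \
    --samples demo/prep/samples.tsv --n-boot 200 --seed 3 --out demo/coclust
# -> 19 of 35 patients co-cluster at AU >= 0.95
triprot survival --matrix demo/prep/filtered.tsv \
    --samples demo/prep/samples.tsv --clinical demo/cohort/clinical.csv \
    --protein PROT00001 --out demo/surv
# -> PROT00001 (post): log-rank p = 0.68, HR(high vs low) = 0.83 [0.35, 1.97]
```

All of this is also available as a library (`import triprot`); the CLI is a
thin layer over the same functions.

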