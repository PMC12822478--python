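# Methods

This note records the models, parameter choices, and numerical conventions
behind `crlmkit`, and what the synthetic-data tests do and do not establish.

## Study design assumed

Matched triplets per patient — adjacent normal colorectal tissue (N),
primary tumor (T), liver metastasis (LM) — with gene-level copy number,
mRNA, protein (TMT), and phosphosite matrices on log2 scale, clinical
follow-up (overall survival, optional progression-free survival, clinical
risk score CRS 0–5 with ≥ 3 as high risk), a kinase→phosphosite substrate
map, an rMATS-style alternative-splicing table (PSI per sample,
IncLevelDifference, FDR), and per-phosphosite functional-score annotations.
Phosphosite ids follow the fixed grammar `GENE_[STY]position`
(e.g. `EIF4B_S422`) so joins with annotations are deterministic.

## Statistical conventions

* **Rank tests.** The rank-sum test enumerates exactly when
  min(n₁, n₂) ≤ 8 and there are no ties, otherwise it uses the normal
  approximation with tie correction and 0.5 continuity correction; the
  signed-rank test drops zero differences (Wilcoxon convention), is exact
  for n ≤ 15 tie-free, and approximates otherwise. The branch taken is
  recorded in `TestResult.method`. Fully degenerate inputs return p = 1
  with a `DegenerateDataWarning` instead of failing.
* **Multiple testing.** "FDR" is always step-up Benjamini–Hochberg, applied
  within the natural family (within a layer for cis scans and differential
  tables, across sets for ORA, across kinases for KSEA, across the full
  factor×event grid for the splicing network).
* **Correlation.** Spearman with average ranks for ties, pairwise deletion
  of missing values, ≥ 4 complete pairs, p from the t approximation with
  n − 2 df. A constant vector yields a flagged missing ρ, never zero.
* **Survival.** Product-limit estimator; censoring at an event time counts
  as at risk for that time. Log-rank uses the hypergeometric variance at
  tied event times and a χ²(1) reference; this is asymptotic, and the test
  suite checks it against a 10,000-draw permutation oracle with a fixed
  0.02 approximation allowance. Median splits send ties to the low stratum
  and refuse fully degenerate inputs.
* **Fold change** is the difference of group means of log2 values (not a
  ratio of medians), matching the normalization pipeline; threshold filters
  use raw p together with fold change (q is reported alongside), with
  layer defaults mRNA 1.5, protein 1.2, phosphosite 1.5, all p < 0.05,
  strict inequalities.
* **Missing data.** Zeros are data; missing is an empty cell or "NA".
  Statistical tests never see imputed values; feature-mean imputation is
  confined to PCA ordination and consensus clustering. Features need ≥ 3
  observed values per group to be tested (skips are logged so counts are
  auditable).

## Preranked GSEA

Genes are sorted by the ranking metric (default: signed log2 fold change
from the paired contrast), descending, ties broken by gene id for
determinism. The running sum adds |r|^w/Σ|r_hit|^w at hits (w = 1 default)
and subtracts 1/(N − m) at misses; ES is the extremum, with the positive
extremum winning exact ties (a 1e-12 tolerance absorbs float noise). NES
divides |ES| by the mean of same-sign gene-label-permutation ES values;
nominal p is the same-sign permutation tail with the +1 correction; FDR
follows the pooled positive/negative normalized-score convention, clipped
at 1. Permutations are gene-label (not phenotype) and the seed is
mandatory. The weight-0 statistic is verified against an exhaustive
running-sum oracle for all lists with N ≤ 8.

## KSEA

z = (mean over quantified substrates − background mean) · √m / background
sd, where the background is every quantified site in the contrast; p is
two-sided normal, BH across kinases, and kinases with fewer than 3
quantified substrates are excluded and logged. Contrasts default to the
pairing structure: per-site median of per-patient LM − T differences for
the tissue contrast, unpaired group mean difference for subtype contrasts.
Note that any other planted or real biology (tissue- or subtype-shifted
proteins propagating to their sites) widens the background distribution and
attenuates z; this is a property of the statistic, not an implementation
artifact.

## Consensus subtyping

250 iterations by default (pipeline demo uses fewer): sample 80% of samples
without replacement, z-score features within the subsample, k-means
(10 restarts) for each k; consensus(i, j) = co-clustered / co-sampled.
Final labels cut average-linkage hierarchical clustering of 1 − consensus.
k is chosen by **minimum PAC** (proportion of consensus entries in
(0.1, 0.9)), tie-broken by delta-area — the classical delta-area rule with
Δ(k_min) = area(k_min) systematically favors the smallest candidate even
when a larger k is unambiguous (a balanced three-block cohort is the
counterexample), so PAC is primary and both are reported; an explicit
override always wins. Cluster names follow the metabolism convention: when
a metabolism gene set is supplied, the cluster with the higher median
metabolism score is C1; otherwise the largest cluster is C1.

## Biomarker cascades

Every candidate keeps a per-stage record (pass/fail plus the statistic), so
the trace is monotone and auditable. Normal-tissue samples inherit their
patient's LM subtype for the six-set construction. The protein cascade
requires the candidate to be higher in C1-LM than **each** of C2-LM, C1-T,
C2-T, C1-N, C2-N (FC > 1.2 and rank-sum p < 0.05, unpaired by default);
the phosphosite cascade tests C1 vs C2 within LM (|FC| > 1.5), then the
functional score (> 0.5; a missing score fails that stage explicitly), and
both end with a median-split log-rank (p < 0.05) within LM samples.
Dependency-list intersection deduplicates genes across lists, keeps the
source list names, and ranks by the paired LM-vs-T signed-rank p.

## Synthetic cohort: the stated world

Defaults: 34 patients (102 samples), 8000 genes (300-gene metabolism and
RNA-function subtype blocks; 245 LM-enriched and 96 T-enriched genes;
500 cis genes), ≈ 2 phosphosites per gene, 5 planted kinases × 15
substrates (+1 log2 in LM) plus 10 decoy kinases, hazard ratio 3 for C1 vs
C2 with exponential survival (baseline median 1500 days) and exponential
censoring (≈ 22% censored), ≈ 15% missingness on the MS layers, 3 IRS
replicate columns, 60 AS events (20 subtype-shifted, 11 driven by 6
splicing-factor proteins).

* **Cis chain.** CNV states ∈ {−1, 0, +1} per patient (P(±1) = 0.15 each)
  are shared by T and LM and diploid in N. Latent signal:
  mRNA* = a·CNV + ε_m, protein* = mRNA* + ε_p, site* = protein* + ε_s.
  Target Spearman levels (0.6, 0.4, 0.25) are converted to Pearson via the
  bivariate-normal relation ρ_P = 2 sin(πρ_S/6) and the noise scales are
  solved in closed form; infeasible target orderings raise with the
  violated constraint. Observed values add per-feature baselines
  (N(0, 1.5)), per-sample loading offsets (N(0, 0.3), removed by median
  normalization), and the planted shifts.
* **Effects.** Tissue effect 2.0 log2 (LM-/T-enriched blocks; 70% of it
  visible at the mRNA layer), subtype effect 2.0 log2 — about 2 pooled
  protein SDs — applied in LM only (metabolism block up in C1, RNA-function
  block up in C2), propagating to phosphosites. Protein biomarkers are the
  first 10 metabolism genes, given a +3 baseline so intensity-dependent
  missingness rarely removes them (their defining property is reliable
  quantification); their first sites are the phospho biomarkers with
  functional scores ≥ 0.8.
* **Missingness.** MCAR 2% plus MNAR logistic P(miss) = σ(−2.8 − x) in
  log2 abundance, calibrated to ≈ 15% overall on the MS layers; mRNA and
  CNV are complete (sequencing layers). IRS columns are the cohort mean
  profile + N(0, 0.1) and carry no missingness.
* **Splicing.** Subtype events shift PSI by ±0.25 between C1 and C2
  (noise 0.05, clipped to [0, 1]); factor-driven events follow the
  standardized factor-protein profile (slope 0.15). The table's
  IncLevelDifference and FDR columns are computed from the generated PSI
  (rank-sum + BH), like the rMATS output they emulate.
* **Clinical.** CRS ~ Binomial(5, 0.45) independent of survival — so a
  CRS split is expectedly non-prognostic while the subtype split is.
  PFS is a crude Uniform(0.3, 1) fraction of OS with the same event flag.
* **Determinism.** One seed; every component draws from its own fixed-key
  substream, so adding a layer never perturbs another layer's draws.

**What a green test establishes.** Recovery tests show the pipeline finds
structure of the planted kind at the planted effect sizes under idealized
noise (independent Gaussian, shared shift per block, no batch effects, no
TMT ratio compression, no isoform ambiguity). They do not establish
robustness to correlated noise, plex effects, or mis-mapped sites, and
"precision" against the truth manifest treats equivalent-by-construction
features (e.g. other metabolism-block genes in the biomarker cascade) as
neutral, not false.

**Power notes.** The survival stage of the biomarker cascade is a
median-split log-rank at HR 3: with d events its z is roughly
√(d/4)·ln 3 attenuated by the split's misclassification (~15% at protein
noise, ~25% at phosphosite noise). At the default 34 patients this gives
~50–80% per-marker power — which is why the planted-recovery acceptance
test uses 150 patients (recall ≥ 0.9 needs ≥ 95% per-marker power), while
the phosphosite cascade's survival stage remains the binding constraint and
is asserted as a majority, not totality. The kinase-recovery check isolates
the kinase world (other planted effects zero) because tissue/subtype blocks
legitimately widen the KSEA background (see above).

## Known limitations

* No Cox regression, stratified log-rank, batch correction, or model-based
  imputation (out of scope by design).
* The LM-/T-enriched set construction is a declared, parameterized default
  (paired signed-rank q < 0.05, |FC| > 1.5, detected in ≥ 50% of pairs);
  alternative criteria are a single config change.
* GSEA FDR uses the pooled-permutation convention; with very few sets the
  q-values are coarse.
* The phosphosite cis scan reports the most significant site per gene
  (per-site records are also emitted); no localization-probability
  recomputation — the class I/II label is consumed from the annotation.
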