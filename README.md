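# crlmkit

Proteogenomic analysis of paired colorectal-cancer cohorts with liver
metastasis: adjacent normal (N), primary tumor (T), and liver metastasis
(LM) tissue from the same patients, profiled at the copy-number, mRNA,
protein (TMT), and phosphosite levels.

The package is aimed at computational biologists who have gene-level
matrices in hand (plus clinical follow-up, a kinase–substrate map, an
rMATS-style splicing table, and phosphosite annotations) and want the
standard downstream battery for this study design, with every threshold
explicit and auditable:

* **QC / normalization** — log2 + per-sample median centering, missingness
  filters, MAD-based variance selection, PCA, internal-reference-sample
  (IRS) reproducibility.
* **SCNA cis effects** — per-gene Spearman correlation of copy number with
  its own mRNA / protein / phosphosite abundance, BH-adjusted within layer,
  with the multi-layer significance pattern (Venn classification).
* **Differential testing** — Wilcoxon rank-sum (unpaired) or signed-rank on
  per-patient differences (paired), layer-specific fold-change/p filters,
  hypergeometric over-representation against the quantified universe.
* **Signatures + GSEA** — LM-/T-enriched protein sets from the paired
  contrast; preranked GSEA (weighted Kolmogorov–Smirnov running sum,
  gene-label permutation NES/FDR); median signature scores; median-split
  Kaplan–Meier survival.
* **KSEA** — kinase activity z-scores from substrate phosphosite fold
  changes.
* **Consensus subtyping** — resampled k-means consensus clustering of LM
  samples on MAD-selected proteins, PAC-based k selection, C1/C2 naming by
  metabolism score.
* **Biomarker cascades** — the protein workflow (missingness < 10%; higher
  in C1-LM than the five other subtype–tissue sets with FC > 1.2, p < 0.05;
  median-split log-rank p < 0.05) and the phosphosite workflow (C1 vs C2
  FC > 1.5, functional score > 0.5, log-rank p < 0.05), with a full
  per-stage audit trail, plus dependency-list intersection.
* **Splicing** — AS-event filtering (FDR < 0.05, |ΔPSI| > 0.1), per-event
  survival, and splicing-factor/event Spearman correlation networks.
* **Synthetic cohorts** — a generator that plants all of the above
  (cis-effect attenuation, subtypes with survival difference, active
  kinases, biomarkers, AS events, MNAR missingness, IRS replicates) with a
  machine-readable truth manifest, so every stage is testable end to end.

## Core statistics

For a kinase with m quantified substrate sites and per-site contrast values
s (e.g. median per-patient log2(LM/T)), against the background of all
quantified sites:

    z = (mean(s_substrates) − mean(s_background)) · √m / sd(s_background)

with a two-sided normal p and BH adjustment across kinases.

Preranked GSEA uses the weighted running sum: down the ranked list, hits add
|r_i|^w / Σ|r_hit|^w, misses subtract 1/(N − m); ES is the maximal
deviation, NES normalizes by the same-sign permutation mean, and FDR follows
the pooled positive/negative NES convention.

Survival uses the Kaplan–Meier product-limit estimator and the two-group
log-rank χ² = (O − E)² / V with hypergeometric variance at tied event
times. "FDR" is Benjamini–Hochberg throughout.

## Worked example

Simulate a default cohort (34 patients, 102 samples, 8000 genes,
~16k phosphosites) and run every stage:

```bash
crlmkit run-all --seed 1 --outdir results/pipeline
```

With seed 1 this prints `completed stages: qc, cis, diff, signature, ksea,
subtype, biomarker, splicing, survival` (about 75 s on one CPU) and writes
flat TSV artifacts. Highlights of that run:

* `cis_records.tsv` — significant cis genes per layer in T samples:
  398 (mRNA) ≥ 27 (protein) ≥ 1 (phosphosite), the expected attenuation of
  copy-number effects down the central dogma.
* `kinase_activities.tsv` — the five planted kinases are the top five by
  |z| (KIN5 z = 5.35 … KIN2 z = 2.60, all q < 0.03); all decoys are
  non-significant.
* `selection_report.tsv` / `labels.tsv` — k = 2 is selected (PAC = 0.0) and
  the C1/C2 labels match the planted subtypes for all 34 LM samples.
* `gsea_results.tsv` — the LM-enriched signature scores NES = +3.43 and the
  T-enriched signature NES = −3.94 on the LM-vs-T ranking, both q < 0.05.
* `survival_tests.tsv` — subtype C1 vs C2 log-rank p = 0.023 (the planted
  hazard ratio is 3), while the CRS high/low split is not significant
  (p = 0.087), since CRS is generated independently of survival.

Each number above is recomputed by the command; artifact files also include
`biomarker_trace.tsv` (per-candidate, per-stage audit) and
`factor_event_edges.tsv` (splicing-factor network).

The library mirrors the CLI one-to-one, e.g.:

```python
from crlmkit.simulate import SyntheticConfig, generate_cohort
from crlmkit.preprocess import normalize_log2_median
from crlmkit.ksea import paired_site_contrast, ksea_scores

bundle = generate_cohort(SyntheticConfig(seed=1))
phos = normalize_log2_median(
    bundle.matrices["phosphosite"].drop_samples(bundle.irs_sample_ids))
activities = ksea_scores(paired_site_contrast(phos, bundle.clinical),
                         bundle.kinase_map)
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the complete pipeline on the default synthetic cohort from scratch
(all randomness derived from `--seed`), verifies that every stage completes,
and writes the results JSON; pipeline artifacts land in
`results/pipeline/`. The property-level guarantees (exact-test oracles,
BH brute force, permutation log-rank, planted-truth recovery for KSEA,
GSEA, subtyping, cis attenuation, and the biomarker cascade, null
calibration, and end-to-end determinism) live in
`tests/test_acceptance.py`.
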