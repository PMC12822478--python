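"""End-to-end pipeline wiring: simulate/load -> QC -> cis -> differential ->
signatures/GSEA -> KSEA -> subtyping -> biomarkers -> splicing -> survival.

Each stage writes flat TSV artifacts into the output directory, every
threshold is echoed to ``run.log`` once per stage, and a ``MANIFEST`` lists
the completed stages so partial runs remain auditable.  All randomness flows
from the single config seed through fixed per-stage offsets.
"""

from __future__ import annotations

import logging
import os
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import cis as cis_mod
from . import io as io_mod
from . import ksea as ksea_mod
from . import signatures as sig_mod
from . import splicing as splice_mod
from . import subtypes as sub_mod
from .biomarkers import (BiomarkerPolicy, biomarker_frame,
                         dependency_intersect, phospho_biomarker_scan,
                         protein_biomarker_scan)
from .differential import (ThresholdPolicy, diff_records_frame,
                           differential_table, layer_threshold_filter,
                           pathway_ora)
from .io import (ClinicalRecord, GeneSetCollection, OmicsMatrix,
                 clinical_frame, load_as_events, load_clinical,
                 load_kinase_substrate_map, load_mutation_matrix,
                 load_omics_matrix, load_site_annotation, write_as_events,
                 write_clinical, write_gene_sets, write_kinase_substrate_map,
                 write_mutation_matrix, write_omics_matrix,
                 write_site_annotation)
from .preprocess import (filter_by_missingness, irs_reproducibility,
                         mad_select, normalize_log2_median, pca_embed)
from .simulate import (CohortBundle, SyntheticConfig, cohort_summary,
                       generate_cohort, load_truth_manifest,
                       write_truth_manifest)
from .stats import km_curve, logrank_test

logger = logging.getLogger("crlmkit.pipeline")

ALL_STAGES = ("qc", "cis", "diff", "signature", "ksea", "subtype",
              "biomarker", "splicing", "survival")


# ---------------------------------------------------------------------------
# Bundle persistence
# ---------------------------------------------------------------------------

_BUNDLE_FILES = {
    "cnv": "cnv.tsv", "mrna": "mrna.tsv", "protein": "protein.tsv",
    "phosphosite": "phosphosite.tsv",
}


def write_bundle(bundle: CohortBundle, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for layer, fname in _BUNDLE_FILES.items():
        write_omics_matrix(bundle.matrices[layer], out / fname)
    write_clinical(bundle.clinical, out / "clinical.tsv")
    write_kinase_substrate_map(bundle.kinase_map, out / "kinase_substrate.tsv")
    write_as_events(bundle.as_events, out / "as_events.tsv")
    write_site_annotation(bundle.site_annotation, out / "site_annotation.tsv")
    write_mutation_matrix(bundle.mutations, out / "mutations.tsv")
    write_truth_manifest(bundle.truth, out / "truth_manifest.tsv")
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(bundle.config.to_dict(), fh)
    with open(out / "irs_samples.txt", "w") as fh:
        fh.write("\n".join(bundle.irs_sample_ids) + "\n")
    cohort_summary(bundle).to_csv(out / "cohort_summary.tsv", sep="\t",
                                  index=False)


def load_bundle(indir) -> CohortBundle:
    ind = Path(indir)
    with open(ind / "config.yaml") as fh:
        config = SyntheticConfig.from_dict(yaml.safe_load(fh))
    matrices = {layer: load_omics_matrix(ind / fname, layer)
                for layer, fname in _BUNDLE_FILES.items()}
    with open(ind / "irs_samples.txt") as fh:
        irs = [line.strip() for line in fh if line.strip()]
    return CohortBundle(
        config=config, matrices=matrices,
        clinical=load_clinical(ind / "clinical.tsv"),
        kinase_map=load_kinase_substrate_map(ind / "kinase_substrate.tsv"),
        as_events=load_as_events(ind / "as_events.tsv"),
        site_annotation=load_site_annotation(ind / "site_annotation.tsv"),
        mutations=load_mutation_matrix(ind / "mutations.tsv"),
        truth=load_truth_manifest(ind / "truth_manifest.tsv"),
        irs_sample_ids=irs)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def default_pipeline_config(seed: int = 0) -> Dict:
    return {
        "seed": seed,
        "synthetic": {},          # SyntheticConfig overrides
        "stages": list(ALL_STAGES),
        "mad_threshold": 1.0,
        "missingness_max": 0.10,
        "cis": {"min_pairs": 10, "alpha": 0.05},
        "gsea": {"n_perm": 1000, "weight": 1.0},
        "consensus": {"k_range": [2, 3, 4], "resample_frac": 0.8,
                      "n_iter": 100, "override_k": None},
        "splicing": {"fdr_max": 0.05, "min_abs_delta": 0.1},
        "crs_high": 3,
    }


def _tissue_samples(clinical: Sequence[ClinicalRecord], tissue: str,
                    columns) -> List[str]:
    return [r.sample_id for r in clinical
            if r.tissue == tissue and r.sample_id in columns]


def _paired_ids(clinical: Sequence[ClinicalRecord], columns,
                t1: str = "LM", t2: str = "T"):
    by_patient: Dict[str, Dict[str, str]] = {}
    for r in clinical:
        if r.sample_id in columns:
            by_patient.setdefault(r.patient_id, {})[r.tissue] = r.sample_id
    g1, g2 = [], []
    for patient in sorted(by_patient):
        d = by_patient[patient]
        if t1 in d and t2 in d:
            g1.append(d[t1])
            g2.append(d[t2])
    return g1, g2


def run_pipeline(config: Dict, outdir, bundle: Optional[CohortBundle] = None
                 ) -> List[str]:
    """Execute the enabled stages in dependency order; returns the list of
    completed stages (also written to MANIFEST)."""
    cfg = default_pipeline_config()
    cfg.update(config or {})
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("crlmkit")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    completed: List[str] = []
    seed = int(cfg["seed"])
    try:
        with open(out / "resolved_config.yaml", "w") as fh:
            yaml.safe_dump(cfg, fh)
        if bundle is None:
            syn = dict(cfg.get("synthetic") or {})
            syn.setdefault("seed", seed)
            bundle = generate_cohort(SyntheticConfig.from_dict(syn))
        stages = list(cfg.get("stages") or ALL_STAGES)
        clinical = bundle.clinical
        cohort_summary(bundle).to_csv(out / "cohort_summary.tsv", sep="\t",
                                      index=False)

        # --- QC / normalization (always required downstream) ---
        logger.info("qc: median normalization; IRS columns %s",
                    bundle.irs_sample_ids)
        norm: Dict[str, OmicsMatrix] = {}
        qc_rows = []
        for layer in ("mrna", "protein", "phosphosite"):
            m = normalize_log2_median(bundle.matrices[layer])
            if bundle.irs_sample_ids and layer in ("protein", "phosphosite"):
                irs_corr = irs_reproducibility(m, bundle.irs_sample_ids)
                for i in irs_corr.index:
                    for j in irs_corr.columns:
                        qc_rows.append({"layer": layer, "metric": "irs_spearman",
                                        "a": i, "b": j,
                                        "value": irs_corr.loc[i, j]})
                m = m.drop_samples(bundle.irs_sample_ids)
            qc_rows.append({"layer": layer, "metric": "missing_fraction",
                            "a": "", "b": "", "value": m.missing_fraction()})
            norm[layer] = m
        norm["cnv"] = bundle.matrices["cnv"]
        if "qc" in stages:
            pd.DataFrame(qc_rows).to_csv(out / "qc_report.tsv", sep="\t",
                                         index=False)
            coords, var = pca_embed(norm["protein"], n_components=2)
            coords["variance_explained_pc1"] = var[0]
            coords["variance_explained_pc2"] = var[1]
            coords.to_csv(out / "pca_coordinates.tsv", sep="\t",
                          index_label="sample_id")
            completed.append("qc")

        if "cis" in stages:
            ccfg = cfg["cis"]
            logger.info("cis: min_pairs=%d alpha=%g", ccfg["min_pairs"],
                        ccfg["alpha"])
            frames = []
            venn_frames = []
            for tissue in ("T", "LM"):
                records_by_layer = {}
                for layer in ("mrna", "protein", "phosphosite"):
                    samples = _tissue_samples(clinical, tissue,
                                              norm[layer].data.columns)
                    recs = cis_mod.cis_correlation_scan(
                        norm["cnv"], norm[layer], samples,
                        min_pairs=ccfg["min_pairs"], alpha=ccfg["alpha"])
                    records_by_layer[layer] = recs
                    df = cis_mod.cis_records_frame(recs)
                    df.insert(0, "tissue", tissue)
                    frames.append(df)
                venn = cis_mod.classify_cis_venn(records_by_layer)
                venn.insert(0, "tissue", tissue)
                venn_frames.append(venn)
            pd.concat(frames).to_csv(out / "cis_records.tsv", sep="\t",
                                     index=False)
            pd.concat(venn_frames).to_csv(out / "cis_venn.tsv", sep="\t",
                                          index=False)
            completed.append("cis")

        diff_by_layer = {}
        if {"diff", "signature", "ksea"} & set(stages):
            policy = ThresholdPolicy()
            for layer in ("mrna", "protein", "phosphosite"):
                lm, t = _paired_ids(clinical, norm[layer].data.columns)
                diff_by_layer[layer] = differential_table(
                    norm[layer], lm, t, paired=True)
            if "diff" in stages:
                logger.info("diff: thresholds %s", policy.thresholds)
                frames = []
                for layer, recs in diff_by_layer.items():
                    df = diff_records_frame(recs)
                    kept = {r.feature for r in
                            layer_threshold_filter(recs, policy)}
                    df["passes_threshold"] = df["feature"].isin(kept)
                    frames.append(df)
                pd.concat(frames).to_csv(out / "diff_records.tsv", sep="\t",
                                         index=False)
                completed.append("diff")

        lm_sig = t_sig = None
        if "signature" in stages:
            gcfg = cfg["gsea"]
            logger.info("signature: q<0.05, FC>1.5, detect>=50%%; gsea n_perm=%d "
                        "weight=%g", gcfg["n_perm"], gcfg["weight"])
            lm_sig, t_sig = sig_mod.build_enriched_sets(norm["protein"], clinical)
            sig_sets = {s.name: s.members for s in (lm_sig, t_sig) if s.members}
            if sig_sets:
                write_gene_sets(GeneSetCollection(
                    sig_sets, {k: "signature" for k in sig_sets}),
                    out / "signatures.gmt")
                ranked = pd.Series(
                    {r.feature: r.log2fc for r in diff_by_layer["protein"]})
                gsea = sig_mod.preranked_gsea(
                    ranked, GeneSetCollection(sig_sets),
                    n_perm=gcfg["n_perm"], weight=gcfg["weight"],
                    seed=seed + 101)
                sig_mod.gsea_results_frame(gsea).to_csv(
                    out / "gsea_results.tsv", sep="\t", index=False)
            if lm_sig.members:
                scores = sig_mod.sample_signature_score(norm["protein"], lm_sig)
                scores.to_frame("score").to_csv(out / "signature_scores.tsv",
                                                sep="\t", index_label="sample_id")
                t_scores = scores[[r.sample_id for r in clinical
                                   if r.tissue == "T"
                                   and r.sample_id in scores.index]]
                try:
                    hi, lo, test = sig_mod.score_stratified_survival(
                        t_scores, clinical)
                    pd.DataFrame([{"contrast": "signature_high_vs_low",
                                   "statistic": test.statistic,
                                   "p": test.p_value}]).to_csv(
                        out / "signature_survival.tsv", sep="\t", index=False)
                except ValueError as exc:
                    logger.warning("signature survival skipped: %s", exc)
            completed.append("signature")

        if "ksea" in stages:
            logger.info("ksea: min_substrates=3, paired LM-T contrast")
            contrast = ksea_mod.paired_site_contrast(norm["phosphosite"],
                                                     clinical)
            acts = ksea_mod.ksea_scores(contrast, bundle.kinase_map)
            ksea_mod.activities_frame(acts).to_csv(
                out / "kinase_activities.tsv", sep="\t", index=False)
            evidence = ksea_mod.substrate_annotation(
                acts, bundle.kinase_map, diff_by_layer.get("phosphosite", []))
            evidence.to_csv(out / "kinase_substrate_evidence.tsv", sep="\t",
                            index=False)
            completed.append("ksea")

        subtype_by_patient: Dict[str, str] = {}
        if "subtype" in stages:
            scfg = cfg["consensus"]
            logger.info("subtype: MAD>%g, k_range=%s, resample=%g, n_iter=%d",
                        cfg["mad_threshold"], scfg["k_range"],
                        scfg["resample_frac"], scfg["n_iter"])
            lm_cols = _tissue_samples(clinical, "LM",
                                      norm["protein"].data.columns)
            lm_mat = norm["protein"].subset_samples(lm_cols)
            feats = mad_select(lm_mat, cfg["mad_threshold"])
            if len(feats) < 10:
                logger.warning("only %d MAD-selected features; using top 500 "
                               "by MAD instead", len(feats))
                feats = mad_select(lm_mat, -1.0)[:500]
            res = sub_mod.consensus_cluster(
                lm_mat, feats, k_range=scfg["k_range"],
                resample_frac=scfg["resample_frac"], n_iter=scfg["n_iter"],
                seed=seed + 202)
            chosen, report = sub_mod.select_k(res, override=scfg.get("override_k"))
            report.to_csv(out / "selection_report.tsv", sep="\t", index=False)
            for k, C in res.consensus.items():
                C.to_csv(out / f"consensus_k{k}.tsv", sep="\t")
            labels = sub_mod.canonical_subtype_labels(
                res.labels[chosen], lm_mat, bundle.truth.metabolism_genes)
            labels.to_frame("subtype").to_csv(out / "labels.tsv", sep="\t",
                                              index_label="sample_id")
            sample_to_patient = {r.sample_id: r.patient_id for r in clinical}
            subtype_by_patient = {sample_to_patient[s]: lab
                                  for s, lab in labels.items()
                                  if s in sample_to_patient}
            if len(bundle.mutations):
                mut_labels = pd.Series(
                    {s: subtype_by_patient.get(sample_to_patient.get(s))
                     for s in bundle.mutations.columns}).dropna()
                lm_mut = mut_labels[[s for s in mut_labels.index
                                     if s.endswith("_LM")]]
                if lm_mut.nunique() == 2:
                    sub_mod.mutation_association(
                        bundle.mutations, lm_mut).to_csv(
                        out / "mutation_association.tsv", sep="\t", index=False)
            completed.append("subtype")

        if "biomarker" in stages:
            if not subtype_by_patient:
                subtype_by_patient = dict(bundle.truth.subtype_by_patient)
            from .simulate import assign_subtypes
            labeled = assign_subtypes(clinical, subtype_by_patient)
            policy = BiomarkerPolicy(max_missing_frac=cfg["missingness_max"])
            logger.info("biomarker: missing<%g, protein FC>%g, phospho FC>%g, "
                        "p<%g, score>%g, logrank p<%g",
                        policy.max_missing_frac, policy.protein_min_fc,
                        policy.phospho_min_fc, policy.p_max,
                        policy.functional_score_min, policy.logrank_p_max)
            prot_recs, _ = protein_biomarker_scan(norm["protein"], labeled,
                                                  policy=policy)
            phos_recs = phospho_biomarker_scan(norm["phosphosite"],
                                               bundle.site_annotation, labeled,
                                               policy=policy)
            trace = pd.concat([biomarker_frame(prot_recs),
                               biomarker_frame(phos_recs)])
            trace.to_csv(out / "biomarker_trace.tsv", sep="\t", index=False)
            final = trace[trace["final"]]
            final.to_csv(out / "biomarker_final.tsv", sep="\t", index=False)
            completed.append("biomarker")

        if "splicing" in stages:
            pcfg = cfg["splicing"]
            logger.info("splicing: fdr<%g, |dPSI|>%g", pcfg["fdr_max"],
                        pcfg["min_abs_delta"])
            filtered = splice_mod.filter_as_events(
                bundle.as_events, fdr_max=pcfg["fdr_max"],
                min_abs_delta=pcfg["min_abs_delta"])
            filtered.events.to_csv(out / "as_filtered.tsv", sep="\t")
            scan = splice_mod.as_survival_scan(filtered, clinical)
            scan.to_csv(out / "as_survival.tsv", sep="\t", index=False)
            factor_genes = [g for g in bundle.truth.rna_function_genes[:6]
                            if g in norm["protein"].data.index] or \
                list(norm["protein"].data.index[:6])
            factors = OmicsMatrix("protein",
                                  norm["protein"].data.loc[factor_genes],
                                  True, True)
            edges = splice_mod.factor_event_network(factors, filtered)
            splice_mod.edges_frame(edges).to_csv(
                out / "factor_event_edges.tsv", sep="\t", index=False)
            completed.append("splicing")

        if "survival" in stages:
            logger.info("survival: CRS high-risk >= %d; log-rank", cfg["crs_high"])
            rows = []
            pat = clinical_frame(clinical).drop_duplicates("patient_id")
            high = pat["crs"] >= cfg["crs_high"]
            if high.sum() >= 2 and (~high).sum() >= 2:
                res = logrank_test(pat.loc[high, "os_time"],
                                   pat.loc[high, "os_event"],
                                   pat.loc[~high, "os_time"],
                                   pat.loc[~high, "os_event"])
                rows.append({"contrast": "crs_high_vs_low",
                             "statistic": res.statistic, "p": res.p_value})
            if subtype_by_patient:
                pat["subtype"] = pat["patient_id"].map(subtype_by_patient)
                c1 = pat["subtype"] == "C1"
                c2 = pat["subtype"] == "C2"
                if c1.sum() >= 2 and c2.sum() >= 2:
                    res = logrank_test(pat.loc[c1, "os_time"],
                                       pat.loc[c1, "os_event"],
                                       pat.loc[c2, "os_time"],
                                       pat.loc[c2, "os_event"])
                    rows.append({"contrast": "subtype_c1_vs_c2",
                                 "statistic": res.statistic, "p": res.p_value})
            pd.DataFrame(rows, columns=["contrast", "statistic", "p"]).to_csv(
                out / "survival_tests.tsv", sep="\t", index=False)
            completed.append("survival")
    finally:
        with open(out / "MANIFEST", "w") as fh:
            fh.write("\n".join(completed) + "\n")
        root.removeHandler(handler)
        handler.close()
    return completed
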