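"""Cascaded subtype-specific biomarker nomination.

Two workflows, both recording every stage so failed candidates keep their
failing stage:

* proteins — candidates quantified with < 10% missing values; higher in the
  C1 subtype of LM than in each of the five other subtype-tissue sets
  (C2-LM, C1-T, C2-T, C1-N, C2-N; fold change > 1.2 and p < 0.05 in every
  comparison); pathway annotation of the survivors; and log-rank p < 0.05 on
  a median split of the LM samples.
* phosphosites — < 10% missing; |fold change| > 1.5 with p < 0.05 between C1
  and C2 LM samples; functional score > 0.5; log-rank p < 0.05 on a median
  split.

Normal-tissue samples inherit their patient's LM subtype for the six-set
construction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .differential import pathway_ora
from .io import (ClinicalRecord, GeneSetCollection, OmicsMatrix,
                 SiteAnnotation)
from .stats import logrank_test, median_split, wilcoxon_rank_sum

logger = logging.getLogger(__name__)


@dataclass
class BiomarkerPolicy:
    max_missing_frac: float = 0.10
    protein_min_fc: float = 1.2
    phospho_min_fc: float = 1.5
    p_max: float = 0.05
    functional_score_min: float = 0.5
    logrank_p_max: float = 0.05
    min_per_group: int = 3


@dataclass
class BiomarkerRecord:
    feature: str
    layer: str
    stages: Dict[str, Tuple[bool, str]] = field(default_factory=dict)
    final: bool = False
    failing_stage: Optional[str] = None

    def record(self, stage: str, passed: bool, detail: str) -> bool:
        self.stages[stage] = (passed, detail)
        if not passed and self.failing_stage is None:
            self.failing_stage = stage
        return passed


def _sample_groups(clinical: Sequence[ClinicalRecord], columns
                   ) -> Dict[str, List[str]]:
    """Six subtype-tissue sample sets; N samples carry the patient subtype."""
    groups: Dict[str, List[str]] = {f"{s}-{t}": []
                                    for s in ("C1", "C2") for t in ("LM", "T", "N")}
    missing_subtype = 0
    for r in clinical:
        if r.sample_id not in columns:
            continue
        if r.subtype is None:
            missing_subtype += 1
            continue
        groups[f"{r.subtype}-{r.tissue}"].append(r.sample_id)
    if missing_subtype and not any(groups.values()):
        raise ValueError("no clinical records carry subtype labels")
    return groups


def _lm_survival(clinical: Sequence[ClinicalRecord], columns):
    rows = [(r.sample_id, r.os_time, r.os_event)
            for r in clinical if r.tissue == "LM" and r.sample_id in columns]
    return rows


def _survival_stage(values: pd.Series, lm_rows, policy: BiomarkerPolicy
                    ) -> Tuple[bool, str]:
    """Median-split log-rank within LM samples for one candidate feature."""
    sub = [(v, t, e) for (sid, t, e) in lm_rows
           for v in [values.get(sid, np.nan)] if np.isfinite(v)]
    if len(sub) < 2 * policy.min_per_group:
        return False, f"only {len(sub)} LM samples quantified"
    vals = np.array([s[0] for s in sub])
    times = np.array([s[1] for s in sub])
    events = np.array([s[2] for s in sub])
    try:
        high = median_split(vals)
    except ValueError:
        return False, "degenerate abundance split"
    if high.sum() < 2 or (~high).sum() < 2:
        return False, "degenerate abundance split"
    res = logrank_test(times[high], events[high], times[~high], events[~high])
    return res.p_value < policy.logrank_p_max, f"logrank_p={res.p_value:.4g}"


def protein_biomarker_scan(protein: OmicsMatrix,
                           clinical: Sequence[ClinicalRecord],
                           sets: Optional[GeneSetCollection] = None,
                           policy: Optional[BiomarkerPolicy] = None
                           ) -> Tuple[List[BiomarkerRecord], pd.DataFrame]:
    """Protein cascade; returns the audit records and the ORA annotation of
    the stage-2 survivors (reported, never a filter)."""
    policy = policy or BiomarkerPolicy()
    cols = set(protein.data.columns)
    groups = _sample_groups(clinical, cols)
    if not groups["C1-LM"] or not groups["C2-LM"]:
        raise ValueError("subtype labels absent for LM samples")
    clinical_cols = [r.sample_id for r in clinical if r.sample_id in cols]
    lm_rows = _lm_survival(clinical, cols)
    others = ["C2-LM", "C1-T", "C2-T", "C1-N", "C2-N"]
    min_l2 = math.log2(policy.protein_min_fc)
    records: List[BiomarkerRecord] = []
    survivors: List[str] = []
    data = protein.data[clinical_cols]
    miss_frac = data.isna().mean(axis=1)
    for feature in protein.data.index:
        rec = BiomarkerRecord(feature=feature, layer="protein")
        records.append(rec)
        if not rec.record("missingness", miss_frac[feature] < policy.max_missing_frac,
                          f"missing_frac={miss_frac[feature]:.3f}"):
            continue
        ref = protein.data.loc[feature, groups["C1-LM"]].dropna()
        ok = True
        if len(ref) < policy.min_per_group:
            rec.record("differential", False, "too few C1-LM values")
            continue
        for other in others:
            vals = protein.data.loc[feature, groups[other]].dropna()
            if len(vals) < policy.min_per_group:
                ok = rec.record(f"vs_{other}", False, "too few values")
                break
            log2fc = float(ref.mean() - vals.mean())
            res = wilcoxon_rank_sum(ref, vals)
            passed = log2fc > min_l2 and res.p_value < policy.p_max
            ok = rec.record(f"vs_{other}", passed,
                            f"log2fc={log2fc:.3f};p={res.p_value:.4g}")
            if not ok:
                break
        if not ok:
            continue
        survivors.append(feature)
        if not rec.record("survival",
                          *_survival_stage(protein.data.loc[feature], lm_rows,
                                           policy)):
            continue
        rec.final = True
    ora = pd.DataFrame()
    if sets is not None and survivors:
        ora = pathway_ora(survivors, list(protein.data.index), sets)
    logger.info("protein cascade: %d candidates, %d stage-2 survivors, "
                "%d final", len(records), len(survivors),
                sum(r.final for r in records))
    return records, ora


def phospho_biomarker_scan(phospho: OmicsMatrix,
                           annotation: SiteAnnotation,
                           clinical: Sequence[ClinicalRecord],
                           policy: Optional[BiomarkerPolicy] = None
                           ) -> List[BiomarkerRecord]:
    """Phosphosite cascade: C1-vs-C2 differential, functional score, survival."""
    policy = policy or BiomarkerPolicy()
    cols = set(phospho.data.columns)
    groups = _sample_groups(clinical, cols)
    if not groups["C1-LM"] or not groups["C2-LM"]:
        raise ValueError("subtype labels absent for LM samples")
    clinical_cols = [r.sample_id for r in clinical if r.sample_id in cols]
    lm_rows = _lm_survival(clinical, cols)
    min_l2 = math.log2(policy.phospho_min_fc)
    records: List[BiomarkerRecord] = []
    data = phospho.data[clinical_cols]
    miss_frac = data.isna().mean(axis=1)
    for site in phospho.data.index:
        rec = BiomarkerRecord(feature=site, layer="phosphosite")
        records.append(rec)
        if not rec.record("missingness", miss_frac[site] < policy.max_missing_frac,
                          f"missing_frac={miss_frac[site]:.3f}"):
            continue
        c1 = phospho.data.loc[site, groups["C1-LM"]].dropna()
        c2 = phospho.data.loc[site, groups["C2-LM"]].dropna()
        if len(c1) < policy.min_per_group or len(c2) < policy.min_per_group:
            rec.record("differential", False, "too few values per subtype")
            continue
        log2fc = float(c1.mean() - c2.mean())
        res = wilcoxon_rank_sum(c1, c2)
        if not rec.record("differential",
                          abs(log2fc) > min_l2 and res.p_value < policy.p_max,
                          f"log2fc={log2fc:.3f};p={res.p_value:.4g}"):
            continue
        score = annotation.functional_score(site)
        if score is None:
            rec.record("functional_score", False, "score unavailable")
            continue
        if not rec.record("functional_score",
                          score > policy.functional_score_min,
                          f"score={score:.3f}"):
            continue
        if not rec.record("survival",
                          *_survival_stage(phospho.data.loc[site], lm_rows,
                                           policy)):
            continue
        rec.final = True
    logger.info("phospho cascade: %d candidates, %d final",
                len(records), sum(r.final for r in records))
    return records


def dependency_intersect(c1_up_proteins: Sequence[str],
                         dependency_lists: Dict[str, Sequence[str]],
                         protein: OmicsMatrix,
                         clinical: Sequence[ClinicalRecord]) -> pd.DataFrame:
    """Intersect C1-up proteins with named dependency gene lists and rank the
    intersection by the paired LM-vs-T signed-rank significance."""
    from .stats import wilcoxon_signed_rank
    for name, genes in dependency_lists.items():
        if not list(genes):
            raise ValueError(f"dependency list {name!r} is empty")
    sources: Dict[str, List[str]] = {}
    for name, genes in dependency_lists.items():
        for g in genes:
            sources.setdefault(g, []).append(name)
    shared = [g for g in c1_up_proteins
              if g in sources and g in protein.data.index]
    by_patient: Dict[str, Dict[str, str]] = {}
    for r in clinical:
        if r.sample_id in protein.data.columns:
            by_patient.setdefault(r.patient_id, {})[r.tissue] = r.sample_id
    pairs = [(d["LM"], d["T"]) for d in by_patient.values()
             if "LM" in d and "T" in d]
    rows = []
    for gene in shared:
        lm = protein.data.loc[gene, [p[0] for p in pairs]].to_numpy(float)
        t = protein.data.loc[gene, [p[1] for p in pairs]].to_numpy(float)
        ok = np.isfinite(lm) & np.isfinite(t)
        if ok.sum() < 3:
            rows.append({"gene": gene, "sources": ";".join(sources[gene]),
                         "log2fc_lm_vs_t": np.nan, "p": np.nan})
            continue
        diffs = lm[ok] - t[ok]
        res = wilcoxon_signed_rank(diffs)
        rows.append({"gene": gene, "sources": ";".join(sorted(set(sources[gene]))),
                     "log2fc_lm_vs_t": float(np.mean(diffs)), "p": res.p_value})
    df = pd.DataFrame(rows, columns=["gene", "sources", "log2fc_lm_vs_t", "p"])
    if len(df):
        df = df.sort_values(["p", "gene"], kind="stable").reset_index(drop=True)
    return df


def biomarker_frame(records: Sequence[BiomarkerRecord]) -> pd.DataFrame:
    """Full audit trail: one row per candidate with stage pass/fail details."""
    rows = []
    for r in records:
        row = {"feature": r.feature, "layer": r.layer, "final": r.final,
               "failing_stage": r.failing_stage or ""}
        for stage, (passed, detail) in r.stages.items():
            row[f"stage_{stage}"] = "pass" if passed else "fail"
            row[f"detail_{stage}"] = detail
        rows.append(row)
    return pd.DataFrame(rows)
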