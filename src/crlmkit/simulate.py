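"""Synthetic multi-omics CRLM cohort with planted, recoverable ground truth.

The generator emulates the structure of a paired normal / primary tumor /
liver-metastasis (N/T/LM) proteogenomic cohort:

* per-patient gene-level copy-number states in {-1, 0, +1} whose cis effect
  attenuates down the central dogma (mRNA > protein > phosphosite), with the
  noise scales solved analytically from target Spearman levels;
* two LM proteomic subtypes driven by disjoint gene blocks (a "metabolism"
  block up in C1, an "RNA function" block up in C2) with subtype-dependent
  exponential survival;
* LM- and T-enriched protein blocks shared across patients (tissue effects);
* planted kinases whose substrate phosphosites shift between LM and T;
* intensity-dependent (MNAR logistic) plus completely-at-random missingness
  on the MS layers, internal-reference (IRS) replicate columns, an
  rMATS-like alternative-splicing table with subtype- and splicing-factor-
  driven events, and a small binary mutation matrix.

Everything is deterministic given the config seed: each component draws from
its own fixed-key substream, so adding one layer never perturbs another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .io import (ASEventTable, ClinicalRecord, GeneSetCollection,
                 KinaseSubstrateMap, OmicsMatrix, SiteAnnotation)
from .stats import bh_adjust, wilcoxon_rank_sum

EVENT_TYPE_WEIGHTS = {"SE": 0.72, "MXE": 0.15, "A3SS": 0.05, "A5SS": 0.04, "RI": 0.04}

# fixed substream keys: adding a component never reseeds another
_STREAMS = {"structure": 0, "cnv": 1, "mrna": 2, "protein": 3, "phospho": 4,
            "missing": 5, "irs": 6, "survival": 7, "splicing": 8,
            "mutation": 9, "clinical": 10, "annotation": 11}


class InfeasibleConfig(ValueError):
    """The requested cohort cannot be generated; message names the constraint."""


@dataclass
class SyntheticConfig:
    """Stated world of the synthetic cohort.  Defaults mirror the cohort
    shape of a 34-patient paired N/T/LM study, scaled to run in minutes."""

    seed: int
    n_patients: int = 34
    n_genes: int = 8000
    metabolism_block: int = 300
    rna_function_block: int = 300
    n_lm_enriched: int = 245
    n_t_enriched: int = 96
    n_cis_genes: int = 500
    n_protein_biomarkers: int = 10
    sites_per_gene_mean: float = 2.0
    # target Spearman of CNV with (mrna, protein, phosphosite) for cis genes
    cis_targets: Tuple[float, float, float] = (0.6, 0.4, 0.25)
    cnv_alt_prob: float = 0.15          # P(+1) = P(-1) per gene per patient
    sigma_mrna: float = 0.5             # log2 biological noise at the mRNA layer
    tissue_effect: float = 2.0          # log2 shift of LM-/T-enriched blocks
    mrna_tissue_fraction: float = 0.7   # fraction of tissue effect visible in mRNA
    subtype_effect: float = 2.0         # log2 shift of subtype blocks in LM
    kinase_panel: Tuple[Tuple[str, int, float], ...] = tuple(
        (f"KIN{i}", 15, 1.0) for i in range(1, 6))
    n_decoy_kinases: int = 10
    decoy_substrates: int = 10
    log_hazard_ratio: float = math.log(3.0)   # C1 vs C2
    baseline_median_os: float = 1500.0        # days, C2 subtype
    censor_rate: float = 2.0e-4               # per day, exponential censoring
    mcar_rate: float = 0.02
    mnar_slope: float = 1.0
    mnar_intercept: float = -2.8
    n_irs_replicates: int = 3
    sigma_irs: float = 0.1
    baseline_sd: float = 1.5            # per-feature abundance offsets
    sample_offset_sd: float = 0.3       # per-sample loading offsets
    n_as_events: int = 60
    n_subtype_events: int = 20
    psi_shift: float = 0.25
    psi_noise: float = 0.05
    n_splicing_factors: int = 6
    n_factor_edges: int = 11

    def validate(self) -> None:
        r1, r2, r3 = self.cis_targets
        if not (0 < r3 < r2 < r1 < 1):
            raise InfeasibleConfig(
                f"cis targets must satisfy 0 < phospho < protein < mrna < 1, "
                f"got {self.cis_targets}")
        blocks = (self.metabolism_block + self.rna_function_block +
                  self.n_lm_enriched + self.n_t_enriched + self.n_cis_genes)
        if blocks > self.n_genes:
            raise InfeasibleConfig(
                f"gene blocks ({blocks}) exceed total genes ({self.n_genes})")
        if self.n_protein_biomarkers > self.metabolism_block:
            raise InfeasibleConfig("biomarkers must fit inside the metabolism block")
        for name in ("cnv_alt_prob", "mcar_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise InfeasibleConfig(f"{name}={v} outside [0, 1]")
        if self.n_patients < 4:
            raise InfeasibleConfig("need at least 4 patients")
        if self.seed is None:
            raise InfeasibleConfig("seed is mandatory")

    @classmethod
    def from_dict(cls, d: Dict) -> "SyntheticConfig":
        d = dict(d)
        if "kinase_panel" in d:
            d["kinase_panel"] = tuple(tuple(k) for k in d["kinase_panel"])
        if "cis_targets" in d:
            d["cis_targets"] = tuple(d["cis_targets"])
        return cls(**d)

    def to_dict(self) -> Dict:
        d = asdict(self)
        d["kinase_panel"] = [list(k) for k in self.kinase_panel]
        d["cis_targets"] = list(self.cis_targets)
        return d


@dataclass
class TruthManifest:
    """Planted ground truth; every id exists in the generated matrices."""

    subtype_by_patient: Dict[str, str]
    cis_genes: List[str]
    metabolism_genes: List[str]
    rna_function_genes: List[str]
    lm_enriched_genes: List[str]
    t_enriched_genes: List[str]
    active_kinases_lm_vs_t: List[str]
    protein_biomarkers: List[str]
    phospho_biomarkers: List[str]
    true_hazard_ratio: float
    planted_as_events: List[str]
    factor_event_edges: List[Tuple[str, str]]


@dataclass
class CohortBundle:
    """Everything one pipeline run consumes, plus the planted truth."""

    config: SyntheticConfig
    matrices: Dict[str, OmicsMatrix]
    clinical: List[ClinicalRecord]
    kinase_map: KinaseSubstrateMap
    as_events: ASEventTable
    site_annotation: SiteAnnotation
    mutations: pd.DataFrame
    truth: TruthManifest
    irs_sample_ids: List[str]


def _rng(seed: int, component: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[component],)))


def _spearman_to_pearson(rho_s: float) -> float:
    """Bivariate-normal relation rho_P = 2 sin(pi * rho_S / 6)."""
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


def generate_cohort(config: SyntheticConfig) -> CohortBundle:
    config.validate()
    seed = config.seed

    # ---- structure: genes, blocks, sites, patients, subtypes ----
    rs = _rng(seed, "structure")
    genes = [f"G{i:05d}" for i in range(config.n_genes)]
    i0 = 0
    met = genes[i0:i0 + config.metabolism_block]; i0 += config.metabolism_block
    rna = genes[i0:i0 + config.rna_function_block]; i0 += config.rna_function_block
    lm_up = genes[i0:i0 + config.n_lm_enriched]; i0 += config.n_lm_enriched
    t_up = genes[i0:i0 + config.n_t_enriched]; i0 += config.n_t_enriched
    cis = genes[i0:i0 + config.n_cis_genes]; i0 += config.n_cis_genes
    null_genes = genes[i0:]
    biomarker_genes = met[:config.n_protein_biomarkers]

    n_sites_per_gene = rs.poisson(config.sites_per_gene_mean, size=config.n_genes)
    # planted biomarker / metabolism genes keep at least one site
    for g in biomarker_genes:
        gi = genes.index(g)
        n_sites_per_gene[gi] = max(n_sites_per_gene[gi], 1)
    sites: List[str] = []
    site_parent_idx: List[int] = []
    for gi, g in enumerate(genes):
        positions = rs.choice(np.arange(1, 2000), size=n_sites_per_gene[gi],
                              replace=False) if n_sites_per_gene[gi] else []
        for pos in sorted(positions):
            residue = rs.choice(["S", "T", "Y"], p=[0.75, 0.2, 0.05])
            sites.append(f"{g}_{residue}{pos}")
            site_parent_idx.append(gi)
    site_parent_idx = np.asarray(site_parent_idx)
    n_sites = len(sites)

    patients = [f"P{i + 1:02d}" for i in range(config.n_patients)]
    subtype_arr = np.array(["C1"] * (config.n_patients // 2) +
                           ["C2"] * (config.n_patients - config.n_patients // 2))
    subtype_arr = subtype_arr[rs.permutation(config.n_patients)]
    subtype_by_patient = dict(zip(patients, subtype_arr))

    tissues = ["N", "T", "LM"]
    sample_ids = [f"{p}_{t}" for p in patients for t in tissues]
    sample_tissue = np.array([s.rsplit("_", 1)[1] for s in sample_ids])
    sample_patient_idx = np.repeat(np.arange(config.n_patients), len(tissues))
    sample_subtype = subtype_arr[sample_patient_idx]
    is_lm = sample_tissue == "LM"
    is_t = sample_tissue == "T"
    is_tumor = is_lm | is_t
    n_samples = len(sample_ids)

    # ---- noise scales solved from the cis targets ----
    r1, r2, r3 = (_spearman_to_pearson(r) for r in config.cis_targets)
    sd_cnv = math.sqrt(2.0 * config.cnv_alt_prob)
    if sd_cnv == 0:
        raise InfeasibleConfig("cnv_alt_prob=0 leaves no copy-number variation")
    a = r1 * config.sigma_mrna / (sd_cnv * math.sqrt(1.0 - r1 ** 2))
    c = a * sd_cnv
    sigma_p = c * math.sqrt(1.0 / r2 ** 2 - 1.0 / r1 ** 2)
    sigma_s = c * math.sqrt(1.0 / r3 ** 2 - 1.0 / r2 ** 2)

    # ---- copy number (patient-level gene states) ----
    rc = _rng(seed, "cnv")
    p_alt = config.cnv_alt_prob
    cnv_states = rc.choice([-1, 0, 1], size=(config.n_genes, config.n_patients),
                           p=[p_alt, 1 - 2 * p_alt, p_alt]).astype(float)
    a_vec = np.zeros(config.n_genes)
    a_vec[[genes.index(g) for g in cis]] = a

    # latent per-sample CNV (tumor tissues carry the patient state, N is diploid)
    cnv_sample = cnv_states[:, sample_patient_idx] * is_tumor[None, :]

    # ---- latent signal chain ----
    rm = _rng(seed, "mrna")
    m_star = a_vec[:, None] * cnv_sample + rm.normal(
        0.0, config.sigma_mrna, size=(config.n_genes, n_samples))
    rp = _rng(seed, "protein")
    p_star = m_star + rp.normal(0.0, sigma_p, size=(config.n_genes, n_samples))

    # ---- block shift matrices (log2) ----
    def rows(gene_list):
        return np.asarray([genes.index(g) for g in gene_list], dtype=int)

    prot_shift = np.zeros((config.n_genes, n_samples))
    prot_shift[np.ix_(rows(lm_up), np.where(is_lm)[0])] += config.tissue_effect
    prot_shift[np.ix_(rows(t_up), np.where(is_t)[0])] += config.tissue_effect
    c1_lm = is_lm & (sample_subtype == "C1")
    c2_lm = is_lm & (sample_subtype == "C2")
    prot_shift[np.ix_(rows(met), np.where(c1_lm)[0])] += config.subtype_effect
    prot_shift[np.ix_(rows(rna), np.where(c2_lm)[0])] += config.subtype_effect

    mrna_shift = np.zeros((config.n_genes, n_samples))
    mrna_shift[np.ix_(rows(lm_up), np.where(is_lm)[0])] += (
        config.tissue_effect * config.mrna_tissue_fraction)
    mrna_shift[np.ix_(rows(t_up), np.where(is_t)[0])] += (
        config.tissue_effect * config.mrna_tissue_fraction)

    # ---- kinase panel: substrate sites shifted in LM ----
    null_site_mask = np.isin(site_parent_idx, rows(null_genes)) if null_genes else \
        np.zeros(n_sites, bool)
    null_site_pool = list(np.where(null_site_mask)[0])
    rs2 = _rng(seed, "phospho")
    need = sum(k[1] for k in config.kinase_panel) + \
        config.n_decoy_kinases * config.decoy_substrates
    if need > len(null_site_pool):
        raise InfeasibleConfig(
            f"kinase panel needs {need} substrate sites, only "
            f"{len(null_site_pool)} null-gene sites available")
    chosen = rs2.choice(null_site_pool, size=need, replace=False)
    ks_map: Dict[str, set] = {}
    site_kinase_shift = np.zeros(n_sites)
    ptr = 0
    for name, m, shift in config.kinase_panel:
        sub_idx = chosen[ptr:ptr + m]; ptr += m
        ks_map[name] = {sites[i] for i in sub_idx}
        site_kinase_shift[sub_idx] = shift
    for d in range(config.n_decoy_kinases):
        sub_idx = chosen[ptr:ptr + config.decoy_substrates]
        ptr += config.decoy_substrates
        ks_map[f"DECOY{d + 1}"] = {sites[i] for i in sub_idx}

    s_star = p_star[site_parent_idx, :] + rs2.normal(
        0.0, sigma_s, size=(n_sites, n_samples))
    phos_shift = prot_shift[site_parent_idx, :] + \
        site_kinase_shift[:, None] * is_lm[None, :]

    # ---- observed matrices: baselines + sample offsets + signal + shifts ----
    baseline_m = rm.normal(0.0, config.baseline_sd, size=config.n_genes)
    baseline_p = rp.normal(0.0, config.baseline_sd, size=config.n_genes)
    baseline_p[rows(biomarker_genes)] = 3.0 + rp.normal(0.0, 0.2,
                                                        size=len(biomarker_genes))
    baseline_s = rs2.normal(0.0, config.baseline_sd, size=n_sites)
    # planted phospho biomarkers: first site of each biomarker gene, kept abundant
    phospho_biomarkers = []
    for g in biomarker_genes:
        gi = genes.index(g)
        first = int(np.where(site_parent_idx == gi)[0][0])
        phospho_biomarkers.append(sites[first])
        baseline_s[first] = 3.0
    off_m = rm.normal(0.0, config.sample_offset_sd, size=n_samples)
    off_p = rp.normal(0.0, config.sample_offset_sd, size=n_samples)
    off_s = rs2.normal(0.0, config.sample_offset_sd, size=n_samples)

    mrna_obs = baseline_m[:, None] + off_m[None, :] + m_star + mrna_shift
    prot_obs = baseline_p[:, None] + off_p[None, :] + p_star + prot_shift
    phos_obs = baseline_s[:, None] + off_s[None, :] + s_star + phos_shift

    # ---- missingness on the MS layers (MCAR union MNAR logistic) ----
    rmiss = _rng(seed, "missing")

    def apply_missing(obs: np.ndarray) -> np.ndarray:
        p_mnar = 1.0 / (1.0 + np.exp(-(config.mnar_intercept -
                                       config.mnar_slope * obs)))
        miss = (rmiss.random(obs.shape) < p_mnar) | \
               (rmiss.random(obs.shape) < config.mcar_rate)
        out = obs.copy()
        out[miss] = np.nan
        return out

    prot_final = apply_missing(prot_obs)
    phos_final = apply_missing(phos_obs)

    # ---- IRS replicate columns: cohort mean profile + tight noise ----
    rirs = _rng(seed, "irs")
    irs_ids = [f"IRS_{i + 1}" for i in range(config.n_irs_replicates)]
    prot_irs = prot_obs.mean(axis=1)[:, None] + rirs.normal(
        0.0, config.sigma_irs, size=(config.n_genes, config.n_irs_replicates))
    phos_irs = phos_obs.mean(axis=1)[:, None] + rirs.normal(
        0.0, config.sigma_irs, size=(n_sites, config.n_irs_replicates))

    tumor_cols = [s for s, t in zip(sample_ids, is_tumor) if t]
    matrices = {
        "cnv": OmicsMatrix("cnv", pd.DataFrame(
            cnv_sample[:, is_tumor], index=genes, columns=tumor_cols),
            is_normalized=True),
        "mrna": OmicsMatrix("mrna", pd.DataFrame(
            mrna_obs, index=genes, columns=sample_ids)),
        "protein": OmicsMatrix("protein", pd.DataFrame(
            np.hstack([prot_final, prot_irs]), index=genes,
            columns=sample_ids + irs_ids)),
        "phosphosite": OmicsMatrix("phosphosite", pd.DataFrame(
            np.hstack([phos_final, phos_irs]), index=sites,
            columns=sample_ids + irs_ids)),
    }

    # ---- survival & clinical ----
    rsv = _rng(seed, "survival")
    rcl = _rng(seed, "clinical")
    h0 = math.log(2.0) / config.baseline_median_os
    hazard = h0 * np.exp(config.log_hazard_ratio * (subtype_arr == "C1"))
    event_time = rsv.exponential(1.0 / hazard)
    censor_time = rsv.exponential(1.0 / config.censor_rate, size=config.n_patients) \
        if config.censor_rate > 0 else np.full(config.n_patients, np.inf)
    os_time = np.minimum(event_time, censor_time)
    os_event = (event_time <= censor_time).astype(int)
    pfs_frac = rsv.uniform(0.3, 1.0, size=config.n_patients)
    crs = rcl.binomial(5, 0.45, size=config.n_patients)
    clinical = []
    for si, sid in enumerate(sample_ids):
        pi = sample_patient_idx[si]
        clinical.append(ClinicalRecord(
            patient_id=patients[pi], sample_id=sid, tissue=sample_tissue[si],
            os_time=round(float(os_time[pi]), 1), os_event=int(os_event[pi]),
            crs=int(crs[pi]),
            pfs_time=round(float(os_time[pi] * pfs_frac[pi]), 1),
            pfs_event=int(os_event[pi])))

    # ---- alternative splicing table over LM samples ----
    ras = _rng(seed, "splicing")
    lm_ids = [s for s, f in zip(sample_ids, is_lm) if f]
    lm_subtype = sample_subtype[is_lm]
    n_events = config.n_as_events
    if config.n_subtype_events + config.n_factor_edges > n_events:
        raise InfeasibleConfig("planted AS events exceed n_as_events")
    event_ids = [f"AS{i + 1:04d}" for i in range(n_events)]
    event_genes = list(ras.choice(genes, size=n_events, replace=False))
    etypes = ras.choice(list(EVENT_TYPE_WEIGHTS), size=n_events,
                        p=list(EVENT_TYPE_WEIGHTS.values()))
    psi = np.empty((n_events, len(lm_ids)))
    planted_events = event_ids[:config.n_subtype_events]
    factor_genes = rna[:config.n_splicing_factors]
    edge_events = event_ids[config.n_subtype_events:
                            config.n_subtype_events + config.n_factor_edges]
    edges: List[Tuple[str, str]] = []
    prot_lm = prot_obs[:, is_lm]
    for ei in range(n_events):
        noise = ras.normal(0.0, config.psi_noise, size=len(lm_ids))
        if event_ids[ei] in planted_events:
            sign = 1.0 if ei % 2 == 0 else -1.0
            base = 0.5 + sign * config.psi_shift * (lm_subtype == "C1") - \
                sign * config.psi_shift / 2.0
            psi[ei] = base + noise
        elif event_ids[ei] in edge_events:
            fg = factor_genes[len(edges) % len(factor_genes)]
            prof = prot_lm[genes.index(fg)]
            z = (prof - prof.mean()) / (prof.std() + 1e-12)
            sign = 1.0 if ei % 2 == 0 else -1.0
            psi[ei] = 0.5 + sign * 0.15 * z + noise
            edges.append((fg, event_ids[ei]))
        else:
            psi[ei] = ras.uniform(0.2, 0.8) + noise
    psi = np.clip(psi, 0.0, 1.0)
    # rMATS-style summary columns from the generated PSI (C1 vs C2 contrast)
    c1_cols = lm_subtype == "C1"
    ild = psi[:, c1_cols].mean(axis=1) - psi[:, ~c1_cols].mean(axis=1)
    pvals = np.array([
        wilcoxon_rank_sum(psi[ei, c1_cols], psi[ei, ~c1_cols]).p_value
        if psi[ei].std() > 0 else 1.0
        for ei in range(n_events)])
    fdr = bh_adjust(pvals)
    as_table = ASEventTable(
        events=pd.DataFrame({"gene": event_genes, "event_type": etypes,
                             "inc_level_difference": np.clip(ild, -1, 1),
                             "fdr": fdr}, index=pd.Index(event_ids, name="event_id")),
        psi=pd.DataFrame(psi, index=pd.Index(event_ids, name="event_id"),
                         columns=lm_ids))

    # ---- phosphosite annotation ----
    rann = _rng(seed, "annotation")
    scores = rann.uniform(0.0, 1.0, size=n_sites)
    loc = np.where(rann.random(n_sites) < 0.85, "I", "II")
    for s in phospho_biomarkers:
        i = sites.index(s)
        scores[i] = 0.8 + rann.uniform(0.0, 0.15)
        loc[i] = "I"
    annotation = SiteAnnotation(pd.DataFrame(
        {"functional_score": scores, "localization_class": loc},
        index=pd.Index(sites, name="site")))

    # ---- minimal binary mutation matrix (patient-level, tumor columns) ----
    rmu = _rng(seed, "mutation")
    mut_genes = [f"MUT{i + 1:02d}" for i in range(10)]
    freq_c1 = np.array([0.6, 0.6, 0.6, 0.25, 0.25, 0.25, 0.1, 0.1, 0.1, 0.1])
    freq_c2 = np.array([0.6, 0.6, 0.6, 0.0, 0.0, 0.0, 0.1, 0.1, 0.1, 0.1])
    freqs = np.where((subtype_arr == "C1")[None, :], freq_c1[:, None],
                     freq_c2[:, None])
    mut_pat = (rmu.random((10, config.n_patients)) < freqs).astype(float)
    mutations = pd.DataFrame(mut_pat[:, sample_patient_idx[is_tumor]],
                             index=mut_genes, columns=tumor_cols)

    truth = TruthManifest(
        subtype_by_patient=subtype_by_patient,
        cis_genes=list(cis), metabolism_genes=list(met),
        rna_function_genes=list(rna), lm_enriched_genes=list(lm_up),
        t_enriched_genes=list(t_up),
        active_kinases_lm_vs_t=[k[0] for k in config.kinase_panel if k[2] != 0],
        protein_biomarkers=list(biomarker_genes),
        phospho_biomarkers=phospho_biomarkers,
        true_hazard_ratio=math.exp(config.log_hazard_ratio),
        planted_as_events=list(planted_events),
        factor_event_edges=edges)

    return CohortBundle(config=config, matrices=matrices, clinical=clinical,
                        kinase_map=KinaseSubstrateMap(ks_map), as_events=as_table,
                        site_annotation=annotation, mutations=mutations,
                        truth=truth, irs_sample_ids=irs_ids)


def assign_subtypes(clinical: Sequence[ClinicalRecord],
                    subtype_by_patient: Dict[str, str]) -> List[ClinicalRecord]:
    """Return new clinical records with the subtype field filled per patient."""
    out = []
    for r in clinical:
        out.append(ClinicalRecord(
            patient_id=r.patient_id, sample_id=r.sample_id, tissue=r.tissue,
            os_time=r.os_time, os_event=r.os_event, crs=r.crs,
            subtype=subtype_by_patient.get(r.patient_id),
            pfs_time=r.pfs_time, pfs_event=r.pfs_event))
    return out


def cohort_summary(bundle: CohortBundle) -> pd.DataFrame:
    """Counts of samples per tissue/subtype, features and missingness per layer."""
    if not bundle.clinical:
        raise ValueError("empty bundle: no clinical samples")
    rows = []
    tissue_counts: Dict[str, int] = {}
    for r in bundle.clinical:
        tissue_counts[r.tissue] = tissue_counts.get(r.tissue, 0) + 1
    rows.append(("samples", "total", len(bundle.clinical)))
    for t in ("N", "T", "LM"):
        rows.append(("samples", f"tissue_{t}", tissue_counts.get(t, 0)))
    sub_counts: Dict[str, int] = {}
    for s in bundle.truth.subtype_by_patient.values():
        sub_counts[s] = sub_counts.get(s, 0) + 1
    for s in ("C1", "C2"):
        rows.append(("patients", f"subtype_{s}", sub_counts.get(s, 0)))
    for layer, m in bundle.matrices.items():
        rows.append((layer, "n_features", m.shape[0]))
        rows.append((layer, "n_samples", m.shape[1]))
        frac = m.missing_fraction()
        if not 0 <= frac <= 1:
            raise AssertionError("missingness fraction outside [0, 1]")
        rows.append((layer, "missing_fraction", round(frac, 4)))
    return pd.DataFrame(rows, columns=["section", "key", "value"])


# ---------------------------------------------------------------------------
# Truth manifest serialization
# ---------------------------------------------------------------------------

def write_truth_manifest(truth: TruthManifest, path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("section\tkey\tvalue\n")
        for pat, sub in truth.subtype_by_patient.items():
            fh.write(f"subtype\t{pat}\t{sub}\n")
        for section in ("cis_genes", "metabolism_genes", "rna_function_genes",
                        "lm_enriched_genes", "t_enriched_genes",
                        "active_kinases_lm_vs_t", "protein_biomarkers",
                        "phospho_biomarkers", "planted_as_events"):
            for item in getattr(truth, section):
                fh.write(f"{section}\t{item}\t\n")
        for factor, event in truth.factor_event_edges:
            fh.write(f"factor_event_edge\t{factor}\t{event}\n")
        fh.write(f"scalar\ttrue_hazard_ratio\t{truth.true_hazard_ratio!r}\n")


def load_truth_manifest(path) -> TruthManifest:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    lists: Dict[str, List[str]] = {}
    subtypes: Dict[str, str] = {}
    edges: List[Tuple[str, str]] = []
    hr = float("nan")
    for _, row in df.iterrows():
        sec, key, val = row["section"], row["key"], row["value"]
        if sec == "subtype":
            subtypes[key] = val
        elif sec == "factor_event_edge":
            edges.append((key, val))
        elif sec == "scalar" and key == "true_hazard_ratio":
            hr = float(val)
        else:
            lists.setdefault(sec, []).append(key)
    return TruthManifest(
        subtype_by_patient=subtypes,
        cis_genes=lists.get("cis_genes", []),
        metabolism_genes=lists.get("metabolism_genes", []),
        rna_function_genes=lists.get("rna_function_genes", []),
        lm_enriched_genes=lists.get("lm_enriched_genes", []),
        t_enriched_genes=lists.get("t_enriched_genes", []),
        active_kinases_lm_vs_t=lists.get("active_kinases_lm_vs_t", []),
        protein_biomarkers=lists.get("protein_biomarkers", []),
        phospho_biomarkers=lists.get("phospho_biomarkers", []),
        true_hazard_ratio=hr,
        planted_as_events=lists.get("planted_as_events", []),
        factor_event_edges=edges)
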