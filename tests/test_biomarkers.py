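"""Biomarker cascades: stage bookkeeping, planted recovery, monotonicity."""

import numpy as np
import pandas as pd
import pytest

from crlmkit.biomarkers import (BiomarkerPolicy, dependency_intersect,
                                phospho_biomarker_scan, protein_biomarker_scan)
from crlmkit.io import ClinicalRecord, OmicsMatrix, SiteAnnotation
from crlmkit.preprocess import normalize_log2_median
from crlmkit.simulate import assign_subtypes, generate_cohort
from tests.conftest import small_config


def cascade_cohort(seed=31, **overrides):
    """Cohort sized so the survival stage (median-split log-rank at HR 3)
    has adequate power for the planted markers."""
    overrides.setdefault("n_patients", 150)
    cfg = small_config(seed=seed, **overrides)
    b = generate_cohort(cfg)
    prot = normalize_log2_median(
        b.matrices["protein"].drop_samples(b.irs_sample_ids))
    phos = normalize_log2_median(
        b.matrices["phosphosite"].drop_samples(b.irs_sample_ids))
    clin = assign_subtypes(b.clinical, b.truth.subtype_by_patient)
    return b, prot, phos, clin


@pytest.fixture(scope="module")
def cascade():
    return cascade_cohort()


def toy_cascade(c1_lm_shift=2.0, break_group=None, n_per_group=8, seed=0):
    """One feature, six explicit sample groups; optionally flatten the shift
    in a single comparison group."""
    rng = np.random.default_rng(seed)
    groups = ["C1-LM", "C2-LM", "C1-T", "C2-T", "C1-N", "C2-N"]
    cols, vals, clin = [], [], []
    pid = 0
    for g in groups:
        subtype, tissue = g.split("-")
        for i in range(n_per_group):
            sid = f"P{pid:03d}_{tissue}"
            base = rng.normal(0, 0.3)
            if g == "C1-LM":
                base += c1_lm_shift
            if break_group and g == break_group:
                base += c1_lm_shift  # this group is as high as C1-LM
            cols.append(sid)
            vals.append(base)
            clin.append(ClinicalRecord(
                patient_id=f"P{pid:03d}", sample_id=sid, tissue=tissue,
                subtype=subtype, os_time=float(rng.exponential(500) + 1),
                os_event=int(rng.random() < 0.8)))
            pid += 1
    data = pd.DataFrame([vals], index=["CAND"], columns=cols)
    return OmicsMatrix("protein", data, is_normalized=True), clin


class TestProteinCascade:
    def test_planted_markers_recovered(self, cascade):
        b, prot, _, clin = cascade
        recs, _ = protein_biomarker_scan(prot, clin)
        final = {r.feature for r in recs if r.final}
        planted = set(b.truth.protein_biomarkers)
        recall = len(final & planted) / len(planted)
        assert recall >= 0.75  # survival stage has ~98% per-marker power

    def test_failing_comparison_is_named(self):
        m, clin = toy_cascade(break_group="C1-N")
        recs, _ = protein_biomarker_scan(m, clin)
        rec = recs[0]
        assert not rec.final
        assert rec.failing_stage == "vs_C1-N"
        assert rec.stages["vs_C2-LM"][0]  # earlier comparisons passed

    def test_high_missingness_rejected_at_stage_one(self):
        m, clin = toy_cascade()
        vals = m.data.copy()
        n_missing = int(np.ceil(0.12 * vals.shape[1]))
        vals.iloc[0, :n_missing] = np.nan
        m2 = OmicsMatrix("protein", vals, is_normalized=True)
        recs, _ = protein_biomarker_scan(m2, clin)
        assert recs[0].failing_stage == "missingness"

    def test_missing_subtype_labels_rejected(self, cascade):
        b, prot, _, _ = cascade
        with pytest.raises(ValueError, match="subtype"):
            protein_biomarker_scan(prot, b.clinical)  # unlabeled records

    def test_cascade_monotone_in_thresholds(self, cascade):
        b, prot, _, clin = cascade
        strict = BiomarkerPolicy()
        loose = BiomarkerPolicy(max_missing_frac=0.2, protein_min_fc=1.1,
                                p_max=0.1, logrank_p_max=0.1)
        final_strict = {r.feature for r in
                        protein_biomarker_scan(prot, clin, policy=strict)[0]
                        if r.final}
        final_loose = {r.feature for r in
                       protein_biomarker_scan(prot, clin, policy=loose)[0]
                       if r.final}
        assert final_strict <= final_loose


class TestPhosphoCascade:
    def test_planted_sites_recovered(self, cascade):
        b, _, phos, clin = cascade
        recs = phospho_biomarker_scan(phos, b.site_annotation, clin)
        planted = set(b.truth.phospho_biomarkers)
        mine = [r for r in recs if r.feature in planted]
        # every planted site clears missingness, differential, and score
        reached_survival = [r for r in mine
                            if r.final or r.failing_stage == "survival"]
        assert len(reached_survival) == len(planted)
        # the survival stage is lower-powered at phosphosite noise levels;
        # require a majority, not all
        assert sum(r.final for r in mine) >= len(planted) / 2

    def test_low_functional_score_rejected_at_that_stage(self):
        m, clin = toy_cascade()
        site = "CAND_S1"
        phos = OmicsMatrix("phosphosite",
                           m.data.rename(index={"CAND": site}),
                           is_normalized=True)
        ann = SiteAnnotation(pd.DataFrame(
            {"functional_score": [0.4], "localization_class": ["I"]},
            index=pd.Index([site], name="site")))
        recs = phospho_biomarker_scan(phos, ann, clin)
        assert recs[0].failing_stage == "functional_score"
        assert recs[0].stages["differential"][0]

    def test_nonsignificant_fold_change_rejected(self):
        # |FC| large but noisy -> differential stage must fail on p
        rng = np.random.default_rng(9)
        m, clin = toy_cascade(c1_lm_shift=0.0)
        site = "CAND_S1"
        vals = m.data.rename(index={"CAND": site}).copy()
        # big spread, no systematic difference
        vals.iloc[0] = rng.normal(0, 3.0, vals.shape[1])
        phos = OmicsMatrix("phosphosite", vals, is_normalized=True)
        ann = SiteAnnotation(pd.DataFrame(
            {"functional_score": [0.9], "localization_class": ["I"]},
            index=pd.Index([site], name="site")))
        recs = phospho_biomarker_scan(phos, ann, clin)
        assert recs[0].failing_stage == "differential"


class TestDependencyIntersect:
    def test_disjoint_lists_empty_table(self, cascade):
        b, prot, _, clin = cascade
        out = dependency_intersect(b.truth.protein_biomarkers,
                                   {"crc": ["ZZZ1"], "hcc": ["ZZZ2"]},
                                   prot, clin)
        assert out.empty

    def test_planted_dependency_gene_ranked_first(self, cascade):
        b, prot, _, clin = cascade
        planted = b.truth.protein_biomarkers[0]
        lm_up = b.truth.lm_enriched_genes[0]  # strong paired LM-T effect
        decoy = b.truth.cis_genes[0]          # no LM-T effect
        out = dependency_intersect([lm_up, decoy],
                                   {"crc": [lm_up, decoy]}, prot, clin)
        assert out["gene"].iloc[0] == lm_up

    def test_duplicates_deduplicated_with_sources(self, cascade):
        b, prot, _, clin = cascade
        g = b.truth.lm_enriched_genes[0]
        out = dependency_intersect([g], {"crc": [g], "hcc": [g]}, prot, clin)
        assert len(out) == 1
        assert out["sources"].iloc[0] == "crc;hcc"

    def test_empty_list_rejected(self, cascade):
        b, prot, _, clin = cascade
        with pytest.raises(ValueError, match="empty"):
            dependency_intersect(["G1"], {"crc": []}, prot, clin)
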