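"""Generator contracts: determinism, cohort shape, planted-structure
recovery targets, and the attenuation/stability invariants."""

import numpy as np
import pandas as pd
import pytest

from crlmkit.io import site_to_gene
from crlmkit.preprocess import irs_reproducibility, normalize_log2_median
from crlmkit.simulate import (InfeasibleConfig, SyntheticConfig,
                              cohort_summary, generate_cohort,
                              load_truth_manifest, write_truth_manifest)
from crlmkit.stats import km_curve, spearman_corr
from tests.conftest import small_config


class TestDeterminism:
    def test_same_seed_byte_identical(self):
        a = generate_cohort(small_config(seed=11))
        b = generate_cohort(small_config(seed=11))
        for layer in a.matrices:
            pd.testing.assert_frame_equal(a.matrices[layer].data,
                                          b.matrices[layer].data)
        pd.testing.assert_frame_equal(a.as_events.psi, b.as_events.psi)
        assert a.truth == b.truth
        assert [r.__dict__ for r in a.clinical] == [r.__dict__ for r in b.clinical]

    def test_different_seeds_differ(self):
        a = generate_cohort(small_config(seed=11))
        b = generate_cohort(small_config(seed=12))
        assert not a.matrices["protein"].data.equals(b.matrices["protein"].data)


class TestCohortShape:
    def test_default_config_produces_102_samples(self):
        # 34 patients with matched N/T/LM triplets
        cfg = SyntheticConfig(seed=3, n_genes=400, metabolism_block=20,
                              rna_function_block=20, n_lm_enriched=20,
                              n_t_enriched=10, n_cis_genes=50,
                              n_protein_biomarkers=5, n_as_events=20,
                              n_subtype_events=6, n_factor_edges=4)
        assert cfg.n_patients == 34
        summary = cohort_summary(generate_cohort(cfg))
        total = summary.query("section == 'samples' and key == 'total'")
        assert int(total["value"].iloc[0]) == 102

    def test_missingness_fraction_bounded(self, bundle):
        summary = cohort_summary(bundle)
        fracs = summary[summary["key"] == "missing_fraction"]["value"]
        assert ((fracs >= 0) & (fracs <= 1)).all()

    def test_empty_bundle_rejected(self, bundle):
        import dataclasses
        empty = dataclasses.replace(bundle, clinical=[])
        with pytest.raises(ValueError, match="empty"):
            cohort_summary(empty)

    def test_every_planted_id_exists(self, bundle):
        prot = set(bundle.matrices["protein"].feature_ids)
        phos = set(bundle.matrices["phosphosite"].feature_ids)
        truth = bundle.truth
        assert set(truth.cis_genes) <= prot
        assert set(truth.protein_biomarkers) <= prot
        assert set(truth.phospho_biomarkers) <= phos
        assert set(truth.planted_as_events) <= set(bundle.as_events.event_ids)
        for kinase in truth.active_kinases_lm_vs_t:
            assert bundle.kinase_map[kinase] <= phos


class TestInfeasibleConfigs:
    @pytest.mark.parametrize("overrides,match", [
        (dict(cis_targets=(0.3, 0.4, 0.25)), "cis targets"),
        (dict(n_genes=100), "gene blocks"),
        (dict(n_patients=2), "patients"),
        (dict(mcar_rate=1.5), "mcar_rate"),
    ])
    def test_violated_constraint_named(self, overrides, match):
        with pytest.raises(InfeasibleConfig, match=match):
            generate_cohort(small_config(**overrides))


class TestPlantedStructure:
    def test_cis_targets_recovered_within_tolerance(self):
        # config targets (0.6, 0.4, 0.25); empirical medians within +-0.1
        cfg = small_config(seed=21, n_patients=40)
        b = generate_cohort(cfg)
        t_cols = [r.sample_id for r in b.clinical if r.tissue == "T"]
        cnv = b.matrices["cnv"].data[t_cols]
        layers = {
            "mrna": normalize_log2_median(b.matrices["mrna"]),
            "protein": normalize_log2_median(
                b.matrices["protein"].drop_samples(b.irs_sample_ids)),
        }
        medians = {}
        for name, m in layers.items():
            rhos = []
            for g in b.truth.cis_genes:
                rho, _ = spearman_corr(cnv.loc[g], m.data.loc[g, t_cols])
                if np.isfinite(rho):
                    rhos.append(rho)
            medians[name] = np.median(rhos)
        phos = normalize_log2_median(
            b.matrices["phosphosite"].drop_samples(b.irs_sample_ids))
        site_of = {}
        for s in phos.feature_ids:
            site_of.setdefault(site_to_gene(s), s)
        rhos = []
        for g in b.truth.cis_genes:
            if g in site_of:
                rho, _ = spearman_corr(cnv.loc[g],
                                       phos.data.loc[site_of[g], t_cols])
                if np.isfinite(rho):
                    rhos.append(rho)
        medians["phosphosite"] = np.median(rhos)
        for target, layer in zip(cfg.cis_targets,
                                 ("mrna", "protein", "phosphosite")):
            assert abs(medians[layer] - target) < 0.1, (layer, medians)

    def test_attenuation_ordering_in_expectation(self, bundle):
        b = bundle
        t_cols = [r.sample_id for r in b.clinical if r.tissue == "T"]
        cnv = b.matrices["cnv"].data[t_cols]
        means = {}
        for layer in ("mrna", "protein"):
            m = b.matrices[layer]
            rhos = []
            for g in b.truth.cis_genes:
                rho, _ = spearman_corr(cnv.loc[g], m.data.loc[g, t_cols])
                if np.isfinite(rho):
                    rhos.append(abs(rho))
            means[layer] = np.mean(rhos)
        assert means["mrna"] > means["protein"]

    def test_irs_replicates_tightly_correlated(self, bundle):
        m = normalize_log2_median(bundle.matrices["protein"])
        corr = irs_reproducibility(m, bundle.irs_sample_ids)
        off_diag = corr.to_numpy()[~np.eye(len(corr), dtype=bool)]
        assert off_diag.min() > 0.95

    def test_c1_subtype_has_shorter_survival(self, bundle):
        truth = bundle.truth
        seen = {}
        for r in bundle.clinical:
            seen.setdefault(r.patient_id, r)
        groups = {"C1": [], "C2": []}
        for pid, rec in seen.items():
            groups[truth.subtype_by_patient[pid]].append(rec)
        med = {}
        for sub, recs in groups.items():
            curve = km_curve([r.os_time for r in recs],
                             [r.os_event for r in recs])
            med[sub] = curve.median_survival()
        assert med["C1"] < med["C2"]


def test_truth_manifest_round_trip(bundle, tmp_path):
    path = tmp_path / "truth.tsv"
    write_truth_manifest(bundle.truth, path)
    back = load_truth_manifest(path)
    assert back == bundle.truth
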