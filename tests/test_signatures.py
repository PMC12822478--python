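"""Signature construction, preranked GSEA against exhaustive oracles,
sample scoring, and survival stratification."""

import itertools

import numpy as np
import pandas as pd
import pytest

from crlmkit.io import GeneSetCollection, OmicsMatrix
from crlmkit.preprocess import normalize_log2_median
from crlmkit.signatures import (SignatureSet, _es_from_hits,
                                build_enriched_sets, preranked_gsea,
                                sample_signature_score,
                                score_stratified_survival)
from crlmkit.io import ClinicalRecord


def brute_force_es(scores, hit_mask, weight):
    """Independent oracle: explicit running-sum walk over the full list."""
    scores = np.asarray(scores, dtype=float)
    hit_mask = np.asarray(hit_mask, dtype=bool)
    n_miss = (~hit_mask).sum()
    if n_miss == 0:
        return 1.0
    w = np.abs(scores[hit_mask]) ** weight if weight != 0 else \
        np.ones(hit_mask.sum())
    total = w.sum() if w.sum() > 0 else float(len(w))
    if w.sum() == 0:
        w = np.ones(len(w))
    running = 0.0
    walk = []
    wi = 0
    for i in range(len(scores)):
        if hit_mask[i]:
            running += w[wi] / total
            wi += 1
        else:
            running -= 1.0 / n_miss
        walk.append(running)
    up, down = max(walk), min(walk)
    return up if up >= -down - 1e-12 else down  # positive wins exact ties


class TestEnrichmentScore:
    def test_hand_walk_example(self):
        # scores [4,3,2,1], hits at ranks 1 and 3, weight 1 -> ES = 2/3
        es, _ = _es_from_hits(np.array([4.0, 3.0, 2.0, 1.0]),
                              np.array([0, 2]), 1.0)
        assert es == pytest.approx(2 / 3)

    def test_single_top_hit_weight_zero(self):
        es, _ = _es_from_hits(np.array([4.0, 3.0, 2.0, 1.0]),
                              np.array([0]), 0.0)
        assert es == pytest.approx(1.0)

    def test_matches_walk_oracle_exhaustively(self):
        # all lists N <= 8, all non-trivial hit subsets, both weights
        rng = np.random.default_rng(0)
        for n in range(2, 9):
            scores = np.sort(rng.uniform(0.1, 5.0, n))[::-1]
            for r in range(1, n):
                for hits in itertools.combinations(range(n), r):
                    mask = np.zeros(n, bool)
                    mask[list(hits)] = True
                    for weight in (0.0, 1.0):
                        es, _ = _es_from_hits(scores, np.array(hits), weight)
                        assert es == pytest.approx(
                            brute_force_es(scores, mask, weight), abs=1e-12)

    def test_weight_zero_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(2)
        scores = np.sort(rng.uniform(0.5, 4.0, 8))[::-1]
        hits = np.array([1, 4, 6])
        es1, _ = _es_from_hits(scores, hits, 0.0)
        es2, _ = _es_from_hits(np.exp(scores), hits, 0.0)
        assert es1 == pytest.approx(es2)


class TestPrerankedGsea:
    def test_planted_up_set_significant(self):
        rng = np.random.default_rng(3)
        genes = [f"G{i}" for i in range(400)]
        metric = pd.Series(rng.normal(0, 1, 400), index=genes)
        metric.iloc[:25] += 2.0  # planted up-shifted set
        sets = GeneSetCollection({"UP": set(genes[:25]),
                                  "NULL": set(genes[200:225])})
        results = {r.set_name: r
                   for r in preranked_gsea(metric, sets, n_perm=500, seed=9)}
        assert results["UP"].nes > 0
        assert results["UP"].q < 0.05
        assert results["NULL"].q > 0.05

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        metric = pd.Series(rng.normal(size=100),
                           index=[f"G{i}" for i in range(100)])
        sets = GeneSetCollection({"S": set(metric.index[:10])})
        a = preranked_gsea(metric, sets, n_perm=100, seed=5)
        b = preranked_gsea(metric, sets, n_perm=100, seed=5)
        assert a[0].nes == b[0].nes and a[0].p == b[0].p

    def test_disjoint_set_skipped_with_warning(self):
        metric = pd.Series([1.0, 0.5], index=["G1", "G2"])
        sets = GeneSetCollection({"S": {"GX"}})
        with pytest.warns(UserWarning, match="skipped"):
            assert preranked_gsea(metric, sets, n_perm=10, seed=0) == []

    def test_nonfinite_metric_rejected(self):
        metric = pd.Series([1.0, np.nan], index=["G1", "G2"])
        with pytest.raises(ValueError, match="finite"):
            preranked_gsea(metric, GeneSetCollection({"S": {"G1"}}), seed=0)


class TestSignatureScore:
    def _matrix(self, rows, cols, vals):
        return OmicsMatrix("protein", pd.DataFrame(vals, index=rows,
                                                   columns=cols),
                           is_normalized=True)

    def test_median_of_members(self):
        m = self._matrix(["A", "B", "C"], ["S1"], [[1.0], [2.0], [9.0]])
        sig = SignatureSet("LM_enriched", {"A", "B", "C"})
        assert sample_signature_score(m, sig)["S1"] == 2.0

    def test_all_members_missing_scores_nan(self):
        m = self._matrix(["A", "B"], ["S1", "S2"],
                         [[1.0, np.nan], [2.0, np.nan]])
        sig = SignatureSet("LM_enriched", {"A", "B"})
        with pytest.warns(UserWarning, match="score set missing"):
            scores = sample_signature_score(m, sig)
        assert np.isnan(scores["S2"]) and scores["S1"] == 1.5

    def test_constant_shift_equivariance(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(10, 3))
        m1 = self._matrix([f"G{i}" for i in range(10)], list("abc"), vals)
        shifted = vals.copy()
        shifted[:, 1] += 2.5
        m2 = self._matrix([f"G{i}" for i in range(10)], list("abc"), shifted)
        sig = SignatureSet("s", {f"G{i}" for i in range(10)})
        s1 = sample_signature_score(m1, sig)
        s2 = sample_signature_score(m2, sig)
        assert s2["b"] - s1["b"] == pytest.approx(2.5)
        assert s2["a"] == pytest.approx(s1["a"])

    def test_empty_set_rejected(self, toy_matrix):
        with pytest.raises(ValueError, match="empty"):
            sample_signature_score(toy_matrix, SignatureSet("s", set()))


class TestScoreSurvival:
    def _clinical(self, times, events):
        return [ClinicalRecord(f"P{i}", f"P{i}_T", "T", t, e)
                for i, (t, e) in enumerate(zip(times, events))]

    def test_median_split_convention(self):
        clin = self._clinical([10, 20, 30, 40], [1, 1, 1, 1])
        scores = pd.Series([1.0, 2.0, 3.0, 4.0],
                           index=[f"P{i}_T" for i in range(4)])
        hi, lo, test = score_stratified_survival(scores, clin)
        # strata {1,2} / {3,4}: two subjects each
        assert hi.at_risk[0] == 2 and lo.at_risk[0] == 2

    def test_identical_survival_p_one(self):
        times = [10, 20, 10, 20]
        clin = self._clinical(times, [1, 1, 1, 1])
        scores = pd.Series([1.0, 1.0, 2.0, 2.0],
                           index=[f"P{i}_T" for i in range(4)])
        _, _, test = score_stratified_survival(scores, clin)
        assert test.p_value == pytest.approx(1.0)

    def test_degenerate_scores_rejected(self):
        clin = self._clinical([10, 20, 30, 40], [1, 1, 1, 1])
        scores = pd.Series([2.0] * 4, index=[f"P{i}_T" for i in range(4)])
        with pytest.raises(ValueError, match="degenerate"):
            score_stratified_survival(scores, clin)


class TestBuildEnrichedSets:
    def test_recovers_planted_blocks(self, bundle):
        prot = normalize_log2_median(
            bundle.matrices["protein"].drop_samples(bundle.irs_sample_ids))
        lm_sig, t_sig = build_enriched_sets(prot, bundle.clinical)
        planted_lm = set(bundle.truth.lm_enriched_genes)
        planted_t = set(bundle.truth.t_enriched_genes)
        recall = len(lm_sig.members & planted_lm) / len(planted_lm)
        # subtype-block genes also differ between LM and T (they shift only
        # in LM), so precision is measured against all truly shifted genes
        truly_up_in_lm = planted_lm | set(bundle.truth.metabolism_genes) | \
            set(bundle.truth.rna_function_genes)
        precision = len(lm_sig.members & truly_up_in_lm) / len(lm_sig.members)
        assert recall >= 0.9
        assert precision >= 0.9
        assert len(t_sig.members & planted_t) / len(planted_t) >= 0.9

    def test_exclusion_list_sets_flag(self, bundle):
        prot = normalize_log2_median(
            bundle.matrices["protein"].drop_samples(bundle.irs_sample_ids))
        target = bundle.truth.lm_enriched_genes[0]
        lm_sig, _ = build_enriched_sets(prot, bundle.clinical,
                                        exclude=[target])
        assert target not in lm_sig.members
        assert lm_sig.tissue_specific_removed

    def test_too_few_pairs_rejected(self, bundle):
        prot = normalize_log2_median(
            bundle.matrices["protein"].drop_samples(bundle.irs_sample_ids))
        clin = [r for r in bundle.clinical if r.patient_id in
                {"P01", "P02", "P03"}]
        with pytest.raises(ValueError, match="pairs"):
            build_enriched_sets(prot, clin)
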