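"""Metastasis signature sets, preranked GSEA, sample scoring, and
signature-stratified survival.

The LM-/T-enriched signature construction uses the paired LM-vs-T contrast:
BH q below a cut, fold change above a cut, and detection in at least half of
the pairs; membership direction follows the sign of the fold change.  The
preranked GSEA is the weighted Kolmogorov-Smirnov running-sum statistic with
gene-label permutation for NES and FDR, normalized separately for positive
and negative scores.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .differential import differential_table
from .io import ClinicalRecord, GeneSetCollection, OmicsMatrix
from .stats import SurvivalCurve, TestResult, km_curve, logrank_test, median_split

logger = logging.getLogger(__name__)


@dataclass
class SignatureSet:
    """Named signature set; may be empty after a null construction, in which
    case downstream scoring and GSEA reject it."""

    name: str
    members: Set[str]
    params: Dict = field(default_factory=dict)
    tissue_specific_removed: bool = False


@dataclass
class GseaResult:
    set_name: str
    es: float
    nes: float
    p: float
    q: float
    size: int
    leading_edge: List[str]


def build_enriched_sets(protein: OmicsMatrix,
                        clinical: Sequence[ClinicalRecord],
                        q_max: float = 0.05, min_fold_change: float = 1.5,
                        min_detect_frac: float = 0.5,
                        exclude: Optional[Iterable[str]] = None
                        ) -> Tuple[SignatureSet, SignatureSet]:
    """Paired LM-vs-T differential proteins split by direction into the
    LM-enriched and T-enriched signature sets."""
    by_patient: Dict[str, Dict[str, str]] = {}
    for r in clinical:
        if r.sample_id in protein.data.columns:
            by_patient.setdefault(r.patient_id, {})[r.tissue] = r.sample_id
    pairs = [(d["LM"], d["T"]) for d in by_patient.values()
             if "LM" in d and "T" in d]
    if len(pairs) < 5:
        raise ValueError(f"need >= 5 LM/T pairs, got {len(pairs)}")
    lm_ids = [p[0] for p in pairs]
    t_ids = [p[1] for p in pairs]
    records = differential_table(protein, lm_ids, t_ids, paired=True)
    min_l2 = math.log2(min_fold_change)
    min_pairs = min_detect_frac * len(pairs)
    excluded = set(exclude or [])
    lm_members, t_members = set(), set()
    removed = False
    for rec in records:
        if rec.q >= q_max or abs(rec.log2fc) <= min_l2 or rec.n1 < min_pairs:
            continue
        if rec.feature in excluded:
            removed = True
            continue
        (lm_members if rec.log2fc > 0 else t_members).add(rec.feature)
    params = {"q_max": q_max, "min_fold_change": min_fold_change,
              "min_detect_frac": min_detect_frac, "n_pairs": len(pairs)}
    logger.info("signature construction: %d LM-enriched, %d T-enriched proteins",
                len(lm_members), len(t_members))
    return (SignatureSet("LM_enriched", lm_members, params, removed),
            SignatureSet("T_enriched", t_members, params, removed))


# ---------------------------------------------------------------------------
# Preranked GSEA
# ---------------------------------------------------------------------------

def _es_from_hits(abs_scores: np.ndarray, hit_idx: np.ndarray,
                  weight: float) -> Tuple[float, int]:
    """Weighted KS enrichment score from sorted hit positions.

    Returns (ES, peak index into hit_idx) where the peak index locates the
    running-sum extremum for leading-edge extraction.
    """
    n = len(abs_scores)
    m = len(hit_idx)
    if m == n:
        return 1.0, m - 1
    w = abs_scores[hit_idx] ** weight if weight != 0 else np.ones(m)
    total = w.sum()
    if total == 0:  # all hit scores zero under positive weight
        w = np.ones(m)
        total = float(m)
    step_miss = 1.0 / (n - m)
    cumw = np.cumsum(w) / total
    miss_before = hit_idx - np.arange(m)
    after_hit = cumw - miss_before * step_miss
    before_hit = np.concatenate([[0.0], cumw[:-1]]) - miss_before * step_miss
    i_max = int(np.argmax(after_hit))
    i_min = int(np.argmin(before_hit))
    # positive extremum wins exact ties (tolerance absorbs float noise)
    if after_hit[i_max] >= -before_hit[i_min] - 1e-12:
        return float(after_hit[i_max]), i_max
    return float(before_hit[i_min]), i_min


def preranked_gsea(ranked: pd.Series, sets: GeneSetCollection,
                   n_perm: int = 1000, weight: float = 1.0,
                   seed: int = 0) -> List[GseaResult]:
    """Preranked gene set enrichment analysis.

    ``ranked`` maps gene id to a finite ranking metric (e.g. signed log2 fold
    change); genes are sorted descending with ties broken by id for
    determinism.  NES and FDR come from gene-label permutations, normalized
    separately for positive and negative scores (GSEA convention).
    """
    vals = ranked.to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("ranking metric must be finite for all genes")
    order = sorted(range(len(ranked)), key=lambda i: (-vals[i], ranked.index[i]))
    genes = np.asarray(ranked.index)[order]
    scores = vals[order]
    abs_scores = np.abs(scores)
    n = len(genes)
    pos = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng(seed)

    results = []
    null_nes_pool: List[np.ndarray] = []
    obs: List[Tuple[str, float, np.ndarray, np.ndarray]] = []
    for name in sets:
        members = [g for g in sets[name] if g in pos]
        if not members:
            warnings.warn(f"gene set {name!r} has no genes in the ranked list; "
                          "skipped", stacklevel=2)
            continue
        hit_idx = np.sort(np.array([pos[g] for g in members]))
        es, peak = _es_from_hits(abs_scores, hit_idx, weight)
        null = np.array([
            _es_from_hits(abs_scores,
                          np.sort(rng.choice(n, size=len(hit_idx), replace=False)),
                          weight)[0]
            for _ in range(n_perm)])
        # leading edge: hits at or before (after) the running-sum peak
        if es >= 0:
            le = [genes[i] for i in hit_idx[:peak + 1]]
        else:
            le = [genes[i] for i in hit_idx[peak:]]
        obs.append((name, es, null, np.array(le, dtype=object)))

    def _norm(es_val: float, null: np.ndarray) -> Tuple[float, float]:
        same = null[null >= 0] if es_val >= 0 else -null[null < 0]
        if len(same) == 0 or same.mean() == 0:
            return float("nan"), 1.0
        nes = abs(es_val) / same.mean() * (1 if es_val >= 0 else -1)
        p = (1 + np.sum(same >= abs(es_val))) / (1 + len(same))
        return float(nes), float(p)

    nes_obs: List[float] = []
    nominal_p: List[float] = []
    null_nes_all: List[float] = []
    for name, es, null, le in obs:
        nes, p = _norm(es, null)
        nes_obs.append(nes)
        nominal_p.append(p)
        for e in null:
            same = null[null >= 0] if e >= 0 else -null[null < 0]
            if len(same) and same.mean() != 0:
                null_nes_all.append(abs(e) / same.mean() * (1 if e >= 0 else -1))
    null_nes_arr = np.asarray(null_nes_all)
    nes_arr = np.asarray(nes_obs)

    for (name, es, null, le), nes, p in zip(obs, nes_obs, nominal_p):
        if np.isnan(nes):
            q = 1.0
        elif nes >= 0:
            num_pool = null_nes_arr[null_nes_arr >= 0]
            num = np.mean(num_pool >= nes) if len(num_pool) else 0.0
            den_pool = nes_arr[nes_arr >= 0]
            den = np.mean(den_pool >= nes) if len(den_pool) else 1.0
            q = min(1.0, num / den) if den > 0 else 1.0
        else:
            num_pool = null_nes_arr[null_nes_arr < 0]
            num = np.mean(num_pool <= nes) if len(num_pool) else 0.0
            den_pool = nes_arr[nes_arr < 0]
            den = np.mean(den_pool <= nes) if len(den_pool) else 1.0
            q = min(1.0, num / den) if den > 0 else 1.0
        results.append(GseaResult(set_name=name, es=es,
                                  nes=0.0 if np.isnan(nes) else nes,
                                  p=p, q=float(q),
                                  size=int(np.sum(np.isin(genes, list(sets[name])))),
                                  leading_edge=list(le)))
    return results


def gsea_results_frame(results: Sequence[GseaResult]) -> pd.DataFrame:
    rows = [{**r.__dict__, "leading_edge": ";".join(r.leading_edge)}
            for r in results]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Sample scoring and survival stratification
# ---------------------------------------------------------------------------

def sample_signature_score(matrix: OmicsMatrix, signature: SignatureSet,
                           min_quantified_frac: float = 0.5) -> pd.Series:
    """Per-sample median abundance over the signature members.

    Samples quantifying fewer than ``min_quantified_frac`` of the members get
    a missing score (with a warning)."""
    if not signature.members:
        raise ValueError("empty signature set")
    members = [m for m in signature.members if m in matrix.data.index]
    if not members:
        raise ValueError("no signature members present in the matrix")
    sub = matrix.data.loc[members]
    frac = sub.notna().mean(axis=0)
    scores = sub.median(axis=0, skipna=True)
    low = frac < min_quantified_frac
    if low.any():
        warnings.warn(f"{int(low.sum())} samples quantify < "
                      f"{min_quantified_frac:.0%} of signature members; "
                      "score set missing", stacklevel=2)
        scores[low] = np.nan
    scores.name = signature.name
    return scores


def score_stratified_survival(scores: pd.Series,
                              clinical: Sequence[ClinicalRecord],
                              ) -> Tuple[SurvivalCurve, SurvivalCurve, TestResult]:
    """Median-split the scores (ties to the low stratum), then Kaplan-Meier
    and log-rank between the high and low strata.

    One survival entry per patient: if several samples of a patient carry a
    score the first is used."""
    by_sample = {r.sample_id: r for r in clinical}
    seen_patients = set()
    vals, times, events = [], [], []
    for sid, score in scores.items():
        if sid not in by_sample or not np.isfinite(score):
            continue
        rec = by_sample[sid]
        if rec.patient_id in seen_patients:
            continue
        seen_patients.add(rec.patient_id)
        vals.append(float(score))
        times.append(rec.os_time)
        events.append(rec.os_event)
    if len(vals) < 4:
        raise ValueError("need >= 4 scored patients for stratified survival")
    vals = np.asarray(vals)
    high = median_split(vals)
    if high.sum() < 2 or (~high).sum() < 2:
        raise ValueError("degenerate split: fewer than 2 patients per stratum")
    times = np.asarray(times)
    events = np.asarray(events)
    curve_high = km_curve(times[high], events[high])
    curve_low = km_curve(times[~high], events[~high])
    test = logrank_test(times[high], events[high], times[~high], events[~high])
    return curve_high, curve_low, test
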