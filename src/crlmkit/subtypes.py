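"""Consensus-clustering subtype discovery with k selection and stability
reporting.

Samples are repeatedly subsampled without replacement, features z-scored, and
clustered with k-means; the consensus matrix entry (i, j) is the fraction of
co-sampled iterations in which i and j landed in the same cluster.  Final
labels per k come from average-linkage hierarchical clustering of
1 - consensus.  k is selected by the largest relative increase in the area
under the consensus CDF, with the proportion of ambiguous clustering (PAC)
reported as a secondary criterion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.cluster import AgglomerativeClustering, KMeans

from .io import OmicsMatrix
from .stats import fisher_exact_2x2, bh_adjust

logger = logging.getLogger(__name__)


@dataclass
class ConsensusResult:
    consensus: Dict[int, pd.DataFrame]
    labels: Dict[int, pd.Series]
    cdf_area: Dict[int, float]
    delta_area: Dict[int, float]
    pac: Dict[int, float]
    mean_within_consensus: Dict[int, float]
    params: Dict
    audit: Dict[int, List[Tuple[np.ndarray, np.ndarray]]]
    chosen_k: Optional[int] = None

    def __post_init__(self) -> None:
        for k, c in self.consensus.items():
            arr = c.to_numpy()
            if not np.allclose(arr, arr.T):
                raise AssertionError(f"consensus matrix for k={k} not symmetric")
            if np.any(arr < -1e-12) or np.any(arr > 1 + 1e-12):
                raise AssertionError(f"consensus entries for k={k} outside [0, 1]")


def _impute_zscore(matrix: OmicsMatrix, feature_ids: Sequence[str]) -> np.ndarray:
    """Samples x features array, feature-mean imputed (clustering only)."""
    sub = matrix.data.loc[list(feature_ids)]
    X = sub.to_numpy(dtype=float).T
    col_means = np.nanmean(X, axis=0)
    col_means = np.where(np.isfinite(col_means), col_means, 0.0)
    idx = np.where(np.isnan(X))
    X = X.copy()
    X[idx] = np.take(col_means, idx[1])
    return X


def consensus_cluster(matrix: OmicsMatrix, feature_ids: Sequence[str],
                      k_range: Sequence[int] = range(2, 7),
                      resample_frac: float = 0.8, n_iter: int = 250,
                      seed: int = 0, n_init: int = 10) -> ConsensusResult:
    """Resampled k-means consensus clustering over a feature selection."""
    k_range = sorted(set(int(k) for k in k_range))
    X = _impute_zscore(matrix, feature_ids)
    n = X.shape[0]
    if n < 2 * max(k_range):
        raise ValueError(f"need >= {2 * max(k_range)} samples for k up to "
                         f"{max(k_range)}, got {n}")
    rng = np.random.default_rng(seed)
    n_sub = max(max(k_range) + 1, int(round(resample_frac * n)))
    co_sampled = np.zeros((n, n))
    co_clustered = {k: np.zeros((n, n)) for k in k_range}
    audit: Dict[int, List[Tuple[np.ndarray, np.ndarray]]] = {k: [] for k in k_range}
    for _ in range(n_iter):
        idx = np.sort(rng.choice(n, size=n_sub, replace=False))
        Xs = X[idx]
        mu = Xs.mean(axis=0)
        sd = Xs.std(axis=0)
        sd[sd == 0] = 1.0
        Xz = (Xs - mu) / sd
        co_sampled[np.ix_(idx, idx)] += 1
        for k in k_range:
            km = KMeans(n_clusters=k, n_init=n_init,
                        random_state=int(rng.integers(2 ** 31)))
            lab = km.fit_predict(Xz)
            same = lab[:, None] == lab[None, :]
            co_clustered[k][np.ix_(idx, idx)] += same
            audit[k].append((idx.copy(), lab.copy()))

    sample_ids = matrix.data.columns
    consensus: Dict[int, pd.DataFrame] = {}
    labels: Dict[int, pd.Series] = {}
    cdf_area: Dict[int, float] = {}
    pac: Dict[int, float] = {}
    mwc: Dict[int, float] = {}
    with np.errstate(invalid="ignore", divide="ignore"):
        for k in k_range:
            C = np.where(co_sampled > 0, co_clustered[k] / co_sampled, 0.0)
            np.fill_diagonal(C, 1.0)
            C = (C + C.T) / 2.0
            consensus[k] = pd.DataFrame(C, index=sample_ids, columns=sample_ids)
            agg = AgglomerativeClustering(n_clusters=k, metric="precomputed",
                                          linkage="average")
            lab = agg.fit_predict(1.0 - C)
            labels[k] = pd.Series(lab, index=sample_ids, name=f"k{k}")
            iu = np.triu_indices(n, k=1)
            vals = np.sort(C[iu])
            # area under the empirical CDF of consensus entries over [0, 1]
            cdf_area[k] = float(np.mean(1.0 - vals))
            pac[k] = float(np.mean((vals > 0.1) & (vals < 0.9)))
            within = C[iu][lab[iu[0]] == lab[iu[1]]]
            mwc[k] = float(within.mean()) if len(within) else float("nan")
    delta: Dict[int, float] = {}
    prev = None
    for k in k_range:
        if prev is None:
            delta[k] = cdf_area[k]
        else:
            delta[k] = (cdf_area[k] - cdf_area[prev]) / cdf_area[prev] \
                if cdf_area[prev] > 0 else 0.0
        prev = k
    params = {"k_range": k_range, "resample_frac": resample_frac,
              "n_iter": n_iter, "seed": seed, "inner": "kmeans",
              "n_init": n_init, "n_features": len(list(feature_ids))}
    return ConsensusResult(consensus=consensus, labels=labels,
                           cdf_area=cdf_area, delta_area=delta, pac=pac,
                           mean_within_consensus=mwc, params=params,
                           audit=audit)


def select_k(result: ConsensusResult, override: Optional[int] = None
             ) -> Tuple[int, pd.DataFrame]:
    """Choose the k with the lowest proportion of ambiguous clustering (PAC),
    tie-broken by delta-area; an explicit override wins regardless.

    PAC is preferred over the raw delta-area maximum because the
    smallest-k convention (delta = area itself) systematically favors the
    first candidate even when a larger k is unambiguous."""
    ks = sorted(result.consensus)
    if len(ks) < 2 and override is None:
        raise ValueError("need >= 2 candidate k for selection")
    report = pd.DataFrame({
        "k": ks,
        "cdf_area": [result.cdf_area[k] for k in ks],
        "delta_area": [result.delta_area[k] for k in ks],
        "pac": [result.pac[k] for k in ks],
        "mean_within_consensus": [result.mean_within_consensus[k] for k in ks],
    })
    if override is not None:
        if override not in result.consensus:
            raise ValueError(f"override k={override} was not clustered")
        chosen = int(override)
    else:
        best = report.sort_values(["pac", "delta_area", "k"],
                                  ascending=[True, False, True],
                                  kind="stable").iloc[0]
        chosen = int(best["k"])
    result.chosen_k = chosen
    return chosen, report


def canonical_subtype_labels(labels: pd.Series, matrix: Optional[OmicsMatrix] = None,
                             metabolism_genes: Optional[Sequence[str]] = None
                             ) -> pd.Series:
    """Map integer cluster labels to C1..Ck.

    By default the largest cluster is C1; when a metabolism gene set and the
    clustered matrix are supplied, the cluster with the higher median
    metabolism-set score is named C1 instead (the metabolism-subtype
    convention)."""
    counts = labels.value_counts()
    order = list(counts.index)
    if matrix is not None and metabolism_genes:
        members = [g for g in metabolism_genes if g in matrix.data.index]
        if members:
            score = matrix.data.loc[members].median(axis=0, skipna=True)
            med = {c: float(score[labels.index[labels == c]].median())
                   for c in counts.index}
            order = sorted(counts.index, key=lambda c: -med[c])
    mapping = {c: f"C{i + 1}" for i, c in enumerate(order)}
    return labels.map(mapping)


def mutation_association(mutations: pd.DataFrame, subtype: pd.Series
                         ) -> pd.DataFrame:
    """Per-gene Fisher exact test of mutation frequency between two subtypes.

    ``subtype`` maps sample id -> C1/C2 over the mutation-matrix columns."""
    shared = [s for s in mutations.columns if s in subtype.index]
    labels = subtype[shared]
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ValueError(f"expected two subtypes, got {groups}")
    rows = []
    for gene in mutations.index:
        vals = mutations.loc[gene, shared]
        a = int(((vals == 1) & (labels == groups[0])).sum())
        b = int(((vals == 0) & (labels == groups[0])).sum())
        c = int(((vals == 1) & (labels == groups[1])).sum())
        d = int(((vals == 0) & (labels == groups[1])).sum())
        odds, p = fisher_exact_2x2([[a, b], [c, d]])
        rows.append({"gene": gene, f"freq_{groups[0]}": a / max(a + b, 1),
                     f"freq_{groups[1]}": c / max(c + d, 1),
                     "odds_ratio": odds, "p": p})
    df = pd.DataFrame(rows)
    if len(df):
        df["q"] = bh_adjust(df["p"].to_numpy())
    return df
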