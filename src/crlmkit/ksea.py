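"""Kinase-substrate enrichment analysis (KSEA).

Kinase activity is inferred from the aggregate fold change of a kinase's
annotated substrate phosphosites against all quantified sites:

    z = (mean_substrates - mean_background) * sqrt(m) / sd_background

with a two-sided normal p-value and BH adjustment across kinases.  Kinases
with fewer than ``min_substrates`` quantified substrates are excluded and
logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .differential import DiffRecord
from .io import ClinicalRecord, KinaseSubstrateMap, OmicsMatrix
from .stats import bh_adjust

logger = logging.getLogger(__name__)


@dataclass
class KinaseActivity:
    kinase: str
    z: float
    p: float
    q: float
    m: int                     # quantified substrates
    mean_substrate_log2fc: float
    direction: int


def ksea_scores(site_log2fc: pd.Series, ksmap: KinaseSubstrateMap,
                min_substrates: int = 3) -> List[KinaseActivity]:
    """Substrate-set z-scores for every kinase with enough quantified sites.

    ``site_log2fc`` maps phosphosite id to a finite contrast value; all
    quantified sites form the background (>= 20 required).
    """
    vals = site_log2fc.dropna()
    arr = vals.to_numpy(dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("contrast values must be finite")
    if len(arr) < 20:
        raise ValueError(f"need >= 20 quantified sites as background, got {len(arr)}")
    bg_mean = float(arr.mean())
    bg_sd = float(arr.std(ddof=1))
    if bg_sd == 0:
        raise ValueError("background standard deviation is zero")
    activities: List[KinaseActivity] = []
    pvals: List[float] = []
    n_excluded = 0
    for kinase in sorted(ksmap.substrates):
        sub_vals = vals.reindex(list(ksmap[kinase])).dropna()
        m = len(sub_vals)
        if m < min_substrates:
            n_excluded += 1
            continue
        sub_mean = float(sub_vals.mean())
        z = (sub_mean - bg_mean) * np.sqrt(m) / bg_sd
        p = 2.0 * sps.norm.sf(abs(z))
        activities.append(KinaseActivity(
            kinase=kinase, z=float(z), p=float(p), q=np.nan, m=m,
            mean_substrate_log2fc=sub_mean, direction=int(np.sign(z))))
        pvals.append(p)
    if n_excluded:
        logger.info("KSEA: excluded %d kinases with < %d quantified substrates",
                    n_excluded, min_substrates)
    for act, q in zip(activities, bh_adjust(np.array(pvals))):
        act.q = float(q)
    return activities


def activities_frame(activities: Sequence[KinaseActivity]) -> pd.DataFrame:
    return pd.DataFrame([a.__dict__ for a in activities])


def paired_site_contrast(phospho: OmicsMatrix,
                         clinical: Sequence[ClinicalRecord],
                         tissue1: str = "LM", tissue2: str = "T") -> pd.Series:
    """Per-site median of per-patient log2 differences (tissue1 - tissue2);
    the default contrast for paired LM-vs-T kinase activity."""
    by_patient: Dict[str, Dict[str, str]] = {}
    for r in clinical:
        if r.sample_id in phospho.data.columns:
            by_patient.setdefault(r.patient_id, {})[r.tissue] = r.sample_id
    pairs = [(d[tissue1], d[tissue2]) for d in by_patient.values()
             if tissue1 in d and tissue2 in d]
    if not pairs:
        raise ValueError(f"no patients with paired {tissue1}/{tissue2} samples")
    a = phospho.data[[p[0] for p in pairs]].to_numpy(dtype=float)
    b = phospho.data[[p[1] for p in pairs]].to_numpy(dtype=float)
    diffs = a - b
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN sites
        med = np.nanmedian(diffs, axis=1)
    return pd.Series(med, index=phospho.data.index)


def group_site_contrast(phospho: OmicsMatrix, group1: Sequence[str],
                        group2: Sequence[str],
                        min_per_group: int = 3) -> pd.Series:
    """Per-site unpaired group mean difference (group1 - group2); the default
    contrast for subtype (C1 vs C2) kinase activity."""
    x = phospho.data[list(group1)].to_numpy(dtype=float)
    y = phospho.data[list(group2)].to_numpy(dtype=float)
    nx = np.isfinite(x).sum(axis=1)
    ny = np.isfinite(y).sum(axis=1)
    with np.errstate(invalid="ignore"):
        diff = np.nanmean(x, axis=1) - np.nanmean(y, axis=1)
    diff[(nx < min_per_group) | (ny < min_per_group)] = np.nan
    return pd.Series(diff, index=phospho.data.index)


def substrate_annotation(activities: Sequence[KinaseActivity],
                         ksmap: KinaseSubstrateMap,
                         site_records: Sequence[DiffRecord],
                         alpha: float = 0.05) -> pd.DataFrame:
    """Evidence table: per significant kinase, its quantified substrates with
    site-level effect sizes; substrates absent from the differential records
    appear with a missing effect and a flag."""
    by_site = {r.feature: r for r in site_records}
    rows = []
    for act in activities:
        if act.p >= alpha:
            continue
        for site in sorted(ksmap[act.kinase]):
            rec = by_site.get(site)
            rows.append({
                "kinase": act.kinase, "kinase_z": act.z, "site": site,
                "site_log2fc": rec.log2fc if rec else np.nan,
                "site_q": rec.q if rec else np.nan,
                "missing_from_diff": rec is None})
    return pd.DataFrame(rows, columns=["kinase", "kinase_z", "site",
                                       "site_log2fc", "site_q",
                                       "missing_from_diff"])
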