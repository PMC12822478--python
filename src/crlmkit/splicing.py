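"""Downstream analysis of externally produced alternative-splicing tables:
event filtering, per-event survival association, and splicing-factor /
event correlation networks.

PSI computation itself (rMATS) is out of scope; the module consumes an
rMATS-like TSV with a strict schema and applies the standard downstream
filters (FDR < 0.05 and |IncLevelDifference| > 0.1, both strict).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .io import ASEventTable, ClinicalRecord, OmicsMatrix
from .stats import bh_adjust, km_curve, logrank_test, median_split, spearman_corr

logger = logging.getLogger(__name__)


@dataclass
class FactorEventEdge:
    factor: str
    event_id: str
    rho: float
    p: float
    q: float
    sign: int


def filter_as_events(table: ASEventTable, fdr_max: float = 0.05,
                     min_abs_delta: float = 0.1) -> ASEventTable:
    """Events with fdr < fdr_max and |inc_level_difference| > min_abs_delta."""
    keep = (table.events["fdr"] < fdr_max) & \
           (table.events["inc_level_difference"].abs() > min_abs_delta)
    return ASEventTable(events=table.events.loc[keep],
                        psi=table.psi.loc[keep])


def as_survival_scan(table: ASEventTable,
                     clinical: Sequence[ClinicalRecord],
                     min_psi_frac: float = 0.8,
                     alpha: float = 0.05) -> pd.DataFrame:
    """Median-PSI split Kaplan-Meier / log-rank per event.

    Direction: ``good`` when the high-PSI stratum has the longer median
    survival, ``poor`` otherwise; ``ns`` above the significance level.
    Constant-PSI or under-quantified events are skipped and logged.
    """
    surv = {r.sample_id: (r.os_time, r.os_event) for r in clinical}
    shared = [s for s in table.psi.columns if s in surv]
    rows = []
    n_skipped = 0
    for event_id in table.event_ids:
        psi = table.psi.loc[event_id, shared].to_numpy(dtype=float)
        ok = np.isfinite(psi)
        if ok.mean() < min_psi_frac or ok.sum() < 6:
            n_skipped += 1
            continue
        vals = psi[ok]
        times = np.array([surv[s][0] for s, o in zip(shared, ok) if o])
        events = np.array([surv[s][1] for s, o in zip(shared, ok) if o])
        try:
            high = median_split(vals)
        except ValueError:
            n_skipped += 1
            continue
        if high.sum() < 2 or (~high).sum() < 2:
            n_skipped += 1
            continue
        res = logrank_test(times[high], events[high], times[~high], events[~high])
        med_high = km_curve(times[high], events[high]).median_survival()
        med_low = km_curve(times[~high], events[~high]).median_survival()
        if res.p_value >= alpha:
            direction = "ns"
        else:
            direction = "good" if med_high > med_low else "poor"
        rows.append({"event_id": event_id, "logrank_p": res.p_value,
                     "median_os_high": med_high, "median_os_low": med_low,
                     "direction": direction})
    if n_skipped:
        logger.info("AS survival scan: skipped %d events (constant or "
                    "under-quantified PSI)", n_skipped)
    return pd.DataFrame(rows, columns=["event_id", "logrank_p",
                                       "median_os_high", "median_os_low",
                                       "direction"])


def survival_direction_counts(scan: pd.DataFrame) -> Dict[str, int]:
    counts = {"good": 0, "poor": 0, "ns": 0}
    for d in scan.get("direction", []):
        counts[d] = counts.get(d, 0) + 1
    return counts


def factor_event_network(factor_proteins: OmicsMatrix,
                         table: ASEventTable, alpha: float = 0.05,
                         min_pairs: int = 4) -> List[FactorEventEdge]:
    """All factor x event Spearman correlations over shared samples, BH across
    the full grid; edges with q < alpha retained with their sign."""
    shared = [s for s in factor_proteins.data.columns if s in table.psi.columns]
    raw: List[Tuple[str, str, float, float]] = []
    n_skipped = 0
    for factor in factor_proteins.data.index:
        fvals = factor_proteins.data.loc[factor, shared].to_numpy(dtype=float)
        for event_id in table.event_ids:
            psi = table.psi.loc[event_id, shared].to_numpy(dtype=float)
            ok = np.isfinite(fvals) & np.isfinite(psi)
            if ok.sum() < min_pairs:
                n_skipped += 1
                continue
            rho, p = spearman_corr(fvals[ok], psi[ok])
            if not np.isfinite(rho):
                n_skipped += 1
                continue
            raw.append((factor, event_id, rho, p))
    if n_skipped:
        logger.info("factor-event network: skipped %d pairs (<%d shared "
                    "samples or constant)", n_skipped, min_pairs)
    if not raw:
        return []
    qvals = bh_adjust(np.array([r[3] for r in raw]))
    return [FactorEventEdge(factor=f, event_id=e, rho=rho, p=p, q=float(q),
                            sign=int(np.sign(rho)))
            for (f, e, rho, p), q in zip(raw, qvals) if q < alpha]


def edges_frame(edges: Sequence[FactorEventEdge]) -> pd.DataFrame:
    return pd.DataFrame([e.__dict__ for e in edges],
                        columns=["factor", "event_id", "rho", "p", "q", "sign"])
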