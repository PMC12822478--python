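"""Layer-aware differential testing and over-representation analysis.

Group contrasts use the Wilcoxon rank-sum test (unpaired) or the signed-rank
test on per-patient differences (paired).  Fold change is the difference of
group means on the log2 scale.  The layer threshold policy mirrors common
practice for paired tumor cohorts: fold-change cut 1.5 for mRNA and
phosphosites, 1.2 for proteins, with raw p < 0.05 (q is reported alongside
for downstream use).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .io import GeneSetCollection, OmicsMatrix
from .stats import (bh_adjust, hypergeom_enrich, wilcoxon_rank_sum,
                    wilcoxon_signed_rank)

logger = logging.getLogger(__name__)


@dataclass
class DiffRecord:
    feature: str
    layer: str
    log2fc: float     # group1 minus group2 mean of log2 values
    p: float
    q: float
    direction: int    # sign(log2fc)
    n1: int
    n2: int
    paired: bool


@dataclass
class ThresholdPolicy:
    """Per-layer (min fold change, max p) differential filters."""

    thresholds: Dict[str, Tuple[float, float]] = field(default_factory=lambda: {
        "mrna": (1.5, 0.05),
        "protein": (1.2, 0.05),
        "phosphosite": (1.5, 0.05),
    })

    def __post_init__(self) -> None:
        for layer, (fc, p) in self.thresholds.items():
            if fc <= 1:
                raise ValueError(f"{layer}: fold-change threshold must be > 1")
            if not 0 < p <= 1:
                raise ValueError(f"{layer}: p threshold must be in (0, 1]")

    def for_layer(self, layer: str) -> Tuple[float, float]:
        if layer not in self.thresholds:
            raise KeyError(f"no thresholds for layer {layer!r}")
        return self.thresholds[layer]


def differential_table(matrix: OmicsMatrix, group1: Sequence[str],
                       group2: Sequence[str], paired: bool = False,
                       min_per_group: int = 3) -> List[DiffRecord]:
    """Per-feature contrast of two disjoint sample groups.

    Paired mode matches ``group1[i]`` to ``group2[i]`` (same patient order)
    and tests per-patient differences with the signed-rank test.  Features
    with fewer than ``min_per_group`` observed values per group (or fewer
    complete pairs in paired mode) are skipped and logged.
    """
    g1, g2 = list(group1), list(group2)
    if not g1 or not g2:
        raise ValueError("both groups must be non-empty")
    if set(g1) & set(g2):
        raise ValueError("groups must be disjoint")
    if paired and len(g1) != len(g2):
        raise ValueError("paired mode requires equal-length, patient-matched groups")
    x_all = matrix.data[g1].to_numpy(dtype=float)
    y_all = matrix.data[g2].to_numpy(dtype=float)
    records: List[DiffRecord] = []
    pvals: List[float] = []
    n_skipped = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # degenerate-feature warnings are logged
        for i, feature in enumerate(matrix.data.index):
            x = x_all[i]
            y = y_all[i]
            if paired:
                ok = np.isfinite(x) & np.isfinite(y)
                if ok.sum() < min_per_group:
                    n_skipped += 1
                    continue
                diffs = x[ok] - y[ok]
                res = wilcoxon_signed_rank(diffs)
                log2fc = float(np.mean(diffs))
                n1 = n2 = int(ok.sum())
            else:
                xv, yv = x[np.isfinite(x)], y[np.isfinite(y)]
                if len(xv) < min_per_group or len(yv) < min_per_group:
                    n_skipped += 1
                    continue
                res = wilcoxon_rank_sum(xv, yv)
                log2fc = float(xv.mean() - yv.mean())
                n1, n2 = len(xv), len(yv)
            records.append(DiffRecord(
                feature=feature, layer=matrix.layer, log2fc=log2fc,
                p=res.p_value, q=np.nan, direction=int(np.sign(log2fc)),
                n1=n1, n2=n2, paired=paired))
            pvals.append(res.p_value)
    if n_skipped:
        logger.info("differential (%s): skipped %d features with < %d values "
                    "per group", matrix.layer, n_skipped, min_per_group)
    if records:
        for rec, q in zip(records, bh_adjust(np.array(pvals))):
            rec.q = float(q)
    return records


def diff_records_frame(records: Sequence[DiffRecord]) -> pd.DataFrame:
    cols = ["feature", "layer", "log2fc", "p", "q", "direction",
            "n1", "n2", "paired"]
    return pd.DataFrame([r.__dict__ for r in records], columns=cols)


def layer_threshold_filter(records: Sequence[DiffRecord],
                           policy: Optional[ThresholdPolicy] = None
                           ) -> List[DiffRecord]:
    """Keep records with |fold change| strictly above the layer cut and raw
    p strictly below the layer p threshold."""
    policy = policy or ThresholdPolicy()
    out = []
    for r in records:
        fc_min, p_max = policy.for_layer(r.layer)
        if 2.0 ** abs(r.log2fc) > fc_min and r.p < p_max:
            out.append(r)
    return out


def pathway_ora(selected: Sequence[str], universe: Sequence[str],
                sets: GeneSetCollection, alpha: float = 0.05) -> pd.DataFrame:
    """Hypergeometric over-representation of each set in the selection.

    The universe is the quantified-feature background (not the genome); the
    selection must be a subset of it.  Sets are intersected with the universe
    before testing; BH across sets.
    """
    uni = set(universe)
    sel = set(selected)
    offenders = sorted(sel - uni)
    if offenders:
        raise ValueError(f"selected features outside universe: {offenders[:5]}")
    rows = []
    for name in sets:
        members = sets[name] & uni
        if not members:
            continue
        overlap = len(members & sel)
        p = 1.0 if overlap == 0 else hypergeom_enrich(
            overlap, len(members), len(sel), len(uni))
        rows.append({"set": name, "set_size": len(members), "overlap": overlap,
                     "p": p})
    df = pd.DataFrame(rows, columns=["set", "set_size", "overlap", "p"])
    if len(df):
        df["q"] = bh_adjust(df["p"].to_numpy())
        df["significant"] = df["q"] < alpha
        df = df.sort_values("p", kind="stable").reset_index(drop=True)
    else:
        df["q"] = []
        df["significant"] = []
    return df
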