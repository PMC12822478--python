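"""Per-gene SCNA cis-effect scans and multi-layer significance classification.

A cis effect is the Spearman correlation of a gene's copy-number value with
its own abundance at a given omics layer, computed over a tissue subset and
FDR-controlled within each layer.  Phosphosites are mapped to their parent
gene; the gene-level record carries the most significant site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .io import OmicsMatrix, site_to_gene
from .stats import bh_adjust, spearman_corr

logger = logging.getLogger(__name__)


@dataclass
class CisRecord:
    gene: str
    layer: str
    rho: float
    p: float
    q: float
    n_pairs: int
    significant: bool
    site: Optional[str] = None  # best site for the phosphosite layer


def cis_correlation_scan(cnv: OmicsMatrix, layer_matrix: OmicsMatrix,
                         sample_ids: Sequence[str], min_pairs: int = 10,
                         alpha: float = 0.05) -> List[CisRecord]:
    """Spearman(CNV, layer) per gene over a tissue subset; BH within layer.

    Genes with fewer than ``min_pairs`` complete pairs, or a constant vector,
    are skipped and counted in the log.  For the phosphosite layer every site
    is tested and the gene record keeps the smallest-p site.
    """
    shared = [s for s in sample_ids
              if s in cnv.data.columns and s in layer_matrix.data.columns]
    if len(shared) < min_pairs:
        raise ValueError(
            f"only {len(shared)} shared samples; need >= {min_pairs}")
    is_site_layer = layer_matrix.layer == "phosphosite"
    cnv_sub = cnv.data[shared]
    lay_sub = layer_matrix.data[shared]

    rows: List[Tuple[str, Optional[str], float, float, int]] = []
    n_skipped = 0
    for fid in lay_sub.index:
        gene = site_to_gene(fid) if is_site_layer else fid
        if gene not in cnv_sub.index:
            continue
        x = cnv_sub.loc[gene].to_numpy(dtype=float)
        y = lay_sub.loc[fid].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < min_pairs:
            n_skipped += 1
            continue
        rho, p = spearman_corr(x[ok], y[ok])
        if not np.isfinite(rho):  # constant CNV or abundance
            n_skipped += 1
            continue
        rows.append((gene, fid if is_site_layer else None, rho, p, int(ok.sum())))
    if n_skipped:
        logger.info("cis scan (%s): skipped %d features (<%d pairs or constant)",
                    layer_matrix.layer, n_skipped, min_pairs)
    if not rows:
        return []

    # aggregate phosphosites per gene by the most significant site
    if is_site_layer:
        best: Dict[str, Tuple[str, Optional[str], float, float, int]] = {}
        for row in rows:
            gene = row[0]
            if gene not in best or row[3] < best[gene][3]:
                best[gene] = row
        rows = list(best.values())

    pvals = np.array([r[3] for r in rows])
    qvals = bh_adjust(pvals)
    return [CisRecord(gene=g, layer=layer_matrix.layer, rho=rho, p=p,
                      q=float(q), n_pairs=n, significant=bool(q < alpha),
                      site=site)
            for (g, site, rho, p, n), q in zip(rows, qvals)]


def cis_records_frame(records: Sequence[CisRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


_LAYER_ORDER = ("mrna", "protein", "phosphosite")


def classify_cis_venn(records_by_layer: Dict[str, Sequence[CisRecord]],
                      cag_list: Optional[Sequence[str]] = None
                      ) -> pd.DataFrame:
    """Per-gene significance pattern across the three expression layers.

    Categories: ``mrna_only``, ``mrna+protein``, ``all_three``, every other
    combination, and ``none``.  The returned frame also flags membership in a
    user-supplied cancer-associated-gene list.
    """
    sig: Dict[str, set] = {}
    genes: set = set()
    for layer in _LAYER_ORDER:
        recs = records_by_layer.get(layer, [])
        sig[layer] = {r.gene for r in recs if r.significant}
        genes |= {r.gene for r in recs}
    cag = set(cag_list or [])
    rows = []
    for g in sorted(genes):
        pattern = [layer for layer in _LAYER_ORDER if g in sig[layer]]
        if not pattern:
            category = "none"
        elif len(pattern) == 3:
            category = "all_three"
        elif pattern == ["mrna"]:
            category = "mrna_only"
        else:
            category = "+".join(pattern)
        rows.append({"gene": g, "category": category, "is_cag": g in cag})
    df = pd.DataFrame(rows, columns=["gene", "category", "is_cag"])
    return df


def venn_counts(venn: pd.DataFrame) -> pd.DataFrame:
    """Counts per category with the cancer-associated-gene overlap."""
    if venn.empty:
        return pd.DataFrame(columns=["category", "n_genes", "n_cag"])
    grouped = venn.groupby("category").agg(
        n_genes=("gene", "size"), n_cag=("is_cag", "sum")).reset_index()
    return grouped
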