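"""Normalization, missingness filtering, variance selection, ordination, and
internal-reference-sample (IRS) reproducibility QC.

The normalization contract mirrors standard TMT practice: log2 transform of
positive raw intensities followed by per-sample median subtraction over the
non-missing values.  Statistical tests downstream never see imputed values;
mean imputation is confined to ordination and clustering.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .io import OmicsMatrix, ValidationError
from .stats import spearman_corr

logger = logging.getLogger(__name__)


@dataclass
class QCReport:
    """Per-layer QC artifacts: medians, missingness, IRS agreement, PCA."""

    median_before: pd.Series
    median_after: pd.Series
    missing_fraction: float
    irs_spearman: Optional[pd.DataFrame] = None
    pca_coordinates: Optional[pd.DataFrame] = None
    pca_variance_explained: Optional[np.ndarray] = None


def normalize_log2_median(m: OmicsMatrix) -> OmicsMatrix:
    """Log2 transform (if raw) then subtract each sample's median.

    Idempotent: a matrix already flagged normalized is returned unchanged.
    Raises on nonpositive raw intensities or an all-missing sample column.
    """
    if m.is_normalized:
        return m
    data = m.data.copy()
    if not m.log2_scale:
        bad = (data <= 0)
        if bad.any().any():
            col = bad.any(axis=0).idxmax()
            row = bad[col].idxmax()
            raise ValidationError(
                f"nonpositive raw intensity at feature {row!r}, sample {col!r}")
        data = np.log2(data)
    all_missing = data.isna().all(axis=0)
    if all_missing.any():
        raise ValidationError(
            f"all-missing sample column(s): {list(data.columns[all_missing])[:5]}")
    medians = data.median(axis=0, skipna=True)
    data = data.sub(medians, axis=1)
    return OmicsMatrix(m.layer, data, is_normalized=True, log2_scale=True)


def filter_by_missingness(m: OmicsMatrix, max_missing_frac: float,
                          groups: Optional[Dict[str, Sequence[str]]] = None
                          ) -> OmicsMatrix:
    """Keep features whose missing fraction is strictly below the threshold.

    With ``groups`` (name -> sample ids) the criterion must hold within every
    group; otherwise it is evaluated across all samples.  Samples are never
    removed and feature order is preserved.
    """
    if not 0 <= max_missing_frac <= 1:
        raise ValueError("max_missing_frac must lie in [0, 1]")
    if max_missing_frac == 1.0:
        return m
    if groups:
        keep = pd.Series(True, index=m.data.index)
        for name, samples in groups.items():
            frac = m.data.loc[:, list(samples)].isna().mean(axis=1)
            keep &= frac < max_missing_frac
    else:
        keep = m.data.isna().mean(axis=1) < max_missing_frac
    dropped = int((~keep).sum())
    if dropped:
        logger.info("missingness filter (<%g): dropped %d / %d features",
                    max_missing_frac, dropped, len(keep))
    return OmicsMatrix(m.layer, m.data.loc[keep], m.is_normalized, m.log2_scale)


def mad_select(m: OmicsMatrix, mad_threshold: float,
               min_values: int = 3) -> List[str]:
    """Feature ids with raw median-absolute-deviation strictly above threshold.

    The MAD carries no 1.4826 consistency constant ("MAD > 1" is a bare cut on
    log2 data).  Features with fewer than ``min_values`` observed values are
    excluded with a warning.
    """
    counts = m.data.notna().sum(axis=1)
    too_few = counts < min_values
    if too_few.any():
        warnings.warn(
            f"{int(too_few.sum())} features with < {min_values} observed values "
            "excluded from MAD selection", stacklevel=2)
    usable = m.data.loc[~too_few]
    med = usable.median(axis=1, skipna=True)
    mad = (usable.sub(med, axis=0)).abs().median(axis=1, skipna=True)
    return list(usable.index[mad > mad_threshold])


def pca_embed(m: OmicsMatrix, n_components: int = 2):
    """Centered PCA of samples (features mean-imputed for ordination only).

    Component signs follow the largest-loading-positive convention so repeat
    runs are identical.  Returns (coordinates DataFrame samples x PCs,
    variance-explained fractions).
    """
    n_samples = m.data.shape[1]
    if n_components > min(m.data.shape):
        raise ValueError(
            f"n_components={n_components} exceeds matrix rank bound {min(m.data.shape)}")
    X = m.data.to_numpy(dtype=float).T  # samples x features
    col_means = np.nanmean(X, axis=0)
    col_means = np.where(np.isfinite(col_means), col_means, 0.0)
    inds = np.where(np.isnan(X))
    X = X.copy()
    X[inds] = np.take(col_means, inds[1])
    pca = PCA(n_components=n_components, svd_solver="full")
    with np.errstate(invalid="ignore"):
        coords = pca.fit_transform(X)
    var_ratio = np.nan_to_num(pca.explained_variance_ratio_, nan=0.0)
    # deterministic sign: the loading with largest magnitude is positive
    for j in range(n_components):
        comp = pca.components_[j]
        if comp[np.argmax(np.abs(comp))] < 0:
            coords[:, j] *= -1
    cols = [f"PC{j + 1}" for j in range(n_components)]
    return (pd.DataFrame(coords, index=m.data.columns, columns=cols),
            var_ratio)


def irs_reproducibility(m: OmicsMatrix, irs_sample_ids: Sequence[str]
                        ) -> pd.DataFrame:
    """Pairwise Spearman correlation of internal-reference replicate columns
    over mutually non-missing features."""
    irs = list(irs_sample_ids)
    if len(irs) < 2:
        raise ValueError("need >= 2 IRS columns")
    unknown = [s for s in irs if s not in m.data.columns]
    if unknown:
        raise ValidationError(f"unknown IRS sample ids: {unknown}")
    out = pd.DataFrame(np.eye(len(irs)), index=irs, columns=irs)
    for i in range(len(irs)):
        for j in range(i + 1, len(irs)):
            rho, _ = spearman_corr(m.data[irs[i]], m.data[irs[j]])
            out.iloc[i, j] = out.iloc[j, i] = rho
    return out


def qc_report(m: OmicsMatrix, irs_sample_ids: Optional[Sequence[str]] = None,
              n_components: int = 2) -> QCReport:
    """Normalization medians, missingness, IRS agreement, and PCA in one pass."""
    before = m.data.median(axis=0, skipna=True)
    norm = normalize_log2_median(m)
    after = norm.data.median(axis=0, skipna=True)
    irs = None
    analysis = norm
    if irs_sample_ids:
        irs = irs_reproducibility(norm, irs_sample_ids)
        analysis = norm.drop_samples(irs_sample_ids)
    coords, var = pca_embed(analysis, n_components=n_components)
    return QCReport(median_before=before, median_after=after,
                    missing_fraction=analysis.missing_fraction(),
                    irs_spearman=irs, pca_coordinates=coords,
                    pca_variance_explained=var)
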