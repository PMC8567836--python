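"""Individual similarity-network construction.

A subject's network has one node per atlas region and, as the edge between
two regions, the Pearson correlation between their (min-max normalized)
radiomics feature vectors. Cohorts of networks are summarized entrywise by
their mean and standard deviation.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np

from .features import FeatureCatalog
from .types import RegionFeatureTable, SimilarityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "minmax_normalize",
    "remove_redundant_features",
    "build_r2sn",
    "aggregate_networks",
    "rowwise_correlation",
]


def minmax_normalize(t: RegionFeatureTable) -> RegionFeatureTable:
    """Rescale each feature column to [0, 1] across the subject's regions.

    A constant column carries no regional contrast; it is mapped to 0.5
    with a warning rather than dividing by zero.
    """
    m = t.matrix
    lo = m.min(axis=0)
    hi = m.max(axis=0)
    span = hi - lo
    const = span == 0
    if const.any():
        names = [t.feature_ids[k] for k in np.nonzero(const)[0]]
        warnings.warn(f"constant feature column(s) mapped to 0.5: {names}",
                      stacklevel=2)
    span_safe = np.where(const, 1.0, span)
    out = (m - lo) / span_safe
    out[:, const] = 0.5
    return RegionFeatureTable(out, t.region_labels, t.feature_ids,
                              subject_id=t.subject_id, flags=dict(t.flags))


def remove_redundant_features(
    tables: list[RegionFeatureTable],
    threshold: float = 0.9,
) -> FeatureCatalog:
    """Drop features highly correlated (|R| > threshold) with kept ones.

    All (region, subject) rows are pooled; features are scanned greedily in
    catalog order and a feature is dropped as soon as its absolute Pearson
    correlation with an already-kept feature exceeds the threshold, which
    makes the result deterministic. Constant columns are dropped with a
    warning.
    """
    if not tables:
        raise ValueError("no tables given")
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    feature_ids = tables[0].feature_ids
    if len(feature_ids) < 2:
        raise ValueError("need at least 2 features")
    for t in tables[1:]:
        if t.feature_ids != feature_ids:
            raise ValueError("tables disagree on feature columns")
    pooled = np.vstack([t.matrix for t in tables])
    stds = pooled.std(axis=0)
    kept: list[int] = []
    for k, fid in enumerate(feature_ids):
        if stds[k] == 0:
            warnings.warn(f"constant feature column dropped: {fid}", stacklevel=2)
            continue
        drop = False
        for j in kept:
            r = np.corrcoef(pooled[:, k], pooled[:, j])[0, 1]
            if abs(r) > threshold:
                drop = True
                break
        if not drop:
            kept.append(k)
    return FeatureCatalog([feature_ids[k] for k in kept], name="reduced")


def rowwise_correlation(matrix: np.ndarray) -> np.ndarray:
    """Pearson correlation between every pair of rows, unit diagonal.

    Shared correlation kernel for radiomics- and gene-based networks.
    Raises if any row is constant (correlation undefined), naming the rows.
    """
    matrix = np.asarray(matrix, dtype=float)
    bad = np.nonzero(matrix.max(axis=1) == matrix.min(axis=1))[0]
    if bad.size:
        raise ValueError(f"constant profile for row index(es) {bad.tolist()}; "
                         "Pearson correlation undefined")
    c = np.corrcoef(matrix)
    np.fill_diagonal(c, 1.0)
    return np.clip((c + c.T) / 2.0, -1.0, 1.0)


def build_r2sn(t: RegionFeatureTable, kind: str = "R2SN") -> SimilarityMatrix:
    """Interregional Pearson-correlation network from a feature table.

    The table should already be min-max normalized (the correlation itself
    is invariant to affine rescaling of a region's full vector, but the
    normalization determines how features are weighted against each other).
    """
    if t.n_features < 3:
        raise ValueError("need at least 3 features per region")
    try:
        c = rowwise_correlation(t.matrix)
    except ValueError as e:
        raise ValueError(f"subject {t.subject_id!r}: {e}") from e
    return SimilarityMatrix(c, t.region_labels, kind=kind, subject_id=t.subject_id)


def aggregate_networks(nets: list[SimilarityMatrix], mode: str = "mean") -> SimilarityMatrix:
    """Entrywise mean or standard deviation (N-1) across subjects."""
    if not nets:
        raise ValueError("no networks given")
    labels = nets[0].region_labels
    for n in nets[1:]:
        if not np.array_equal(n.region_labels, labels):
            raise ValueError("networks disagree on region set")
    stack = np.stack([n.matrix for n in nets])
    if mode == "mean":
        out = stack.mean(axis=0)
    elif mode == "std":
        if len(nets) < 2:
            raise ValueError("std aggregation needs at least 2 subjects")
        out = stack.std(axis=0, ddof=1)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    out = (out + out.T) / 2.0
    return SimilarityMatrix(out, labels, kind=nets[0].kind, subject_id=mode)
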