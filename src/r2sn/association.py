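"""Gene-expression and behavioral associations of similarity networks.

A gene similarity network (GSN) correlates regional gene-expression
profiles exactly as the radiomics network correlates regional feature
profiles (one shared Pearson kernel). Network-to-network similarity is
assessed edge-wise, optionally adjusting both edge vectors for the
Euclidean distance between region centroids (a proxy for spatial
autocorrelation), and node-wise through mean connective strength.
Behavioral scores are related to individual networks edge-by-edge, and to
nodal graph metrics node-by-node, with Bonferroni control of the
family-wise error rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .graph import GraphMetricsRecord
from .network import rowwise_correlation
from .types import LabeledVolume, SimilarityMatrix, edge_vector

__all__ = [
    "GeneExpressionTable",
    "AssociationResult",
    "build_gsn",
    "region_centroids",
    "distance_matrix",
    "edge_correlation_with_covariate",
    "node_strength_correlation",
    "edge_score_association",
    "node_metric_score_association",
    "NODE_METRICS",
]


@dataclass
class GeneExpressionTable:
    """Region x gene expression values aligned to the atlas regions."""

    matrix: np.ndarray
    region_labels: np.ndarray
    gene_ids: list[str]
    excluded_regions: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.region_labels = np.asarray(self.region_labels)
        if self.matrix.shape[0] != len(self.region_labels):
            raise ValueError("row count must match region count")
        if self.matrix.shape[1] != len(self.gene_ids):
            raise ValueError("column count must match gene count")


@dataclass
class AssociationResult:
    """Per-test correlations with raw and Bonferroni-corrected p values."""

    r: np.ndarray
    p_raw: np.ndarray
    p_corrected: np.ndarray
    significant: np.ndarray
    n_tests: int
    alpha: float
    labels: np.ndarray | None = None
    flagged: np.ndarray | None = None

    @property
    def n_significant(self) -> int:
        return int(self.significant.sum())


def build_gsn(g: GeneExpressionTable) -> SimilarityMatrix:
    """Region x region Pearson correlation of gene-expression profiles."""
    if g.matrix.shape[1] < 3:
        raise ValueError("need at least 3 genes")
    try:
        c = rowwise_correlation(g.matrix)
    except ValueError as e:
        bad = [int(g.region_labels[i])
               for i in range(len(g.region_labels))
               if np.std(g.matrix[i]) == 0]
        raise ValueError(f"constant expression profile for region(s) {bad}") from e
    return SimilarityMatrix(c, g.region_labels, kind="GSN", subject_id="")


def region_centroids(vol: LabeledVolume) -> dict[int, np.ndarray]:
    """World-space (mm) centroid of every region: affine @ mean voxel index."""
    out = {}
    for lab in vol.region_labels:
        idx = np.argwhere(vol.labels == lab)
        c_vox = idx.mean(axis=0)
        c_world = vol.affine @ np.append(c_vox, 1.0)
        out[int(lab)] = c_world[:3]
    return out


def distance_matrix(centroids: dict[int, np.ndarray],
                    region_labels: np.ndarray | None = None) -> np.ndarray:
    """Pairwise Euclidean distances (mm) between region centroids."""
    labels = sorted(centroids) if region_labels is None else [int(l) for l in region_labels]
    missing = [l for l in labels if l not in centroids]
    if missing:
        raise ValueError(f"missing centroid for label(s) {missing}")
    pts = np.stack([centroids[l] for l in labels])
    diff = pts[:, None, :] - pts[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))


def _residualize(y: np.ndarray, covariate: np.ndarray) -> np.ndarray:
    X = np.column_stack([np.ones_like(covariate), covariate])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def edge_correlation_with_covariate(
    a: SimilarityMatrix,
    b: SimilarityMatrix,
    d: np.ndarray | None = None,
) -> tuple[float, float]:
    """Edge-wise Pearson correlation between two networks, optionally
    partialling out interregional distance.

    With a distance matrix ``d``, both networks' edge vectors are
    residualized on the distance edge vector by least squares and the
    residuals are correlated (first-order partial correlation); the
    p value uses the t transform with n_edges - 3 degrees of freedom.
    Without ``d`` a plain correlation with n_edges - 2 df is returned.
    """
    if not np.array_equal(a.region_labels, b.region_labels):
        raise ValueError("networks disagree on region set")
    x = a.edge_vector()
    y = b.edge_vector()
    n = x.size
    scale_x, scale_y = x.std(), y.std()
    if d is not None:
        dv = edge_vector(np.asarray(d, dtype=float))
        x = _residualize(x, dv)
        y = _residualize(y, dv)
        df = n - 3
    else:
        df = n - 2
    # residuals at rounding-noise level count as zero variance
    if x.std() <= 1e-10 * max(scale_x, 1e-300) or \
            y.std() <= 1e-10 * max(scale_y, 1e-300):
        warnings.warn("zero-variance residuals: correlation undefined", stacklevel=2)
        return float("nan"), float("nan")
    r = float(np.corrcoef(x, y)[0, 1])
    t = r * np.sqrt(df / max(1.0 - r**2, np.finfo(float).tiny))
    p = 2.0 * stats.t.sf(abs(t), df)
    return r, float(p)


def node_strength_correlation(
    a: SimilarityMatrix, b: SimilarityMatrix
) -> tuple[float, float]:
    """Pearson r and p between the two networks' node-strength vectors."""
    if not np.array_equal(a.region_labels, b.region_labels):
        raise ValueError("networks disagree on region set")
    sa, sb = a.node_strength(), b.node_strength()
    if sa.std() == 0 or sb.std() == 0:
        warnings.warn("zero-variance node strengths", stacklevel=2)
        return float("nan"), float("nan")
    r, p = stats.pearsonr(sa, sb)
    return float(r), float(p)


def _columnwise_pearson(x: np.ndarray, score: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Correlate each column of x with score; returns (r, p, flagged)."""
    n = score.size
    xc = x - x.mean(axis=0)
    sc = score - score.mean()
    sx = xc.std(axis=0)
    flagged = sx == 0
    denom = np.where(flagged, 1.0, sx) * sc.std() * n
    r = (xc * sc[:, None]).sum(axis=0) / denom
    r[flagged] = np.nan
    r = np.clip(r, -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p[np.isclose(np.abs(r), 1.0)] = 0.0
    p[flagged] = np.nan
    return r, p, flagged


def _bonferroni(p_raw: np.ndarray, n_tests: int, alpha: float):
    p_corr = np.minimum(1.0, p_raw * n_tests)
    sig = p_corr < alpha
    sig &= ~np.isnan(p_corr)
    return p_corr, sig


def edge_score_association(
    nets: list[SimilarityMatrix],
    scores: np.ndarray,
    alpha: float = 0.05,
) -> AssociationResult:
    """Edge-by-edge correlation of network weight with a behavioral score.

    Each of the n(n-1)/2 edges is correlated across subjects with the
    score; p values are Bonferroni-corrected over all edges.
    """
    scores = np.asarray(scores, dtype=float)
    if len(nets) < 3:
        raise ValueError("need at least 3 subjects")
    if len(nets) != scores.size:
        raise ValueError("one score per subject required")
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    if scores.std() == 0:
        raise ValueError("constant score vector")
    edges = np.stack([n.edge_vector() for n in nets])
    r, p, flagged = _columnwise_pearson(edges, scores)
    n_tests = edges.shape[1]
    p_corr, sig = _bonferroni(p, n_tests, alpha)
    return AssociationResult(r, p, p_corr, sig, n_tests, alpha, flagged=flagged)


#: nodal metrics that can be tested against a score
NODE_METRICS = {
    "degree": "degree",
    "neighbor_degree": "neighbor_degree",
    "betweenness": "betweenness",
    "global_efficiency": "nodal_efficiency",
    "clustering": "clustering",
}


def node_metric_score_association(
    records: list[GraphMetricsRecord],
    metric_id: str,
    scores: np.ndarray,
    alpha: float = 0.05,
) -> AssociationResult:
    """Node-by-node correlation of a graph metric with a behavioral score.

    ``records`` holds one GraphMetricsRecord per subject, all at the same
    binarization threshold; Bonferroni correction uses N = n_regions.
    Nodes whose metric is constant across subjects are flagged (NaN).
    """
    if metric_id not in NODE_METRICS:
        raise ValueError(f"metric_id must be one of {sorted(NODE_METRICS)}")
    scores = np.asarray(scores, dtype=float)
    if len(records) != scores.size:
        raise ValueError("one score per subject required")
    if scores.std() == 0:
        raise ValueError("constant score vector")
    thresholds = {r.threshold for r in records}
    if len(thresholds) > 1:
        raise ValueError(f"records span multiple thresholds: {sorted(thresholds)}")
    attr = NODE_METRICS[metric_id]
    x = np.stack([getattr(r, attr) for r in records])  # (subjects, nodes)
    r, p, flagged = _columnwise_pearson(x, scores)
    n_tests = x.shape[1]
    p_corr, sig = _bonferroni(p, n_tests, alpha)
    return AssociationResult(r, p, p_corr, sig, n_tests, alpha, flagged=flagged)
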