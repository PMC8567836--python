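"""Reproducibility statistics for similarity networks.

Three complementary analyses:

* split-half consistency — the cohort is randomly split into two halves
  many times; each iteration correlates the two half-cohort mean networks
  edge-wise, giving a distribution of Pearson r values;
* feature-subset robustness — networks are rebuilt from random feature
  subsets (e.g. 20 of the 25 marker features) and the subset mean network
  is correlated against the full-feature mean network;
* edge-wise test-retest ICC — per edge, a one-way random-effects ANOVA
  across subjects x repeated sessions gives
  ICC = (BMS - WMS) / BMS, with BMS/WMS the between-/within-subject mean
  squares. Negative estimates are reported as computed (an optional
  truncation flag clips them at 0).

A control check correlates node strength against region size (voxel
count), which should be near zero for a size-unbiased network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .network import build_r2sn, minmax_normalize
from .types import RegionFeatureTable, SimilarityMatrix, edge_vector

__all__ = [
    "SessionStack",
    "ReliabilityReport",
    "splithalf_consistency",
    "feature_subset_robustness",
    "edge_icc",
    "node_size_strength_check",
]


@dataclass
class SessionStack:
    """Networks indexed by (subject, session) with a rectangular design."""

    networks: dict[tuple[str, str], SimilarityMatrix]

    def __post_init__(self) -> None:
        subjects = sorted({s for s, _ in self.networks})
        sessions = sorted({v for _, v in self.networks})
        for s in subjects:
            have = sorted(v for (ss, v) in self.networks if ss == s)
            if have != sessions:
                raise ValueError(f"subject {s!r} has sessions {have}, "
                                 f"expected {sessions}")
        labels = next(iter(self.networks.values())).region_labels
        for net in self.networks.values():
            if not np.array_equal(net.region_labels, labels):
                raise ValueError("networks disagree on region set")
        self.subjects = subjects
        self.sessions = sessions
        self.region_labels = labels

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_sessions(self) -> int:
        return len(self.sessions)

    def edge_array(self) -> np.ndarray:
        """Edges as an array of shape (n_subjects, n_sessions, n_edges)."""
        return np.stack([
            np.stack([self.networks[(s, v)].edge_vector() for v in self.sessions])
            for s in self.subjects
        ])


@dataclass
class ReliabilityReport:
    splithalf_r: np.ndarray | None = None
    subset_r: np.ndarray | None = None
    icc_map: np.ndarray | None = None
    node_size_r: float | None = None
    node_size_p: float | None = None
    extra: dict = field(default_factory=dict)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.corrcoef(x, y)[0, 1])


def splithalf_consistency(
    nets: list[SimilarityMatrix],
    n_iter: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Distribution of Pearson r between mean networks of random halves.

    Each iteration permutes the cohort, splits it into two disjoint halves
    (floor/ceil split for odd cohorts), averages each half's edge vectors
    and correlates the two means.
    """
    if len(nets) < 4:
        raise ValueError("need at least 4 subjects")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    edges = np.stack([n.edge_vector() for n in nets])
    n = edges.shape[0]
    half = n // 2
    rng = np.random.default_rng(seed)
    out = np.empty(n_iter)
    for it in range(n_iter):
        perm = rng.permutation(n)
        m1 = edges[perm[:half]].mean(axis=0)
        m2 = edges[perm[half:]].mean(axis=0)
        out[it] = _pearson(m1, m2)
    return out


def feature_subset_robustness(
    tables: list[RegionFeatureTable],
    k: int = 20,
    n_iter: int = 1000,
    seed: int = 0,
    normalized: bool = False,
    max_resample: int = 100,
) -> np.ndarray:
    """Pearson r between subset-feature and full-feature mean networks.

    Each iteration draws ``k`` of the features without replacement,
    rebuilds every subject's network from that subset and correlates the
    subset mean network against the full-feature mean network. A subset
    that leaves some region with a constant feature vector (so its network
    is undefined) is flagged and redrawn.
    """
    if not tables:
        raise ValueError("no tables given")
    n_features = tables[0].n_features
    if not 1 <= k <= n_features:
        raise ValueError(f"k must lie in [1, {n_features}]")
    if not normalized:
        tables = [minmax_normalize(t) for t in tables]
    full_edges = np.stack([build_r2sn(t).edge_vector() for t in tables]).mean(axis=0)
    rng = np.random.default_rng(seed)
    out = np.empty(n_iter)
    n_flagged = 0
    for it in range(n_iter):
        for _ in range(max_resample):
            cols = rng.choice(n_features, size=k, replace=False)
            try:
                sub_edges = np.stack([
                    build_r2sn(RegionFeatureTable(
                        t.matrix[:, cols], t.region_labels,
                        [t.feature_ids[c] for c in cols], subject_id=t.subject_id))
                    .edge_vector()
                    for t in tables
                ]).mean(axis=0)
                break
            except ValueError:
                n_flagged += 1
        else:
            raise RuntimeError("could not draw a non-degenerate feature subset")
        out[it] = _pearson(full_edges, sub_edges)
    if n_flagged:
        warnings.warn(f"{n_flagged} degenerate feature subsets were redrawn",
                      stacklevel=2)
    return out


def edge_icc(stack: SessionStack, truncate: bool = False,
             variant: str = "average") -> np.ndarray:
    """Per-edge one-way random-effects ICC from a subjects x sessions design.

    BMS is the between-subject mean square and WMS the within-subject
    (between-session) mean square. The default ``variant="average"`` is
    ICC = (BMS - WMS) / BMS, the reliability of the k-session average;
    under the one-way model it estimates
    k sigma_b^2 / (k sigma_b^2 + sigma_w^2). ``variant="single"`` is the
    single-measurement transform
    ICC = (BMS - WMS) / (BMS + (k - 1) WMS), which estimates the raw
    variance ratio sigma_b^2 / (sigma_b^2 + sigma_w^2); the two coincide
    for k = 2 only in the absence of noise. Edges with BMS = 0 are NaN
    (undefined); negative estimates are reported as computed unless
    ``truncate`` clips them at 0.
    """
    if stack.n_subjects < 2 or stack.n_sessions < 2:
        raise ValueError("need >= 2 subjects and >= 2 sessions")
    if variant not in ("average", "single"):
        raise ValueError("variant must be 'average' or 'single'")
    x = stack.edge_array()  # (s, k, E)
    s, k, _ = x.shape
    subj_mean = x.mean(axis=1)            # (s, E)
    grand = x.mean(axis=(0, 1))           # (E,)
    bms = k * ((subj_mean - grand) ** 2).sum(axis=0) / (s - 1)
    wms = ((x - subj_mean[:, None, :]) ** 2).sum(axis=(0, 1)) / (s * (k - 1))
    denom = bms if variant == "average" else bms + (k - 1) * wms
    with np.errstate(divide="ignore", invalid="ignore"):
        icc = (bms - wms) / denom
    icc[bms == 0] = np.nan
    if truncate:
        icc = np.where(np.isnan(icc), icc, np.maximum(icc, 0.0))
    return icc


def node_size_strength_check(
    mean_net: SimilarityMatrix,
    voxel_counts: np.ndarray,
) -> tuple[float, float]:
    """Pearson r and two-sided p between node strength and region size.

    Returns (nan, nan) when either vector has zero variance.
    """
    counts = np.asarray(voxel_counts, dtype=float)
    if (counts <= 0).any():
        raise ValueError("voxel counts must be positive")
    strength = mean_net.node_strength()
    if counts.shape != strength.shape:
        raise ValueError("voxel_counts length must match region count")
    def _near_constant(x: np.ndarray) -> bool:
        return np.ptp(x) <= 1e-12 * max(1.0, float(np.abs(x).max()))

    if _near_constant(strength) or _near_constant(counts):
        warnings.warn("zero-variance input: correlation undefined", stacklevel=2)
        return float("nan"), float("nan")
    r, p = stats.pearsonr(strength, counts)
    return float(r), float(p)
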