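"""Per-region radiomics feature extraction.

The catalog has 47 features per region: 14 first-order intensity
statistics, 22 gray-level co-occurrence matrix (GLCM) texture features and
11 gray-level run-length matrix (GLRLM) texture features, following the
classical radiomics feature definitions. A distinguished 25-feature subset
(7 intensity + 18 texture) is the default marker set used for network
construction after redundancy removal.

Texture features are computed per spatial direction — the 13 unique 3D
offsets at distance 1 — and averaged over directions in which the region
admits at least one voxel pair. Gray levels come from equal-width
quantization over the region's own intensity range (default 32 levels).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .types import LabeledVolume, RegionFeatureTable

logger = logging.getLogger(__name__)

__all__ = [
    "FIRST_ORDER_FEATURES",
    "GLCM_FEATURES",
    "GLRLM_FEATURES",
    "RESERVED_25",
    "DIRECTIONS_13",
    "FeatureCatalog",
    "full_catalog",
    "reserved25_catalog",
    "ExtractionParams",
    "GLCMatrix",
    "GLRLMatrix",
    "quantize_region",
    "first_order_features",
    "compute_glcm",
    "glcm_features",
    "compute_glrlm",
    "glrlm_features",
    "extract_region_features",
]

# --------------------------------------------------------------------------
# Catalog

FIRST_ORDER_FEATURES = [
    "firstorder_energy",
    "firstorder_entropy",
    "firstorder_kurtosis",
    "firstorder_maximum",
    "firstorder_mean",
    "firstorder_mad",
    "firstorder_median",
    "firstorder_minimum",
    "firstorder_range",
    "firstorder_rms",
    "firstorder_skewness",
    "firstorder_std",
    "firstorder_uniformity",
    "firstorder_variance",
]

GLCM_FEATURES = [
    "glcm_autocorrelation",
    "glcm_cluster_prominence",
    "glcm_cluster_shade",
    "glcm_cluster_tendency",
    "glcm_contrast",
    "glcm_correlation",
    "glcm_difference_entropy",
    "glcm_dissimilarity",
    "glcm_energy",
    "glcm_entropy",
    "glcm_homogeneity1",
    "glcm_homogeneity2",
    "glcm_imc1",
    "glcm_imc2",
    "glcm_idmn",
    "glcm_idn",
    "glcm_inverse_variance",
    "glcm_maximum_probability",
    "glcm_sum_average",
    "glcm_sum_entropy",
    "glcm_sum_variance",
    "glcm_variance",
]

GLRLM_FEATURES = [
    "glrlm_sre",
    "glrlm_lre",
    "glrlm_gln",
    "glrlm_rln",
    "glrlm_rp",
    "glrlm_lgre",
    "glrlm_hgre",
    "glrlm_srlge",
    "glrlm_srhge",
    "glrlm_lrlge",
    "glrlm_lrhge",
]

#: The reserved 25-feature marker set (7 intensity + 18 texture) kept after
#: removing features that are highly redundant with the rest of the catalog.
RESERVED_25 = [
    "firstorder_energy",
    "firstorder_kurtosis",
    "firstorder_maximum",
    "firstorder_mad",
    "firstorder_minimum",
    "firstorder_skewness",
    "firstorder_entropy",
    "glcm_autocorrelation",
    "glcm_cluster_prominence",
    "glcm_cluster_shade",
    "glcm_cluster_tendency",
    "glcm_contrast",
    "glcm_correlation",
    "glcm_energy",
    "glcm_entropy",
    "glcm_homogeneity1",
    "glcm_imc1",
    "glcm_maximum_probability",
    "glcm_sum_entropy",
    "glrlm_sre",
    "glrlm_lre",
    "glrlm_gln",
    "glrlm_lgre",
    "glrlm_hgre",
    "glrlm_lrhge",
]

_FAMILY = {}
for _f in FIRST_ORDER_FEATURES:
    _FAMILY[_f] = "intensity"
for _f in GLCM_FEATURES:
    _FAMILY[_f] = "glcm"
for _f in GLRLM_FEATURES:
    _FAMILY[_f] = "glrlm"


@dataclass
class FeatureCatalog:
    """Ordered list of feature ids with their family membership."""

    feature_ids: list[str]
    name: str = "custom"

    def __post_init__(self) -> None:
        self.feature_ids = list(self.feature_ids)
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicate feature ids in catalog")

    def __len__(self) -> int:
        return len(self.feature_ids)

    def __iter__(self):
        return iter(self.feature_ids)

    def family(self, feature_id: str) -> str:
        return _FAMILY.get(feature_id, "other")

    def counts_by_family(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for f in self.feature_ids:
            fam = self.family(f)
            out[fam] = out.get(fam, 0) + 1
        return out

    def subset(self, feature_ids: list[str], name: str = "subset") -> "FeatureCatalog":
        missing = [f for f in feature_ids if f not in self.feature_ids]
        if missing:
            raise ValueError(f"features not in catalog: {missing}")
        return FeatureCatalog(list(feature_ids), name=name)


def full_catalog() -> FeatureCatalog:
    """The full 47-feature catalog (14 intensity + 22 GLCM + 11 GLRLM)."""
    return FeatureCatalog(
        FIRST_ORDER_FEATURES + GLCM_FEATURES + GLRLM_FEATURES, name="full"
    )


def reserved25_catalog() -> FeatureCatalog:
    """The fixed 25-feature marker set used for network construction."""
    return FeatureCatalog(RESERVED_25, name="reserved25")


def _unique_directions() -> np.ndarray:
    dirs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                d = (dx, dy, dz)
                if d == (0, 0, 0):
                    continue
                # keep one representative per +/- pair
                if d < tuple(-c for c in d):
                    continue
                dirs.append(d)
    return np.array(dirs, dtype=int)


#: The 13 unique 3D neighbor offsets (one per +/- direction pair).
DIRECTIONS_13 = _unique_directions()
assert DIRECTIONS_13.shape == (13, 3)


# --------------------------------------------------------------------------
# Quantization and first-order statistics


def quantize_region(values: np.ndarray, n_levels: int) -> np.ndarray:
    """Equal-width quantization of intensities into levels 1..n_levels.

    Bins span the region's own [min, max]; the maximum maps to the top
    level and a constant region maps everywhere to level 1.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty region")
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.ones(values.shape, dtype=np.int64)
    width = (hi - lo) / n_levels
    levels = np.floor((values - lo) / width).astype(np.int64) + 1
    return np.clip(levels, 1, n_levels)


def first_order_features(values: np.ndarray, n_bins: int = 32) -> dict[str, float]:
    """The 14 first-order intensity statistics of a region.

    entropy/uniformity use an equal-width histogram with ``n_bins`` bins;
    skewness and kurtosis use population moments (kurtosis non-excess);
    std and variance use the N-1 denominator. A zero-variance region
    returns skewness and kurtosis 0 (logged) so downstream correlations
    never see NaN.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty region")
    n = x.size
    mean = x.mean()
    dev = x - mean
    m2 = np.mean(dev**2)
    if m2 > 0:
        skew = np.mean(dev**3) / m2**1.5
        kurt = np.mean(dev**4) / m2**2
    else:
        logger.warning("zero-variance region: skewness/kurtosis set to 0")
        skew = 0.0
        kurt = 0.0
    if x.max() > x.min():
        hist, _ = np.histogram(x, bins=n_bins, range=(x.min(), x.max()))
        p = hist / n
        p = p[p > 0]
        entropy = float(-(p * np.log2(p)).sum())
        uniformity = float((p**2).sum())
    else:
        entropy = 0.0
        uniformity = 1.0
    if n > 1:
        var = float(np.var(x, ddof=1))
    else:
        var = 0.0
    return {
        "firstorder_energy": float((x**2).sum()),
        "firstorder_entropy": entropy,
        "firstorder_kurtosis": float(kurt),
        "firstorder_maximum": float(x.max()),
        "firstorder_mean": float(mean),
        "firstorder_mad": float(np.abs(dev).mean()),
        "firstorder_median": float(np.median(x)),
        "firstorder_minimum": float(x.min()),
        "firstorder_range": float(x.max() - x.min()),
        "firstorder_rms": float(np.sqrt(np.mean(x**2))),
        "firstorder_skewness": float(skew),
        "firstorder_std": float(np.sqrt(var)),
        "firstorder_uniformity": uniformity,
        "firstorder_variance": var,
    }


# --------------------------------------------------------------------------
# GLCM


@dataclass
class GLCMatrix:
    """Symmetric, normalized gray-level co-occurrence matrix."""

    probabilities: np.ndarray  # n_levels x n_levels, sums to 1 when valid
    n_levels: int
    direction: np.ndarray = field(default_factory=lambda: np.array([0, 0, 1]))
    distance: int = 1
    n_pairs: int = 0
    valid: bool = True


def _offset_views(shape: tuple[int, ...], offset: np.ndarray):
    """Slices (src, dst) so that arr[dst] = arr shifted by +offset from src."""
    src, dst = [], []
    for size, o in zip(shape, offset):
        o = int(o)
        if o >= 0:
            src.append(slice(0, size - o))
            dst.append(slice(o, size))
        else:
            src.append(slice(-o, size))
            dst.append(slice(0, size + o))
    return tuple(src), tuple(dst)


def compute_glcm(
    levels: np.ndarray,
    mask: np.ndarray,
    direction: np.ndarray,
    distance: int = 1,
    n_levels: int | None = None,
) -> GLCMatrix:
    """Co-occurrence counts of level pairs at ``direction * distance``.

    Only voxel pairs with both members inside the region mask contribute;
    pairs are accumulated symmetrically (both orderings). If the region
    admits no pair in this direction the matrix is flagged invalid.
    """
    levels = np.asarray(levels)
    mask = np.asarray(mask, dtype=bool)
    if levels.shape != mask.shape:
        raise ValueError("levels and mask shapes differ")
    direction = np.asarray(direction, dtype=int)
    if n_levels is None:
        n_levels = int(levels[mask].max()) if mask.any() else 1
    offset = direction * int(distance)
    src, dst = _offset_views(levels.shape, offset)
    valid = mask[src] & mask[dst]
    a = levels[src][valid] - 1
    b = levels[dst][valid] - 1
    counts = np.zeros((n_levels, n_levels), dtype=float)
    if a.size:
        np.add.at(counts, (a, b), 1.0)
        np.add.at(counts, (b, a), 1.0)
        probs = counts / counts.sum()
        return GLCMatrix(probs, n_levels, direction, distance, n_pairs=int(a.size))
    return GLCMatrix(counts, n_levels, direction, distance, n_pairs=0, valid=False)


def glcm_features(g: GLCMatrix) -> dict[str, float]:
    """The 22 GLCM texture features of a normalized co-occurrence matrix.

    Entropic quantities use log base 2. For a degenerate matrix with a
    single nonzero cell the correlation and information-measure features
    are 0/0; they are returned as 0 with a logged warning.
    """
    if not g.valid:
        raise ValueError("GLCM is invalid (no voxel pairs)")
    p = np.asarray(g.probabilities, dtype=float)
    ng = g.n_levels
    i = np.arange(1, ng + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float((i * px).sum())
    mu_y = float((i * py).sum())
    sig_x = float(np.sqrt(((i - mu_x) ** 2 * px).sum()))
    sig_y = float(np.sqrt(((i - mu_y) ** 2 * py).sum()))

    # distributions of i+j (2..2Ng) and |i-j| (0..Ng-1)
    ksum = np.arange(2, 2 * ng + 1, dtype=float)
    p_sum = np.zeros(2 * ng - 1)
    np.add.at(p_sum, (ii + jj).astype(int).ravel() - 2, p.ravel())
    kdiff = np.arange(0, ng, dtype=float)
    p_diff = np.zeros(ng)
    np.add.at(p_diff, np.abs(ii - jj).astype(int).ravel(), p.ravel())

    def ent(q: np.ndarray) -> float:
        q = q[q > 0]
        return float(-(q * np.log2(q)).sum() + 0.0) if q.size else 0.0

    hxy = ent(p)
    hx = ent(px)
    hy = ent(py)
    pxpy = np.outer(px, py)
    nz = (p > 0) & (pxpy > 0)
    hxy1 = float(-(p[nz] * np.log2(pxpy[nz])).sum())
    hxy2 = ent(pxpy)

    absdiff = np.abs(ii - jj)
    contrast = float(((ii - jj) ** 2 * p).sum())
    cluster_base = ii + jj - mu_x - mu_y

    if sig_x > 0 and sig_y > 0:
        correlation = float(((ii * jj * p).sum() - mu_x * mu_y) / (sig_x * sig_y))
    else:
        logger.warning("degenerate GLCM: correlation set to 0")
        correlation = 0.0
    denom_imc = max(hx, hy)
    if denom_imc > 0:
        imc1 = float((hxy - hxy1) / denom_imc)
    else:
        logger.warning("degenerate GLCM: IMC1 set to 0")
        imc1 = 0.0
    arg = 1.0 - np.exp(-2.0 * (hxy2 - hxy))
    imc2 = float(np.sqrt(arg)) if arg > 0 else 0.0

    offdiag = absdiff > 0
    inverse_variance = float((p[offdiag] / absdiff[offdiag] ** 2).sum())
    sum_average = float((ksum * p_sum).sum())

    return {
        "glcm_autocorrelation": float((ii * jj * p).sum()),
        "glcm_cluster_prominence": float((cluster_base**4 * p).sum()),
        "glcm_cluster_shade": float((cluster_base**3 * p).sum()),
        "glcm_cluster_tendency": float((cluster_base**2 * p).sum()),
        "glcm_contrast": contrast,
        "glcm_correlation": correlation,
        "glcm_difference_entropy": ent(p_diff),
        "glcm_dissimilarity": float((absdiff * p).sum()),
        "glcm_energy": float((p**2).sum()),
        "glcm_entropy": hxy,
        "glcm_homogeneity1": float((p / (1.0 + absdiff)).sum()),
        "glcm_homogeneity2": float((p / (1.0 + absdiff**2)).sum()),
        "glcm_imc1": imc1,
        "glcm_imc2": imc2,
        "glcm_idmn": float((p / (1.0 + absdiff**2 / ng**2)).sum()),
        "glcm_idn": float((p / (1.0 + absdiff / ng)).sum()),
        "glcm_inverse_variance": inverse_variance,
        "glcm_maximum_probability": float(p.max()),
        "glcm_sum_average": sum_average,
        "glcm_sum_entropy": ent(p_sum),
        "glcm_sum_variance": float(((ksum - sum_average) ** 2 * p_sum).sum()),
        "glcm_variance": float(((ii - mu_x) ** 2 * p).sum()),
    }


# --------------------------------------------------------------------------
# GLRLM


@dataclass
class GLRLMatrix:
    """Gray-level run-length counts: levels x run lengths."""

    counts: np.ndarray  # n_levels x max_run_length, integer-valued
    direction: np.ndarray
    n_levels: int


def compute_glrlm(
    levels: np.ndarray,
    mask: np.ndarray,
    direction: np.ndarray,
    n_levels: int | None = None,
) -> GLRLMatrix:
    """Maximal same-level runs along ``direction``, truncated at the region
    boundary.

    Implemented as a vectorized recurrence: sweeping slabs along the
    direction's dominant axis, the running length ending at a voxel is the
    predecessor's length + 1 when the predecessor is an in-region voxel of
    the same level, else 1. Runs are recorded at voxels with no in-region
    same-level successor.
    """
    levels = np.asarray(levels)
    mask = np.asarray(mask, dtype=bool)
    if levels.shape != mask.shape:
        raise ValueError("levels and mask shapes differ")
    if not mask.any():
        raise ValueError("empty region")
    direction = np.asarray(direction, dtype=int)
    if n_levels is None:
        n_levels = int(levels[mask].max())

    # continuation flag: voxel continues the run of voxel - direction
    src, dst = _offset_views(levels.shape, direction)
    cont = np.zeros(levels.shape, dtype=bool)
    cont[dst] = mask[dst] & mask[src] & (levels[dst] == levels[src])

    ax = int(np.argmax(np.abs(direction)))
    step = int(direction[ax])
    order = range(levels.shape[ax]) if step > 0 else range(levels.shape[ax] - 1, -1, -1)
    # lateral shift applied to the predecessor slab
    lateral = list(direction)
    lateral[ax] = 0

    runlen = np.zeros(levels.shape, dtype=np.int64)
    sl = [slice(None)] * 3
    prev_sl = [slice(None)] * 3
    for idx in order:
        sl[ax] = idx
        cur = tuple(sl)
        runlen[cur] = mask[cur].astype(np.int64)
        prev_idx = idx - step
        if 0 <= prev_idx < levels.shape[ax]:
            prev_sl[ax] = prev_idx
            prev = runlen[tuple(prev_sl)]
            if any(lateral):
                lsrc, ldst = _offset_views(prev.shape, np.array(lateral)[
                    [a for a in range(3) if a != ax]])
                shifted = np.zeros_like(prev)
                shifted[ldst] = prev[lsrc]
                prev = shifted
            c = cont[cur]
            runlen[cur][c] = prev[c] + 1

    # run ends: in-mask voxels whose successor does not continue the run
    is_cont_of_prev = cont  # voxel continues its predecessor
    ends = mask.copy()
    ends[src] &= ~is_cont_of_prev[dst]

    end_levels = levels[ends] - 1
    end_lengths = runlen[ends]
    max_len = int(end_lengths.max())
    counts = np.zeros((n_levels, max_len), dtype=float)
    np.add.at(counts, (end_levels, end_lengths - 1), 1.0)
    return GLRLMatrix(counts, direction, n_levels)


def glrlm_features(r: GLRLMatrix, n_voxels: int) -> dict[str, float]:
    """The 11 run-length features (SRE, LRE, GLN, RLN, RP, LGRE, HGRE,
    SRLGE, SRHGE, LRLGE, LRHGE)."""
    c = np.asarray(r.counts, dtype=float)
    n_runs = c.sum()
    if n_runs == 0:
        raise ValueError("GLRLM has zero runs")
    g = np.arange(1, c.shape[0] + 1, dtype=float)[:, None]
    l = np.arange(1, c.shape[1] + 1, dtype=float)[None, :]
    per_level = c.sum(axis=1)
    per_length = c.sum(axis=0)
    return {
        "glrlm_sre": float((c / l**2).sum() / n_runs),
        "glrlm_lre": float((c * l**2).sum() / n_runs),
        "glrlm_gln": float((per_level**2).sum() / n_runs),
        "glrlm_rln": float((per_length**2).sum() / n_runs),
        "glrlm_rp": float(n_runs / n_voxels),
        "glrlm_lgre": float((c / g**2).sum() / n_runs),
        "glrlm_hgre": float((c * g**2).sum() / n_runs),
        "glrlm_srlge": float((c / (g**2 * l**2)).sum() / n_runs),
        "glrlm_srhge": float((c * g**2 / l**2).sum() / n_runs),
        "glrlm_lrlge": float((c * l**2 / g**2).sum() / n_runs),
        "glrlm_lrhge": float((c * g**2 * l**2).sum() / n_runs),
    }


# --------------------------------------------------------------------------
# Full extraction


@dataclass
class ExtractionParams:
    """Knobs for full-volume extraction.

    n_levels : gray levels for texture quantization (per-region min-max).
    n_bins : histogram bins for first-order entropy/uniformity.
    distance : GLCM offset distance in voxels.
    min_region_voxels : regions smaller than this are flagged (error when
        ``strict``); 27 voxels = a 3x3x3 neighborhood.
    """

    n_levels: int = 32
    n_bins: int = 32
    distance: int = 1
    min_region_voxels: int = 27
    strict: bool = False


def _bbox(mask: np.ndarray) -> tuple[slice, ...]:
    out = []
    for ax in range(mask.ndim):
        other = tuple(a for a in range(mask.ndim) if a != ax)
        line = mask.any(axis=other)
        nz = np.nonzero(line)[0]
        out.append(slice(nz[0], nz[-1] + 1))
    return tuple(out)


def region_features(
    values_volume: np.ndarray,
    mask: np.ndarray,
    params: ExtractionParams | None = None,
) -> dict[str, float]:
    """All 47 features for a single region mask within a volume crop."""
    params = params or ExtractionParams()
    bb = _bbox(mask)
    vcrop = np.asarray(values_volume, dtype=float)[bb]
    mcrop = np.asarray(mask, dtype=bool)[bb]
    vals = vcrop[mcrop]

    out = first_order_features(vals, n_bins=params.n_bins)

    lev_crop = np.zeros(mcrop.shape, dtype=np.int64)
    lev_crop[mcrop] = quantize_region(vals, params.n_levels)

    glcm_acc: dict[str, list[float]] = {f: [] for f in GLCM_FEATURES}
    glrlm_acc: dict[str, list[float]] = {f: [] for f in GLRLM_FEATURES}
    n_vox = int(mcrop.sum())
    for direction in DIRECTIONS_13:
        g = compute_glcm(lev_crop, mcrop, direction, distance=params.distance,
                         n_levels=params.n_levels)
        if g.valid:
            for k, v in glcm_features(g).items():
                glcm_acc[k].append(v)
        r = compute_glrlm(lev_crop, mcrop, direction, n_levels=params.n_levels)
        for k, v in glrlm_features(r, n_vox).items():
            glrlm_acc[k].append(v)

    for k, vs in glcm_acc.items():
        if vs:
            out[k] = float(np.mean(vs))
        else:
            logger.warning("region has no valid GLCM direction; %s set to 0", k)
            out[k] = 0.0
    for k, vs in glrlm_acc.items():
        out[k] = float(np.mean(vs))
    return out


def extract_region_features(
    vol: LabeledVolume,
    catalog: FeatureCatalog | None = None,
    params: ExtractionParams | None = None,
    subject_id: str = "",
) -> RegionFeatureTable:
    """Compute the catalog features for every labeled region of a volume.

    Returns a table with one row per region (atlas label order) and one
    column per catalog feature. Regions below ``params.min_region_voxels``
    raise in strict mode, otherwise they are flagged and still computed.
    """
    catalog = catalog or full_catalog()
    params = params or ExtractionParams()
    unknown = [f for f in catalog if f not in _FAMILY]
    if unknown:
        raise ValueError(f"catalog contains non-computable features: {unknown}")
    labels = vol.region_labels
    if labels.size == 0:
        raise ValueError("volume has no labeled regions")
    rows = np.empty((labels.size, len(catalog)), dtype=float)
    flags: dict[int, str] = {}
    counts = vol.voxel_counts()
    for ridx, lab in enumerate(labels):
        n_vox = counts[int(lab)]
        if n_vox < params.min_region_voxels:
            msg = f"region {lab} has only {n_vox} voxels (< {params.min_region_voxels})"
            if params.strict:
                raise ValueError(msg)
            warnings.warn(msg, stacklevel=2)
            flags[int(lab)] = "small_region"
        feats = region_features(vol.intensities, vol.labels == lab, params)
        rows[ridx] = [feats[f] for f in catalog]
    return RegionFeatureTable(rows, labels, list(catalog), subject_id=subject_id,
                              flags=flags)
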