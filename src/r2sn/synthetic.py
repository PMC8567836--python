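"""Synthetic inputs with known ground truth.

Every generator is a pure, seeded function of its spec, and each returns
the ground-truth parameters it planted so that recovery tests are
self-describing:

* textured labeled phantoms standing in for preprocessed brain volumes —
  non-overlapping block (or spherical) regions whose intensity fields are
  region-mean + spatially smoothed Gaussian noise, with regions grouped
  into a small number of texture classes so that the resulting similarity
  networks have realistic modular structure;
* cohorts of similarity matrices with a shared modular latent network,
  per-subject effects (sd sigma_b) and per-session noise (sd sigma_w), so
  the implied edge ICC is sigma_b^2 / (sigma_b^2 + sigma_w^2);
* region x gene expression tables whose coupling to a feature table is a
  tunable mixture weight;
* behavioral scores driven by planted network edges at a chosen effect
  size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
from scipy.ndimage import gaussian_filter

from .association import GeneExpressionTable
from .reliability import SessionStack
from .types import (LabeledVolume, RegionFeatureTable, SimilarityMatrix,
                    edge_pairs, matrix_from_edge_vector)

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "make_phantom",
    "make_cohort",
    "make_phantom_cohort_tables",
    "make_gene_table",
    "make_scores",
    "latent_modular_network",
]


def _factor3(n: int) -> tuple[int, int, int]:
    """Factor n into three integers as balanced as possible."""
    best = (1, 1, n)
    best_score = n
    for a in range(1, int(round(n ** (1 / 3))) + 2):
        if n % a:
            continue
        m = n // a
        for b in range(a, int(np.sqrt(m)) + 1):
            if m % b:
                continue
            c = m // b
            score = c - a
            if score < best_score:
                best_score = score
                best = (a, b, c)
    return best


@dataclass
class PhantomSpec:
    """Recipe for a textured, labeled 3D phantom.

    Regions are grouped into ``n_classes`` texture classes; a class fixes
    the intensity mean, noise amplitude and spatial smoothing length, and
    each region adds a small seeded jitter, so same-class regions have
    similar (but not identical) radiomics profiles.
    """

    shape: tuple[int, int, int] = (30, 30, 24)
    n_regions: int = 90
    layout: str = "blocks"           # "blocks" or "spheres"
    n_classes: int = 6
    mean_range: tuple[float, float] = (80.0, 130.0)
    noise_sigma_range: tuple[float, float] = (4.0, 10.0)
    smoothness_range: tuple[float, float] = (0.4, 1.6)
    mean_jitter: float = 2.0
    global_noise: float = 1.0
    min_region_voxels: int = 27
    seed: int = 0


def _region_param_table(spec: PhantomSpec, rng: np.random.Generator) -> dict:
    classes = np.arange(spec.n_regions) % spec.n_classes
    cmeans = np.linspace(*spec.mean_range, spec.n_classes)
    csigmas = np.linspace(*spec.noise_sigma_range, spec.n_classes)
    csmooth = np.linspace(*spec.smoothness_range, spec.n_classes)
    return {
        "class_of_region": classes,
        "mean": cmeans[classes] + rng.normal(0, spec.mean_jitter, spec.n_regions),
        "noise_sigma": csigmas[classes],
        "smoothness": csmooth[classes],
    }


def make_phantom(spec: PhantomSpec) -> tuple[LabeledVolume, dict]:
    """Generate a labeled textured phantom; returns (volume, ground_truth).

    Region intensity = region mean + noise_sigma * smoothed standardized
    Gaussian field + global white noise. Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    labels = np.zeros(spec.shape, dtype=np.int32)
    if spec.layout == "blocks":
        a, b, c = _factor3(spec.n_regions)
        sizes = (spec.shape[0] // a, spec.shape[1] // b, spec.shape[2] // c)
        if min(sizes) < 3:
            raise ValueError(f"grid {spec.shape} too small for {spec.n_regions} "
                             f"blocks of >= 3 voxels per axis")
        lab = 1
        for ia in range(a):
            for ib in range(b):
                for ic in range(c):
                    labels[ia * sizes[0]:(ia + 1) * sizes[0],
                           ib * sizes[1]:(ib + 1) * sizes[1],
                           ic * sizes[2]:(ic + 1) * sizes[2]] = lab
                    lab += 1
    elif spec.layout == "spheres":
        # spheres on the same block grid, radius fitting inside each block
        a, b, c = _factor3(spec.n_regions)
        sizes = (spec.shape[0] // a, spec.shape[1] // b, spec.shape[2] // c)
        r = max(min(sizes) // 2 - 1, 2)
        grid = np.indices(spec.shape)
        lab = 1
        for ia in range(a):
            for ib in range(b):
                for ic in range(c):
                    center = ((ia + 0.5) * sizes[0], (ib + 0.5) * sizes[1],
                              (ic + 0.5) * sizes[2])
                    d2 = sum((grid[k] - center[k]) ** 2 for k in range(3))
                    sphere = d2 <= r**2
                    if (labels[sphere] != 0).any():
                        raise ValueError("overlapping spheres")
                    labels[sphere] = lab
                    lab += 1
    else:
        raise ValueError(f"unknown layout {spec.layout!r}")

    counts = np.bincount(labels.ravel())[1:]
    if (counts < spec.min_region_voxels).any():
        raise ValueError("a region is below the minimum voxel count")

    params = _region_param_table(spec, rng)
    intensities = rng.normal(0.0, spec.global_noise, spec.shape)
    for ridx in range(spec.n_regions):
        lab = ridx + 1
        mask = labels == lab
        field_noise = rng.normal(0.0, 1.0, spec.shape)
        smooth = gaussian_filter(field_noise, params["smoothness"][ridx])
        sm_vals = smooth[mask]
        sd = sm_vals.std()
        if sd > 0:
            sm_vals = (sm_vals - sm_vals.mean()) / sd
        intensities[mask] += params["mean"][ridx] + params["noise_sigma"][ridx] * sm_vals

    vol = LabeledVolume(intensities, labels,
                        label_names={i + 1: f"region_{i + 1}"
                                     for i in range(spec.n_regions)})
    truth = {"spec": spec, **params}
    return vol, truth


def latent_modular_network(
    n_regions: int,
    n_modules: int = 9,
    within_range: tuple[float, float] = (0.68, 0.90),
    between_range: tuple[float, float] = (0.15, 0.65),
    seed: int = 0,
) -> np.ndarray:
    """Modular latent similarity matrix: strong within-module edges, weaker
    between-module edges, mimicking the community structure of brain
    covariance networks."""
    rng = np.random.default_rng(seed)
    modules = np.arange(n_regions) % n_modules
    i, j = edge_pairs(n_regions)
    same = modules[i] == modules[j]
    vals = np.where(
        same,
        rng.uniform(*within_range, size=i.size),
        rng.uniform(*between_range, size=i.size),
    )
    return matrix_from_edge_vector(vals, n_regions, diag=1.0)


@dataclass
class CohortSpec:
    """Recipe for a (subject, session) cohort of similarity matrices."""

    n_subjects: int = 40
    n_sessions: int = 1
    n_regions: int = 90
    sigma_b: float = 0.10     # between-subject edge sd
    sigma_w: float = 0.05     # within-subject (session) edge sd
    n_modules: int = 9
    latent: np.ndarray | None = None
    seed: int = 0

    @property
    def implied_icc(self) -> float:
        tot = self.sigma_b**2 + self.sigma_w**2
        return self.sigma_b**2 / tot if tot > 0 else float("nan")


def make_cohort(spec: CohortSpec) -> tuple[SessionStack, dict]:
    """Generate per-(subject, session) similarity matrices.

    Each subject's network is the shared latent plus a symmetric edge-wise
    subject effect (sd sigma_b); each session adds edge-wise noise (sd
    sigma_w). Matrices are re-symmetrized, clipped to [-1, 1] with a
    warning if clipping touches more than 1% of edges, and given a unit
    diagonal.
    """
    if spec.sigma_b < 0 or spec.sigma_w < 0:
        raise ValueError("variances must be non-negative")
    rng = np.random.default_rng(spec.seed)
    latent = (spec.latent if spec.latent is not None else
              latent_modular_network(spec.n_regions, spec.n_modules,
                                     seed=int(rng.integers(2**31 - 1))))
    n = spec.n_regions
    i, j = edge_pairs(n)
    lat_edges = latent[i, j]
    labels = np.arange(1, n + 1)
    networks = {}
    n_clipped = 0
    for s in range(spec.n_subjects):
        subj_edges = lat_edges + rng.normal(0.0, spec.sigma_b, i.size)
        for v in range(spec.n_sessions):
            e = subj_edges + rng.normal(0.0, spec.sigma_w, i.size)
            n_clipped += int(((e < -1) | (e > 1)).sum())
            e = np.clip(e, -1.0, 1.0)
            m = matrix_from_edge_vector(e, n, diag=1.0)
            networks[(f"sub-{s:03d}", f"ses-{v}")] = SimilarityMatrix(
                m, labels, kind="R2SN", subject_id=f"sub-{s:03d}")
    frac = n_clipped / (spec.n_subjects * spec.n_sessions * i.size)
    if frac > 0.01:
        warnings.warn(f"clipping affected {frac:.1%} of edges; "
                      "cohort spec may be too extreme", stacklevel=2)
    truth = {"spec": spec, "latent": latent, "implied_icc": spec.implied_icc,
             "clipped_fraction": frac}
    return SessionStack(networks), truth


def make_phantom_cohort_tables(
    n_subjects: int,
    base_spec: PhantomSpec | None = None,
    catalog=None,
    params=None,
    seed: int = 0,
) -> list[RegionFeatureTable]:
    """Extract feature tables from a cohort of phantoms drawn from one
    population: all subjects share the region/class parameters, and only
    the noise realization differs by subject."""
    from .features import extract_region_features, reserved25_catalog

    base_spec = base_spec or PhantomSpec()
    catalog = catalog or reserved25_catalog()
    tables = []
    for s in range(n_subjects):
        spec = PhantomSpec(**{**base_spec.__dict__,
                              "seed": seed * 100003 + s,
                              "mean_jitter": 0.0})
        vol, _ = make_phantom(spec)
        tables.append(extract_region_features(vol, catalog, params,
                                              subject_id=f"sub-{s:03d}"))
    return tables


def make_gene_table(
    n_regions: int,
    n_genes: int = 500,
    coupling_to: RegionFeatureTable | np.ndarray | None = None,
    strength: float = 0.0,
    seed: int = 0,
) -> tuple[GeneExpressionTable, dict]:
    """Region x gene table with tunable coupling to a feature table.

    Each gene's regional profile is ``strength`` times a random linear map
    of the (standardized) regional feature profile plus ``1 - strength``
    times independent noise, so the GSN-to-R2SN edge correlation grows
    monotonically with ``strength``.
    """
    if not 0.0 <= strength <= 1.0:
        raise ValueError("strength must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    if coupling_to is not None and strength > 0:
        feats = (coupling_to.matrix if isinstance(coupling_to, RegionFeatureTable)
                 else np.asarray(coupling_to, dtype=float))
        if feats.shape[0] != n_regions:
            raise ValueError("coupling table must have one row per region")
        z = feats - feats.mean(axis=0)
        sd = z.std(axis=0)
        z = z / np.where(sd == 0, 1.0, sd)
        mixing = rng.normal(0.0, 1.0, (feats.shape[1], n_genes)) / np.sqrt(feats.shape[1])
        signal = z @ mixing
    else:
        signal = np.zeros((n_regions, n_genes))
    noise = rng.normal(0.0, 1.0, (n_regions, n_genes))
    expr = strength * signal + (1.0 - strength) * noise
    table = GeneExpressionTable(expr, np.arange(1, n_regions + 1),
                                [f"gene_{k:05d}" for k in range(n_genes)])
    truth = {"strength": strength, "n_genes": n_genes, "seed": seed}
    return table, truth


def make_scores(
    nets: list[SimilarityMatrix],
    planted_edges: list[tuple[int, int]] | None = None,
    effect: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """Behavioral scores driven by planted edges.

    score_s = effect * standardized mean of the planted edge values in
    subject s's network + unit Gaussian noise. ``planted_edges`` uses
    0-based region index pairs. With ``effect=0`` the scores are pure
    noise (the null).
    """
    if effect != 0 and not planted_edges:
        raise ValueError("non-zero effect needs planted edges")
    rng = np.random.default_rng(seed)
    n_sub = len(nets)
    scores = rng.normal(0.0, 1.0, n_sub)
    if effect != 0:
        vals = np.array([
            np.mean([net.matrix[i, j] for (i, j) in planted_edges])
            for net in nets
        ])
        sd = vals.std()
        if sd > 0:
            vals = (vals - vals.mean()) / sd
        scores = scores + effect * vals
    truth = {"planted_edges": planted_edges or [], "effect": effect, "seed": seed}
    return scores, truth
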