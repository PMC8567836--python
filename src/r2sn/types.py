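"""Core data containers shared across the package.

The containers are thin, validated wrappers around numpy arrays with the
labels needed to keep regions and features aligned through the pipeline:
a labeled 3D volume in, a region x feature table per subject, a region x
region similarity matrix per subject (or aggregated), and an edge-vector
view used by every downstream statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LabeledVolume",
    "RegionFeatureTable",
    "SimilarityMatrix",
    "edge_vector",
    "edge_pairs",
    "matrix_from_edge_vector",
]


@dataclass
class LabeledVolume:
    """A 3D scalar image plus an integer region-label volume.

    Parameters
    ----------
    intensities : ndarray, shape (nx, ny, nz)
        Scalar image in arbitrary units (already preprocessed/aligned).
    labels : ndarray of int, same shape
        Region labels; 0 is background.
    affine : ndarray, shape (4, 4)
        Voxel-index to world (mm) transform.
    label_names : dict, optional
        Map label -> region name.
    """

    intensities: np.ndarray
    labels: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    label_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise TypeError("labels must be an integer array")
        if self.intensities.shape != self.labels.shape:
            raise ValueError(
                f"intensities shape {self.intensities.shape} != labels shape "
                f"{self.labels.shape}"
            )
        if self.intensities.ndim != 3:
            raise ValueError("expected 3D volumes")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if (self.labels < 0).any():
            raise ValueError("labels must be non-negative")

    @property
    def region_labels(self) -> np.ndarray:
        """Sorted unique non-background labels."""
        labs = np.unique(self.labels)
        return labs[labs > 0]

    def voxel_counts(self) -> dict[int, int]:
        labs, counts = np.unique(self.labels[self.labels > 0], return_counts=True)
        return dict(zip(labs.tolist(), counts.tolist()))

    def region_mask(self, label: int) -> np.ndarray:
        mask = self.labels == label
        if not mask.any():
            raise ValueError(f"label {label} has no voxels")
        return mask


@dataclass
class RegionFeatureTable:
    """Per-subject region x feature matrix (e.g. 90 x 47 or 90 x 25)."""

    matrix: np.ndarray
    region_labels: np.ndarray
    feature_ids: list[str]
    subject_id: str = ""
    flags: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.region_labels = np.asarray(self.region_labels)
        self.feature_ids = list(self.feature_ids)
        if self.matrix.shape != (len(self.region_labels), len(self.feature_ids)):
            raise ValueError(
                f"matrix shape {self.matrix.shape} inconsistent with "
                f"{len(self.region_labels)} regions x {len(self.feature_ids)} features"
            )
        if not np.isfinite(self.matrix).all():
            raise ValueError("feature table contains non-finite entries")

    @property
    def n_regions(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def subset(self, feature_ids: list[str]) -> "RegionFeatureTable":
        """Column subset, preserving the given feature order."""
        idx = [self.feature_ids.index(f) for f in feature_ids]
        return RegionFeatureTable(
            self.matrix[:, idx], self.region_labels, list(feature_ids),
            subject_id=self.subject_id, flags=dict(self.flags),
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, columns=self.feature_ids)
        df.insert(0, "region", self.region_labels)
        return df


@dataclass
class SimilarityMatrix:
    """Symmetric region x region similarity network (R2SN or GSN).

    ``kind`` distinguishes radiomics networks ("R2SN") from gene-expression
    networks ("GSN"); ``subject_id`` is a subject identifier or the
    aggregate tags "mean"/"std".
    """

    matrix: np.ndarray
    region_labels: np.ndarray
    kind: str = "R2SN"
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.region_labels = np.asarray(self.region_labels)
        n = len(self.region_labels)
        if self.matrix.shape != (n, n):
            raise ValueError(f"matrix shape {self.matrix.shape} != ({n}, {n})")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-12):
            raise ValueError("similarity matrix must be symmetric")

    @property
    def n_regions(self) -> int:
        return self.matrix.shape[0]

    def edge_vector(self) -> np.ndarray:
        return edge_vector(self.matrix)

    def node_strength(self) -> np.ndarray:
        """Mean off-diagonal entry per row (mean connective strength)."""
        n = self.n_regions
        return (self.matrix.sum(axis=1) - np.diag(self.matrix)) / (n - 1)


def edge_pairs(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical edge ordering: row-major upper triangle, i < j.

    This ordering is fixed and shared by every statistic in the package so
    that edge vectors from different analyses are always comparable.
    """
    return np.triu_indices(n, k=1)


def edge_vector(matrix: np.ndarray) -> np.ndarray:
    """Upper-triangle (i < j) entries of a square matrix in canonical order."""
    matrix = np.asarray(matrix)
    i, j = edge_pairs(matrix.shape[0])
    return matrix[i, j]


def matrix_from_edge_vector(values: np.ndarray, n: int, diag: float = 1.0) -> np.ndarray:
    """Inverse of :func:`edge_vector`: rebuild the symmetric matrix."""
    values = np.asarray(values, dtype=float)
    if values.size != n * (n - 1) // 2:
        raise ValueError("edge vector length does not match n(n-1)/2")
    m = np.full((n, n), diag, dtype=float)
    i, j = edge_pairs(n)
    m[i, j] = values
    m[j, i] = values
    return m
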