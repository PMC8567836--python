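"""File formats, manifests and the end-to-end pipeline.

NIfTI volumes in; CSV (full double precision, with a metadata comment
header carrying tool version, config hash and seed) out. The pipeline is
deterministic: rerunning with the same inputs, config and seed produces
byte-identical CSVs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from . import __version__
from .features import (ExtractionParams, FeatureCatalog, extract_region_features,
                       full_catalog, reserved25_catalog)
from .graph import threshold_sweep
from .network import aggregate_networks, build_r2sn, minmax_normalize
from .types import LabeledVolume, RegionFeatureTable, SimilarityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "read_labeled_volume",
    "write_feature_table",
    "read_feature_table",
    "write_similarity",
    "read_similarity",
    "write_edge_list",
    "read_manifest",
    "run_pipeline",
]


def read_labeled_volume(image_path: str | Path, atlas_path: str | Path) -> LabeledVolume:
    """Load an intensity NIfTI and a label NIfTI into a LabeledVolume.

    The two images must share shape and affine (within 1e-4); no
    resampling is attempted. Float label volumes with integral values are
    cast with a warning.
    """
    img = nib.load(str(image_path))
    atl = nib.load(str(atlas_path))
    data = np.asanyarray(img.dataobj, dtype=float)
    labels = np.asanyarray(atl.dataobj)
    if data.shape != labels.shape:
        raise ValueError(f"image shape {data.shape} does not match atlas shape "
                         f"{labels.shape}; resample upstream")
    if not np.allclose(img.affine, atl.affine, atol=1e-4):
        raise ValueError("image and atlas affines differ by more than 1e-4; "
                         "refusing to guess an alignment")
    if not np.issubdtype(labels.dtype, np.integer):
        if np.allclose(labels, np.round(labels)):
            warnings.warn("float label volume with integral values cast to int",
                          stacklevel=2)
            labels = np.round(labels).astype(np.int32)
        else:
            raise ValueError("atlas volume has non-integer labels")
    return LabeledVolume(data, labels.astype(np.int32), affine=img.affine)


def _meta_header(seed=None, config: dict | None = None) -> str:
    cfg = json.dumps(config or {}, sort_keys=True, default=str)
    h = hashlib.sha256(cfg.encode()).hexdigest()[:12]
    return f"# r2sn version={__version__} config_hash={h} seed={seed}\n"


def write_feature_table(t: RegionFeatureTable, path: str | Path,
                        seed=None, config: dict | None = None) -> None:
    path = Path(path)
    with open(path, "w") as f:
        f.write(_meta_header(seed, config))
        t.to_dataframe().to_csv(f, index=False, float_format="%.17g")


def read_feature_table(path: str | Path, subject_id: str = "") -> RegionFeatureTable:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    return RegionFeatureTable(df.iloc[:, 1:].to_numpy(float),
                              df["region"].to_numpy(),
                              list(df.columns[1:]),
                              subject_id=subject_id)


def write_similarity(m: SimilarityMatrix, path: str | Path,
                     seed=None, config: dict | None = None) -> None:
    path = Path(path)
    df = pd.DataFrame(m.matrix,
                      index=[str(l) for l in m.region_labels],
                      columns=[str(l) for l in m.region_labels])
    with open(path, "w") as f:
        f.write(_meta_header(seed, config))
        f.write(f"# kind={m.kind} subject={m.subject_id}\n")
        df.to_csv(f, float_format="%.17g")


def read_similarity(path: str | Path) -> SimilarityMatrix:
    kind, subject = "R2SN", ""
    with open(path) as f:
        for line in f:
            if not line.startswith("#"):
                break
            if line.startswith("# kind="):
                parts = dict(tok.split("=", 1) for tok in line[2:].split())
                kind = parts.get("kind", kind)
                subject = parts.get("subject", subject)
    df = pd.read_csv(path, comment="#", index_col=0,
                     float_precision="round_trip")
    labels = np.array([int(c) if str(c).lstrip("-").isdigit() else c
                       for c in df.columns])
    return SimilarityMatrix(df.to_numpy(float), labels, kind=kind,
                            subject_id=subject)


def write_edge_list(m: SimilarityMatrix, path: str | Path) -> None:
    from .types import edge_pairs
    i, j = edge_pairs(m.n_regions)
    df = pd.DataFrame({
        "region_i": m.region_labels[i],
        "region_j": m.region_labels[j],
        "weight": m.matrix[i, j],
    })
    df.to_csv(path, index=False)


def read_manifest(path: str | Path, require_paths: bool = True) -> pd.DataFrame:
    """Manifest CSV with columns subject, session, image, atlas (+ extras).

    (subject, session) pairs must be unique; referenced paths must exist.
    """
    df = pd.read_csv(path)
    required = {"subject", "session"}
    if not required.issubset(df.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    dup = df.duplicated(subset=["subject", "session"])
    if dup.any():
        raise ValueError("duplicate (subject, session) rows in manifest")
    if require_paths:
        base = Path(path).parent
        for col in ("image", "atlas", "path"):
            if col in df.columns:
                resolved = []
                for p in df[col]:
                    full = Path(p)
                    if not full.is_absolute():
                        full = base / full
                    if not full.exists():
                        raise ValueError(f"manifest references missing file: {p}")
                    resolved.append(str(full))
                df[col] = resolved
    return df


_CATALOGS = {"full": full_catalog, "reserved25": reserved25_catalog}


def run_pipeline(manifest: pd.DataFrame | str | Path, config: dict,
                 out_dir: str | Path) -> Path:
    """Extract -> normalize -> network -> aggregate -> graph sweep.

    config keys (all optional): catalog ("reserved25"|"full"), n_levels,
    n_bins, distance, seed, thresholds {tmin, tmax, tstep}, n_nulls.
    Outputs per-subject feature and network CSVs, mean/std networks, a
    per-threshold graph-metrics CSV and an echo of the config.
    """
    if not isinstance(manifest, pd.DataFrame):
        manifest = read_manifest(manifest)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    catalog = _CATALOGS.get(config.get("catalog", "reserved25"))
    if catalog is None:
        raise ValueError(f"unknown catalog {config.get('catalog')!r}")
    catalog = catalog()
    params = ExtractionParams(
        n_levels=int(config.get("n_levels", 32)),
        n_bins=int(config.get("n_bins", 32)),
        distance=int(config.get("distance", 1)),
    )
    (out / "config.json").write_text(
        json.dumps({**config, "version": __version__}, sort_keys=True, indent=2,
                   default=str) + "\n")

    nets = []
    for _, row in manifest.iterrows():
        sid = str(row["subject"])
        stage = "extract"
        try:
            vol = read_labeled_volume(row["image"], row["atlas"])
            table = extract_region_features(vol, catalog, params, subject_id=sid)
            write_feature_table(table, out / f"{sid}_features.csv",
                                seed=seed, config=config)
            stage = "network"
            net = build_r2sn(minmax_normalize(table))
            write_similarity(net, out / f"{sid}_network.csv",
                             seed=seed, config=config)
            nets.append(net)
        except Exception as e:
            raise RuntimeError(
                f"pipeline stage {stage!r} failed for subject {sid!r}: {e}") from e
        logger.info("subject %s done", sid)

    mean_net = aggregate_networks(nets, "mean")
    write_similarity(mean_net, out / "mean_network.csv", seed=seed, config=config)
    if len(nets) > 1:
        std_net = aggregate_networks(nets, "std")
        write_similarity(std_net, out / "std_network.csv", seed=seed, config=config)

    th = config.get("thresholds", {})
    thresholds = np.round(np.arange(float(th.get("tmin", 0.50)),
                                    float(th.get("tmax", 0.75)) + 1e-9,
                                    float(th.get("tstep", 0.01))), 10)
    records = threshold_sweep(mean_net, thresholds,
                              n_nulls=int(config.get("n_nulls", 100)), seed=seed)
    rows = []
    for rec in records:
        rows.append({
            "threshold": rec.threshold, "C": rec.C, "L": rec.L,
            "sparseness": rec.sparseness,
            "global_efficiency": rec.global_efficiency,
            "frac_connected_pairs": rec.frac_connected_pairs,
            "gamma": rec.gamma, "lambda": rec.lam, "sigma": rec.sigma,
            "c_random": rec.c_random, "l_random": rec.l_random,
            "n_nulls": rec.n_nulls, "flags": ";".join(rec.flags),
        })
    with open(out / "graph_metrics.csv", "w") as f:
        f.write(_meta_header(seed, config))
        pd.DataFrame(rows).to_csv(f, index=False, float_format="%.17g")

    node_rows = []
    for rec in records:
        for k, lab in enumerate(mean_net.region_labels):
            node_rows.append({
                "threshold": rec.threshold, "region": lab,
                "degree": rec.degree[k],
                "neighbor_degree": rec.neighbor_degree[k],
                "betweenness": rec.betweenness[k],
                "clustering": rec.clustering[k],
                "nodal_efficiency": rec.nodal_efficiency[k],
            })
    with open(out / "node_metrics.csv", "w") as f:
        f.write(_meta_header(seed, config))
        pd.DataFrame(node_rows).to_csv(f, index=False, float_format="%.17g")
    return out
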