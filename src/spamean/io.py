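"""Readers and writers: AnnData h5ad, MatrixMarket/CSV triplets, JSON reports.

All artifacts travel through :class:`~spamean.types.DatasetBundle`.
Expression is stored spots x genes (rows = spots). Spatial coordinates
live in an ``obsm`` slot (default key ``"spatial"``); a bundle without
coordinates is loadable for metric work but rejected by the imputer.
Writes are atomic: files are written to a temporary sibling and renamed.
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import anndata as ad
import scipy.sparse as sp

from .types import DatasetBundle, SpatialMap, SpotGeneMatrix

__all__ = [
    "read_h5ad",
    "write_h5ad",
    "read_tabular",
    "write_outputs",
    "bundle_to_anndata",
    "anndata_to_bundle",
]

SPATIAL_KEY = "spatial"
LABEL_KEY = "true_labels"


def _dense(X) -> np.ndarray:
    return np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X)


def anndata_to_bundle(
    adata: ad.AnnData,
    spatial_key: str = SPATIAL_KEY,
    label_key: str = LABEL_KEY,
    is_normalized: bool = False,
) -> DatasetBundle:
    """Materialize an AnnData object (sparse or dense X) into a bundle."""
    matrix = SpotGeneMatrix(
        _dense(adata.X),
        np.asarray(adata.obs_names, dtype=object),
        np.asarray(adata.var_names, dtype=object),
        is_normalized=is_normalized,
    )
    coords = None
    if spatial_key in adata.obsm:
        coords = SpatialMap(np.asarray(adata.obsm[spatial_key], dtype=float))
    labels = None
    if label_key in adata.obs:
        labels = np.asarray(adata.obs[label_key])
    layers = {name: _dense(layer) for name, layer in adata.layers.items()}
    return DatasetBundle(matrix=matrix, coords=coords, true_labels=labels,
                         layers=layers)


def bundle_to_anndata(
    bundle: DatasetBundle,
    spatial_key: str = SPATIAL_KEY,
    label_key: str = LABEL_KEY,
) -> ad.AnnData:
    adata = ad.AnnData(
        X=np.asarray(bundle.matrix.values, dtype=float),
        obs=pd.DataFrame(index=pd.Index(bundle.matrix.spot_ids, name="spot_id")),
        var=pd.DataFrame(index=pd.Index(bundle.matrix.gene_ids, name="gene_id")),
    )
    if bundle.coords is not None:
        adata.obsm[spatial_key] = bundle.coords.coords
    if bundle.true_labels is not None:
        adata.obs[label_key] = pd.Categorical(
            np.asarray(bundle.true_labels).astype(str)
        )
    for name, layer in bundle.layers.items():
        adata.layers[name] = np.asarray(layer, dtype=float)
    adata.uns["provenance"] = json.dumps(bundle.provenance)
    return adata


def read_h5ad(
    path: str | os.PathLike,
    spatial_key: str = SPATIAL_KEY,
    label_key: str = LABEL_KEY,
    is_normalized: bool = False,
) -> DatasetBundle:
    """Load a bundle from an h5ad file.

    Missing coordinates produce a coordinate-free bundle (accepted for
    metric computation, refused by :func:`spamean.impute.impute`).
    """
    adata = ad.read_h5ad(path)
    bundle = anndata_to_bundle(adata, spatial_key, label_key, is_normalized)
    bundle.log("read_h5ad", path=str(path))
    return bundle


def write_h5ad(bundle: DatasetBundle, path: str | os.PathLike,
               spatial_key: str = SPATIAL_KEY) -> Path:
    """Atomically write a bundle to h5ad (temp file + rename)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    adata = bundle_to_anndata(bundle, spatial_key)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".h5ad.tmp")
    os.close(fd)
    try:
        adata.write_h5ad(tmp)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)
    return path


def read_tabular(
    matrix_path: str | os.PathLike,
    coords_path: str | os.PathLike,
    labels_path: Optional[str | os.PathLike] = None,
) -> DatasetBundle:
    """Load a bundle from a matrix file plus coordinate (and label) CSVs.

    ``matrix_path`` is either a MatrixMarket ``.mtx`` (spots x genes, with
    optional ``<stem>_spots.txt`` / ``<stem>_genes.txt`` id sidecars) or a
    CSV with spot ids in the first column and gene ids in the header.
    ``coords_path`` is a CSV with columns ``spot_id,x,y``; an optional
    labels CSV has ``spot_id,label``. Spot order follows the matrix file;
    the other files are joined on ``spot_id``.
    """
    matrix_path = Path(matrix_path)
    if matrix_path.suffix == ".mtx":
        from scipy.io import mmread

        X = np.asarray(mmread(matrix_path).todense())
        spot_file = matrix_path.with_name(matrix_path.stem + "_spots.txt")
        gene_file = matrix_path.with_name(matrix_path.stem + "_genes.txt")
        if spot_file.exists():
            spot_ids = np.loadtxt(spot_file, dtype=str, ndmin=1).astype(object)
        else:
            spot_ids = np.array([f"spot_{i}" for i in range(X.shape[0])], dtype=object)
        if gene_file.exists():
            gene_ids = np.loadtxt(gene_file, dtype=str, ndmin=1).astype(object)
        else:
            gene_ids = np.array([f"gene_{j}" for j in range(X.shape[1])], dtype=object)
    else:
        df = pd.read_csv(matrix_path, index_col=0)
        X = df.to_numpy()
        spot_ids = df.index.to_numpy(dtype=object).astype(str).astype(object)
        gene_ids = df.columns.to_numpy(dtype=object).astype(str).astype(object)

    matrix = SpotGeneMatrix(X, spot_ids, gene_ids)

    coords_df = pd.read_csv(coords_path, dtype={"spot_id": str}).set_index("spot_id")
    missing = [s for s in matrix.spot_ids if s not in coords_df.index]
    if missing:
        raise ValueError(
            f"coordinates missing for spot ids (first few): {missing[:5]}"
        )
    coords = SpatialMap(
        coords_df.loc[list(matrix.spot_ids), ["x", "y"]].to_numpy(dtype=float)
    )

    labels = None
    if labels_path is not None:
        lab_df = pd.read_csv(labels_path, dtype={"spot_id": str}).set_index("spot_id")
        missing = [s for s in matrix.spot_ids if s not in lab_df.index]
        if missing:
            raise ValueError(
                f"labels missing for spot ids (first few): {missing[:5]}"
            )
        labels = lab_df.loc[list(matrix.spot_ids)].iloc[:, 0].to_numpy()

    bundle = DatasetBundle(matrix=matrix, coords=coords, true_labels=labels)
    bundle.log("read_tabular", matrix=str(matrix_path), coords=str(coords_path))
    return bundle


def _atomic_json(obj, path: Path) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".json.tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            json.dump(obj, fh, indent=2, sort_keys=True)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def write_outputs(
    bundle: DatasetBundle,
    report: dict,
    path_prefix: str | os.PathLike,
) -> dict[str, Path]:
    """Write ``<prefix>.h5ad`` and ``<prefix>.report.json`` atomically."""
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    h5ad_path = write_h5ad(bundle, prefix.with_suffix(".h5ad"))
    report_path = prefix.parent / (prefix.name + ".report.json")
    _atomic_json(report, report_path)
    return {"h5ad": h5ad_path, "report": report_path}
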