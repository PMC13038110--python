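"""Readers and writers for the interchange formats.

References travel either as an MTX triplet directory (``matrix.mtx`` +
``cells.tsv`` + ``genes.tsv``) or as an AnnData ``.h5ad`` container; bulk
matrices and survival tables as delimited text; deconvolution results as
delimited tables plus one combined HDF5 container.
"""

from __future__ import annotations

import json
from pathlib import Path

import anndata as ad
import h5py
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

__all__ = [
    "write_reference", "read_reference",
    "read_bulk", "write_bulk",
    "read_survival", "write_survival",
    "write_deconvolution", "read_deconvolution",
    "write_run_config",
]

_OBS_COLUMNS = ("cell_type", "condition", "split")


def write_reference(ref: ad.AnnData, path, fmt: str = "h5ad") -> Path:
    """Write a reference as ``.h5ad`` or as an MTX triplet directory."""
    path = Path(path)
    if fmt == "h5ad":
        out = ref.copy()
        out.uns = {k: v for k, v in ref.uns.items() if k != "markers_idx"}
        out.write_h5ad(path)
        return path
    if fmt == "mtx":
        path.mkdir(parents=True, exist_ok=True)
        X = ref.X
        spio.mmwrite(path / "matrix.mtx", sparse.csr_matrix(X))
        cols = [c for c in _OBS_COLUMNS if c in ref.obs.columns]
        ref.obs[cols].to_csv(path / "cells.tsv", sep="\t")
        pd.DataFrame(index=ref.var_names).to_csv(path / "genes.tsv", sep="\t")
        return path
    raise ValueError(f"unknown reference format {fmt!r}")


def _validate_reference(ref: ad.AnnData, label_column: str) -> ad.AnnData:
    if label_column not in ref.obs.columns:
        raise ValueError(f"reference is missing the {label_column!r} cell label column")
    if ref.var_names.duplicated().any():
        dup = ref.var_names[ref.var_names.duplicated()][0]
        raise ValueError(f"duplicate gene identifier {dup!r} in reference")
    X = ref.X.toarray() if sparse.issparse(ref.X) else np.asarray(ref.X)
    if not np.allclose(X, np.round(X)) or X.min() < 0:
        raise ValueError("reference counts must be non-negative integers")
    ref.X = X.astype(np.int32)
    if label_column != "cell_type":
        ref.obs["cell_type"] = ref.obs[label_column]
    if not isinstance(ref.obs["cell_type"].dtype, pd.CategoricalDtype):
        ref.obs["cell_type"] = pd.Categorical(ref.obs["cell_type"])
    return ref


def read_reference(path, label_column: str = "cell_type") -> ad.AnnData:
    """Read and validate a reference from ``.h5ad`` or an MTX triplet directory."""
    path = Path(path)
    if path.is_dir():
        mtx = path / "matrix.mtx"
        if not mtx.exists():
            raise FileNotFoundError(f"{path} has no matrix.mtx")
        X = sparse.csr_matrix(spio.mmread(mtx))
        obs = pd.read_csv(path / "cells.tsv", sep="\t", index_col=0)
        var = pd.read_csv(path / "genes.tsv", sep="\t", index_col=0)
        if X.shape != (obs.shape[0], var.shape[0]):
            raise ValueError(
                f"matrix shape {X.shape} does not match {obs.shape[0]} cells x "
                f"{var.shape[0]} genes in the metadata")
        obs.index = obs.index.astype(str)
        var.index = var.index.astype(str)
        ref = ad.AnnData(X=X.toarray(), obs=obs, var=var)
    else:
        ref = ad.read_h5ad(path)
    return _validate_reference(ref, label_column)


def read_bulk(path, normalize: bool = False) -> pd.DataFrame:
    """Read a genes x samples delimited matrix (TSV/CSV by extension)."""
    path = Path(path)
    sep = "," if path.suffix == ".csv" else "\t"
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    samples = header[1:]  # pandas mangles duplicate headers, so check the raw line
    dupes = pd.Index(samples)[pd.Index(samples).duplicated()]
    if len(dupes):
        raise ValueError(f"duplicate sample identifier {dupes[0]!r} in bulk matrix")
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate gene identifier {dup!r} in bulk matrix")
    if normalize:
        from .pseudobulk import normalize_log_cpm
        df = pd.DataFrame(normalize_log_cpm(df.to_numpy().T, axis=1).T,
                          index=df.index, columns=df.columns)
    return df


def write_bulk(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    sep = "," if path.suffix == ".csv" else "\t"
    df.to_csv(path, sep=sep)
    return path


def read_survival(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str})
    missing = {"patient_id", "time", "event"} - set(df.columns)
    if missing:
        raise ValueError(f"survival table is missing columns {sorted(missing)}")
    if df["patient_id"].duplicated().any():
        raise ValueError("duplicate patient_id in survival table")
    if (df["time"] < 0).any():
        raise ValueError("negative follow-up time in survival table")
    if not set(df["event"].unique()) <= {0, 1}:
        raise ValueError("event indicator must be 0/1")
    return df


def write_survival(df: pd.DataFrame, path) -> Path:
    df.to_csv(path, sep="\t", index=False)
    return Path(path)


def write_deconvolution(p_hat: np.ndarray, G_hat: np.ndarray, sample_ids,
                        gene_ids, cell_types, outdir) -> Path:
    """Write proportions (samples x types TSV), per-sample GEP TSVs, and a
    combined HDF5 container; column order follows the checkpoint's cell-type
    order."""
    outdir = Path(outdir)
    (outdir / "geps").mkdir(parents=True, exist_ok=True)
    props = pd.DataFrame(p_hat, index=pd.Index(sample_ids, name="sample"),
                         columns=cell_types)
    props.to_csv(outdir / "proportions.tsv", sep="\t")
    for i, sid in enumerate(sample_ids):
        pd.DataFrame(G_hat[i], index=pd.Index(gene_ids, name="gene"),
                     columns=cell_types).to_csv(
            outdir / "geps" / f"{sid}.tsv", sep="\t")
    with h5py.File(outdir / "deconvolution.h5", "w") as f:
        f.create_dataset("proportions", data=np.asarray(p_hat))
        f.create_dataset("geps", data=np.asarray(G_hat), compression="gzip")
        f.attrs["sample_ids"] = [str(s) for s in sample_ids]
        f.attrs["gene_ids"] = list(gene_ids)
        f.attrs["cell_types"] = list(cell_types)
    return outdir


def read_deconvolution(outdir):
    with h5py.File(Path(outdir) / "deconvolution.h5", "r") as f:
        return (f["proportions"][...], f["geps"][...],
                list(f.attrs["sample_ids"]), list(f.attrs["gene_ids"]),
                list(f.attrs["cell_types"]))


def write_run_config(outdir, **resolved) -> Path:
    """Record the fully resolved configuration and seed next to the outputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "run_config.json"
    path.write_text(json.dumps(resolved, indent=2, default=str) + "\n")
    return path
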