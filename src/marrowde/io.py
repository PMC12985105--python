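"""On-disk dataset format: Matrix Market counts plus TSV sidecars.

A dataset directory holds ``matrix.mtx`` (cells x features, 1-based
coordinate integer format), ``cells.tsv`` (cell_id, subject_id, batch,
cell_type, multiplet) and ``features.tsv`` (feature_id, modality). The pair
:func:`write_dataset` / :func:`read_dataset` round-trips an AnnData exactly.
"""

from __future__ import annotations

from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import FormatError

__all__ = ["write_dataset", "read_dataset"]


def write_dataset(adata: ad.AnnData, path: str | Path) -> Path:
    """Write counts + metadata to ``path`` (created if absent)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    X = adata.X if sp.issparse(adata.X) else sp.csr_matrix(adata.X)
    scipy.io.mmwrite(path / "matrix.mtx", X.astype(np.int64), field="integer")
    adata.obs.to_csv(path / "cells.tsv", sep="\t")
    adata.var.to_csv(path / "features.tsv", sep="\t")
    return path


def read_dataset(path: str | Path) -> ad.AnnData:
    """Read a dataset directory back into an AnnData of integer counts."""
    path = Path(path)
    mtx = path / "matrix.mtx"
    if not mtx.exists():
        raise FormatError(f"no matrix.mtx under {path}")
    try:
        X = scipy.io.mmread(mtx)
    except Exception as exc:  # scipy raises ValueError on malformed headers/coords
        raise FormatError(f"malformed Matrix Market file {mtx}: {exc}") from exc
    X = sp.csr_matrix(X)
    if (X.data < 0).any():
        raise FormatError(f"{mtx}: negative counts")
    obs = pd.read_csv(path / "cells.tsv", sep="\t", index_col=0)
    var = pd.read_csv(path / "features.tsv", sep="\t", index_col=0)
    if X.shape != (len(obs), len(var)):
        raise FormatError(
            f"matrix shape {X.shape} does not match sidecars ({len(obs)}, {len(var)})"
        )
    if "multiplet" in obs.columns:
        obs["multiplet"] = obs["multiplet"].astype(bool)
    obs.index = obs.index.astype(str)
    var.index = var.index.astype(str)
    return ad.AnnData(X=X.astype(np.int64), obs=obs, var=var)
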