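"""Subject-level pseudobulk track.

Counts are summed per (subject, cell type) unit, normalized to
log2(CPM + 1) over the modality panel, and each feature is fit by ordinary
least squares on the subject design (group + batch + other outcome) within
each cell type. Aggregation collapses the pseudo-replication of cells, at
the cost of power in a 14-subject cohort — which is why this track is used
as a direction/significance check against the mixed model rather than on
its own.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .cohort import CohortTable, ContrastSpec
from .mixedmodel import _drop_constant, build_design

__all__ = ["PseudobulkMatrix", "aggregate", "test_pseudobulk"]


@dataclass
class PseudobulkMatrix:
    """Summed counts per (subject, cell type) unit, with normalized values."""

    units: pd.DataFrame  # subject_id, cell_type, n_cells (included units)
    raw: pd.DataFrame  # units x features, integer sums
    normalized: pd.DataFrame  # units x features, log2(CPM + 1) per modality panel
    excluded: pd.DataFrame  # units dropped for having fewer than min_cells cells
    modality: pd.Series  # feature -> modality


def aggregate(matrix: ad.AnnData, min_cells: int = 3) -> PseudobulkMatrix:
    """Sum counts per (subject, cell type); drop and report units below ``min_cells``.

    CPM normalization uses the per-unit library size within each modality
    panel separately, so RNA and protein scales do not mix.
    """
    X = sp.csr_matrix(matrix.X)
    keys = pd.MultiIndex.from_frame(matrix.obs[["subject_id", "cell_type"]])
    codes, uniques = pd.factorize(keys)
    n_units = len(uniques)
    ind = sp.csr_matrix(
        (np.ones(len(codes)), (codes, np.arange(len(codes)))),
        shape=(n_units, len(codes)),
    )
    raw = np.asarray((ind @ X).todense()).astype(np.int64)
    n_cells = np.bincount(codes, minlength=n_units)
    units = pd.DataFrame(
        {
            "subject_id": [u[0] for u in uniques],
            "cell_type": [u[1] for u in uniques],
            "n_cells": n_cells,
        }
    )
    keep = units["n_cells"] >= min_cells
    modality = matrix.var["modality"]
    norm = np.zeros_like(raw, dtype=np.float64)
    for mod in modality.unique():
        cols = (modality == mod).to_numpy()
        lib = raw[:, cols].sum(axis=1, keepdims=True).astype(np.float64)
        with np.errstate(divide="ignore", invalid="ignore"):
            cpm = np.where(lib > 0, raw[:, cols] / lib * 1e6, 0.0)
        norm[:, cols] = np.log2(cpm + 1.0)
    idx = pd.MultiIndex.from_frame(units[["subject_id", "cell_type"]])
    raw_df = pd.DataFrame(raw, index=idx, columns=matrix.var.index)
    norm_df = pd.DataFrame(norm, index=idx, columns=matrix.var.index)
    return PseudobulkMatrix(
        units=units[keep].reset_index(drop=True),
        raw=raw_df[keep.to_numpy()],
        normalized=norm_df[keep.to_numpy()],
        excluded=units[~keep].reset_index(drop=True),
        modality=modality,
    )


def test_pseudobulk(
    pb: PseudobulkMatrix,
    cohort: CohortTable,
    contrast: ContrastSpec,
    modality: str = "rna",
    extra_factor: str | None = None,
) -> pd.DataFrame:
    """Per-feature OLS on normalized pseudobulk within each cell type.

    Two-sided t-test on the group coefficient; no multiplicity adjustment on
    this track (the consensus rule uses its raw p < 0.05). The solve is
    vectorized across features: one pseudoinverse per cell type applied to
    the whole response matrix.
    """
    cols = (pb.modality == modality).to_numpy()
    feats = pb.normalized.columns[cols]
    rows = []
    in_contrast = contrast.positive_group | contrast.negative_group
    for ct in sorted(pb.units["cell_type"].unique()):
        m = (pb.units["cell_type"] == ct) & pb.units["subject_id"].isin(in_contrast)
        subjects = pb.units.loc[m, "subject_id"].tolist()
        n_pos = len(set(subjects) & contrast.positive_group)
        n_neg = len(set(subjects) & contrast.negative_group)
        Y = pb.normalized.loc[
            list(zip(subjects, [ct] * len(subjects))), feats
        ].to_numpy()
        note = None
        if n_pos < 2 or n_neg < 2:
            note = "group_missing"
        else:
            X, names = build_design(cohort, contrast, subjects, extra_factor)
            X, names = _drop_constant(X, names)
            if contrast.variable not in names:
                note = "group_constant"
            elif len(subjects) <= X.shape[1] or np.linalg.matrix_rank(X) < X.shape[1]:
                note = "insufficient_subjects"
        if note is not None:
            for f in feats:
                rows.append(_pb_row(f, ct, contrast, modality, note=note,
                                    n_subjects=len(subjects)))
            continue
        k = names.index(contrast.variable)
        n, p = X.shape
        XtX_inv = np.linalg.inv(X.T @ X)
        B = XtX_inv @ X.T @ Y  # p x features
        resid = Y - X @ B
        dof = n - p
        s2 = (resid**2).sum(axis=0) / dof
        se = np.sqrt(s2 * XtX_inv[k, k])
        eff = B[k]
        # an exactly-fit response (zero residual variance up to round-off)
        # gives p = 1 for a zero effect and p -> 0 for a nonzero one
        scale = max(1.0, float((Y**2).mean())) if Y.size else 1.0
        exact = s2 < 1e-18 * scale
        eff = np.where(exact & (np.abs(eff) < 1e-8 * np.sqrt(scale)), 0.0, eff)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, eff / se, 0.0)
        pvals = 2.0 * stats.t.sf(np.abs(t), dof)
        pvals = np.where(exact, np.where(eff == 0.0, 1.0, 0.0), pvals)
        for fi, f in enumerate(feats):
            rows.append(
                _pb_row(f, ct, contrast, modality, effect=float(eff[fi]),
                        se=float(se[fi]), z=float(t[fi]), p=float(pvals[fi]),
                        converged=True, n_subjects=len(subjects))
            )
    out = pd.DataFrame(rows)
    out["track"] = "pseudobulk"
    return out


def _pb_row(f, ct, contrast, modality, effect=np.nan, se=np.nan, z=np.nan,
            p=np.nan, converged=False, note=None, n_subjects=0):
    return {
        "feature_id": f, "cell_type": ct, "contrast": contrast.variable,
        "modality": modality, "effect": effect, "se": se, "z": z, "p": p,
        "converged": converged, "note": note, "n_subjects": n_subjects,
    }
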