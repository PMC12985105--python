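"""Cell-type composition testing on logit-transformed proportions.

Per-subject cell-type proportions are smoothed with a half-count
pseudo-count, logit-transformed, and each cell type is fit by OLS with the
outcome of interest plus batch and the other outcome as covariates.
BH correction spans all cell types x both contrasts.
"""

from __future__ import annotations

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logit

from .cohort import CohortTable, ContrastSpec
from .errors import DesignError
from .mixedmodel import _drop_constant, bh_adjust, build_design

__all__ = ["subject_proportions", "test_composition", "composition_track"]


def subject_proportions(obs: pd.DataFrame | ad.AnnData) -> pd.DataFrame:
    """Subject x cell-type proportion table; rows sum to 1.

    Accepts cell metadata (with ``subject_id`` and ``cell_type`` columns) or
    an AnnData. Cell types absent from a subject appear as 0.
    """
    if isinstance(obs, ad.AnnData):
        obs = obs.obs
    counts = pd.crosstab(obs["subject_id"], obs["cell_type"])
    totals = counts.sum(axis=1)
    empty = totals == 0
    if empty.any():
        import warnings

        warnings.warn(f"subjects with no cells excluded: {list(counts.index[empty])}")
        counts = counts[~empty]
        totals = totals[~empty]
    return counts.div(totals, axis=0)


def test_composition(
    obs: pd.DataFrame | ad.AnnData,
    cohort: CohortTable,
    contrast: ContrastSpec,
    eps: float = 0.5,
) -> pd.DataFrame:
    """OLS on smoothed logit proportions per cell type, for one contrast.

    Smoothing uses p* = (k + eps) / (n + 2 eps) with k the subject's count of
    the type and n the subject's total, keeping the logit finite at k = 0 or
    k = n. q-values are assigned at the family level by
    :func:`composition_track`.
    """
    if isinstance(obs, ad.AnnData):
        obs = obs.obs
    counts = pd.crosstab(obs["subject_id"], obs["cell_type"])
    in_contrast = contrast.positive_group | contrast.negative_group
    counts = counts[counts.index.isin(in_contrast)]
    totals = counts.sum(axis=1)
    subjects = list(counts.index)
    if (
        len(set(subjects) & contrast.positive_group) < 2
        or len(set(subjects) & contrast.negative_group) < 2
    ):
        raise DesignError("fewer than 2 subjects per group with cells")
    smoothed = (counts + eps).div(totals + 2 * eps, axis=0)
    Y = logit(smoothed.to_numpy())
    X, names = build_design(cohort, contrast, subjects)
    X, names = _drop_constant(X, names)
    if np.linalg.matrix_rank(X) < X.shape[1] or len(subjects) <= X.shape[1]:
        raise DesignError("degenerate composition design")
    k = names.index(contrast.variable)
    XtX_inv = np.linalg.inv(X.T @ X)
    B = XtX_inv @ X.T @ Y
    resid = Y - X @ B
    dof = len(subjects) - X.shape[1]
    s2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(s2 * XtX_inv[k, k])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, B[k] / se, 0.0)
    p = np.where(se > 0, 2.0 * stats.t.sf(np.abs(t), dof), 1.0)
    return pd.DataFrame(
        {
            "cell_type": counts.columns,
            "contrast": contrast.variable,
            "effect": B[k],
            "se": se,
            "t": t,
            "p": p,
            "n_subjects": len(subjects),
        }
    )


def composition_track(
    obs: pd.DataFrame | ad.AnnData,
    cohort: CohortTable,
    contrasts: list[ContrastSpec],
    eps: float = 0.5,
) -> pd.DataFrame:
    """Both contrasts with BH over the cell types x contrasts family."""
    res = pd.concat(
        [test_composition(obs, cohort, c, eps=eps) for c in contrasts],
        ignore_index=True,
    )
    res["q"] = bh_adjust(res["p"].to_numpy())
    return res
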