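"""Confounder sensitivity of feature prioritization.

With 14 subjects, clinical covariates cannot all be modeled jointly.
Instead, each eligible clinical factor (minority pool > 3 subjects after
majority-vs-rest binarization) is added to the mixed model's fixed effects
one at a time, and the signed -log10 p vector over features is correlated
(Pearson by default) against the baseline fit, per cell type and modality.
A correlation near 1 means the factor barely moves the prioritization.
"""

from __future__ import annotations

import warnings

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortTable, ContrastSpec
from .consensus import signed_logp
from .mixedmodel import test_all_features

__all__ = ["robustness_scan", "correlate_signed_logp"]

_KEY = ["feature_id", "cell_type"]


def correlate_signed_logp(
    base: pd.DataFrame, augmented: pd.DataFrame, method: str = "pearson"
) -> pd.DataFrame:
    """Per-cell-type correlation of signed -log10 p between two fits.

    Only features testable (finite p) in BOTH fits enter the pair of
    vectors; cell types with fewer than 3 shared features are skipped.
    A pooled row (cell_type='_pooled') aggregates across all cell types.
    """
    b = base.set_index(_KEY)
    a = augmented.set_index(_KEY)
    shared = b.index.intersection(a.index)
    b, a = b.loc[shared], a.loc[shared]
    sb = pd.Series(signed_logp(b["p"].fillna(1), b["effect"].fillna(0)), index=shared)
    sa = pd.Series(signed_logp(a["p"].fillna(1), a["effect"].fillna(0)), index=shared)
    ok = b["p"].notna().to_numpy() & a["p"].notna().to_numpy()
    rows = []
    cts = sorted({ct for _, ct in shared})
    for ct in cts + ["_pooled"]:
        if ct == "_pooled":
            m = ok
        else:
            m = ok & (np.array([c for _, c in shared]) == ct)
        n = int(m.sum())
        if n < 3:
            continue
        x, y = sb.to_numpy()[m], sa.to_numpy()[m]
        if np.std(x) == 0 or np.std(y) == 0:
            r = np.nan
        elif method == "pearson":
            r = float(stats.pearsonr(x, y).statistic)
        elif method == "spearman":
            r = float(stats.spearmanr(x, y).statistic)
        else:
            raise ValueError(f"unknown correlation method {method!r}")
        rows.append({"cell_type": ct, "r": r, "n_features": n})
    return pd.DataFrame(rows, columns=["cell_type", "r", "n_features"])


def robustness_scan(
    matrix: ad.AnnData,
    cohort: CohortTable,
    contrast: ContrastSpec,
    factors: list[str],
    modality: str = "rna",
    base_results: pd.DataFrame | None = None,
    method: str = "pearson",
    **fit_kwargs,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Refit the mixed track once per clinical factor and correlate with baseline.

    Returns (correlations, scatter data). ``correlations`` has one row per
    factor x cell type (plus a pooled row); ``scatter`` maps factor ->
    per-feature signed -log10 p pairs so the with/without scatterplots can be
    drawn without refitting. Factors whose augmented design is singular in a
    cell type produce a warning and skip that cell type (the fitter flags
    those results untestable).
    """
    if base_results is None:
        base_results = test_all_features(
            matrix, cohort, contrast, modality=modality, **fit_kwargs
        )
    base = base_results[base_results["contrast"] == contrast.variable]
    corr_rows = []
    scatter: dict[str, pd.DataFrame] = {}
    for factor in factors:
        aug = test_all_features(
            matrix, cohort, contrast, modality=modality, extra_factor=factor,
            **fit_kwargs,
        )
        n_singular = (aug["note"] == "singular_design").sum()
        if n_singular:
            warnings.warn(
                f"factor {factor!r}: {n_singular} results with singular augmented design"
            )
        cors = correlate_signed_logp(base, aug, method=method)
        cors.insert(0, "clinical_factor", factor)
        cors["modality"] = modality
        cors["contrast"] = contrast.variable
        corr_rows.append(cors)
        merged = base.set_index(_KEY)[["p", "effect"]].join(
            aug.set_index(_KEY)[["p", "effect"]], lsuffix="_base", rsuffix="_aug",
            how="inner",
        )
        merged["signed_logp_base"] = signed_logp(
            merged["p_base"].fillna(1), merged["effect_base"].fillna(0)
        )
        merged["signed_logp_aug"] = signed_logp(
            merged["p_aug"].fillna(1), merged["effect_aug"].fillna(0)
        )
        scatter[factor] = merged.reset_index()
    corr = (
        pd.concat(corr_rows, ignore_index=True)
        if corr_rows
        else pd.DataFrame(
            columns=["clinical_factor", "cell_type", "r", "n_features",
                     "modality", "contrast"]
        )
    )
    return corr, scatter
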