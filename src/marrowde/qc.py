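"""Cell-level quality filters on the RNA panel.

Cells are dropped when flagged as multiplets (from sample-multiplexing
calls), when their total RNA UMI count or detected-gene count is below
threshold, or when their novelty score — log10(detected genes) /
log10(total UMI) — indicates a low-complexity cell. All metrics are
computed on RNA features only: the high-count protein tags would otherwise
dominate UMI totals and make the thresholds meaningless.

The printed threshold of 0.55 for "log10(number of genes per UMI)" only
makes sense for the ratio-of-logs form (the standard novelty score):
log10 of the raw ratio genes/UMI is nonpositive for every real cell, so a
0.55 cutoff on that reading would remove everything. The literal reading is
available via ``novelty_form="log_ratio"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = ["QCReport", "qc_filter"]

#: removal precedence: a cell is attributed to its first failing filter
FILTER_ORDER = ("multiplet", "min_umi", "min_genes", "min_novelty")


@dataclass
class QCReport:
    metrics: pd.DataFrame  # per input cell: total_umi, n_genes, novelty, removed_by
    removed: dict[str, int]  # per-filter removal counts
    surviving_cells: list[str]

    @property
    def n_input(self) -> int:
        return len(self.metrics)

    @property
    def n_removed(self) -> int:
        return sum(self.removed.values())

    def summary(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_removed": self.n_removed,
            "n_surviving": len(self.surviving_cells),
            "removed_by": dict(self.removed),
        }


def qc_filter(
    adata: ad.AnnData,
    min_umi: int = 50,
    min_genes: int = 35,
    min_novelty: float = 0.55,
    novelty_form: str = "ratio_of_logs",
) -> tuple[ad.AnnData, QCReport]:
    """Apply multiplet, UMI, gene-count and novelty filters; return survivors + report.

    Thresholds are exclusive lower bounds: a cell is removed when its metric
    is strictly below the threshold.
    """
    rna = (adata.var["modality"] == "rna").to_numpy()
    if rna.sum() == 0:
        raise ValidationError("qc_filter requires at least one RNA feature")
    X = adata[:, rna].X
    total_umi = np.asarray(X.sum(axis=1)).ravel()
    n_genes = np.asarray((X > 0).sum(axis=1)).ravel()
    with np.errstate(divide="ignore", invalid="ignore"):
        if novelty_form == "ratio_of_logs":
            novelty = np.where(
                total_umi > 1, np.log10(np.maximum(n_genes, 1)) / np.log10(total_umi), 0.0
            )
        elif novelty_form == "log_ratio":
            novelty = np.where(
                total_umi > 0, np.log10(np.maximum(n_genes, 1e-12) / total_umi), -np.inf
            )
        else:
            raise ValueError(f"unknown novelty_form {novelty_form!r}")

    multiplet = (
        adata.obs["multiplet"].to_numpy().astype(bool)
        if "multiplet" in adata.obs.columns
        else np.zeros(adata.n_obs, dtype=bool)
    )
    fails = {
        "multiplet": multiplet,
        "min_umi": total_umi < min_umi,
        "min_genes": n_genes < min_genes,
        "min_novelty": novelty < min_novelty,
    }
    removed_by = np.full(adata.n_obs, "", dtype=object)
    for name in FILTER_ORDER:
        hit = fails[name] & (removed_by == "")
        removed_by[hit] = name

    metrics = pd.DataFrame(
        {
            "total_umi": total_umi.astype(int),
            "n_genes": n_genes.astype(int),
            "novelty": novelty,
            "removed_by": removed_by,
        },
        index=adata.obs.index,
    )
    keep = removed_by == ""
    report = QCReport(
        metrics=metrics,
        removed={name: int((removed_by == name).sum()) for name in FILTER_ORDER},
        surviving_cells=list(adata.obs.index[keep]),
    )
    return adata[keep].copy(), report
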