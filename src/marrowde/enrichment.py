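"""Geneset over-representation against the measured-panel background.

The measured panel is a few hundred targeted genes, not the genome, so the
enrichment universe is the panel itself and findings are highlighted at a
nominal one-sided Fisher p < 0.05 without multiplicity adjustment — the
targeted design leaves too little power for FDR control to be informative.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FormatError

__all__ = ["read_gmt", "fisher_enrichment", "enrich_calls"]


def read_gmt(path: str | Path, panel: set[str] | list[str]) -> dict[str, set[str]]:
    """Parse a GMT file, restricting every set to the measured panel.

    Lines are name<TAB>description<TAB>member... Members are deduplicated;
    sets empty after intersection with the panel are dropped with a warning.
    """
    panel = set(panel)
    sets: dict[str, set[str]] = {}
    path = Path(path)
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError(
                f"{path}:{lineno}: GMT line needs name, description and >=1 member"
            )
        name, members = parts[0], set(parts[2:]) - {""}
        if not members:
            raise FormatError(f"{path}:{lineno}: geneset {name!r} has no members")
        on_panel = members & panel
        if not on_panel:
            warnings.warn(f"geneset {name!r} has no members on the panel; dropped")
            continue
        sets[name] = on_panel
    return sets


def fisher_enrichment(
    deg_set: set[str], geneset: set[str], panel: set[str] | list[str]
) -> dict:
    """One-sided (greater) Fisher exact test for DEG/geneset overlap.

    The p-value is the upper hypergeometric tail P(X >= overlap) with the
    panel as universe. Returns the 2x2 table, odds ratio, p and the
    nominal-0.05 highlight flag.
    """
    panel = set(panel)
    deg_set = set(deg_set) & panel
    geneset = set(geneset) & panel
    a = len(deg_set & geneset)  # DE and in set
    b = len(deg_set - geneset)
    c = len(geneset - deg_set)
    d = len(panel) - a - b - c
    # P(X >= a), X ~ Hypergeom(N=panel, K=geneset, n=DEGs)
    p = float(stats.hypergeom.sf(a - 1, a + b + c + d, a + c, a + b))
    odds = (a * d) / (b * c) if b * c > 0 else np.inf if a * d > 0 else np.nan
    return {
        "n_overlap": a,
        "n_de_only": b,
        "n_set_only": c,
        "n_neither": d,
        "odds_ratio": odds,
        "p": min(p, 1.0),
        "highlighted": p < 0.05,
    }


def enrich_calls(
    calls: pd.DataFrame,
    genesets: dict[str, set[str]],
    panel: set[str] | list[str],
    modality: str = "rna",
) -> pd.DataFrame:
    """Enrichment of consensus-called features per (cell type, contrast)."""
    rows = []
    sub = calls[calls["modality"] == modality]
    for (contrast, ct), grp in sub.groupby(["contrast", "cell_type"], sort=True):
        degs = set(grp.loc[grp["called"].astype(bool), "feature_id"])
        if not degs:
            continue
        for name, members in genesets.items():
            res = fisher_enrichment(degs, members, panel)
            rows.append(
                {"geneset": name, "cell_type": ct, "contrast": contrast,
                 "n_de": len(degs), **res}
            )
    cols = ["geneset", "cell_type", "contrast", "n_de", "n_overlap", "n_de_only",
            "n_set_only", "n_neither", "odds_ratio", "p", "highlighted"]
    return pd.DataFrame(rows, columns=cols)
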