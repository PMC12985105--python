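"""Consensus differential calls across the two analysis tracks.

A feature is declared differential for a contrast within a cell type only
when all three conditions hold:

1. its mixed-model q-value passes FDR at alpha (BH over the full family);
2. its pseudobulk p-value is below 0.05;
3. the two tracks agree on the direction of effect.

Mixed models on per-cell counts can show inflated false discovery at small
subject numbers; requiring the conservative subject-level track to agree in
significance and sign trims those calls. Reporting uses the signed
-log10 p of the mixed track.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = ["call_consensus", "signed_logp", "consensus_matrix"]

_KEY = ["feature_id", "cell_type", "contrast", "modality"]
P_FLOOR = 1e-300


def signed_logp(p, effect) -> np.ndarray:
    """sign(effect) * -log10(p), elementwise; zero effect or p=1 maps to 0."""
    p = np.asarray(p, dtype=np.float64)
    effect = np.asarray(effect, dtype=np.float64)
    logp = -np.log10(np.maximum(p, P_FLOOR))
    return np.sign(effect) * logp


def call_consensus(
    mixed: pd.DataFrame, pb: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Three-condition conjunction of the two tracks, keyed per feature/cell type.

    Entries untestable in either track are never called; the blocking reason
    is recorded. Raises if the two tracks disagree on the tested keys.
    """
    m = mixed.set_index(_KEY)
    b = pb.set_index(_KEY)
    if m.index.has_duplicates or b.index.has_duplicates:
        raise ValidationError("duplicate (feature, cell type, contrast, modality) keys")
    if set(m.index) != set(b.index):
        raise ValidationError(
            "mixed and pseudobulk tracks are keyed on different results"
        )
    b = b.loc[m.index]
    out = pd.DataFrame(index=m.index)
    m_ok = m["p"].notna()
    b_ok = b["p"].notna()
    out["cond1_fdr_pass"] = (m["q"] < alpha).fillna(False) & m_ok
    out["cond2_pb_pass"] = (b["p"] < 0.05).fillna(False) & b_ok
    # strict sign agreement: a zero effect on either track fails
    out["cond3_direction_pass"] = (
        m_ok & b_ok & (np.sign(m["effect"]) * np.sign(b["effect"]) > 0)
    )
    out["called"] = (
        out["cond1_fdr_pass"] & out["cond2_pb_pass"] & out["cond3_direction_pass"]
    )
    out["signed_logp"] = signed_logp(m["p"].fillna(1.0), m["effect"].fillna(0.0))
    out.loc[~m_ok, "signed_logp"] = np.nan
    out["mixed_q"] = m["q"]
    out["mixed_effect"] = m["effect"]
    out["pb_p"] = b["p"]
    out["pb_effect"] = b["effect"]
    reason = np.where(m["note"].notna(), "mixed:" + m["note"].astype(str), "")
    reason2 = np.where(b["note"].notna(), "pb:" + b["note"].astype(str), "")
    out["note"] = pd.Series(reason, index=out.index).str.cat(
        pd.Series(reason2, index=out.index), sep=";"
    ).str.strip(";")
    out.loc[out["note"] == "", "note"] = None
    return out.reset_index()


def consensus_matrix(
    calls: pd.DataFrame, contrast: str, modality: str
) -> pd.DataFrame:
    """Heatmap-ready cell types x features matrix of signed -log10 p.

    Called entries are marked by appending '*' in a parallel annotation
    matrix stored in ``attrs['called']``.
    """
    sub = calls[(calls["contrast"] == contrast) & (calls["modality"] == modality)]
    mat = sub.pivot(index="cell_type", columns="feature_id", values="signed_logp")
    star = sub.pivot(index="cell_type", columns="feature_id", values="called")
    mat.attrs["called"] = star.fillna(False)
    return mat
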