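"""QC filter thresholds, accounting, idempotence and monotonicity."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import marrowde as m
from marrowde.errors import ValidationError


def _cell(total_umi: int, n_genes: int, n_feat: int = 100) -> np.ndarray:
    """A count vector with exactly the requested UMI total and detected genes."""
    v = np.zeros(n_feat, dtype=np.int64)
    v[: n_genes - 1] = 1
    v[n_genes - 1] = total_umi - (n_genes - 1)
    return v


def _adata(rows, multiplet=None):
    X = sp.csr_matrix(np.vstack(rows))
    n = X.shape[0]
    obs = pd.DataFrame(
        {
            "subject_id": ["s1"] * n,
            "batch": ["b1"] * n,
            "cell_type": ["t1"] * n,
            "multiplet": multiplet if multiplet is not None else [False] * n,
        },
        index=pd.Index([f"c{i}" for i in range(n)], name="cell_id"),
    )
    var = pd.DataFrame(
        {"modality": ["rna"] * X.shape[1]},
        index=pd.Index([f"g{i}" for i in range(X.shape[1])], name="feature_id"),
    )
    return ad.AnnData(X=X, obs=obs, var=var)


@pytest.mark.parametrize(
    "umi,genes,expected_filter",
    [
        (49, 40, "min_umi"),  # one UMI under the cutoff
        (50, 40, None),  # exactly at the cutoff survives
        (600, 34, "min_genes"),  # novelty 0.551 passes; gene count one short
        (600, 35, None),
        (100, 10, "min_genes"),  # gene filter claims the cell before novelty
        (3000, 81, "min_novelty"),  # novelty 0.549
        (3000, 83, None),  # novelty 0.551
    ],
)
def test_threshold_boundaries(umi, genes, expected_filter):
    adata = _adata([_cell(umi, genes)])
    filtered, report = m.qc_filter(adata)
    assert report.metrics["removed_by"].iloc[0] == (expected_filter or "")
    assert filtered.n_obs == (0 if expected_filter else 1)


def test_low_complexity_cell_caught_by_novelty():
    """UMI=100 with 10 genes: novelty log10(10)/log10(100) = 0.5 < 0.55."""
    adata = _adata([_cell(100, 10)])
    _, report = m.qc_filter(adata, min_genes=5)  # let the novelty filter decide
    assert report.metrics["novelty"].iloc[0] == pytest.approx(0.5)
    assert report.metrics["removed_by"].iloc[0] == "min_novelty"


def test_multiplet_removed_first():
    adata = _adata([_cell(10, 5)], multiplet=[True])  # would fail UMI too
    _, report = m.qc_filter(adata)
    assert report.removed == {"multiplet": 1, "min_umi": 0, "min_genes": 0,
                              "min_novelty": 0}


def test_report_accounts_for_every_cell():
    rows = [_cell(49, 40), _cell(5000, 90), _cell(1000, 34), _cell(100, 10)]
    _, report = m.qc_filter(_adata(rows))
    assert report.n_removed + len(report.surviving_cells) == report.n_input == 4


def test_zero_rna_features_rejected():
    adata = _adata([_cell(100, 50)])
    adata.var["modality"] = "protein"
    with pytest.raises(ValidationError):
        m.qc_filter(adata)


def test_protein_counts_do_not_rescue_low_rna_cells():
    adata = _adata([_cell(30, 20, n_feat=100)])
    adata.var.iloc[90:, 0] = "protein"  # move some features to the ADT panel
    X = adata.X.tolil()
    X[0, 95] = 10_000
    adata.X = X.tocsr()
    _, report = m.qc_filter(adata)
    assert report.metrics["removed_by"].iloc[0] == "min_umi"


def test_idempotence(small_sim):
    _, _, adata, _ = small_sim
    once, _ = m.qc_filter(adata, min_umi=10, min_genes=5, min_novelty=0.3)
    twice, rep2 = m.qc_filter(once, min_umi=10, min_genes=5, min_novelty=0.3)
    assert list(once.obs.index) == list(twice.obs.index)
    assert rep2.n_removed == 0


def test_raising_thresholds_never_adds_survivors(small_sim):
    _, _, adata, _ = small_sim
    base, _ = m.qc_filter(adata, min_umi=10, min_genes=5, min_novelty=0.3)
    for kw in ({"min_umi": 20}, {"min_genes": 8}, {"min_novelty": 0.5}):
        stricter, _ = m.qc_filter(adata, **{"min_umi": 10, "min_genes": 5,
                                            "min_novelty": 0.3, **kw})
        assert set(stricter.obs.index) <= set(base.obs.index)


def test_generator_flagged_cells_all_removed_at_matching_thresholds():
    cfg = m.SimConfig(
        n_subjects=4, n_cell_types=2, n_rna=397, n_protein=5,
        cells_per_subject=(60, 80), outcome_crosstab=(1, 1, 1, 1),
        qc_fail_fraction=0.1, multiplet_fraction=0.05, seed=13,
    )
    _, adata, truth = m.simulate_cohort(cfg)
    _, report = m.qc_filter(adata)
    removed = set(adata.obs.index) - set(report.surviving_cells)
    assert set(adata.obs.index[truth.qc_fail]) <= removed
    assert set(adata.obs.index[truth.multiplet]) <= removed


def test_literal_log_ratio_form_available():
    adata = _adata([_cell(100, 50)])
    filtered, _ = m.qc_filter(adata, min_novelty=-1.0, novelty_form="log_ratio")
    assert filtered.n_obs == 1  # log10(50/100) ~ -0.3 > -1
    filtered, _ = m.qc_filter(adata, novelty_form="log_ratio")
    assert filtered.n_obs == 0  # the printed 0.55 removes everything
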