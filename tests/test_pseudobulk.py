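"""Pseudobulk aggregation exactness and the subject-level regression track."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import marrowde as m
from marrowde.mixedmodel import build_design, _drop_constant


def test_two_cell_sum():
    import anndata as ad
    import scipy.sparse as sp

    X = sp.csr_matrix(np.array([[3], [4]], dtype=np.int64))
    obs = pd.DataFrame(
        {"subject_id": ["s1", "s1"], "cell_type": ["t1", "t1"]},
        index=["c1", "c2"],
    )
    var = pd.DataFrame({"modality": ["rna"]}, index=["g1"])
    pb = m.aggregate(ad.AnnData(X=X, obs=obs, var=var), min_cells=1)
    assert pb.raw.loc[("s1", "t1"), "g1"] == 7


def test_min_cells_units_excluded_and_reported(small_sim):
    _, _, adata, _ = small_sim
    pb = m.aggregate(adata, min_cells=30)
    assert len(pb.excluded) > 0
    assert (pb.excluded["n_cells"] < 30).all()
    assert (pb.units["n_cells"] >= 30).all()


def test_sums_match_brute_force_loop(small_sim):
    _, _, adata, _ = small_sim
    pb = m.aggregate(adata, min_cells=1)
    X = np.asarray(adata.X.todense())
    rng = np.random.default_rng(1)
    units = pb.raw.index.tolist()
    for s, ct in [units[i] for i in rng.choice(len(units), 5, replace=False)]:
        mask = (
            (adata.obs.subject_id == s) & (adata.obs.cell_type == ct)
        ).to_numpy()
        np.testing.assert_array_equal(pb.raw.loc[(s, ct)].to_numpy(),
                                      X[mask].sum(axis=0))


def test_total_count_conservation(small_sim):
    _, _, adata, _ = small_sim
    pb = m.aggregate(adata, min_cells=1)
    assert pb.raw.to_numpy().sum() == adata.X.sum()


def test_equal_response_gives_zero_effect_p_one(cohort):
    import anndata as ad
    import scipy.sparse as sp

    subjects = cohort.subjects
    X = sp.csr_matrix(np.full((14, 2), 5, dtype=np.int64))
    obs = pd.DataFrame(
        {"subject_id": subjects, "cell_type": ["t1"] * 14}, index=subjects
    )
    var = pd.DataFrame({"modality": ["rna", "rna"]}, index=["g1", "g2"])
    pb = m.aggregate(ad.AnnData(X=X, obs=obs, var=var), min_cells=1)
    res = m.test_pseudobulk(pb, cohort, m.build_contrast(cohort, "cgvhd"))
    assert np.allclose(res.effect, 0.0)
    assert np.allclose(res.p, 1.0)


def test_separation_gives_positive_effect_small_p(cohort):
    import anndata as ad
    import scipy.sparse as sp

    cg = m.build_contrast(cohort, "cgvhd")
    subjects = cohort.subjects
    counts = np.array(
        [[1000 if s in cg.positive_group else 10, 500] for s in subjects],
        dtype=np.int64,
    )
    obs = pd.DataFrame(
        {"subject_id": subjects, "cell_type": ["t1"] * 14}, index=subjects
    )
    var = pd.DataFrame({"modality": ["rna", "rna"]}, index=["g1", "g2"])
    pb = m.aggregate(ad.AnnData(X=sp.csr_matrix(counts), obs=obs, var=var),
                     min_cells=1)
    res = m.test_pseudobulk(pb, cohort, cg).set_index("feature_id")
    assert res.loc["g1", "effect"] > 0
    assert res.loc["g1", "p"] < 0.01


def test_matches_statsmodels_ols_per_feature(effect_sim, effect_sim_results):
    _, cohort, adata, _ = effect_sim
    _, _, _, pbres, _ = effect_sim_results
    cg = m.build_contrast(cohort, "cgvhd")
    pb = m.aggregate(adata)
    sub = pbres[(pbres.contrast == "cgvhd") & pbres.p.notna()]
    picks = sub.sample(5, random_state=0)
    for _, row in picks.iterrows():
        units = pb.units[pb.units.cell_type == row.cell_type]
        subjects = units.subject_id.tolist()
        y = pb.normalized.loc[
            list(zip(subjects, [row.cell_type] * len(subjects))), row.feature_id
        ].to_numpy()
        X, names = build_design(cohort, cg, subjects)
        X, names = _drop_constant(X, names)
        ols = sm.OLS(y, X).fit()
        k = names.index("cgvhd")
        assert row.effect == pytest.approx(ols.params[k], rel=1e-8, abs=1e-10)
        assert row.p == pytest.approx(ols.pvalues[k], rel=1e-6, abs=1e-12)


def test_recovers_injected_lfc_on_average(effect_sim_results):
    """Estimated pseudobulk log2 effects scale to the true natural-log LFC."""
    _, truth, _, pbres, _ = effect_sim_results
    mrg = truth.de_effects.merge(
        pbres, on=["contrast", "cell_type", "feature_id"], how="inner"
    ).dropna(subset=["p"])
    # track fits on log2(CPM+1); convert back to natural log for comparison
    est_ln = mrg.effect * np.log(2.0)
    bias = (est_ln * np.sign(mrg.lfc)).mean() - 1.5
    assert abs(bias) < 0.25


def test_track_signs_agree_on_strong_effects(effect_sim_results):
    _, truth, mixed, pbres, calls = effect_sim_results
    key = ["contrast", "cell_type", "feature_id"]
    true_de = truth.de_effects.merge(calls, on=key).dropna(subset=["mixed_q"])
    strong = true_de[(true_de.mixed_q < 0.05) & (true_de.pb_p < 0.05)]
    agree = np.sign(strong.mixed_effect) == np.sign(strong.pb_effect)
    assert agree.mean() > 0.95
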