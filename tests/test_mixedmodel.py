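"""NB mixed-model fitter: closed-form cases, oracles, recovery, BH adjustment."""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

import marrowde as m
from marrowde.errors import DesignError, ValidationError
from marrowde.mixedmodel import bh_adjust, fit_nbmm


def _nb_data(rng, n_subjects=10, cells=400, beta=(0.5, 0.8), phi=0.5, sigma=0.0):
    subj = np.repeat(np.arange(n_subjects), cells)
    x = (subj % 2).astype(float)
    X = np.column_stack([np.ones(len(subj)), x])
    offset = rng.normal(0, 0.3, len(subj))
    u = rng.normal(0, sigma, n_subjects)
    mu = np.exp(beta[0] + beta[1] * x + offset + u[subj])
    r = 1.0 / phi
    y = rng.negative_binomial(r, r / (r + mu))
    return y, X, offset, subj


class TestFitNBMM:
    def test_constant_counts_intercept_only(self):
        """All counts equal c with zero offset: the NB mean MLE is log c."""
        y = np.full(200, 7.0)
        X = np.ones((200, 1))
        fit = fit_nbmm(y, X, np.zeros(200), np.repeat(np.arange(4), 50))
        assert fit.beta[0] == pytest.approx(np.log(7.0), abs=1e-4)

    def test_matches_nb_glm_when_no_subject_variance(self, rng):
        """sigma^2 = 0 data: marginal MLE must coincide with a plain NB GLM."""
        y, X, off, subj = _nb_data(rng)
        fit = fit_nbmm(y, X, off, subj)
        glm = sm.NegativeBinomial(y, X, offset=off).fit(disp=0)
        np.testing.assert_allclose(fit.beta, glm.params[:2], atol=1e-3)
        assert fit.phi == pytest.approx(glm.params[-1], abs=1e-3)
        assert fit.sigma2 < 1e-4

    def test_quadrature_node_doubling_stable(self, rng):
        y, X, off, subj = _nb_data(rng, sigma=0.5)
        f10 = fit_nbmm(y, X, off, subj, n_quad=10)
        f20 = fit_nbmm(y, X, off, subj, n_quad=20)
        assert np.max(np.abs(f10.beta - f20.beta)) < 1e-4

    def test_poisson_data_gives_small_dispersion(self):
        rng = np.random.default_rng(31)
        subj = np.repeat(np.arange(10), 500)
        x = (subj % 2).astype(float)
        X = np.column_stack([np.ones(5000), x])
        mu = np.exp(0.5 + 0.5 * x)
        y = rng.poisson(mu)
        fit = fit_nbmm(y, X, np.zeros(5000), subj)
        assert fit.phi < 0.05

    def test_sigma_recovery(self):
        """Subject SD 0.5, 14 subjects x 200 cells: mean estimate within 0.2."""
        rng = np.random.default_rng(100)
        est = []
        for _ in range(50):
            y, X, off, subj = _nb_data(rng, n_subjects=14, cells=200, sigma=0.5)
            est.append(np.sqrt(fit_nbmm(y, X, off, subj).sigma2))
        assert abs(np.mean(est) - 0.5) < 0.2

    def test_likelihood_not_below_no_random_effect_solution(self, rng):
        """The free-sigma optimum can only improve on the sigma^2 = 0 fit."""
        y, X, off, subj = _nb_data(rng, sigma=0.4)
        free = fit_nbmm(y, X, off, subj)
        glm = sm.NegativeBinomial(y, X, offset=off).fit(disp=0)
        assert free.loglik >= glm.llf - 1e-6

    def test_singular_design_rejected(self, rng):
        y, X, off, subj = _nb_data(rng)
        X2 = np.column_stack([X, X[:, 1]])
        with pytest.raises(DesignError):
            fit_nbmm(y, X2, off, subj)


class TestTestAllFeatures:
    def test_all_zero_feature_marked_untestable(self, small_sim):
        _, cohort, adata, _ = small_sim
        adata = adata.copy()
        X = adata.X.tolil()
        X[:, 0] = 0
        adata.X = X.tocsr()
        res = m.test_all_features(
            adata, cohort, m.build_contrast(cohort, "cgvhd"),
            modality="rna", min_cells=10,
        )
        first = res[res.feature_id == adata.var.index[0]]
        assert (first.note == "low_expression").all()
        assert first.p.isna().all()

    def test_cell_type_absent_from_one_group_flagged(self, small_sim):
        _, cohort, adata, _ = small_sim
        cg = m.build_contrast(cohort, "cgvhd")
        # drop every positive-group cell of one type
        drop = adata.obs.subject_id.isin(cg.positive_group) & (
            adata.obs.cell_type == "ct01"
        )
        res = m.test_all_features(
            adata[~drop.to_numpy()].copy(), cohort, cg, modality="rna", min_cells=10
        )
        assert (res.loc[res.cell_type == "ct01", "note"] == "group_missing").all()

    def test_effect_sign_follows_true_direction(self, effect_sim_results):
        _, truth, mixed, _, _ = effect_sim_results
        de = truth.de_effects.merge(
            mixed, on=["contrast", "cell_type", "feature_id"], how="inner"
        ).dropna(subset=["p"])
        strong = de[de.q < 0.05]
        agree = np.sign(strong.lfc) == np.sign(strong.effect)
        assert agree.mean() > 0.95


class TestBHAdjust:
    def test_worked_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p(self):
        assert bh_adjust([0.05])[0] == pytest.approx(0.05)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.2])

    def test_nan_excluded_from_family(self):
        q = bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(q[1])
        np.testing.assert_allclose(q[[0, 2]], bh_adjust([0.01, 0.04]))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    def test_matches_brute_force_definition(self, ps):
        """q_i = min over j with p_(j) >= p_i of m p_(j) / rank(j), capped at 1."""
        p = np.array(ps)
        q = bh_adjust(p)
        order = np.argsort(p, kind="stable")
        msort = p[order]
        n = len(p)
        brute = np.empty(n)
        for i in range(n):
            brute[i] = min(min(n * msort[j] / (j + 1) for j in range(i, n)), 1.0)
        expected = np.empty(n)
        expected[order] = brute
        np.testing.assert_allclose(q, expected, atol=1e-12)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_statsmodels(self, seed):
        p = np.random.default_rng(seed).random(40)
        np.testing.assert_allclose(
            bh_adjust(p), multipletests(p, method="fdr_bh")[1], atol=1e-12
        )

    def test_q_never_below_p(self, effect_sim_results):
        _, _, mixed, _, _ = effect_sim_results
        ok = mixed.p.notna()
        assert (mixed.q[ok] >= mixed.p[ok] - 1e-12).all()
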