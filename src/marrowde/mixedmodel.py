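"""Per-cell negative-binomial mixed model track.

For each (feature, cell type) the per-cell counts are modeled as

    y_ij | u_j ~ NB(mu_ij, phi),   log mu_ij = x_ij' beta + offset_ij + u_j,
    u_j ~ Normal(0, sigma^2),      Var(y|u) = mu + phi mu^2,

where j indexes subjects: the random intercept absorbs within-subject
correlation, which a plain GLM on pooled cells would ignore (pseudo-
replication). The marginal likelihood factorizes over subjects; each
one-dimensional integral is evaluated by adaptive Gauss-Hermite quadrature
centred and scaled at the per-subject posterior mode. (beta, log phi,
log sigma^2) are jointly maximized by bounded quasi-Newton, initialized from
a Poisson GLM; Wald tests on the group coefficient give per-feature p-values,
adjusted by Benjamini-Hochberg over the full declared family (all features x
cell types x both contrasts, separately per modality).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from numpy.polynomial.hermite_e import hermegauss
from scipy import optimize, special, stats

from .cohort import CohortTable, ContrastSpec, binarize_factor
from .errors import DesignError, ValidationError

__all__ = ["NBMMFit", "fit_nbmm", "test_all_features", "mixed_track", "bh_adjust"]

_LOG_SIGMA2_MIN = np.log(1e-8)
_LOG_SIGMA2_MAX = np.log(25.0)
_LOG_PHI_MIN = np.log(1e-4)
_LOG_PHI_MAX = np.log(100.0)


@dataclass
class NBMMFit:
    beta: np.ndarray
    se: np.ndarray
    cov_beta: np.ndarray
    sigma2: float
    phi: float
    loglik: float
    converged: bool
    boundary_sigma: bool  # sigma^2 estimate pinned at (numerical) zero
    n_iter: int
    colnames: list[str]

    def wald(self, k: int) -> tuple[float, float, float]:
        """(z, p, effect) for coefficient ``k``."""
        se = self.se[k]
        if not np.isfinite(se) or se <= 0:
            return np.nan, np.nan, float(self.beta[k])
        z = float(self.beta[k] / se)
        return z, float(2.0 * stats.norm.sf(abs(z))), float(self.beta[k])


class _Marginal:
    """Negative marginal log-likelihood with per-subject AGQ; caches modes."""

    def __init__(self, y, X, offset, subj_codes, n_subjects, n_quad):
        self.y = y.astype(np.float64)
        self.X = X
        self.offset = offset
        self.s = subj_codes
        self.J = n_subjects
        z, w = hermegauss(n_quad)  # nodes/weights for weight e^{-z^2/2}
        self.z = z
        self.logw = np.log(w)
        self.u_hat = np.zeros(n_subjects)
        self._lgam_y1 = special.gammaln(self.y + 1.0)
        self._const_r = None

    def _cell_ll_parts(self, r):
        # parts independent of u: lgamma(y+r) - lgamma(r) - lgamma(y+1) + r log r
        if self._const_r is not None and self._const_r[0] == r:
            return self._const_r[1]
        const = (
            special.gammaln(self.y + r)
            - special.gammaln(r)
            - self._lgam_y1
            + r * np.log(r)
        )
        self._const_r = (r, const)
        return const

    def _subject_ll(self, eta0, r, u, const):
        """Sum_j of cell log-likelihoods at subject offsets ``u`` (J,)."""
        eta = eta0 + u[self.s]
        # y*eta - (y+r)*log(r + e^eta), stabilized via logaddexp
        t = self.y * eta - (self.y + r) * np.logaddexp(np.log(r), eta)
        return np.bincount(self.s, weights=const + t, minlength=self.J)

    def _find_modes(self, eta0, r, sigma2):
        u = self.u_hat.copy()
        for _ in range(50):
            mu = np.exp(np.clip(eta0 + u[self.s], -700, 700))
            frac = mu / (r + mu)
            g = np.bincount(self.s, weights=self.y - (self.y + r) * frac, minlength=self.J)
            g -= u / sigma2
            h = np.bincount(
                self.s, weights=(self.y + r) * r * frac / (r + mu), minlength=self.J
            )
            h += 1.0 / sigma2
            step = g / h
            np.clip(step, -4.0, 4.0, out=step)
            u += step
            if np.max(np.abs(step)) < 1e-9:
                break
        self.u_hat = u
        return u, h  # h = negative Hessian (positive)

    def nll(self, theta):
        p = self.X.shape[1]
        beta = theta[:p]
        phi = np.exp(theta[p])
        sigma2 = np.exp(theta[p + 1])
        r = 1.0 / phi
        eta0 = self.X @ beta + self.offset
        const = self._cell_ll_parts(r)
        u_hat, neg_hess = self._find_modes(eta0, r, sigma2)
        tau = 1.0 / np.sqrt(neg_hess)
        # adaptive nodes u_jk = u_hat_j + tau_j z_k; Gauss-Hermite (probabilists')
        ll_nodes = np.empty((len(self.z), self.J))
        for k, zk in enumerate(self.z):
            u_k = u_hat + tau * zk
            ll_nodes[k] = (
                self._subject_ll(eta0, r, u_k, const)
                - 0.5 * u_k**2 / sigma2
                + 0.5 * zk**2
            )
        ll_j = special.logsumexp(ll_nodes + self.logw[:, None], axis=0)
        ll_j += np.log(tau) - 0.5 * np.log(2.0 * np.pi * sigma2)
        return -float(ll_j.sum())

    def nll_grad(self, theta):
        """(nll, gradient). Gradients for beta and log phi are the posterior
        expectations of the joint-likelihood score evaluated on the quadrature
        grid (exact for beta/phi at the mode by the envelope property); the
        log sigma^2 component is a central finite difference, since the node
        locations' own sigma^2 dependence is first-order there."""
        p = self.X.shape[1]
        beta = theta[:p]
        phi = np.exp(theta[p])
        sigma2 = np.exp(theta[p + 1])
        r = 1.0 / phi
        eta0 = self.X @ beta + self.offset
        const = self._cell_ll_parts(r)
        u_hat, neg_hess = self._find_modes(eta0, r, sigma2)
        tau = 1.0 / np.sqrt(neg_hess)
        K = len(self.z)
        N = len(self.y)
        s = np.empty((K, self.J))
        resid = np.empty((K, N))  # y - (y+r) mu/(r+mu), per node
        dr_cells = np.empty((K, N))  # d cell-ll / d r, per node
        dig = special.digamma(self.y + r) - special.digamma(r)
        for k, zk in enumerate(self.z):
            u_k = u_hat + tau * zk
            eta = eta0 + u_k[self.s]
            lse = np.logaddexp(np.log(r), eta)
            frac = np.exp(eta - lse)  # mu/(r+mu)
            s[k] = (
                np.bincount(self.s, weights=const + self.y * eta - (self.y + r) * lse,
                            minlength=self.J)
                - 0.5 * u_k**2 / sigma2
                + 0.5 * zk**2
            )
            resid[k] = self.y - (self.y + r) * frac
            dr_cells[k] = dig + np.log(r) + 1.0 - lse - (self.y + r) / r * (1.0 - frac)
        lw = s + self.logw[:, None]
        ll_j = special.logsumexp(lw, axis=0)
        W = np.exp(lw - ll_j[None, :])  # posterior node weights, sum_k = 1 per subject
        nll = -float((ll_j + np.log(tau) - 0.5 * np.log(2 * np.pi * sigma2)).sum())
        Wc = W[:, self.s]  # broadcast weights onto cells
        grad = np.empty(p + 2)
        grad[:p] = -((Wc * resid).sum(axis=0) @ self.X)
        # dll/d log phi = -r dll/dr; nll flips the sign once more
        grad[p] = r * float((Wc * dr_cells).sum())
        h = 1e-5
        tp, tm = theta.copy(), theta.copy()
        tp[p + 1] += h
        tm[p + 1] -= h
        grad[p + 1] = (self.nll(tp) - self.nll(tm)) / (2 * h)
        return nll, grad


def _poisson_irls(y, X, offset, max_iter=50):
    """Poisson GLM by IRLS; deterministic initializer for the NBMM."""
    beta = np.zeros(X.shape[1])
    beta[0] = np.log(max(y.mean(), 1e-3)) - (
        np.log(np.exp(offset).mean()) if np.any(offset) else 0.0
    )
    for _ in range(max_iter):
        eta = np.clip(X @ beta + offset, -30, 30)
        mu = np.exp(eta)
        W = mu
        z = eta - offset + (y - mu) / np.maximum(mu, 1e-10)
        WX = X * W[:, None]
        try:
            beta_new = np.linalg.solve(X.T @ WX, WX.T @ z)
        except np.linalg.LinAlgError:
            break
        if np.max(np.abs(beta_new - beta)) < 1e-10:
            beta = beta_new
            break
        beta = beta_new
    return beta


def fit_nbmm(
    counts: np.ndarray,
    design: np.ndarray,
    offset: np.ndarray,
    subject_ids: np.ndarray,
    n_quad: int = 10,
    max_iter: int = 200,
    tol: float = 1e-6,
    colnames: list[str] | None = None,
) -> NBMMFit:
    """Maximize the marginal NB mixed-model likelihood for one feature.

    ``design`` must be full rank (constant columns other than the intercept
    should be dropped by the caller); ``offset`` is log library size per
    cell; ``subject_ids`` groups cells into subjects.
    """
    y = np.asarray(counts, dtype=np.float64)
    X = np.asarray(design, dtype=np.float64)
    offset = np.asarray(offset, dtype=np.float64)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DesignError("design matrix is singular")
    codes, _ = pd.factorize(np.asarray(subject_ids))
    J = int(codes.max()) + 1
    p = X.shape[1]
    colnames = colnames or [f"b{i}" for i in range(p)]

    beta0 = _poisson_irls(y, X, offset)
    mu0 = np.exp(np.clip(X @ beta0 + offset, -30, 30))
    # method-of-moments dispersion from Poisson residuals
    phi0 = float(np.sum((y - mu0) ** 2 - mu0) / max(np.sum(mu0**2), 1e-12))
    phi0 = float(np.clip(phi0, 2e-4, 50.0))
    # subject-level spread of residual log-rates seeds sigma^2
    with np.errstate(divide="ignore"):
        subj_rate = np.bincount(codes, weights=y) / np.maximum(
            np.bincount(codes, weights=mu0), 1e-12
        )
    s2_0 = float(np.clip(np.var(np.log(np.maximum(subj_rate, 1e-3))), 2e-8, 4.0))

    obj = _Marginal(y, X, offset, codes, J, n_quad)
    theta0 = np.concatenate([beta0, [np.log(phi0), np.log(s2_0)]])
    bounds = [(None, None)] * p + [
        (_LOG_PHI_MIN, _LOG_PHI_MAX),
        (_LOG_SIGMA2_MIN, _LOG_SIGMA2_MAX),
    ]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = optimize.minimize(
            obj.nll_grad,
            theta0,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": max_iter, "ftol": 1e-11, "gtol": tol},
        )
    theta = res.x
    sigma2 = float(np.exp(theta[p + 1]))
    phi = float(np.exp(theta[p]))
    boundary = theta[p + 1] <= _LOG_SIGMA2_MIN + 1e-6
    # L-BFGS-B may stop with an "abnormal line search" flag at a perfectly
    # good optimum when ftol is tighter than the attainable precision; accept
    # the point when the projected gradient is small
    lo = np.array([b[0] if b[0] is not None else -np.inf for b in bounds])
    hi = np.array([b[1] if b[1] is not None else np.inf for b in bounds])
    pg = np.asarray(res.jac, dtype=float).copy()
    pg[(theta <= lo + 1e-9) & (pg > 0)] = 0.0
    pg[(theta >= hi - 1e-9) & (pg < 0)] = 0.0
    ok = bool(res.success) or float(np.max(np.abs(pg))) < 0.05

    # observed information via finite differences; at a sigma^2 boundary the
    # variance-component direction is profiled out at the bound
    free = list(range(p + 1)) + ([] if boundary else [p + 1])
    cov_beta, se = _wald_cov(obj.nll, theta, free, p)
    return NBMMFit(
        beta=theta[:p].copy(),
        se=se,
        cov_beta=cov_beta,
        sigma2=sigma2,
        phi=phi,
        loglik=-float(res.fun),
        converged=ok and bool(np.all(np.isfinite(se))),
        boundary_sigma=bool(boundary),
        n_iter=int(res.nit),
        colnames=list(colnames),
    )


def _wald_cov(nll, theta, free, p):
    """Covariance of beta from a central-difference Hessian over free params."""
    k = len(free)
    h = 1e-4 * np.maximum(np.abs(theta[free]), 1.0)
    H = np.empty((k, k))
    f0 = nll(theta)
    fp = np.empty(k)
    fm = np.empty(k)
    for a in range(k):
        tp, tm = theta.copy(), theta.copy()
        tp[free[a]] += h[a]
        tm[free[a]] -= h[a]
        fp[a], fm[a] = nll(tp), nll(tm)
        H[a, a] = (fp[a] - 2 * f0 + fm[a]) / h[a] ** 2
    for a in range(k):
        for b in range(a + 1, k):
            tpp = theta.copy()
            tpp[free[a]] += h[a]
            tpp[free[b]] += h[b]
            H[a, b] = H[b, a] = (
                nll(tpp) - fp[a] - fp[b] + f0
            ) / (h[a] * h[b])
    try:
        cov = np.linalg.inv(H)
        if np.any(np.diag(cov)[:p] <= 0):
            raise np.linalg.LinAlgError
        return cov[:p, :p], np.sqrt(np.diag(cov)[:p])
    except np.linalg.LinAlgError:
        return np.full((p, p), np.nan), np.full(p, np.nan)


def bh_adjust(p_values, family_size: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with enforced monotonicity.

    Missing entries (NaN) are excluded from the family; ``family_size``
    overrides the family size m when the supplied vector is a subset of a
    larger declared family.
    """
    p = np.asarray(p_values, dtype=np.float64)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValidationError("p-values outside [0, 1]")
    pv = p[ok]
    n = pv.size
    if n == 0:
        return out
    m = family_size if family_size is not None else n
    if m < n:
        raise ValidationError(f"family_size {m} smaller than number of p-values {n}")
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, n + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    res = np.empty(n)
    res[order] = q
    out[ok] = res
    return out


def build_design(
    cohort: CohortTable,
    contrast: ContrastSpec,
    subjects: list[str],
    extra_factor: str | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Per-subject fixed-effect matrix: intercept + group + batch + other outcome.

    ``extra_factor`` appends one binarized clinical factor (majority vs rest)
    for the robustness scan. Returned rows follow ``subjects`` order.
    """
    df = cohort.data.loc[subjects]
    cols = {"intercept": np.ones(len(df))}
    cols[contrast.variable] = df.index.isin(contrast.positive_group).astype(float)
    for cov in contrast.covariates:
        if cov == "batch":
            levels = sorted(df["batch"].unique())
            for lev in levels[1:]:
                cols[f"batch[{lev}]"] = (df["batch"] == lev).to_numpy(float)
        else:
            cols[cov] = df[cov].to_numpy(float)
    if extra_factor is not None:
        cols[extra_factor] = binarize_factor(cohort.data[extra_factor]).loc[
            subjects
        ].to_numpy(float)
    names = list(cols)
    return np.column_stack([cols[c] for c in names]), names


def _drop_constant(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str]]:
    keep = [0] + [
        j for j in range(1, X.shape[1]) if np.ptp(X[:, j]) > 0
    ]
    return X[:, keep], [names[j] for j in keep]


def test_all_features(
    matrix: ad.AnnData,
    cohort: CohortTable,
    contrast: ContrastSpec,
    modality: str = "rna",
    min_cells: int = 20,
    min_expressing: int = 3,
    n_quad: int = 10,
    extra_factor: str | None = None,
    return_fits: bool = False,
) -> pd.DataFrame:
    """Fit the NB mixed model for every (feature, cell type) of one modality.

    Returns one row per feature x cell type with the Wald test on the group
    coefficient. Untestable combinations (too few cells, a group absent from
    the cell type, all-zero or near-zero expression, non-convergence) are
    recorded with a reason and missing p. q-values are NOT assigned here:
    the BH family spans both contrasts (see :func:`mixed_track`).
    """
    feat_mask = (matrix.var["modality"] == modality).to_numpy()
    if feat_mask.sum() == 0:
        raise ValidationError(f"no features with modality {modality!r}")
    in_contrast = matrix.obs["subject_id"].isin(
        contrast.positive_group | contrast.negative_group
    ).to_numpy()
    sub = matrix[in_contrast, feat_mask]
    X_all = sp.csc_matrix(sub.X)
    panel_total = np.asarray(X_all.sum(axis=1)).ravel()
    usable = panel_total > 0
    offset_all = np.zeros(len(panel_total))
    offset_all[usable] = np.log(panel_total[usable])
    features = list(sub.var.index)
    cell_types = sorted(sub.obs["cell_type"].unique())
    subj_all = sub.obs["subject_id"].to_numpy()
    ct_all = sub.obs["cell_type"].to_numpy()

    rows = []
    fits = {}
    for ct in cell_types:
        sel = (ct_all == ct) & usable
        n_ct = int(sel.sum())
        subj = subj_all[sel]
        subjects = sorted(set(subj))
        n_pos = len(set(subjects) & contrast.positive_group)
        n_neg = len(set(subjects) & contrast.negative_group)
        note_ct = None
        if n_ct < min_cells:
            note_ct = "too_few_cells"
        elif n_pos < 2 or n_neg < 2:
            note_ct = "group_missing"
        if note_ct is None:
            subj_design, names = build_design(cohort, contrast, subjects, extra_factor)
            row_of = {s: i for i, s in enumerate(subjects)}
            cell_idx = np.array([row_of[s] for s in subj])
            Xd, names = _drop_constant(subj_design[cell_idx], names)
            if contrast.variable not in names:
                note_ct = "group_constant"
            elif np.linalg.matrix_rank(Xd) < Xd.shape[1]:
                note_ct = "singular_design"
        if note_ct is not None:
            for f in features:
                rows.append(
                    _row(f, ct, contrast, modality, note=note_ct, n_cells=n_ct,
                         n_subjects=len(subjects))
                )
            continue
        k = names.index(contrast.variable)
        offs = offset_all[sel]
        Xcols = X_all[sel]
        for fi, f in enumerate(features):
            y = np.asarray(Xcols[:, fi].todense()).ravel()
            if (y > 0).sum() < min_expressing:
                rows.append(
                    _row(f, ct, contrast, modality, note="low_expression",
                         n_cells=n_ct, n_subjects=len(subjects))
                )
                continue
            try:
                fit = fit_nbmm(y, Xd, offs, subj, n_quad=n_quad, colnames=names)
            except DesignError:
                rows.append(
                    _row(f, ct, contrast, modality, note="singular_design",
                         n_cells=n_ct, n_subjects=len(subjects))
                )
                continue
            z, pval, eff = fit.wald(k)
            note = None if fit.converged else "not_converged"
            rows.append(
                _row(
                    f, ct, contrast, modality,
                    effect=eff, se=float(fit.se[k]), z=z,
                    p=pval if fit.converged else np.nan,
                    converged=fit.converged, note=note,
                    n_cells=n_ct, n_subjects=len(subjects),
                    sigma2=fit.sigma2, phi=fit.phi,
                )
            )
            if return_fits:
                fits[(f, ct)] = fit
    out = pd.DataFrame(rows)
    out["track"] = "mixed"
    return (out, fits) if return_fits else out


def _row(f, ct, contrast, modality, effect=np.nan, se=np.nan, z=np.nan, p=np.nan,
         converged=False, note=None, n_cells=0, n_subjects=0,
         sigma2=np.nan, phi=np.nan):
    return {
        "feature_id": f, "cell_type": ct, "contrast": contrast.variable,
        "modality": modality, "effect": effect, "se": se, "z": z, "p": p,
        "converged": converged, "note": note, "n_cells": n_cells,
        "n_subjects": n_subjects, "sigma2": sigma2, "phi": phi,
    }


def mixed_track(
    matrix: ad.AnnData,
    cohort: CohortTable,
    contrasts: list[ContrastSpec],
    modality: str = "rna",
    **kwargs,
) -> pd.DataFrame:
    """Run the mixed-model track over all contrasts and BH-adjust the family.

    The FDR family pools all features x cell types x contrasts within the
    modality; RNA and protein are adjusted separately.
    """
    parts = [
        test_all_features(matrix, cohort, c, modality=modality, **kwargs)
        for c in contrasts
    ]
    res = pd.concat(parts, ignore_index=True)
    res["q"] = bh_adjust(res["p"].to_numpy())
    return res
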