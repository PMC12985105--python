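"""Synthetic multimodal single-cell cohorts with known ground truth.

The generator emulates a targeted-panel (AbSeq-like) bone-marrow dataset:
a small transplant cohort (default 14 subjects across 3 processing batches)
with two partially overlapping binary outcomes, ~15 cell types whose
proportions vary by subject, a ~397-gene RNA panel and a ~41-marker surface
protein panel. Counts follow a negative binomial model on the log scale:

    log mu = baseline(feature, cell type) + batch effect
             + outcome * LFC + subject intercept + log(cell size factor)

with Var(y) = mu + phi * mu^2 and a shared per-(subject, feature) random
intercept, i.e. exactly the generative structure the downstream mixed model
assumes. Sparse group effects (true log-fold-changes), QC-failing cells and
multiplets are injected and recorded in :class:`SimTruth` so that every
pipeline stage can be tested for recovery, calibration and filtering
behaviour without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .cohort import CohortTable
from .errors import ConfigError

__all__ = ["SimConfig", "SimTruth", "simulate_cohort"]


@dataclass
class SimConfig:
    """Generator configuration; defaults mirror the study design.

    ``outcome_crosstab`` orders the four cells as (cGvHD+/Rel+, cGvHD+/Rel−,
    cGvHD−/Rel+, cGvHD−/Rel−) and must sum to ``n_subjects``.
    ``proportion_effect_types`` maps a contrast name to the cell-type indices
    whose logit-proportion is shifted by ``proportion_effect`` in outcome-
    positive subjects (empty by default: the study design showed no
    composition differences).
    """

    n_subjects: int = 14
    n_batches: int = 3
    n_cell_types: int = 15
    n_rna: int = 397
    n_protein: int = 41
    cells_per_subject: tuple[int, int] = (2500, 4700)
    outcome_crosstab: tuple[int, int, int, int] = (1, 5, 4, 4)
    de_fraction: float = 0.1
    lfc_mean: float = 1.0
    lfc_sd: float = 0.25
    sigma_subject: float = 0.5
    phi: float = 1.0
    batch_effect_sd: float = 0.3
    size_factor_sd: float = 0.3
    proportion_effect: float = 0.0
    proportion_effect_types: dict = field(default_factory=dict)
    prop_noise_sd: float = 0.25  # logit-normal subject variability of proportions
    qc_fail_fraction: float = 0.05
    multiplet_fraction: float = 0.03
    n_null_factors: int = 2
    seed: int = 0

    def validate(self) -> None:
        if sum(self.outcome_crosstab) != self.n_subjects:
            raise ConfigError(
                f"outcome_crosstab {self.outcome_crosstab} does not sum to "
                f"n_subjects={self.n_subjects}"
            )
        if self.n_subjects < 4 or self.n_batches < 1 or self.n_cell_types < 1:
            raise ConfigError("counts must be positive (and n_subjects >= 4)")
        for name in ("de_fraction", "qc_fail_fraction", "multiplet_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if min(self.sigma_subject, self.phi, self.batch_effect_sd) < 0:
            raise ConfigError("variance parameters must be nonnegative")
        if self.cells_per_subject[0] > self.cells_per_subject[1] or self.cells_per_subject[0] < 1:
            raise ConfigError(f"bad cells_per_subject range {self.cells_per_subject}")


@dataclass
class SimTruth:
    """Ground truth emitted alongside a simulated dataset."""

    de_effects: pd.DataFrame  # contrast, cell_type, modality, feature_id, lfc
    proportion_effects: pd.DataFrame  # contrast, cell_type, logit_shift
    sigma_subject: float
    phi: float
    subject_proportions: pd.DataFrame  # subject x cell type, pre-sampling
    qc_fail: np.ndarray  # bool per cell
    multiplet: np.ndarray  # bool per cell

    def de_set(self, contrast: str, cell_type: str, modality: str) -> set[str]:
        d = self.de_effects
        m = (
            (d["contrast"] == contrast)
            & (d["cell_type"] == cell_type)
            & (d["modality"] == modality)
        )
        return set(d.loc[m, "feature_id"])


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = np.exp(logits - logits.max(axis=-1, keepdims=True))
    return z / z.sum(axis=-1, keepdims=True)


def _assign_outcomes(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    cells = []
    for (g, r), n in zip(((1, 1), (1, 0), (0, 1), (0, 0)), cfg.outcome_crosstab):
        cells += [(g, r)] * n
    subjects = [f"S{i + 1:02d}" for i in range(cfg.n_subjects)]
    batches = [f"b{(i % cfg.n_batches) + 1}" for i in range(cfg.n_subjects)]
    df = pd.DataFrame(
        {
            "cgvhd": [c[0] for c in cells],
            "relapse": [c[1] for c in cells],
            "batch": batches,
        },
        index=pd.Index(subjects, name="subject_id"),
    )
    # clinical factors with no expression effect, for robustness null checks;
    # minority size fixed at max(4, n/3) so they pass the eligibility rule
    k = max(4, cfg.n_subjects // 3)
    for j in range(cfg.n_null_factors):
        idx = rng.choice(cfg.n_subjects, size=k, replace=False)
        col = np.zeros(cfg.n_subjects, dtype=int)
        col[idx] = 1
        df[f"null_factor_{j + 1}"] = col
    return df


def simulate_cohort(
    config: SimConfig | None = None,
) -> tuple[CohortTable, ad.AnnData, SimTruth]:
    """Draw one synthetic cohort; fully reproducible given ``config.seed``.

    Returns the clinical table, an :class:`anndata.AnnData` of sparse integer
    counts (cells x features, ``obs``: subject_id/batch/cell_type/multiplet,
    ``var``: modality) and the generator ground truth.
    """
    cfg = config or SimConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    clin = _assign_outcomes(cfg, rng)
    cohort = CohortTable(clin)
    subjects = list(clin.index)
    types = [f"ct{t + 1:02d}" for t in range(cfg.n_cell_types)]
    rna = [f"gene_{i + 1:04d}" for i in range(cfg.n_rna)]
    adt = [f"adt_{i + 1:03d}" for i in range(cfg.n_protein)]
    features = rna + adt
    modality = np.array(["rna"] * cfg.n_rna + ["protein"] * cfg.n_protein)
    n_feat = len(features)

    # feature baselines (log scale): targeted RNA panel vs high-count ADT tags
    base = np.concatenate(
        [
            rng.normal(np.log(0.8), 1.0, size=cfg.n_rna),
            rng.normal(np.log(30.0), 0.8, size=cfg.n_protein),
        ]
    )
    # cell-type identity: sparse per-type shifts on ~15% of features
    type_delta = np.zeros((cfg.n_cell_types, n_feat))
    for t in range(cfg.n_cell_types):
        hit = rng.random(n_feat) < 0.15
        type_delta[t, hit] = rng.normal(0.0, 0.8, size=int(hit.sum()))
    batch_names = sorted(clin["batch"].unique())
    batch_eff = rng.normal(0.0, cfg.batch_effect_sd, size=(len(batch_names), n_feat))
    u = rng.normal(0.0, cfg.sigma_subject, size=(cfg.n_subjects, n_feat))

    # sparse true group effects per (contrast, cell type, modality)
    de_rows = []
    lfc = {c: np.zeros((cfg.n_cell_types, n_feat)) for c in ("cgvhd", "relapse")}
    for contrast in ("cgvhd", "relapse"):
        for t, tname in enumerate(types):
            for mod, ids, off in (("rna", rna, 0), ("protein", adt, cfg.n_rna)):
                n_de = int(round(cfg.de_fraction * len(ids)))
                if n_de == 0:
                    continue
                chosen = rng.choice(len(ids), size=n_de, replace=False)
                signs = rng.choice([-1.0, 1.0], size=n_de)
                mags = np.maximum(rng.normal(cfg.lfc_mean, cfg.lfc_sd, size=n_de), 0.0)
                lfc[contrast][t, chosen + off] = signs * mags
                for c_i, s_i, m_i in zip(chosen, signs, mags):
                    de_rows.append(
                        (contrast, tname, mod, ids[c_i], float(s_i * m_i))
                    )
    de_effects = pd.DataFrame(
        de_rows, columns=["contrast", "cell_type", "modality", "feature_id", "lfc"]
    )

    # subject-specific cell-type proportions with optional outcome shifts
    base_logits = np.log(rng.dirichlet(np.full(cfg.n_cell_types, 5.0)))
    prop_rows = []
    prop_shift = np.zeros((cfg.n_subjects, cfg.n_cell_types))
    for contrast, t_idx in cfg.proportion_effect_types.items():
        pos = clin[contrast].to_numpy() == 1
        for t in np.atleast_1d(t_idx):
            prop_shift[pos, t] += cfg.proportion_effect
            prop_rows.append((contrast, types[int(t)], cfg.proportion_effect))
    subj_logits = (
        base_logits[None, :]
        + rng.normal(0.0, cfg.prop_noise_sd, size=(cfg.n_subjects, cfg.n_cell_types))
        + prop_shift
    )
    subj_props = _softmax(subj_logits)
    proportion_effects = pd.DataFrame(
        prop_rows, columns=["contrast", "cell_type", "logit_shift"]
    )

    n_cells_per_subject = rng.integers(
        cfg.cells_per_subject[0], cfg.cells_per_subject[1] + 1, size=cfg.n_subjects
    )
    r = 1.0 / cfg.phi if cfg.phi > 0 else np.inf

    blocks, obs_rows = [], []
    qc_fail_all, multiplet_all = [], []
    rna_mask = modality == "rna"
    for j, subj in enumerate(subjects):
        n_c = int(n_cells_per_subject[j])
        t_ids = rng.choice(cfg.n_cell_types, size=n_c, p=subj_props[j])
        b = batch_names.index(clin.loc[subj, "batch"])
        log_s = rng.normal(0.0, cfg.size_factor_sd, size=n_c)
        logmu = (
            base[None, :]
            + type_delta[t_ids]
            + batch_eff[b][None, :]
            + u[j][None, :]
            + log_s[:, None]
        )
        for contrast in ("cgvhd", "relapse"):
            if clin.loc[subj, contrast] == 1:
                logmu = logmu + lfc[contrast][t_ids]
        mu = np.exp(logmu)

        qc_fail = rng.random(n_c) < cfg.qc_fail_fraction
        if qc_fail.any():
            # degrade failing cells so their RNA totals land well under QC thresholds
            tot = mu[np.ix_(qc_fail, rna_mask)].sum(axis=1)
            scale = 15.0 / np.maximum(tot, 15.0)
            mu[qc_fail] = mu[qc_fail] * scale[:, None]
        if cfg.phi > 0:
            counts = rng.negative_binomial(r, r / (r + mu))
        else:
            counts = rng.poisson(mu)

        multiplet = rng.random(n_c) < cfg.multiplet_fraction
        if multiplet.any():
            # a multiplet carries a second, independently drawn cell's counts
            idx = np.flatnonzero(multiplet)
            t2 = rng.choice(cfg.n_cell_types, size=len(idx), p=subj_props[j])
            mu2 = np.exp(
                base[None, :] + type_delta[t2] + batch_eff[b][None, :] + u[j][None, :]
            )
            if cfg.phi > 0:
                counts[idx] += rng.negative_binomial(r, r / (r + mu2))
            else:
                counts[idx] += rng.poisson(mu2)

        blocks.append(sp.csr_matrix(counts.astype(np.int64)))
        obs_rows.append(
            pd.DataFrame(
                {
                    "subject_id": subj,
                    "batch": batch_names[b],
                    "cell_type": [types[t] for t in t_ids],
                    "multiplet": multiplet,
                }
            )
        )
        qc_fail_all.append(qc_fail)
        multiplet_all.append(multiplet)

    X = sp.vstack(blocks, format="csr")
    obs = pd.concat(obs_rows, ignore_index=True)
    obs.index = pd.Index([f"cell_{i + 1:06d}" for i in range(len(obs))], name="cell_id")
    var = pd.DataFrame({"modality": modality}, index=pd.Index(features, name="feature_id"))
    adata = ad.AnnData(X=X, obs=obs, var=var)
    adata.uns["sim_seed"] = cfg.seed

    truth = SimTruth(
        de_effects=de_effects,
        proportion_effects=proportion_effects,
        sigma_subject=cfg.sigma_subject,
        phi=cfg.phi,
        subject_proportions=pd.DataFrame(subj_props, index=subjects, columns=types),
        qc_fail=np.concatenate(qc_fail_all),
        multiplet=np.concatenate(multiplet_all),
    )
    return cohort, adata, truth
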