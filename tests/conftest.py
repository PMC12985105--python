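"""Shared fixtures: the packaged cohort and session-scoped simulations.

The heavier simulated datasets are session-scoped so calibration, recovery
and consensus-logic tests share the same draws instead of refitting.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

import marrowde as m

warnings.filterwarnings("ignore", category=RuntimeWarning)


@pytest.fixture(scope="session")
def cohort():
    return m.load_cohort()


@pytest.fixture(scope="session")
def small_sim():
    """Small multimodal cohort with default effect structure."""
    cfg = m.SimConfig(
        n_subjects=14, n_cell_types=2, n_rna=25, n_protein=6,
        cells_per_subject=(60, 80), qc_fail_fraction=0.05,
        multiplet_fraction=0.03, seed=42,
    )
    return cfg, *m.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def effect_sim():
    """14-subject design with strong fixed-magnitude effects (LFC 1.5)."""
    cfg = m.SimConfig(
        n_subjects=14, n_cell_types=3, n_rna=60, n_protein=0,
        cells_per_subject=(250, 350), de_fraction=0.15,
        lfc_mean=1.5, lfc_sd=0.0,
        qc_fail_fraction=0.0, multiplet_fraction=0.0, seed=5,
    )
    return cfg, *m.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def effect_sim_results(effect_sim):
    """Both DE tracks + consensus on the strong-effect simulation."""
    cfg, cohort, adata, truth = effect_sim
    contrasts = [m.build_contrast(cohort, v) for v in ("cgvhd", "relapse")]
    mixed = m.mixed_track(adata, cohort, contrasts, modality="rna")
    pb = m.aggregate(adata)
    pbres = pd.concat(
        [m.test_pseudobulk(pb, cohort, c) for c in contrasts], ignore_index=True
    )
    calls = m.call_consensus(mixed, pbres)
    de_keys = set(
        zip(truth.de_effects.contrast, truth.de_effects.cell_type,
            truth.de_effects.feature_id)
    )
    calls["is_true"] = [
        (c, t, f) in de_keys
        for c, t, f in zip(calls.contrast, calls.cell_type, calls.feature_id)
    ]
    return cohort, truth, mixed, pbres, calls


@pytest.fixture()
def toy_cohort_frame():
    """Minimal 6-subject clinical frame for validation tests."""
    return pd.DataFrame(
        {
            "subject_id": [f"T{i}" for i in range(6)],
            "cgvhd": [1, 1, 1, 0, 0, 0],
            "relapse": [1, 0, 0, 1, 1, 0],
            "batch": ["a", "a", "b", "b", "c", "c"],
        }
    )


def write_cohort_tsv(tmp_path, df, name="cohort.tsv"):
    p = tmp_path / name
    df.to_csv(p, sep="\t", index=False)
    return p


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
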