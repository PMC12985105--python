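#!/usr/bin/env python
"""Generate the desk-scale synthetic cohort used by the downstream scripts.

The generator mirrors the study structure (14 subjects, 3 batches, the
1/5/4/4 outcome cross-tabulation, the full 397-gene + 41-protein panel,
NB counts with subject random intercepts and sparse group effects) but at
a reduced cell count and 5 cell types so the whole analysis chain runs in
minutes on a laptop. The full-scale defaults are available via SimConfig().

Counts go to scratch/ (they are regenerable from the seed); the ground
truth tables and the manifest go to results/.
"""

import json
from pathlib import Path

import marrowde as m

SCRATCH = Path("scratch/sim")
OUT = Path("results/synthetic")
OUT.mkdir(parents=True, exist_ok=True)

cfg = m.SimConfig(
    n_subjects=14, n_batches=3, n_cell_types=5,
    n_rna=397, n_protein=41,
    cells_per_subject=(120, 180),
    de_fraction=0.08, lfc_mean=1.2, lfc_sd=0.3,
    sigma_subject=0.5, phi=1.0, batch_effect_sd=0.3,
    qc_fail_fraction=0.05, multiplet_fraction=0.03,
    seed=2024,
)
cohort, adata, truth = m.simulate_cohort(cfg)
m.write_dataset(adata, SCRATCH)
cohort.data.to_csv(SCRATCH / "cohort.tsv", sep="\t")

truth.de_effects.to_csv(OUT / "truth_de_effects.tsv", sep="\t", index=False)
truth.subject_proportions.to_csv(OUT / "truth_proportions.tsv", sep="\t")
(OUT / "sim_manifest.json").write_text(json.dumps({
    "seed": cfg.seed,
    "n_cells": int(adata.n_obs),
    "n_rna": cfg.n_rna,
    "n_protein": cfg.n_protein,
    "n_cell_types": cfg.n_cell_types,
    "n_true_de": int(len(truth.de_effects)),
    "qc_fail_cells": int(truth.qc_fail.sum()),
    "multiplets": int(truth.multiplet.sum()),
}, indent=2))

print(f"simulated {adata.n_obs} cells x {adata.n_vars} features "
      f"({int(truth.qc_fail.sum())} QC-fail, {int(truth.multiplet.sum())} multiplets)")
print(f"injected {len(truth.de_effects)} true effects "
      f"across {truth.de_effects.cell_type.nunique()} cell types")
print(f"counts -> {SCRATCH}/, truth -> {OUT}/")
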