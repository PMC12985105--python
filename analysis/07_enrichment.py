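#!/usr/bin/env python
"""Geneset over-representation of consensus DEGs against the panel background.

Builds a synthetic GMT over the simulated panel — two sets seeded from the
generator's true cGvHD-differential genes (positive controls) plus random
sets — then runs one-sided Fisher tests per (cell type, contrast) with the
397-gene panel as universe, highlighting nominal p < 0.05.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import marrowde as m
from marrowde.enrichment import enrich_calls, read_gmt

OUT = Path("results/enrichment")
OUT.mkdir(parents=True, exist_ok=True)

adata = m.read_dataset("scratch/qc")
panel = sorted(adata.var.index[adata.var.modality == "rna"])
truth_de = pd.read_csv("results/synthetic/truth_de_effects.tsv", sep="\t")
calls = pd.read_csv("results/de/consensus_rna.tsv", sep="\t")

rng = np.random.default_rng(7)
lines = []
true_genes = sorted(set(truth_de[truth_de.modality == "rna"].feature_id))
for i, name in enumerate(("true_de_seeded_a", "true_de_seeded_b")):
    members = rng.choice(true_genes, size=min(15, len(true_genes)), replace=False)
    lines.append(f"{name}\tsynthetic set seeded from generator truth\t"
                 + "\t".join(members))
for i in range(4):
    members = rng.choice(panel, size=20, replace=False)
    lines.append(f"random_set_{i + 1}\tsynthetic random panel subset\t"
                 + "\t".join(members))
gmt_path = OUT / "synthetic_panel_sets.gmt"
gmt_path.write_text("\n".join(lines) + "\n")

genesets = read_gmt(gmt_path, panel)
res = enrich_calls(calls, genesets, panel, modality="rna")
res.to_csv(OUT / "enrichment.tsv", sep="\t", index=False)

if len(res):
    print(f"{len(res)} geneset x cell type x contrast tests, "
          f"{int(res.highlighted.sum())} highlighted at nominal p < 0.05")
    print(res.sort_values("p").head(6)[
        ["geneset", "cell_type", "contrast", "n_overlap", "n_de", "p"]
    ].to_string(index=False))
else:
    print("no consensus DEGs to test")
print(f"tables -> {OUT}/")
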