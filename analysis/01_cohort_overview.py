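#!/usr/bin/env python
"""Cohort overview: contrasts, outcome cross-tabulation, confounder eligibility.

Loads the packaged 14-subject clinical table, derives both outcome
contrasts (each adjusting for batch and the other outcome), cross-tabulates
the partially overlapping outcomes, and reports which clinical factors have
enough variation (minority pool >= 4 subjects) to enter the robustness scan.
"""

from pathlib import Path

import marrowde as m

OUT = Path("results/cohort")
OUT.mkdir(parents=True, exist_ok=True)

cohort = m.load_cohort()
print(f"cohort: {len(cohort)} subjects, batches: "
      f"{sorted(cohort.data.batch.unique())}")

for variable in ("cgvhd", "relapse"):
    c = m.build_contrast(cohort, variable)
    print(f"{variable}: {c.n_positive} positive vs {c.n_negative} negative "
          f"(covariates: {', '.join(c.covariates)})")

tab = m.crosstab_outcomes(cohort)
tab.to_csv(OUT / "outcome_crosstab.tsv", sep="\t")
print("outcome crosstab (cGvHD x relapse):")
print(tab)

eligible = m.eligible_confounders(cohort)
print(f"eligible robustness factors (minority >= 4): {eligible}")
with open(OUT / "eligible_confounders.txt", "w") as fh:
    fh.write("\n".join(eligible) + "\n")

cohort.data.to_csv(OUT / "cohort_parsed.tsv", sep="\t")
print(f"wrote {OUT}/")
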