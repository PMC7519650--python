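"""Simulate a synthetic chemotherapy cohort and inspect its ground truth.

The generator produces every table the pipeline consumes — variant catalog,
BAF segments, expression, imaging counts, clinical records — plus a sealed
truth record, all reproducible from one seed.
"""

import pandas as pd

from chemomics import simulate as sim

cfg = sim.CohortSimConfig(n_samples=60, seed=42)
cohort = sim.simulate_cohort(cfg)

cat = cohort.variant_catalog
print(f"samples: {len(cat.samples)}")
print(f"median SNVs/sample: {cat.snv_counts().median():.0f}  "
      f"(range {cat.snv_counts().min()}-{cat.snv_counts().max()})")
print(f"median indels/sample: {cat.indel_counts().median():.0f}")
print("subtype mix:", pd.Series(cohort.truth["subtype"]).value_counts().to_dict())
print(f"BRCA2-mutant samples: {sum(cohort.truth['brca2_mutated'].values())}")
print(f"true response rate: {pd.Series(cohort.truth['response']).mean():.2f}")
# Burdens are negative-binomial (wide, like real exomes); the response rate
# reflects the planted logistic model on instability/subtype/immune state.
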