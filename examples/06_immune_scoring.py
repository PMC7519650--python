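"""RNA and protein immune scores, immune subtypes, and the PD-1/PD-L1 axis.

RNA: a cell-type score is the mean expression of its gene list; the immune
score (IS) is the sum over cell types, median-split into hot/cold.
Protein: cell fractions from imaging counts sum to a region IS; the two
region-level median splits map to desert/excluded/infiltrated.
"""

import pandas as pd

from chemomics import immune_expression as imm
from chemomics import immune_imaging as img
from chemomics import simulate as sim

cohort = sim.simulate_cohort(sim.CohortSimConfig(n_samples=80, seed=3))

rna_is = imm.immune_score(cohort.expression, cohort.gene_sets)
hot = imm.dichotomize(rna_is) == "high"
print(f"RNA immune score: median={rna_is.median():.2f}, {hot.sum()} hot / {(~hot).sum()} cold")

labels = img.immune_subtypes(cohort.cell_counts)
print("immune subtypes:", labels.value_counts().to_dict())

cc = cohort.cell_counts.query("region == 'intratumoral'").set_index("sample_id")
groups = img.pd_axis_groups(
    cc["pd1_count"] / cc["total_cells"], cc["pdl1_count"] / cc["total_cells"]
)
print("PD-1/PD-L1 groups:", groups["combined"].value_counts().to_dict())
print("example H-score (10% low, 20% moderate, 30% high):", img.h_score(10, 20, 30))
# Samples simulated as immune-hot should be enriched in the infiltrated
# subtype; the H-score summarizes MHC staining intensity on a 0-300 scale.
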