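"""Select tumor-associated CpG sites and consensus-cluster the samples.

Hypermethylated sites are autosomal probes unmethylated in normal bladder
and leukocyte references but methylated in >= 4 tumors; samples are then
grouped by Monti-style consensus clustering over the selected probes.
"""

import numpy as np
import pandas as pd

from chemomics import methylation as meth

rng = np.random.default_rng(0)
n_probes, n_tumors = 300, 30
group = np.repeat([0, 1, 2], n_tumors // 3)  # three planted methylation states

beta = np.clip(rng.beta(2, 10, (n_probes, n_tumors)) + 0.3 * group + rng.normal(0, 0.03, (n_probes, n_tumors)), 0, 1)
beta = pd.DataFrame(beta, index=[f"cg{i:04d}" for i in range(n_probes)],
                    columns=[f"T{i:02d}" for i in range(n_tumors)])
ann = pd.DataFrame(
    {
        "chrom": rng.choice([str(c) for c in range(1, 23)] + ["X"], n_probes),
        "gene": rng.choice([f"G{i}" for i in range(40)], n_probes),
        "region_class": rng.choice(["TSS200", "TSS1500", "5'UTR", "Body"], n_probes),
    },
    index=beta.index,
)
normal = pd.Series(rng.beta(2, 14, n_probes), index=beta.index)
leuko = pd.Series(rng.beta(2, 14, n_probes), index=beta.index)

sel = meth.select_tumor_cpgs(beta, normal, leuko, ann, "hyper", n=150)
print(f"selected {len(sel.probes)} hypermethylated autosomal CpGs")

res = meth.consensus_cluster(
    beta.loc[sel.probes].T, k_range=(2, 3, 4, 5), n_resamples=200, rng=rng
)
print(f"chosen k = {res.k} (ambiguity per k: "
      + ", ".join(f"{k}:{v:.3f}" for k, v in res.ambiguity.items()) + ")")
print("cluster sizes:", res.labels.value_counts().to_dict())

promoter, body = meth.region_methylation(beta, ann)
print(f"promoter table: {promoter.shape[0]} genes x {promoter.shape[1]} samples")
# k should land on 3 (the planted states); ambiguity is the fraction of
# consensus entries away from 0/1 — lower is a cleaner partition.
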