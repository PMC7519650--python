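import numpy as np
import pandas as pd
import pytest

from chemomics import signatures as sig
from chemomics import simulate as sim


@pytest.fixture(scope="session")
def sig_matrix():
    return sig.load_signature_matrix()


@pytest.fixture(scope="session")
def reference():
    """Small seeded reference with its trinucleotide context index."""
    return sim.synthetic_reference(length=50_000, seed=11)


@pytest.fixture(scope="session")
def small_cohort():
    cfg = sim.CohortSimConfig(
        n_samples=40, snv_rate=200, indel_rate=30, reference_length=50_000, seed=7
    )
    return sim.simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def toy_catalog_df(records):
    """Build a minimal valid variant table from (sample, gene, impact, class) tuples."""
    rows = []
    for i, (sample, gene, impact, vclass) in enumerate(records):
        rows.append(
            {
                "sample_id": sample,
                "gene": gene,
                "chrom": "chr1",
                "pos": 100 + i,
                "ref": "C",
                "alt": "T",
                "variant_class": vclass,
                "impact": impact,
                "polyphen_verdict": "probably_damaging",
                "mutationassessor_verdict": "high",
                "vaf": 0.3,
                "alt_reads": 30,
                "total_reads": 100,
            }
        )
    return pd.DataFrame(rows)
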