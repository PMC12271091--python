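"""Shared builders for test fixtures."""

import numpy as np
import pandas as pd

from gsemkit.sumstats import SumstatsTable


def make_table(label, n_variants=100, seed=0, n=10_000.0, alleles=("A", "G")):
    """Small synthetic sumstats table with standard-normal z."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "variant_id": [f"rs{i}" for i in range(n_variants)],
        "chrom": "1",
        "pos": np.arange(1, n_variants + 1),
        "allele_effect": alleles[0],
        "allele_other": alleles[1],
        "z": rng.standard_normal(n_variants),
        "n": n,
        "freq_effect": rng.uniform(0.05, 0.95, n_variants),
    })
    return SumstatsTable(label, df)
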