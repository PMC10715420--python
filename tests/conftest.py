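import numpy as np
import pandas as pd
import pytest

from mrmediate.gwas_io import HarmonizedSet, SummaryStatsTable


def make_table(rows, trait_name="trait", trait_level=None):
    """Build a SummaryStatsTable from (vid, chrom, pos, ea, oa, eaf, beta, se, p, n) tuples."""
    df = pd.DataFrame(
        rows,
        columns=[
            "variant_id",
            "chromosome",
            "position",
            "effect_allele",
            "other_allele",
            "eaf",
            "beta",
            "se",
            "pvalue",
            "n",
        ],
    )
    return SummaryStatsTable(trait_name, df, trait_level)


@pytest.fixture
def random_harmonized():
    """Factory for random single-exposure harmonized sets."""

    def _make(J=10, seed=0, beta_true=0.5):
        rng = np.random.default_rng(seed)
        gamma = rng.normal(0.1, 0.05, J)
        gamma[gamma == 0] = 0.01
        sigma_gamma = rng.uniform(0.005, 0.02, J)
        sigma_Gamma = rng.uniform(0.01, 0.05, J)
        Gamma = beta_true * gamma + rng.normal(0, sigma_Gamma)
        return HarmonizedSet.from_arrays(gamma, sigma_gamma, Gamma, sigma_Gamma)

    return _make
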