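import numpy as np
import pandas as pd
import pytest

from mrcoloc import SumStatsTable
from mrcoloc.sumstats import two_sided_p


def make_table(trait="trait", snps=None, chrom=None, pos=None, a1=None, a2=None,
               freq=None, beta=None, se=None, p=None, n=None):
    """Small summary-statistics table with sensible defaults per field."""
    m = len(beta) if beta is not None else (len(snps) if snps else 3)
    beta = np.asarray(beta if beta is not None else np.linspace(0.1, 0.3, m), float)
    se = np.asarray(se if se is not None else np.full(m, 0.05), float)
    df = pd.DataFrame({
        "snp": snps if snps is not None else [f"rs{i + 1}" for i in range(m)],
        "chrom": chrom if chrom is not None else ["1"] * m,
        "pos": pos if pos is not None else (1000 * (np.arange(m) + 1)),
        "a1": a1 if a1 is not None else ["A"] * m,
        "a2": a2 if a2 is not None else ["G"] * m,
        "freq": freq if freq is not None else [0.3] * m,
        "beta": beta,
        "se": se,
        "p": p if p is not None else two_sided_p(beta / se),
        "n": n if n is not None else [10_000] * m,
    })
    return SumStatsTable(trait, df)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
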