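import numpy as np
import pandas as pd
import pytest

from neurogwas.core import GenotypeMatrix


def make_geno(dosage, chrom=None, pos=None, info=None, sample_prefix="s"):
    """Build a GenotypeMatrix from a samples x markers array."""
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    chrom = chrom if chrom is not None else ["1"] * m
    pos = pos if pos is not None else [(i + 1) * 1000 for i in range(m)]
    info = info if info is not None else [1.0] * m
    markers = pd.DataFrame(
        {
            "marker": [f"mk{j}" for j in range(m)],
            "chrom": [str(c) for c in chrom],
            "pos": pos,
            "ref": "A",
            "alt": "G",
            "info_score": info,
            "call_rate": 1.0 - np.mean(np.isnan(dosage), axis=0),
        }
    )
    g = GenotypeMatrix(
        sample_ids=[f"{sample_prefix}{i}" for i in range(n)],
        markers=markers,
        dosage=dosage,
    )
    g.validate()
    return g


def make_pheno(values, group=None, sample_prefix="s"):
    values = np.asarray(values, dtype=float)
    group = group if group is not None else np.zeros(len(values), dtype=int)
    return pd.DataFrame(
        {
            "sample_id": [f"{sample_prefix}{i}" for i in range(len(values))],
            "phenotype": values,
            "group": np.asarray(group, dtype=int),
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
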