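import numpy as np
import pandas as pd
import pytest

from famburden.pedigree import Individual, Pedigree


@pytest.fixture
def sib_pair_ped() -> Pedigree:
    return Pedigree(
        "SIB",
        [
            Individual("f", sex="male", affection="unaffected", age_years=70),
            Individual("m", sex="female", affection="unaffected", age_years=68),
            Individual("s1", "f", "m", "male", "affected", 30),
            Individual("s2", "f", "m", "female", "affected", 28),
        ],
    )


@pytest.fixture
def sib_trio_ped() -> Pedigree:
    return Pedigree(
        "TRIO",
        [
            Individual("f", sex="male", affection="unaffected", age_years=70),
            Individual("m", sex="female", affection="unaffected", age_years=68),
            Individual("s1", "f", "m", "male", "affected", 30),
            Individual("s2", "f", "m", "female", "affected", 28),
            Individual("s3", "f", "m", "female", "unaffected", 55),
        ],
    )


@pytest.fixture
def first_cousin_ped() -> Pedigree:
    """Offspring of a first-cousin union (consanguinity loop)."""
    return Pedigree(
        "FC",
        [
            Individual("gf", sex="male"),
            Individual("gm", sex="female"),
            Individual("p1", "gf", "gm", "male"),
            Individual("p2", "gf", "gm", "female"),
            Individual("s1", sex="female"),
            Individual("s2", sex="male"),
            Individual("a", "p1", "s1", "male"),
            Individual("b", "p2", "s2", "female"),
            Individual("c", "a", "b", "male", "affected", 30),
        ],
    )


def make_genotype_matrix(samples, calls, chrom="1", start=1_000_000,
                         step=10_000, r2=None):
    """Small genotype matrix with evenly spaced variants."""
    from famburden.genotypes import GenotypeMatrix

    calls = np.asarray(calls, dtype=np.int8)
    n_var = calls.shape[1]
    variants = pd.DataFrame(
        {
            "variant_id": [f"v{k}" for k in range(n_var)],
            "chrom": [chrom] * n_var,
            "pos": [start + k * step for k in range(n_var)],
            "ref": ["A"] * n_var,
            "alt": ["G"] * n_var,
        }
    )
    if r2 is not None:
        variants["r2"] = r2
    return GenotypeMatrix(samples, variants, calls)
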