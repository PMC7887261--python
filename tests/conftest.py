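import numpy as np
import pandas as pd
import pytest

from carrierscan.types import CohortDataset, VariantRecord


def make_dataset(
    genotypes,
    phenotypes,
    variants=None,
    quality=None,
    depth=None,
    allele_balance=None,
    samples_extra=None,
):
    """Hand-built CohortDataset for unit tests."""
    genotypes = np.asarray(genotypes, dtype=np.int8)
    n_s, n_v = genotypes.shape
    if variants is None:
        variants = [
            VariantRecord("1", 100 * (j + 1), "A", "C", variant_id=f"v{j}")
            for j in range(n_v)
        ]
    samples = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n_s)],
            "phenotype": np.asarray(phenotypes, dtype=int),
            "age": 60.0,
            "sex": "male",
            "smoking": "ever",
            "pack_years": 20.0,
            "fhlc": "no",
            "cohort": "T",
        }
    )
    if samples_extra:
        for k, v in samples_extra.items():
            samples[k] = v
    full = lambda fill: np.full(genotypes.shape, fill, dtype=float)
    return CohortDataset(
        samples=samples,
        variants=variants,
        genotypes=genotypes,
        quality=full(99.0) if quality is None else np.asarray(quality, float),
        depth=full(50.0).astype(int) if depth is None else np.asarray(depth),
        allele_balance=full(np.nan) if allele_balance is None else np.asarray(allele_balance, float),
    )


@pytest.fixture
def tiny_dataset():
    """4 samples (2 cases), 3 variants; sample 0 carries v0, sample 2 carries v1."""
    geno = [[1, 0, 0], [0, 0, 0], [0, 1, 0], [0, 0, 0]]
    return make_dataset(geno, [1, 1, 0, 0])
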