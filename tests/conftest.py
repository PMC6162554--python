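import numpy as np
import pytest

from epiweight.io import Dataset


def make_dataset(columns, phenotype, ids=None) -> Dataset:
    """Build a Dataset from per-SNP genotype columns and a phenotype list."""
    geno = np.column_stack([np.asarray(c, dtype=np.int8) for c in columns])
    ids = ids or [f"S{i}" for i in range(geno.shape[1])]
    return Dataset(geno, np.asarray(phenotype, dtype=np.int8), ids)


def dataset_from_cells(cells, n_snps) -> Dataset:
    """Expand {(g1..gk, pheno): count} cell counts into an explicit Dataset."""
    cols = [[] for _ in range(n_snps)]
    pheno = []
    for key, count in sorted(cells.items()):
        *genos, c = key
        for _ in range(count):
            for j in range(n_snps):
                cols[j].append(genos[j])
            pheno.append(c)
    return make_dataset(cols, pheno)


@pytest.fixture
def xor_dataset() -> Dataset:
    """Two binary-coded SNPs; phenotype is exactly their parity.

    Cell counts are balanced so each SNP alone is independent of the
    phenotype while the pair determines it: the canonical pure-epistasis
    construction.
    """
    cells = {
        (0, 0, 0): 25,
        (0, 1, 1): 25,
        (1, 0, 1): 25,
        (1, 1, 0): 25,
    }
    return dataset_from_cells(cells, n_snps=2)


def random_dataset(rng, n=None, n_snps=None, missing_rate=0.0) -> Dataset:
    n = n if n is not None else int(rng.integers(20, 201))
    n_snps = n_snps if n_snps is not None else int(rng.integers(2, 11))
    geno = rng.integers(0, 3, size=(n, n_snps)).astype(np.int8)
    if missing_rate > 0:
        mask = rng.random(geno.shape) < missing_rate
        geno[mask] = -1
    pheno = rng.integers(0, 2, size=n).astype(np.int8)
    # make sure both phenotype classes are present
    pheno[0], pheno[1] = 0, 1
    return Dataset(geno, pheno, [f"S{i}" for i in range(n_snps)])
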