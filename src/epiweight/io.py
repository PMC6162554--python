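"""Dataset container, delimited-text IO, kNN imputation and bootstrap balancing.

The canonical on-disk form is a GAMETES-style TSV: one header row of SNP
identifiers followed by a binary class column (``Class`` by default), one
sample per row, genotypes coded 0 (homozygous major), 1 (heterozygous),
2 (homozygous minor). Missing genotypes are written as ``NA`` and accepted
as ``NA``, ``-9`` or an empty field on input.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = -1
_MISSING_MARKERS = {"NA", "na", "Na", "-9", ""}


@dataclass
class Dataset:
    """Case-control genotype matrix with a binary phenotype.

    Attributes
    ----------
    genotypes : (n_samples, n_snps) int8 array with values {0, 1, 2} or
        ``MISSING`` (-1) for unobserved cells.
    phenotype : (n_samples,) int8 array, 1 = case, 0 = control.
    snp_ids : one identifier per genotype column.
    provenance : free-form record of where the data came from (source path
        or simulation parameters, resampling history, ...).
    """

    genotypes: np.ndarray
    phenotype: np.ndarray
    snp_ids: list[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.phenotype = np.asarray(self.phenotype, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-D samples x SNPs array")
        if self.phenotype.shape != (self.genotypes.shape[0],):
            raise ValueError(
                f"phenotype length {self.phenotype.shape} does not match "
                f"{self.genotypes.shape[0]} samples"
            )
        if len(self.snp_ids) != self.genotypes.shape[1]:
            raise ValueError(
                f"{len(self.snp_ids)} SNP ids for {self.genotypes.shape[1]} columns"
            )
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid genotype value {self.genotypes[r, c]} at sample {r}, "
                f"SNP {self.snp_ids[c]!r}: genotypes must be 0, 1, 2 or missing"
            )
        if not np.isin(self.phenotype, (0, 1)).all():
            raise ValueError("phenotype must be binary (1 = case, 0 = control)")

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def n_cases(self) -> int:
        return int((self.phenotype == 1).sum())

    @property
    def n_controls(self) -> int:
        return int((self.phenotype == 0).sum())

    def has_missing(self) -> bool:
        return bool((self.genotypes == MISSING).any())

    def copy(self) -> "Dataset":
        return Dataset(
            self.genotypes.copy(),
            self.phenotype.copy(),
            list(self.snp_ids),
            copy.deepcopy(self.provenance),
        )

    def sample_maf(self, snp: int, fold: bool = True) -> float:
        """Sample frequency of the allele coded as minor (allele ``2``).

        With ``fold=True`` the frequency is folded onto (0, 0.5] so that it
        is a minor-allele frequency even when the coded-minor allele is in
        fact the commoner one in this sample.
        """
        col = self.genotypes[:, snp]
        obs = col[col != MISSING]
        if obs.size == 0:
            raise ValueError(f"SNP column {self.snp_ids[snp]!r} is entirely missing")
        q = float(obs.sum()) / (2.0 * obs.size)
        return min(q, 1.0 - q) if fold else q


def write_dataset(dataset: Dataset, path: str | Path, class_column: str = "Class") -> None:
    """Write a tab-separated file with Unix newlines; missing cells as ``NA``."""
    cols = {}
    for j, sid in enumerate(dataset.snp_ids):
        col = dataset.genotypes[:, j].astype(object)
        col[col == MISSING] = "NA"
        cols[sid] = col
    cols[class_column] = dataset.phenotype
    df = pd.DataFrame(cols)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_dataset(
    path: str | Path,
    dialect: str = "gametes_tsv",
    class_column: str = "Class",
) -> Dataset:
    """Read a delimited genotype file into a :class:`Dataset`.

    ``dialect`` is ``gametes_tsv`` (tab-separated, default) or ``csv``.
    The class column is located by name (case-insensitive match against
    ``class_column``); if absent, the last column is taken as the phenotype.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect not in ("gametes_tsv", "csv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    sep = "\t" if dialect == "gametes_tsv" else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need at least one SNP column and a class column")

    matches = [c for c in df.columns if c.lower() == class_column.lower()]
    cls = matches[0] if matches else df.columns[-1]
    snp_cols = [c for c in df.columns if c != cls]

    pheno = pd.to_numeric(df[cls], errors="coerce")
    if pheno.isna().any() or not pheno.isin((0, 1)).all():
        bad = df[cls][~pheno.isin((0, 1))].iloc[0]
        raise ValueError(f"{path}: class column {cls!r} has non-binary value {bad!r}")

    geno = np.empty((df.shape[0], len(snp_cols)), dtype=np.int8)
    for j, c in enumerate(snp_cols):
        raw = df[c].str.strip()
        is_missing = raw.isin(_MISSING_MARKERS)
        vals = pd.to_numeric(raw.mask(is_missing, "0"), errors="coerce")
        ok = vals.isin((0, 1, 2))
        if not ok.all():
            row = int(np.argmax(~ok.to_numpy()))
            raise ValueError(
                f"{path}: invalid genotype {raw.iloc[row]!r} at row {row + 2} "
                f"(sample {row}), column {c!r}: genotypes must be 0, 1, 2 or a "
                f"missing marker ({sorted(m for m in _MISSING_MARKERS if m)})"
            )
        col = vals.to_numpy(dtype=np.int8)
        col[is_missing.to_numpy()] = MISSING
        geno[:, j] = col

    return Dataset(
        geno,
        pheno.to_numpy(dtype=np.int8),
        snp_cols,
        provenance={"source": str(path), "dialect": dialect},
    )


def impute_knn(dataset: Dataset, k_neighbors: int = 5) -> Dataset:
    """Fill missing genotypes by majority vote among the k nearest samples.

    Distance between two samples is the Hamming distance over their mutually
    observed genotype columns, normalised by the number of such columns
    (samples sharing no observed column are at distance 1, the maximum).
    Ties in the vote go to the lower genotype value; nearest-neighbour ties
    are broken by sample order. The result is deterministic and observed
    cells are never altered.
    """
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be >= 1")
    if not dataset.has_missing():
        return dataset
    g = dataset.genotypes
    all_missing_cols = np.flatnonzero((g == MISSING).all(axis=0))
    if all_missing_cols.size:
        raise ValueError(
            f"SNP column {dataset.snp_ids[all_missing_cols[0]]!r} is entirely "
            "missing and cannot be imputed"
        )
    observed = g != MISSING
    if not observed.any(axis=1).all():
        raise ValueError("a sample with no observed genotypes cannot be imputed")

    n = g.shape[0]
    # Normalised Hamming distance via masked mismatch counts.
    obs_f = observed.astype(np.float32)
    shared = obs_f @ obs_f.T  # mutually observed column counts
    matches = np.zeros((n, n), dtype=np.float32)
    for v in (0, 1, 2):
        iv = (np.where(observed, g, MISSING) == v).astype(np.float32)
        matches += iv @ iv.T
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = 1.0 - np.where(shared > 0, matches / shared, 0.0)
    np.fill_diagonal(dist, np.inf)

    out = g.copy()
    rows = np.flatnonzero(~observed.all(axis=1))
    for i in rows:
        order = np.argsort(dist[i], kind="stable")
        for j in np.flatnonzero(~observed[i]):
            donors = order[observed[order, j]][:k_neighbors]
            if donors.size == 0:  # unreachable: column has >=1 observation
                raise ValueError("no donor sample for imputation")
            votes = np.bincount(g[donors, j], minlength=3)
            out[i, j] = int(np.argmax(votes))  # argmax ties -> lower genotype
    result = dataset.copy()
    result.genotypes = out
    result.provenance = dict(result.provenance, imputation={"method": "knn", "k": k_neighbors})
    return result


def balance_bootstrap(dataset: Dataset, rng_seed: int = 0) -> Dataset:
    """Resample the minority class with replacement until classes are equal.

    The majority class is untouched; resampled rows are appended after the
    original samples and the drawn indices are recorded in provenance.
    """
    n_case, n_ctrl = dataset.n_cases, dataset.n_controls
    if n_case == 0 or n_ctrl == 0:
        raise ValueError("both classes must be present to balance")
    if n_case == n_ctrl:
        return dataset
    minority = 1 if n_case < n_ctrl else 0
    pool = np.flatnonzero(dataset.phenotype == minority)
    deficit = abs(n_case - n_ctrl)
    rng = np.random.default_rng(rng_seed)
    extra = rng.choice(pool, size=deficit, replace=True)
    result = dataset.copy()
    result.genotypes = np.vstack([dataset.genotypes, dataset.genotypes[extra]])
    result.phenotype = np.concatenate([dataset.phenotype, dataset.phenotype[extra]])
    result.provenance = dict(
        result.provenance,
        bootstrap={
            "minority_class": int(minority),
            "resampled_indices": extra.tolist(),
            "rng_seed": int(rng_seed),
        },
    )
    return result
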