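"""Penetrance-table case-control simulator.

Generates balanced (or arbitrary-quota) case-control genotype datasets in
the style of the GAMETES family of epistasis simulators: k disease loci
whose joint genotype, drawn under Hardy–Weinberg equilibrium at stated
minor-allele frequencies, determines the case probability through a 3^k
penetrance table; the disease loci are embedded at randomised column
positions among null SNPs that are independent of disease status.

The shipped model catalogue contains small synthetic fixtures (clearly
labelled as such) spanning the classical epistasis archetypes:
multiplicative, threshold, pure-parity (XOR) and a nested three-locus
model with marginal effects.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .io import Dataset

NULL_MAF_RANGE = (0.05, 0.5)


@dataclass(frozen=True)
class PenetranceModel:
    """A k-locus disease model: MAF per locus plus a 3^k penetrance table.

    ``table`` is indexed by genotype tuple, ``table[g1, ..., gk]`` =
    P(case | genotypes g1..gk), each entry in [0, 1].
    """

    k: int
    maf: tuple
    table: np.ndarray
    label: str = "unnamed"

    def __post_init__(self) -> None:
        object.__setattr__(self, "table", np.asarray(self.table, dtype=float))
        if self.table.shape != (3,) * self.k:
            raise ValueError(
                f"penetrance table must have shape {(3,) * self.k}, "
                f"got {self.table.shape}"
            )
        if len(self.maf) != self.k:
            raise ValueError(f"{len(self.maf)} MAFs for k={self.k} loci")
        if any(not 0 < m <= 0.5 for m in self.maf):
            raise ValueError("each MAF must be in (0, 0.5]")
        if ((self.table < 0) | (self.table > 1)).any():
            raise ValueError("penetrance values must be in [0, 1]")

    def genotype_probs(self) -> np.ndarray:
        """HWE probability of each joint genotype cell, shape (3,)*k."""
        p = np.ones(())
        for m in self.maf:
            locus = np.array([(1 - m) ** 2, 2 * m * (1 - m), m ** 2])
            p = np.multiply.outer(p, locus)
        return p

    def prevalence(self) -> float:
        """Population P(case) implied by the table at the model's MAFs."""
        return float((self.genotype_probs() * self.table).sum())

    def marginal_penetrance(self, locus: int) -> np.ndarray:
        """P(case | genotype at one locus), marginalised over the others."""
        probs = self.genotype_probs()
        axes = tuple(a for a in range(self.k) if a != locus)
        joint = (probs * self.table).sum(axis=axes)
        margin = probs.sum(axis=axes)
        return joint / margin


@dataclass
class SimulationSpec:
    """Sample quotas and model for one simulated dataset."""

    n_cases: int
    n_controls: int
    n_null_snps: int
    model: Optional[PenetranceModel] = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_cases, self.n_controls, self.n_null_snps) < 0:
            raise ValueError("counts must be non-negative")


def genotype_hwe(maf: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """n i.i.d. genotypes with P(0,1,2) = ((1−q)², 2q(1−q), q²), q = maf."""
    if not 0 < maf <= 0.5:
        raise ValueError("maf must be in (0, 0.5]")
    p = [(1 - maf) ** 2, 2 * maf * (1 - maf), maf ** 2]
    return rng.choice(3, size=n, p=p).astype(np.int8)


_MAX_DRAWS = 50_000_000


def simulate_dataset(spec: SimulationSpec) -> Dataset:
    """Draw a case-control dataset by rejection sampling against the model.

    Disease-locus genotypes are drawn under HWE; each draw becomes a case
    with probability equal to its penetrance and is kept while its class
    quota is open, until both quotas are exactly filled. Null SNPs are
    drawn independently of status with MAFs uniform on [0.05, 0.5]. The
    disease loci are placed at randomised columns, recorded in
    ``provenance['disease_columns']``. Bit-reproducible for a fixed seed.
    """
    rng = np.random.default_rng(spec.rng_seed)
    model = spec.model
    k = model.k if model is not None else 0
    n_total = spec.n_cases + spec.n_controls

    if model is not None and n_total > 0:
        pen = model.table
        if spec.n_cases > 0 and (pen == 0).all():
            raise ValueError("penetrance table admits no cases")
        if spec.n_controls > 0 and (pen == 1).all():
            raise ValueError("penetrance table admits no controls")
        case_rows, ctrl_rows = [], []
        need_case, need_ctrl = spec.n_cases, spec.n_controls
        locus_p = [
            np.array([(1 - m) ** 2, 2 * m * (1 - m), m ** 2]) for m in model.maf
        ]
        batch = max(4096, 2 * n_total)
        drawn = 0
        while need_case > 0 or need_ctrl > 0:
            if drawn > _MAX_DRAWS:
                raise RuntimeError(
                    f"case/control quotas unattainable after {drawn} draws; "
                    "check the penetrance table and MAFs"
                )
            g = np.column_stack(
                [rng.choice(3, size=batch, p=p) for p in locus_p]
            ).astype(np.int8)
            drawn += batch
            p_case = pen[tuple(g.T)]
            is_case = rng.random(batch) < p_case
            if need_case > 0:
                take = g[is_case][:need_case]
                case_rows.append(take)
                need_case -= take.shape[0]
            if need_ctrl > 0:
                take = g[~is_case][:need_ctrl]
                ctrl_rows.append(take)
                need_ctrl -= take.shape[0]
        disease_geno = np.vstack(
            [np.concatenate(case_rows) if case_rows else np.empty((0, k), np.int8),
             np.concatenate(ctrl_rows) if ctrl_rows else np.empty((0, k), np.int8)]
        )
        phenotype = np.concatenate(
            [np.ones(spec.n_cases, np.int8), np.zeros(spec.n_controls, np.int8)]
        )
    else:
        disease_geno = np.empty((n_total, 0), dtype=np.int8)
        phenotype = np.concatenate(
            [np.ones(spec.n_cases, np.int8), np.zeros(spec.n_controls, np.int8)]
        )

    # shuffle sample order so case/control blocks are interleaved
    order = rng.permutation(n_total)
    disease_geno = disease_geno[order]
    phenotype = phenotype[order]

    null_mafs = rng.uniform(*NULL_MAF_RANGE, size=spec.n_null_snps)
    null_geno = np.empty((n_total, spec.n_null_snps), dtype=np.int8)
    for j, m in enumerate(null_mafs):
        null_geno[:, j] = genotype_hwe(float(m), n_total, rng)

    n_snps = k + spec.n_null_snps
    disease_cols = np.sort(rng.choice(n_snps, size=k, replace=False)) if k else np.array([], int)
    genotypes = np.empty((n_total, n_snps), dtype=np.int8)
    null_cols = [c for c in range(n_snps) if c not in set(disease_cols.tolist())]
    genotypes[:, disease_cols] = disease_geno
    genotypes[:, null_cols] = null_geno
    snp_ids = [f"N{c}" for c in range(n_snps)]
    for rank, c in enumerate(disease_cols):
        snp_ids[c] = f"M{rank}"  # disease ("model") loci

    return Dataset(
        genotypes,
        phenotype,
        snp_ids,
        provenance={
            "simulation": {
                "model": model.label if model is not None else None,
                "maf": list(model.maf) if model is not None else [],
                "n_cases": spec.n_cases,
                "n_controls": spec.n_controls,
                "rng_seed": spec.rng_seed,
            },
            "disease_columns": disease_cols.tolist(),
            "null_mafs": {int(c): float(m) for c, m in zip(null_cols, null_mafs)},
        },
    )


def _table(k: int, fn) -> np.ndarray:
    t = np.empty((3,) * k)
    for g in itertools.product(range(3), repeat=k):
        t[g] = fn(*g)
    return t


def builtin_models() -> dict:
    """Synthetic fixture models covering the classical epistasis archetypes.

    These are small hand-written tables for exercising the pipeline; they
    are not drawn from any published disease-model catalogue.
    """
    models = {}
    models["multiplicative"] = PenetranceModel(
        k=2, maf=(0.3, 0.3),
        table=_table(2, lambda a, b: min(1.0, 0.07 * 1.9 ** (a + b))),
        label="multiplicative",
    )
    # strong two-locus threshold model: risk jumps when both loci carry
    # at least one minor allele
    models["threshold"] = PenetranceModel(
        k=2, maf=(0.3, 0.3),
        table=_table(2, lambda a, b: 0.62 if (a >= 1 and b >= 1) else 0.05),
        label="threshold",
    )
    # pure parity interaction: at MAF 0.5 each locus alone carries no
    # information about status (the regime where marginal-effect searches
    # are expected to struggle)
    models["xor"] = PenetranceModel(
        k=2, maf=(0.5, 0.5),
        table=_table(2, lambda a, b: 0.7 if (a + b) % 2 == 1 else 0.3),
        label="xor",
    )
    # nested three-locus model: a strong two-locus core whose effect is
    # amplified by a third locus; every locus has a marginal effect
    models["nested3"] = PenetranceModel(
        k=3, maf=(0.3, 0.3, 0.25),
        table=_table(
            3,
            lambda a, b, c: 0.04
            * (5.0 if (a >= 1 and b >= 1) else 1.0)
            * (2.0 if (a >= 1 and b >= 1 and c >= 1) else 1.0),
        ),
        label="nested3",
    )
    return models
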