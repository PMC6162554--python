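"""Information-theoretic association measures for genotype data.

All quantities are in nats (natural logarithm) and use maximum-likelihood
plug-in probabilities (cell count / n) with the convention 0·log 0 = 0.
Entropy H, joint entropy, mutual information I(X;C), joint mutual
information I([X1..Xk];C), interaction gain IG, the interaction weight
factor IWF and the (standard and modified) symmetrical uncertainty SU are
all computed from contingency tables of genotype counts against the binary
case/control phenotype.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import MISSING, Dataset

log = logging.getLogger(__name__)

#: largest combination order accepted by default (3^k joint cells must fit)
DEFAULT_K_MAX = 6

#: magnitude of negative float noise tolerated before raising
NEG_TOL = 1e-12

PHENOTYPE_AXIS = "phenotype"


@dataclass(frozen=True)
class DiscreteDistribution:
    """A finite distribution estimated from ``n`` samples."""

    support: tuple
    probs: tuple
    n: int

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if len(self.support) != p.size:
            raise ValueError("support and probs lengths differ")
        if (p < 0).any():
            raise ValueError("probabilities must be non-negative")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError(f"probabilities sum to {p.sum()!r}, not 1")


@dataclass
class JointTable:
    """Joint genotype (and optionally phenotype) counts.

    ``counts`` is shaped ``(3,) * k`` for k SNP axes, with a trailing axis
    of length 2 (control=0, case=1) when the phenotype is included. Cell
    order is lexicographic over genotype tuples, (0,0,..) first.
    """

    axes: list[str]
    counts: np.ndarray
    n: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != len(self.axes):
            raise ValueError("axes/counts dimensionality mismatch")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if int(self.counts.sum()) != self.n:
            raise ValueError("counts do not sum to n")

    @property
    def has_phenotype(self) -> bool:
        return bool(self.axes) and self.axes[-1] == PHENOTYPE_AXIS


def joint_counts(
    dataset: Dataset,
    snp_indices: Sequence[int],
    include_phenotype: bool = True,
) -> JointTable:
    """Count samples over the 3^k joint genotype cells of the given SNPs.

    Zero-count cells are present (with count 0); with ``include_phenotype``
    a trailing control/case axis is added.
    """
    idx = list(snp_indices)
    if len(set(idx)) != len(idx):
        raise ValueError(f"duplicate SNP index in {idx}")
    for i in idx:
        if not 0 <= i < dataset.n_snps:
            raise IndexError(f"SNP index {i} out of range (N={dataset.n_snps})")
    cols = dataset.genotypes[:, idx]
    if (cols == MISSING).any():
        raise ValueError(
            "selected SNP columns contain missing genotypes; impute first "
            "(e.g. epiweight.io.impute_knn)"
        )
    shape = (3,) * len(idx)
    axes = [dataset.snp_ids[i] for i in idx]
    if include_phenotype:
        shape = shape + (2,)
        code = np.ravel_multi_index(
            tuple(cols.T) + (dataset.phenotype,), dims=shape
        )
        axes = axes + [PHENOTYPE_AXIS]
    elif idx:
        code = np.ravel_multi_index(tuple(cols.T), dims=shape)
    else:
        raise ValueError("need at least one SNP axis or the phenotype")
    counts = np.bincount(code, minlength=int(np.prod(shape))).reshape(shape)
    return JointTable(axes=axes, counts=counts, n=dataset.n_samples)


def entropy_from_counts(counts: np.ndarray) -> float:
    """Plug-in Shannon entropy (nats) of a count table of any shape."""
    c = np.asarray(counts, dtype=float).ravel()
    n = c.sum()
    if n <= 0:
        raise ValueError("empty table has no entropy")
    p = c[c > 0] / n
    return float(-(p * np.log(p)).sum())


def entropy(dist: DiscreteDistribution) -> float:
    """H(X) = −Σ p log p in nats, with 0 log 0 := 0."""
    p = np.asarray(dist.probs, dtype=float)
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def joint_entropy(table: JointTable) -> float:
    """Joint entropy of all axes of ``table`` in nats."""
    return entropy_from_counts(table.counts)


def _clamp_mi(value: float) -> float:
    if value < 0:
        if value < -NEG_TOL:
            raise AssertionError(f"mutual information {value} below float-noise floor")
        return 0.0
    return value


def mutual_information(table: JointTable) -> float:
    """I(X;C) = H(X) + H(C) − H(X,C) for a single-SNP × phenotype table."""
    if not table.has_phenotype or table.counts.ndim != 2:
        raise ValueError("table must have exactly one SNP axis and the phenotype axis")
    hx = entropy_from_counts(table.counts.sum(axis=1))
    hc = entropy_from_counts(table.counts.sum(axis=0))
    hxc = entropy_from_counts(table.counts)
    return _clamp_mi(hx + hc - hxc)


def joint_mutual_information(
    dataset: Dataset,
    snp_indices: Sequence[int],
    k_max: int = DEFAULT_K_MAX,
) -> float:
    """I([X1..Xk]; C) = H(X1..Xk) + H(C) − H(X1..Xk, C), in nats."""
    k = len(snp_indices)
    if k < 1:
        raise ValueError("need at least one SNP")
    if k > k_max:
        raise ValueError(
            f"k={k} exceeds k_max={k_max}: the joint table would need 3^{k} "
            f"= {3 ** k} genotype cells"
        )
    table = joint_counts(dataset, snp_indices, include_phenotype=True)
    hx = entropy_from_counts(table.counts.sum(axis=-1))
    hc = entropy_from_counts(table.counts.reshape(-1, 2).sum(axis=0))
    hxc = entropy_from_counts(table.counts)
    return _clamp_mi(hx + hc - hxc)


def interaction_gain(x: int, y: int, dataset: Dataset) -> float:
    """IG(X;Y;C) = I([X,Y];C) − I(X;C) − I(Y;C).

    Positive values indicate synergy between the two SNPs with respect to
    the phenotype, negative values redundancy.
    """
    if x == y:
        raise ValueError("interaction gain requires two distinct SNPs")
    i_xy = joint_mutual_information(dataset, [x, y])
    i_x = mutual_information(joint_counts(dataset, [x]))
    i_y = mutual_information(joint_counts(dataset, [y]))
    return i_xy - i_x - i_y


def interaction_weight_factor(x: int, y: int, dataset: Dataset) -> float:
    """IWF(X,Y) = 1 + IG(X;Y;C) / (H(X) + H(Y)), in [0, 2].

    Values above 1 flag an interacting pair, below 1 a redundant one. If
    both SNPs are constant (H(X)+H(Y)=0) the factor is defined as the
    neutral value 1 and the event is logged.
    """
    hx = entropy_from_counts(joint_counts(dataset, [x], include_phenotype=False).counts)
    hy = entropy_from_counts(joint_counts(dataset, [y], include_phenotype=False).counts)
    denom = hx + hy
    if denom <= 0.0:
        log.warning(
            "IWF(%s, %s): both SNPs constant (H(X)+H(Y)=0); returning neutral 1.0",
            dataset.snp_ids[x], dataset.snp_ids[y],
        )
        return 1.0
    return 1.0 + interaction_gain(x, y, dataset) / denom


def symmetrical_uncertainty(x: int, dataset: Dataset, mode: str = "modified") -> float:
    """Symmetrical uncertainty between SNP ``x`` and the phenotype.

    ``standard``: 2·I(X;C) / (H(X)+H(C)), in [0, 1].
    ``modified`` (default, used by the search): 2·I(X;C) / H(X,C), in
    [0, 2] — normalising by the joint entropy instead of the marginal sum
    sharpens weak associations, since H(X,C) ≤ H(X)+H(C) always.

    A constant SNP scores 0 by convention; a constant phenotype is an error.
    """
    if mode not in ("standard", "modified"):
        raise ValueError(f"unknown SU mode {mode!r}")
    table = joint_counts(dataset, [x], include_phenotype=True)
    hc = entropy_from_counts(table.counts.sum(axis=0))
    if hc <= 0.0:
        raise ValueError("phenotype is constant; SU undefined")
    hx = entropy_from_counts(table.counts.sum(axis=1))
    if hx <= 0.0:
        return 0.0
    hxc = entropy_from_counts(table.counts)
    i_xc = _clamp_mi(hx + hc - hxc)
    denom = (hx + hc) if mode == "standard" else hxc
    return 2.0 * i_xc / denom
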