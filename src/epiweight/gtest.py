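"""Improved G-test of genotype-phenotype association.

The statistic is the likelihood-ratio G = 2 Σ O·ln(O/E) over the I × 2
table of k-way genotype combinations against case/control status, with a
small-cell gate ξ: genotype rows whose total count is at or below ξ are
excluded from the sum and each removes one degree of freedom from the
nominal d = (I−1)(J−1). The p-value is the upper chi-square tail at the
adjusted df; when every row is gated (df = 0) the p-value is 1 and the
combination cannot be declared significant.

Expected counts come from independence margins by default (the classical
G-test). An alternative ``hwe`` mode builds genotype-row probabilities
from per-locus Hardy–Weinberg frequencies (1−q)², 2q(1−q), q² at the
pooled allele-2 frequency q, multiplied across loci and scaled to the
case/control column totals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .info import JointTable, joint_counts
from .io import Dataset

XI_DEFAULT = 5


@dataclass
class GTestResult:
    """Outcome of one improved G-test.

    ``cell_terms`` holds the per-cell O·ln(O/E) contributions (zero in
    gated rows and for empty cells); ``excluded_rows`` counts the genotype
    rows gated out by ξ.
    """

    g: float
    df: int
    p_value: float
    excluded_rows: int
    cell_terms: np.ndarray


def _as_rows(observed) -> np.ndarray:
    counts = observed.counts if isinstance(observed, JointTable) else np.asarray(observed)
    if counts.shape[-1] != 2:
        raise ValueError("observed table must have a trailing case/control axis")
    return counts.reshape(-1, 2).astype(float)


def expected_counts(
    observed,
    mode: str = "independence",
    maf: Sequence[float] | None = None,
) -> np.ndarray:
    """Expected I × 2 counts under the null, by margins or HWE.

    ``independence``: E_ij = (row_i total · column_j total) / n.
    ``hwe``: per-locus Hardy–Weinberg genotype probabilities at allele-2
    frequency ``maf[l]``, multiplied across loci (lexicographic row order)
    and renormalised so each phenotype column sums to its observed total.
    """
    obs = _as_rows(observed)
    n = obs.sum()
    if n <= 0:
        raise ValueError("empty observed table")
    col_tot = obs.sum(axis=0)
    if mode == "independence":
        row_tot = obs.sum(axis=1)
        return np.outer(row_tot, col_tot) / n
    if mode == "hwe":
        if maf is None:
            raise ValueError("hwe mode requires per-SNP allele frequencies")
        q = np.asarray(maf, dtype=float)
        if (3 ** q.size) != obs.shape[0]:
            raise ValueError(
                f"{q.size} allele frequencies for {obs.shape[0]} genotype rows"
            )
        if np.isnan(q).any():
            raise ValueError("allele frequency not computable (all-missing column)")
        row_p = np.ones(1)
        for ql in q:
            locus = np.array([(1 - ql) ** 2, 2 * ql * (1 - ql), ql ** 2])
            row_p = np.kron(row_p, locus)  # lexicographic genotype order
        s = row_p.sum()
        if s <= 0:
            raise ValueError("degenerate HWE probabilities")
        row_p = row_p / s
        return row_p[:, None] * col_tot[None, :]
    raise ValueError(f"unknown expectation mode {mode!r}")


def g_statistic(
    observed, expected, xi: int = XI_DEFAULT
) -> tuple[float, int, int, np.ndarray]:
    """G, adjusted df, excluded-row count and per-cell terms.

    A genotype row is excluded iff its total observed count is ≤ ξ: it
    contributes nothing to G and removes one degree of freedom (floored
    at 0). Cells with O = 0 contribute 0.
    """
    obs = _as_rows(observed)
    exp = _as_rows(expected)
    if obs.shape != exp.shape:
        raise ValueError("observed and expected shapes differ")
    if not 0 <= xi <= 5:
        raise ValueError("xi must be an integer in [0, 5]")
    n_rows, n_cols = obs.shape
    row_tot = obs.sum(axis=1)
    included = row_tot > xi
    excluded = int((~included).sum())
    if (included[:, None] & (exp <= 0) & (obs > 0)).any():
        raise ValueError("zero expected count with positive observed count in an included row")
    terms = np.zeros_like(obs)
    mask = included[:, None] & (obs > 0)
    terms[mask] = obs[mask] * np.log(obs[mask] / exp[mask])
    # Row gating can leave a (rare) negative partial sum; G is floored at 0,
    # the value it takes when the data fit the null at least as well.
    g = max(0.0, 2.0 * float(terms.sum()))
    df = max(0, (n_rows - 1) * (n_cols - 1) - excluded)
    return g, df, excluded, terms


def g_test(
    dataset: Dataset,
    combo: Sequence[int],
    xi: int = XI_DEFAULT,
    mode: str = "independence",
) -> GTestResult:
    """Improved G-test of a k-way SNP combination against the phenotype."""
    table = joint_counts(dataset, combo, include_phenotype=True)
    maf = None
    if mode == "hwe":
        maf = [dataset.sample_maf(i, fold=False) for i in combo]
    exp = expected_counts(table, mode=mode, maf=maf)
    g, df, excluded, terms = g_statistic(table, exp, xi=xi)
    p = float(stats.chi2.sf(g, df)) if df > 0 else 1.0
    return GTestResult(g=g, df=df, p_value=p, excluded_rows=excluded, cell_terms=terms)
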