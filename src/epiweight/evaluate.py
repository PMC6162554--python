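"""Simulation-study evaluation: TP/FP/FN/TN bookkeeping, power, recall,
precision, F-measure, and per-combination AUC.

Definitions (per replicate dataset with one planted disease combination):

* TP — the planted combination is among the candidates and passes the
  p-value threshold;
* FN — the planted combination was found at the search stage but failed
  the test;
* FP — a non-planted candidate that passed the threshold;
* TN — a non-planted candidate that failed it.

Power is the fraction of replicate datasets in which the planted model is
detected (TP count over the number of datasets); recall, precision and
the F-measure summarise the testing stage:

    recall = TP/(TP+FN),  precision = TP/(TP+FP),
    F = 2 / (1/recall + 1/precision).

All four are reported as percentages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from .info import joint_counts
from .io import Dataset
from .search import SNPCombination


@dataclass
class EvaluationReport:
    tp: int
    fp: int
    fn: int
    tn: int
    n_datasets: int
    power: float
    recall: float
    precision: float
    f_measure: float
    flags: list = field(default_factory=list)


def round_pct(x: float) -> float:
    """Two-decimal half-up rounding for reported percentages."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def classify_outcomes(
    results: Sequence[Sequence[SNPCombination]],
    truths: Sequence[Sequence[int]],
) -> tuple[int, int, int, int]:
    """Tally TP/FP/FN/TN over replicate datasets.

    ``results[r]`` is the full annotated candidate list of replicate r
    (every candidate must carry its ``significant`` flag); ``truths[r]``
    is the planted combination's SNP indices for that replicate.
    """
    if len(results) != len(truths):
        raise ValueError("one truth combination is required per replicate")
    tp = fp = fn = tn = 0
    for candidates, truth in zip(results, truths):
        truth_key = tuple(sorted(truth))
        for combo in candidates:
            if combo.significant is None:
                raise ValueError("candidates must be annotated (run annotate_candidates)")
            if combo.key == truth_key:
                if combo.significant:
                    tp += 1
                else:
                    fn += 1
            elif combo.significant:
                fp += 1
            else:
                tn += 1
    return tp, fp, fn, tn


def metrics(counts: tuple[int, int, int, int], n_datasets: int) -> EvaluationReport:
    """Power/recall/precision/F-measure (in %) from TP/FP/FN/TN counts."""
    if n_datasets < 1:
        raise ValueError("need at least one dataset")
    tp, fp, fn, tn = counts
    flags = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            flags.append(f"{name}: zero denominator, reported as 0")
            return 0.0
        return 100.0 * num / den

    power = ratio(tp, n_datasets, "power")
    recall = ratio(tp, tp + fn, "recall")
    precision = ratio(tp, tp + fp, "precision")
    if recall + precision == 0:
        flags.append("f_measure: recall + precision = 0, reported as 0")
        f_measure = 0.0
    else:
        f_measure = 2.0 * recall * precision / (recall + precision)
    return EvaluationReport(
        tp=tp, fp=fp, fn=fn, tn=tn, n_datasets=n_datasets,
        power=power, recall=recall, precision=precision, f_measure=f_measure,
        flags=flags,
    )


def f_measure(recall: float, precision: float) -> float:
    """Harmonic mean 2/(1/recall + 1/precision); 0 when both rates are 0.

    Unit-agnostic: feed fractions to get a fraction, percentages to get a
    percentage.
    """
    if recall < 0 or precision < 0:
        raise ValueError("rates must be non-negative")
    if recall + precision == 0:
        return 0.0
    return 2.0 * recall * precision / (recall + precision)


def auc_combination(dataset: Dataset, combo: Sequence[int]) -> float:
    """Resubstitution AUC of a combination's plug-in genotype risk score.

    Each sample is scored with the case fraction of its joint genotype
    cell; the AUC is the tie-corrected Mann–Whitney statistic of that
    score against case/control status.
    """
    table = joint_counts(dataset, combo, include_phenotype=True)
    counts = table.counts.reshape(-1, 2).astype(float)
    totals = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        risk = np.where(totals > 0, counts[:, 1] / np.maximum(totals, 1), 0.0)
    cols = dataset.genotypes[:, list(combo)]
    cell = np.ravel_multi_index(tuple(cols.T), dims=(3,) * len(combo))
    scores = risk[cell]
    y = dataset.phenotype
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires both cases and controls")
    ranks = rankdata(scores)  # average ranks: tie-corrected Mann-Whitney
    auc = (ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    return float(auc)
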