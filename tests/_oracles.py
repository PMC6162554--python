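"""Naive, sample-loop reference implementations used only as test oracles.

Everything here is written as plain nested loops over raw samples (or
definitional sums over cells), deliberately independent of the package's
vectorised counting path.
"""

from __future__ import annotations

import math
from collections import Counter


def entropy_of_column(values) -> float:
    """H of one variable by direct frequency counting, in nats."""
    n = len(values)
    counts = Counter(values)
    h = 0.0
    for c in counts.values():
        p = c / n
        if p > 0:
            h -= p * math.log(p)
    return h


def joint_entropy_of_columns(columns) -> float:
    """H of the tuple-valued variable formed by zipping the columns."""
    return entropy_of_column(list(zip(*columns)))


def mutual_information_definitional(x, c) -> float:
    """I(X;C) by the definitional sum over cells: Σ p log(p/(p_x p_c))."""
    n = len(x)
    px = Counter(x)
    pc = Counter(c)
    pxc = Counter(zip(x, c))
    total = 0.0
    for (xv, cv), cnt in pxc.items():
        p = cnt / n
        total += p * math.log(p / ((px[xv] / n) * (pc[cv] / n)))
    return total


def joint_mutual_information_loop(columns, c) -> float:
    """I([X1..Xk];C) = H(X...) + H(C) − H(X..., C) by direct counting."""
    hx = joint_entropy_of_columns(columns)
    hc = entropy_of_column(c)
    hxc = joint_entropy_of_columns(list(columns) + [list(c)])
    return hx + hc - hxc


def interaction_gain_loop(x, y, c) -> float:
    return (
        joint_mutual_information_loop([x, y], c)
        - mutual_information_definitional(x, c)
        - mutual_information_definitional(y, c)
    )


def interaction_weight_factor_loop(x, y, c) -> float:
    denom = entropy_of_column(x) + entropy_of_column(y)
    if denom <= 0:
        return 1.0
    return 1.0 + interaction_gain_loop(x, y, c) / denom


def symmetrical_uncertainty_loop(x, c, mode: str) -> float:
    hx = entropy_of_column(x)
    if hx <= 0:
        return 0.0
    hc = entropy_of_column(c)
    hxc = joint_entropy_of_columns([x, c])
    i_xc = hx + hc - hxc
    denom = hx + hc if mode == "standard" else hxc
    return 2.0 * i_xc / denom


def g_statistic_loop(observed, expected, xi: int):
    """G, adjusted df and excluded rows by explicit double loop."""
    n_rows = len(observed)
    n_cols = len(observed[0])
    g = 0.0
    excluded = 0
    for i in range(n_rows):
        row_total = sum(observed[i])
        if row_total <= xi:
            excluded += 1
            continue
        for j in range(n_cols):
            o = observed[i][j]
            if o > 0:
                g += o * math.log(o / expected[i][j])
    df = max(0, (n_rows - 1) * (n_cols - 1) - excluded)
    return max(0.0, 2.0 * g), df, excluded


def expected_independence_loop(observed):
    """Margin-product expected counts by explicit loops."""
    n_rows = len(observed)
    n_cols = len(observed[0])
    n = sum(sum(row) for row in observed)
    row_tot = [sum(observed[i]) for i in range(n_rows)]
    col_tot = [sum(observed[i][j] for i in range(n_rows)) for j in range(n_cols)]
    return [
        [row_tot[i] * col_tot[j] / n for j in range(n_cols)] for i in range(n_rows)
    ]


def tally_outcomes_loop(replicates, truths):
    """Independent TP/FP/FN/TN bookkeeping over (key, significant) pairs."""
    tp = fp = fn = tn = 0
    for combos, truth in zip(replicates, truths):
        truth_key = tuple(sorted(truth))
        for key, significant in combos:
            if tuple(sorted(key)) == truth_key:
                tp += bool(significant)
                fn += not significant
            else:
                fp += bool(significant)
                tn += not significant
    return tp, fp, fn, tn
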