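"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — direct pair enumeration, explicit
running sums, textbook formulas — and shares no code with the package
implementations it checks.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def pair_counting_indices(a, b) -> tuple[float, float]:
    """Rand and adjusted Rand index by explicit enumeration of sample pairs."""
    a = list(a)
    b = list(b)
    n = len(a)
    ss = sd = ds = dd = 0
    for i, j in combinations(range(n), 2):
        same_a = a[i] == a[j]
        same_b = b[i] == b[j]
        if same_a and same_b:
            ss += 1
        elif same_a:
            sd += 1
        elif same_b:
            ds += 1
        else:
            dd += 1
    total = ss + sd + ds + dd
    ri = (ss + dd) / total
    # Hubert-Arabie adjustment from the same pair counts
    sum_rows = ss + sd
    sum_cols = ss + ds
    expected = sum_rows * sum_cols / total
    max_index = (sum_rows + sum_cols) / 2.0
    if max_index == expected:
        ari = 1.0 if ss == sum_rows == sum_cols else 0.0
    else:
        ari = (ss - expected) / (max_index - expected)
    return ri, ari


def set_partitions(n: int):
    """All set partitions of range(n) as label vectors (restricted growth strings)."""
    def rec(prefix, max_label):
        if len(prefix) == n:
            yield list(prefix)
            return
        for lab in range(max_label + 2):
            yield from rec(prefix + [lab], max(max_label, lab))
    if n == 0:
        return
    yield from rec([0], 0)


def ssgsea_running_sum(values, genes, gene_set, weight) -> float:
    """Explicit position-by-position ssGSEA running sum."""
    order = sorted(range(len(genes)), key=lambda i: (-values[i], i))
    n = len(genes)
    n_in = sum(1 for g in genes if g in gene_set)
    n_out = n - n_in
    denom = sum((n - pos) ** weight
                for pos, i in enumerate(order) if genes[i] in gene_set)
    p_in = p_out = 0.0
    score = 0.0
    for pos, i in enumerate(order):
        if genes[i] in gene_set:
            p_in += (n - pos) ** weight / denom
        else:
            p_out += 1.0 / n_out
        score += p_in - p_out
    return score


def logrank_chi2(t1, e1, t2, e2) -> float:
    """Two-group log-rank chi-square from the aggregated risk-set table."""
    t1, e1, t2, e2 = map(np.asarray, (t1, e1, t2, e2))
    times = np.unique(np.concatenate([t1[e1 == 1], t2[e2 == 1]]))
    o_minus_e = 0.0
    var = 0.0
    for t in times:
        n1 = np.sum(t1 >= t)
        n2 = np.sum(t2 >= t)
        d1 = np.sum((t1 == t) & (e1 == 1))
        d2 = np.sum((t2 == t) & (e2 == 1))
        n = n1 + n2
        d = d1 + d2
        if n < 2:
            continue
        e1_t = d * n1 / n
        o_minus_e += d1 - e1_t
        var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1) if n > 1 else 0.0
    return float(o_minus_e ** 2 / var) if var > 0 else 0.0
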