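"""Kaplan-Meier estimation and pairwise log-rank comparison of subtype groups.

The product-limit estimator and the two-group log-rank test are delegated
to lifelines; this module adds the pairwise class-pair matrix reported as
-log10(p), with zero-event pairs flagged as missing instead of forced
into a number. No multiplicity correction is applied to the pairwise
matrix by default (raw pairwise p-values are the reporting convention
here); ``bonferroni=True`` adjusts by the number of pairs for users who
want it.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

from .io import SubtypeLabelSet, SurvivalTable, ValidationError

__all__ = ["km_estimate", "logrank", "pairwise_logrank"]


def km_estimate(t: SurvivalTable) -> pd.DataFrame:
    """Product-limit survival curve for one group.

    Returns a DataFrame with ``time`` and ``survival`` columns: a
    right-continuous, non-increasing step function starting at S(0)=1.
    """
    if len(t.data) == 0:
        raise ValidationError("empty survival table")
    kmf = KaplanMeierFitter()
    kmf.fit(t.data["time"], event_observed=t.data["event"])
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(dtype=float),
                         "survival": sf.iloc[:, 0].to_numpy(dtype=float)})


def logrank(g1: SurvivalTable, g2: SurvivalTable) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p-value).

    Ties in event times are handled by the standard aggregated-risk-set
    formulation. Undefined when the pooled data contain no events.
    """
    if len(g1.data) == 0 or len(g2.data) == 0:
        raise ValidationError("both groups must be non-empty")
    if int(g1.data["event"].sum() + g2.data["event"].sum()) == 0:
        raise ValidationError("log-rank undefined: no events in pooled data")
    res = logrank_test(g1.data["time"], g2.data["time"],
                       event_observed_A=g1.data["event"],
                       event_observed_B=g2.data["event"])
    return float(res.test_statistic), float(res.p_value)


def pairwise_logrank(groups: SubtypeLabelSet, survival: SurvivalTable,
                     bonferroni: bool = False) -> pd.DataFrame:
    """Symmetric class-pair matrix of -log10(log-rank p).

    Pairs whose pooled samples have zero events get NaN (flagged missing)
    rather than a fabricated value. The diagonal is NaN by construction.
    """
    labels = groups.align_to(survival.samples)
    classes = [c for c in groups.scheme.classes if (labels == c).any()]
    if len(classes) < 2:
        raise ValidationError("need at least two non-empty classes")
    n_pairs = len(classes) * (len(classes) - 1) // 2
    out = pd.DataFrame(np.nan, index=classes, columns=classes)
    for a, b in combinations(classes, 2):
        ta = survival.subset(list(labels.index[labels == a]))
        tb = survival.subset(list(labels.index[labels == b]))
        if int(ta.data["event"].sum() + tb.data["event"].sum()) == 0:
            continue  # flagged missing cell
        _, p = logrank(ta, tb)
        if bonferroni:
            p = min(1.0, p * n_pairs)
        val = -np.log10(max(p, np.finfo(float).tiny))
        out.loc[a, b] = val
        out.loc[b, a] = val
    return out
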