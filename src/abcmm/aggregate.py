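"""Per-condition average associations with uncertainty propagation.

The average association of a condition is the mean of its association
values with the other P-1 conditions. For ABC the average is computed for
every posterior draw, giving a full distribution (summarised by median,
IQR and 99% credible interval). For RR, following the field convention,
non-significant (and degenerate) pairs contribute a value of 1 —
independence — and a nonparametric patient bootstrap provides an optional
interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortMatrix, PairTable
from .model import ABCPosterior, equal_tailed_ci
from .rr import RREstimate, estimate_pair

__all__ = [
    "AverageAssociation",
    "average_association_abc",
    "average_association_rr",
    "bootstrap_rr_average",
    "averages_frame",
]


@dataclass(frozen=True)
class AverageAssociation:
    """Average association of one condition with all others.

    ABC summaries carry the posterior distribution of the per-draw mean;
    RR summaries are a point value, optionally with a bootstrap CI.
    """

    condition: int
    measure: str
    value: float  # median (ABC) or point estimate (RR)
    q25: float | None = None
    q75: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None


def average_association_abc(
    posterior: ABCPosterior, condition: int, level: float = 0.99
) -> AverageAssociation:
    """Per-draw mean of ABC over the condition's partners, summarised by
    median, IQR and the equal-tailed credible interval."""
    mask = (posterior.pair_i == condition) | (posterior.pair_j == condition)
    if not mask.any():
        raise ValueError(f"posterior has no pairs involving condition {condition}")
    per_draw = posterior.abc_draws[:, mask].mean(axis=1)
    q25, med, q75 = np.percentile(per_draw, [25, 50, 75])
    lo, hi = equal_tailed_ci(per_draw, level)
    return AverageAssociation(
        condition=condition,
        measure="ABC",
        value=float(med),
        q25=float(q25),
        q75=float(q75),
        ci_low=lo,
        ci_high=hi,
    )


def average_association_rr(
    estimates: list[RREstimate], condition: int
) -> AverageAssociation:
    """Arithmetic mean of RR over the condition's partners, substituting 1
    (independence) for every non-significant or degenerate pair."""
    values = [
        e.rr if (e.significant and not e.degenerate) else 1.0
        for e in estimates
        if condition in (e.i, e.j)
    ]
    if not values:
        raise ValueError(f"no pair estimates involve condition {condition}")
    return AverageAssociation(
        condition=condition, measure="RR", value=float(np.mean(values))
    )


def bootstrap_rr_average(
    cohort: CohortMatrix,
    condition: int,
    b: int = 1000,
    seed: int = 0,
    level: float = 0.99,
    alpha: float = 0.01,
) -> AverageAssociation:
    """Nonparametric patient bootstrap of the RR average association.

    Resamples patients with replacement ``b`` times, recomputing RR,
    Fisher significance and the 1-substituted average in each replicate;
    the interval is the percentile CI of the replicate averages.
    """
    if b < 100:
        raise ValueError("need at least 100 bootstrap replicates")
    rng = np.random.default_rng(seed)
    x = cohort.presence.astype(np.int64)
    n, p = x.shape
    partners = [k for k in range(p) if k != condition]
    averages = np.empty(b)
    for rep in range(b):
        idx = rng.integers(0, n, size=n)
        xb = x[idx]
        col = xb[:, condition]
        n_c = int(col.sum())
        co = col @ xb  # co-occurrence of `condition` with every column
        vals = []
        for k in partners:
            n_k = int(xb[:, k].sum())
            i, j = sorted((condition, k))
            n_i, n_j = (n_c, n_k) if i == condition else (n_k, n_c)
            t = PairTable(i=i, j=j, n=n, n_i=n_i, n_j=n_j, n_ij=int(co[k]))
            e = estimate_pair(t, alpha=alpha)
            vals.append(e.rr if (e.significant and not e.degenerate) else 1.0)
        averages[rep] = np.mean(vals)
    point = average_association_rr(
        [estimate_pair(t, alpha=alpha) for t in _pairs_involving(cohort, condition)],
        condition,
    ).value
    tail = 100 * (1 - level) / 2
    lo, hi = np.percentile(averages, [tail, 100 - tail])
    return AverageAssociation(
        condition=condition,
        measure="RR",
        value=point,
        ci_low=float(lo),
        ci_high=float(hi),
    )


def _pairs_involving(cohort: CohortMatrix, condition: int) -> list[PairTable]:
    from .cohort import pairwise_counts

    return [t for t in pairwise_counts(cohort) if condition in (t.i, t.j)]


def averages_frame(
    posterior: ABCPosterior | None,
    estimates: list[RREstimate] | None,
    labels: list[str],
) -> pd.DataFrame:
    """One row per condition with both measures' average-association
    summaries (whichever inputs are provided)."""
    rows = []
    for k, lab in enumerate(labels):
        row: dict = {"condition": lab}
        if posterior is not None:
            a = average_association_abc(posterior, k)
            row.update(
                abc_median=a.value,
                abc_q25=a.q25,
                abc_q75=a.q75,
                abc_ci_low=a.ci_low,
                abc_ci_high=a.ci_high,
            )
        if estimates is not None:
            row["rr_average"] = average_association_rr(estimates, k).value
        rows.append(row)
    return pd.DataFrame(rows)
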