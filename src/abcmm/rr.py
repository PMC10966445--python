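"""Relative Risk (observed-to-expected lift) with Katz-style intervals.

In the multimorbidity literature "Relative Risk" of a condition pair is the
lift RR_ij = N * N_ij / (N_i * N_j): the ratio of the observed co-occurrence
count to the count expected if the two conditions were independent. This
module computes the lift, log-normal confidence intervals for it, Fisher's
exact significance, and a between-stratum difference test on the log scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import PairTable

__all__ = [
    "RREstimate",
    "relative_risk",
    "rr_confidence_interval",
    "fisher_exact",
    "rr_significance",
    "estimate_pair",
    "estimate_all",
    "compare_rr_between_groups",
]


@dataclass(frozen=True)
class RREstimate:
    """Lift estimate for one pair: point value, CI, Fisher p, significance.

    ``degenerate`` marks pairs where the lift or its interval is undefined
    (a zero margin, or N_ij = 0 for the log-scale interval); degenerate
    pairs are excluded from downstream aggregation rather than patched.
    """

    i: int
    j: int
    rr: float
    ci_low: float
    ci_high: float
    p_value: float
    significant: bool
    degenerate: bool
    level: float = 0.99


def relative_risk(table: PairTable) -> float:
    """Lift N*N_ij/(N_i*N_j); NaN when a margin is zero (degenerate)."""
    if table.n_i == 0 or table.n_j == 0:
        return float("nan")
    return table.n * table.n_ij / (table.n_i * table.n_j)


def _log_lift_se(table: PairTable) -> float:
    """Delta-method SE of log lift: sqrt(1/N_ij - 1/N_i - 1/N_j + 1/N).

    NaN when the variance term is non-positive, which happens for very
    strong positive associations (N_ij close to its margins) where the
    delta approximation breaks down.
    """
    var = 1 / table.n_ij - 1 / table.n_i - 1 / table.n_j + 1 / table.n
    return math.sqrt(var) if var > 0 else float("nan")


def rr_confidence_interval(
    table: PairTable, level: float = 0.99, method: str = "lift-delta"
) -> tuple[float, float]:
    """Log-normal CI for the pair association at the given level.

    method="lift-delta" (default): interval around the lift itself,
    exp(log RR +/- z * SE) with SE = sqrt(1/N_ij - 1/N_i - 1/N_j + 1/N),
    so the point estimate and the interval share one estimand.

    method="katz-2x2": the classical Katz interval around the conditional
    risk ratio [a/(a+b)] / [c/(c+d)] with SE = sqrt(1/a - 1/(a+b) + 1/c
    - 1/(c+d)).

    Returns (nan, nan) for tables where the log-scale interval is
    undefined (N_ij = 0 or a zero margin).
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    z = stats.norm.ppf(0.5 + level / 2)
    if method == "lift-delta":
        if table.n_ij == 0 or table.n_i == 0 or table.n_j == 0:
            return float("nan"), float("nan")
        est = relative_risk(table)
        se = _log_lift_se(table)
    elif method == "katz-2x2":
        a, b, c, d = table.cells()
        if a == 0 or c == 0 or a + b == 0 or c + d == 0:
            return float("nan"), float("nan")
        est = (a / (a + b)) / (c / (c + d))
        se = math.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return est * math.exp(-z * se), est * math.exp(z * se)


def fisher_exact(table: PairTable) -> float:
    """Two-sided Fisher exact p: total hypergeometric probability of tables
    (at fixed margins) no more likely than the observed one."""
    a, b, c, d = table.cells()
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def rr_significance(p_value: float, alpha: float = 0.01) -> bool:
    """Significant iff the Fisher p-value falls below alpha (default 0.01,
    matching the 99% interval convention)."""
    return bool(p_value < alpha)


def estimate_pair(
    table: PairTable,
    level: float = 0.99,
    alpha: float = 0.01,
    method: str = "lift-delta",
) -> RREstimate:
    """Full RR estimate for one pair: lift, CI, Fisher p, significance flag."""
    rr = relative_risk(table)
    degenerate = not math.isfinite(rr) or table.n_ij == 0
    lo, hi = rr_confidence_interval(table, level=level, method=method) if not degenerate else (float("nan"),) * 2
    p = fisher_exact(table)
    return RREstimate(
        i=table.i,
        j=table.j,
        rr=rr,
        ci_low=lo,
        ci_high=hi,
        p_value=p,
        significant=rr_significance(p, alpha) and not degenerate,
        degenerate=degenerate,
        level=level,
    )


def estimate_all(
    tables: list[PairTable],
    level: float = 0.99,
    alpha: float = 0.01,
    method: str = "lift-delta",
) -> list[RREstimate]:
    return [estimate_pair(t, level=level, alpha=alpha, method=method) for t in tables]


def estimates_frame(estimates: list[RREstimate], labels: list[str] | None = None) -> pd.DataFrame:
    """One row per pair: rr, ci bounds, p, flags — the module's tabular output."""
    rows = []
    for e in estimates:
        row = {
            "i": e.i,
            "j": e.j,
            "rr": e.rr,
            "ci_low": e.ci_low,
            "ci_high": e.ci_high,
            "p_value": e.p_value,
            "significant": e.significant,
            "degenerate": e.degenerate,
        }
        if labels is not None:
            row["condition_i"] = labels[e.i]
            row["condition_j"] = labels[e.j]
        rows.append(row)
    return pd.DataFrame(rows)


def compare_rr_between_groups(
    table_a: PairTable, table_b: PairTable
) -> float:
    """Two-sided p for a difference in lift between two strata.

    Normal test on the log-lift difference with delta-method SEs:
    z = (log RR_A - log RR_B) / sqrt(SE_A^2 + SE_B^2). Returns NaN when
    either lift is degenerate (zero margin or zero co-occurrence).
    """
    rr_a, rr_b = relative_risk(table_a), relative_risk(table_b)
    if (
        not math.isfinite(rr_a)
        or not math.isfinite(rr_b)
        or table_a.n_ij == 0
        or table_b.n_ij == 0
    ):
        return float("nan")
    z = (math.log(rr_a) - math.log(rr_b)) / math.hypot(
        _log_lift_se(table_a), _log_lift_se(table_b)
    )
    return float(2 * stats.norm.sf(abs(z)))
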