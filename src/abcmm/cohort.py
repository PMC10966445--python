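"""Binary cohort containers, validation, stratification and pairwise counts.

A cohort is an N x P presence/absence matrix: one row per patient, one 0/1
column per long-term condition (LTC), plus an optional categorical stratum
label per patient (typically sex). All pairwise association estimators in
this package consume the 2x2 contingency tables produced here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConditionPanel",
    "CohortMatrix",
    "PairTable",
    "read_cohort",
    "read_long_cohort",
    "stratify",
    "pairwise_counts",
    "condition_count_histogram",
]


class CohortValidationError(ValueError):
    """Raised when input data violate the binary-cohort contract."""


@dataclass(frozen=True)
class ConditionPanel:
    """Ordered panel of condition names.

    Order is meaningful: it fixes the column order of every cohort matrix
    and the (i, j) indexing of every pair table.
    """

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) < 2:
            raise CohortValidationError("a condition panel needs at least 2 conditions")
        if len(set(self.labels)) != len(self.labels):
            dupes = {l for l in self.labels if list(self.labels).count(l) > 1}
            raise CohortValidationError(f"duplicate condition names: {sorted(dupes)}")
        if any((not isinstance(l, str)) or l == "" for l in self.labels):
            raise CohortValidationError("condition names must be non-empty strings")

    @property
    def size(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def pairs(self) -> Iterable[tuple[int, int]]:
        """All unordered index pairs (i, j) with i < j, in row-major order."""
        p = self.size
        for i in range(p):
            for j in range(i + 1, p):
                yield i, j


@dataclass
class CohortMatrix:
    """N patients x P conditions presence matrix with optional strata."""

    panel: ConditionPanel
    presence: np.ndarray  # (N, P) of {0, 1}, dtype int8
    strata: np.ndarray | None = None  # (N,) of str labels

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence)
        if self.presence.ndim != 2:
            raise CohortValidationError("presence must be a 2-D matrix")
        n, p = self.presence.shape
        if n < 1:
            raise CohortValidationError("cohort is empty")
        if p != self.panel.size:
            raise CohortValidationError(
                f"presence has {p} columns but the panel lists {self.panel.size} conditions"
            )
        bad = ~np.isin(self.presence, (0, 1))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise CohortValidationError(
                f"non-binary value {self.presence[r, c]!r} at patient {r}, "
                f"condition {self.panel.labels[c]!r}"
            )
        self.presence = self.presence.astype(np.int8)
        if self.strata is not None:
            self.strata = np.asarray(self.strata, dtype=object)
            if self.strata.shape != (n,):
                raise CohortValidationError("strata must hold one label per patient")

    @property
    def n_patients(self) -> int:
        return self.presence.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.presence.shape[1]

    def prevalence(self) -> pd.Series:
        """Per-condition prevalence (fraction of patients with the condition)."""
        return pd.Series(
            self.presence.mean(axis=0), index=list(self.panel.labels), name="prevalence"
        )

    def marginal_counts(self) -> np.ndarray:
        return self.presence.sum(axis=0).astype(int)

    def stratum_labels(self) -> list[str]:
        if self.strata is None:
            return []
        return sorted(set(self.strata))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.presence, columns=list(self.panel.labels))
        if self.strata is not None:
            df.insert(0, "stratum", self.strata)
        return df

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class PairTable:
    """2x2 contingency counts for one unordered condition pair (i < j).

    Cells: a = both, b = i only, c = j only, d = neither; a+b+c+d = N.
    """

    i: int
    j: int
    n: int
    n_i: int
    n_j: int
    n_ij: int

    def __post_init__(self) -> None:
        if self.i >= self.j:
            raise CohortValidationError("pair indices must satisfy i < j")
        if self.n_ij > min(self.n_i, self.n_j):
            raise CohortValidationError("co-occurrence count exceeds a marginal count")
        if min(self.a, self.b, self.c, self.d) < 0:
            raise CohortValidationError("negative implied cell count")

    @property
    def a(self) -> int:
        return self.n_ij

    @property
    def b(self) -> int:
        return self.n_i - self.n_ij

    @property
    def c(self) -> int:
        return self.n_j - self.n_ij

    @property
    def d(self) -> int:
        return self.n - self.n_i - self.n_j + self.n_ij

    def cells(self) -> tuple[int, int, int, int]:
        return self.a, self.b, self.c, self.d


def _validate_binary_column(col: pd.Series, name: str) -> np.ndarray:
    """Coerce a cohort CSV column to 0/1, raising with row/column context."""
    vals = col
    if vals.isna().any():
        row = int(vals.index[vals.isna()][0])
        raise CohortValidationError(
            f"missing value at row {row}, condition column {name!r}; "
            "missing indicators are rejected, not imputed"
        )
    mapped = vals.map(
        lambda v: {True: 1, False: 0, "true": 1, "false": 0, "True": 1, "False": 0}.get(
            v, v
        )
    )
    arr = pd.to_numeric(mapped, errors="coerce")
    bad = arr.isna() | ~arr.isin((0, 1))
    if bad.any():
        row = int(arr.index[bad][0])
        raise CohortValidationError(
            f"non-binary value {vals.loc[row]!r} at row {row}, condition column {name!r}"
        )
    return arr.to_numpy(dtype=np.int8)


def read_cohort(
    path: str | Path,
    condition_columns: Sequence[str] | None = None,
    stratum_column: str | None = None,
) -> CohortMatrix:
    """Read a wide cohort CSV (one row per patient, one 0/1 column per LTC).

    Parameters
    ----------
    path
        CSV file with a header row.
    condition_columns
        Columns to treat as condition indicators, in panel order. Default:
        every column except ``stratum_column``.
    stratum_column
        Optional column holding a categorical stratum label (e.g. sex).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if df.shape[0] == 0:
        raise CohortValidationError(f"{path}: cohort is empty")
    if condition_columns is None:
        condition_columns = [c for c in df.columns if c != stratum_column]
    missing = [c for c in condition_columns if c not in df.columns]
    if missing:
        raise CohortValidationError(f"{path}: missing condition columns {missing}")
    panel = ConditionPanel(tuple(condition_columns))
    cols = [_validate_binary_column(df[c], c) for c in condition_columns]
    presence = np.column_stack(cols)
    strata = None
    if stratum_column is not None:
        if stratum_column not in df.columns:
            raise CohortValidationError(f"{path}: missing stratum column {stratum_column!r}")
        strata = df[stratum_column].astype(str).to_numpy(dtype=object)
    return CohortMatrix(panel=panel, presence=presence, strata=strata)


def read_long_cohort(
    path: str | Path,
    patient_column: str = "patient",
    condition_column: str = "condition",
    panel: Sequence[str] | None = None,
) -> CohortMatrix:
    """Convenience converter for long-format data (one row per diagnosis).

    Every listed (patient, condition) row marks presence; patients appearing
    only with conditions outside ``panel`` still contribute all-zero rows.
    """
    df = pd.read_csv(path)
    for col in (patient_column, condition_column):
        if col not in df.columns:
            raise CohortValidationError(f"{path}: missing column {col!r}")
    patients = list(dict.fromkeys(df[patient_column]))
    if panel is None:
        panel = sorted(set(df[condition_column]))
    panel_obj = ConditionPanel(tuple(panel))
    pat_idx = {p: k for k, p in enumerate(patients)}
    cond_idx = {c: k for k, c in enumerate(panel_obj.labels)}
    presence = np.zeros((len(patients), panel_obj.size), dtype=np.int8)
    for pat, cond in zip(df[patient_column], df[condition_column]):
        if cond in cond_idx:
            presence[pat_idx[pat], cond_idx[cond]] = 1
    return CohortMatrix(panel=panel_obj, presence=presence)


def stratify(cohort: CohortMatrix, stratum: str) -> CohortMatrix:
    """Sub-cohort of patients carrying the given stratum label; panel unchanged."""
    if cohort.strata is None:
        raise CohortValidationError("cohort has no stratum labels")
    mask = cohort.strata == stratum
    if not mask.any():
        raise CohortValidationError(
            f"unknown stratum {stratum!r}; available: {cohort.stratum_labels()}"
        )
    return CohortMatrix(
        panel=cohort.panel,
        presence=cohort.presence[mask],
        strata=cohort.strata[mask],
    )


def pairwise_counts(cohort: CohortMatrix) -> list[PairTable]:
    """2x2 tables for every unordered condition pair (P*(P-1)/2 tables).

    Computed via the cross-product matrix X.T @ X, whose diagonal holds the
    marginal counts N_i and off-diagonal the co-occurrence counts N_ij.
    """
    x = cohort.presence.astype(np.int64)
    cross = x.T @ x
    n = cohort.n_patients
    tables = []
    for i, j in cohort.panel.pairs():
        tables.append(
            PairTable(i=i, j=j, n=n, n_i=int(cross[i, i]), n_j=int(cross[j, j]), n_ij=int(cross[i, j]))
        )
    return tables


def condition_count_histogram(cohort: CohortMatrix) -> dict:
    """Distribution of the per-patient condition count.

    Returns a dict with the histogram (count of patients with 0, 1, 2, ...
    conditions), its mean and standard deviation — the standard cohort
    descriptors (share with no LTC, with one LTC, mean burden, ...).
    """
    per_patient = cohort.presence.sum(axis=1)
    values, counts = np.unique(per_patient, return_counts=True)
    hist = {int(v): int(c) for v, c in zip(values, counts)}
    return {
        "histogram": hist,
        "n": cohort.n_patients,
        "mean": float(per_patient.mean()),
        "sd": float(per_patient.std(ddof=1)) if cohort.n_patients > 1 else 0.0,
    }
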