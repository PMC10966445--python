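"""Shared fixtures: small cohorts, a calibrated 6-condition truth, and one
session-scoped joint-model fit reused by recovery, network and aggregation
tests."""

from __future__ import annotations

import numpy as np
import pytest

from abcmm import (
    ABCModelSpec,
    CohortMatrix,
    ConditionPanel,
    build_model,
    fit,
    generate_cohort,
    generate_truth,
    pairwise_counts,
)

# study-style fixture: six conditions spanning common to rare, one planted
# negative association and two positive ones of different strength
RECOVERY_PREVALENCES = np.array([0.25, 0.20, 0.10, 0.15, 0.05, 0.08])
RECOVERY_ASSOCIATIONS = {(0, 1): 0.5, (2, 3): 2.0, (4, 5): 4.0}
RECOVERY_N = 10_000


@pytest.fixture(scope="session")
def recovery_truth():
    return generate_truth(
        6,
        prevalences=RECOVERY_PREVALENCES,
        associations=RECOVERY_ASSOCIATIONS,
        seed=11,
        mode="copula",
    )


@pytest.fixture(scope="session")
def recovery_cohort(recovery_truth):
    return generate_cohort(recovery_truth, RECOVERY_N, seed=12)


@pytest.fixture(scope="session")
def recovery_fit(recovery_cohort):
    spec = ABCModelSpec(draws=4_000, warmup=1_000, thin=5, seed=13)
    model = build_model(pairwise_counts(recovery_cohort), spec)
    return fit(model, spec)


@pytest.fixture
def small_cohort():
    """5 patients, 3 conditions, hand-countable pair tables."""
    presence = np.array(
        [
            [1, 0, 0],
            [1, 0, 1],
            [1, 1, 1],
            [0, 1, 0],
            [0, 1, 1],
        ]
    )
    return CohortMatrix(panel=ConditionPanel(("A", "B", "C")), presence=presence)


@pytest.fixture
def stratified_cohort():
    rng = np.random.default_rng(7)
    presence = (rng.random((40, 4)) < 0.3).astype(int)
    strata = np.array(["men"] * 15 + ["women"] * 25, dtype=object)
    return CohortMatrix(
        panel=ConditionPanel(("A", "B", "C", "D")), presence=presence, strata=strata
    )
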