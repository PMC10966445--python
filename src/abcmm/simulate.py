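"""Synthetic binary cohorts with known ground-truth association structure.

Two generative modes, both reporting their implied truth (marginal
prevalences and pairwise lifts) in closed form:

* ``trigger`` — the mechanism story behind the association model: each
  condition i fires independently with rate g_i, and each pair (i, j) has a
  shared trigger firing with rate s_ij that produces both conditions at
  once. Shared triggers can only raise co-occurrence, so implied lifts are
  >= 1.
* ``copula`` — a correlated latent Gaussian vector thresholded at
  per-condition quantiles; latent correlations rho_ij may be negative, so
  lifts below 1 (conditions avoiding each other) are reachable.

Requested per-pair lifts are calibrated by numeric root-finding on the
closed forms, so generator truths are exact targets for parameter-recovery
experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np
from scipy import optimize, stats

from .cohort import CohortMatrix, ConditionPanel

__all__ = [
    "GeneratorTruth",
    "generate_truth",
    "generate_cohort",
    "generate_stratified_cohort",
    "implied_truth",
]

_CAL_TOL = 1e-9  # calibration tolerance on implied lifts and marginals


@dataclass
class GeneratorTruth:
    """Generator parameters plus their implied marginals and lifts.

    ``g``/``s`` are the trigger-mode rates (independent and shared);
    ``rho``/``thresholds`` the copula-mode latent correlations and
    upper-tail cutoffs. ``pi`` and ``lifts`` are the implied truths
    recomputed from whichever parameter set is active.
    """

    mode: str  # "trigger" | "copula"
    p: int
    g: np.ndarray | None = None  # (P,) independent trigger rates
    s: np.ndarray | None = None  # (P, P) symmetric shared trigger rates
    rho: np.ndarray | None = None  # (P, P) latent correlation matrix
    thresholds: np.ndarray | None = None  # (P,) latent cutoffs
    pi: np.ndarray = field(default_factory=lambda: np.array([]))
    lifts: np.ndarray = field(default_factory=lambda: np.array([]))
    labels: tuple[str, ...] | None = None

    def panel(self) -> ConditionPanel:
        labels = self.labels or tuple(f"C{k:02d}" for k in range(self.p))
        return ConditionPanel(labels)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "mode": self.mode,
            "p": self.p,
            "labels": list(self.panel().labels),
            "pi": self.pi.tolist(),
            "lifts": self.lifts.tolist(),
        }
        if self.mode == "trigger":
            payload["g"] = self.g.tolist()
            payload["s"] = self.s.tolist()
        else:
            payload["rho"] = self.rho.tolist()
            payload["thresholds"] = self.thresholds.tolist()
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "GeneratorTruth":
        d = json.loads(Path(path).read_text())
        kwargs = dict(
            mode=d["mode"],
            p=d["p"],
            labels=tuple(d["labels"]),
            pi=np.array(d["pi"]),
            lifts=np.array(d["lifts"]),
        )
        if d["mode"] == "trigger":
            kwargs["g"] = np.array(d["g"])
            kwargs["s"] = np.array(d["s"])
        else:
            kwargs["rho"] = np.array(d["rho"])
            kwargs["thresholds"] = np.array(d["thresholds"])
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# closed-form implied truths


def _trigger_absent_prob(g: np.ndarray, s: np.ndarray) -> np.ndarray:
    """P(condition i absent) = (1 - g_i) * prod_k (1 - s_ik)."""
    return (1 - g) * np.prod(1 - s, axis=1)


def _trigger_implied(g: np.ndarray, s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p = len(g)
    absent = _trigger_absent_prob(g, s)
    pi = 1 - absent
    lifts = np.ones((p, p))
    one_minus_s = 1 - s
    prod_i = np.prod(one_minus_s, axis=1)  # prod over all k (s_ii = 0)
    for i in range(p):
        for j in range(i + 1, p):
            # P(i and j absent): no independent triggers, no shared trigger
            # s_ij, and none of either condition's other shared triggers.
            both_absent = (
                (1 - g[i])
                * (1 - g[j])
                * (1 - s[i, j])
                * (prod_i[i] / one_minus_s[i, j])
                * (prod_i[j] / one_minus_s[i, j])
            )
            joint = 1 - absent[i] - absent[j] + both_absent
            if pi[i] > 0 and pi[j] > 0:
                lifts[i, j] = lifts[j, i] = joint / (pi[i] * pi[j])
    return pi, lifts


def _orthant_prob(zi: float, zj: float, rho: float) -> float:
    """P(Z_i > zi, Z_j > zj) for standard bivariate normal with corr rho."""
    cdf2 = stats.multivariate_normal(
        mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]], allow_singular=True
    ).cdf([zi, zj])
    return float(1 - stats.norm.cdf(zi) - stats.norm.cdf(zj) + cdf2)


def _copula_implied(
    thresholds: np.ndarray, rho: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    p = len(thresholds)
    pi = stats.norm.sf(thresholds)
    lifts = np.ones((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            if rho[i, j] != 0.0:
                joint = _orthant_prob(thresholds[i], thresholds[j], rho[i, j])
                lifts[i, j] = lifts[j, i] = joint / (pi[i] * pi[j])
    return pi, lifts


def implied_truth(truth: GeneratorTruth) -> tuple[np.ndarray, np.ndarray]:
    """Recompute implied marginals pi_i and pairwise lifts L_ij from the
    generator parameters (closed form; no simulation)."""
    if truth.mode == "trigger":
        return _trigger_implied(truth.g, truth.s)
    return _copula_implied(truth.thresholds, truth.rho)


# ---------------------------------------------------------------------------
# truth calibration


def _check_feasible(pi: np.ndarray, associations: dict[tuple[int, int], float]) -> None:
    for (i, j), lift in associations.items():
        if lift <= 0:
            raise ValueError(f"pair {(i, j)}: target lift must be positive, got {lift}")
        joint = lift * pi[i] * pi[j]
        lo = max(0.0, pi[i] + pi[j] - 1.0)
        hi = min(pi[i], pi[j])
        if not lo < joint < hi:
            raise ValueError(
                f"pair {(i, j)}: target lift {lift} at prevalences "
                f"({pi[i]:.4g}, {pi[j]:.4g}) implies joint {joint:.4g} outside "
                f"the feasible interval ({lo:.4g}, {hi:.4g})"
            )


def _calibrate_trigger(
    pi_target: np.ndarray, associations: dict[tuple[int, int], float]
) -> tuple[np.ndarray, np.ndarray]:
    """Alternating root-finding: solve each s_ij for its target lift, then
    reset every g_i to hit the target marginals; iterate to 1e-9."""
    p = len(pi_target)
    s = np.zeros((p, p))

    def solve_g(s_mat: np.ndarray) -> np.ndarray:
        # pi_i = 1 - (1 - g_i) * Q_i with Q_i = prod_k (1 - s_ik)
        q = np.prod(1 - s_mat, axis=1)
        ratio = (1 - pi_target) / q
        if (ratio > 1).any():
            bad = int(np.argmax(ratio))
            raise ValueError(
                f"condition {bad}: shared triggers alone exceed the target "
                f"prevalence {pi_target[bad]:.4g}; targets are infeasible"
            )
        return 1 - ratio

    for _ in range(200):
        for (i, j), lift in associations.items():
            if lift == 1.0:
                continue

            def lift_err(sij: float, i=i, j=j, lift=lift) -> float:
                # lift implied by this s_ij once g is re-solved so that the
                # marginals stay exactly on target
                s_try = s.copy()
                s_try[i, j] = s_try[j, i] = sij
                _, lifts = _trigger_implied(solve_g(s_try), s_try)
                return lifts[i, j] - lift

            # largest s_ij keeping both g_i, g_j >= 0 (marginal fully
            # trigger-driven at the boundary)
            cap = 1.0
            for k in (i, j):
                other = np.prod(1 - s[k]) / (1 - s[i, j])
                cap = min(cap, 1 - (1 - pi_target[k]) / other)
            hi = cap * (1 - 1e-9)
            if hi <= 0 or lift_err(hi) < 0:
                raise ValueError(f"pair {(i, j)}: lift {lift} unreachable in trigger mode")
            sol = optimize.brentq(lift_err, 0.0, hi, xtol=1e-15, rtol=8.9e-16)
            s[i, j] = s[j, i] = sol
        g = solve_g(s)
        pi, lifts = _trigger_implied(g, s)
        err = max(
            np.max(np.abs(pi - pi_target)),
            max(
                (abs(lifts[i, j] - l) for (i, j), l in associations.items()),
                default=0.0,
            ),
        )
        if err < _CAL_TOL:
            return g, s
    raise RuntimeError("trigger calibration did not converge")


def _calibrate_copula(
    pi_target: np.ndarray, associations: dict[tuple[int, int], float]
) -> tuple[np.ndarray, np.ndarray]:
    p = len(pi_target)
    thresholds = stats.norm.isf(pi_target)  # upper-tail cutoffs: exact marginals
    rho = np.eye(p)
    for (i, j), lift in associations.items():
        if lift == 1.0:
            continue
        target_joint = lift * pi_target[i] * pi_target[j]

        def joint_err(r: float, i=i, j=j) -> float:
            return _orthant_prob(thresholds[i], thresholds[j], r) - target_joint

        sol = optimize.brentq(joint_err, -0.9999, 0.9999, xtol=1e-13)
        rho[i, j] = rho[j, i] = sol
    try:
        np.linalg.cholesky(rho)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "requested association pattern yields a non-positive-definite "
            "latent correlation matrix"
        ) from exc
    return thresholds, rho


def generate_truth(
    p: int,
    prevalence_range: tuple[float, float] = (0.001, 0.45),
    associations: dict[tuple[int, int], float] | None = None,
    seed: int = 0,
    mode: str = "auto",
    prevalences: np.ndarray | None = None,
    labels: tuple[str, ...] | None = None,
) -> GeneratorTruth:
    """Draw heterogeneous prevalences and calibrate planted pairwise lifts.

    Prevalences are drawn log-uniformly over ``prevalence_range`` (unless
    given explicitly), mirroring real LTC panels whose prevalence spans
    orders of magnitude. ``associations`` maps pairs (i, j), i < j, to
    target lifts; unlisted pairs are independent (lift 1). ``mode="auto"``
    picks ``trigger`` when every target lift is >= 1 and ``copula``
    otherwise (shared triggers cannot produce negative association).
    """
    associations = {tuple(sorted(k)): float(v) for k, v in (associations or {}).items()}
    rng = np.random.default_rng(seed)
    if prevalences is None:
        lo, hi = prevalence_range
        if not 0 < lo <= hi < 1:
            raise ValueError("prevalence_range must satisfy 0 < lo <= hi < 1")
        prevalences = np.exp(rng.uniform(np.log(lo), np.log(hi), size=p))
    else:
        prevalences = np.asarray(prevalences, dtype=float)
        if prevalences.shape != (p,):
            raise ValueError("prevalences must have one entry per condition")
    _check_feasible(prevalences, associations)
    if mode == "auto":
        mode = "trigger" if all(v >= 1 for v in associations.values()) else "copula"
    if mode == "trigger":
        if any(v < 1 for v in associations.values()):
            raise ValueError("trigger mode cannot target lifts below 1; use copula mode")
        g, s = _calibrate_trigger(prevalences, associations)
        truth = GeneratorTruth(mode="trigger", p=p, g=g, s=s, labels=labels)
    elif mode == "copula":
        thresholds, rho = _calibrate_copula(prevalences, associations)
        truth = GeneratorTruth(
            mode="copula", p=p, rho=rho, thresholds=thresholds, labels=labels
        )
    else:
        raise ValueError(f"unknown generator mode {mode!r}")
    truth.pi, truth.lifts = implied_truth(truth)
    return truth


# ---------------------------------------------------------------------------
# cohort generation


def generate_cohort(truth: GeneratorTruth, n: int, seed: int = 0) -> CohortMatrix:
    """Draw N patients from the generator.

    Trigger mode: presence_i = 1 iff the independent trigger I_i fires or
    any shared trigger S_ij involving i fires. Copula mode: threshold a
    correlated latent Gaussian vector at the per-condition cutoffs.
    """
    rng = np.random.default_rng(seed)
    p = truth.p
    if truth.mode == "trigger":
        presence = rng.random((n, p)) < truth.g
        for i in range(p):
            for j in range(i + 1, p):
                if truth.s[i, j] > 0:
                    shared = rng.random(n) < truth.s[i, j]
                    presence[:, i] |= shared
                    presence[:, j] |= shared
    else:
        chol = np.linalg.cholesky(truth.rho)
        z = rng.standard_normal((n, p)) @ chol.T
        presence = z > truth.thresholds
    return CohortMatrix(panel=truth.panel(), presence=presence.astype(np.int8))


def generate_stratified_cohort(
    truths: dict[str, GeneratorTruth],
    sizes: dict[str, int],
    seed: int = 0,
) -> CohortMatrix:
    """Concatenate per-stratum cohorts (one truth per stratum label) into a
    single cohort with stratum labels; panels must match."""
    labels = sorted(truths)
    panels = {tuple(truths[k].panel().labels) for k in labels}
    if len(panels) != 1:
        raise ValueError("all strata must share one condition panel")
    blocks, strata = [], []
    for offset, name in enumerate(labels):
        sub = generate_cohort(truths[name], sizes[name], seed=seed + offset)
        blocks.append(sub.presence)
        strata.extend([name] * sizes[name])
    return CohortMatrix(
        panel=truths[labels[0]].panel(),
        presence=np.vstack(blocks),
        strata=np.array(strata, dtype=object),
    )
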