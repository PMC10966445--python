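"""Joint Bayesian inference of Association Beyond Chance (ABC).

The generative model: each condition i has an independent-factor rate f_i,
and each unordered pair (i, j) a signed shared-mechanism excess f_ij. The
association measure is

    ABC_ij = 1 + f_ij / (f_i * f_j),

the ratio of co-appearance through common mechanisms to co-appearance by
chance, shifted by one so that ABC = 1 means independence (directly
comparable to the relative-risk lift). ABC > 1 indicates common mechanisms
promoting co-occurrence; ABC < 1, mechanisms hindering it.

Each pair's 2x2 table contributes a multinomial likelihood with cell
probabilities

    p11 = f_i * f_j * ABC_ij,   p10 = f_i - p11,
    p01 = f_j - p11,            p00 = 1 - f_i - f_j + p11,

subject to the feasibility bounds max(0, f_i + f_j - 1) <= p11 <=
min(f_i, f_j). Crucially, each f_i is a single parameter shared across all
pairs involving condition i, so every association is informed by the
condition's behaviour in the rest of the panel; the product over pairs is a
composite likelihood (patients are reused across pairs).

Priors are weakly informative and regulated by hyperpriors; the prior on
log ABC is centred at 0 (ABC = 1), which shrinks poorly-evidenced
associations toward independence and biases the measure against false
positives.

Sampling uses the affine-invariant ensemble sampler (emcee) over a fully
vectorised log-density; walker groups stand in for chains in the split-R-hat
and effective-sample-size diagnostics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln, logit

from .cohort import CohortMatrix, PairTable, pairwise_counts

logger = logging.getLogger(__name__)

__all__ = [
    "ABCModelSpec",
    "ABCPosterior",
    "AbcJointModel",
    "abc_from_params",
    "build_model",
    "fit",
    "fit_cohort",
    "hpdi_mode",
    "equal_tailed_ci",
    "abc_significance",
    "compare_groups",
]

_LOG2PI = float(np.log(2 * np.pi))
_TINY = 1e-300


def abc_from_params(f_i: float, f_j: float, f_ij: float) -> float:
    """ABC_ij = 1 + f_ij/(f_i*f_j); f_ij = 0 is independence, f_ij < 0 a
    negative association."""
    if not (0 < f_i < 1 and 0 < f_j < 1):
        raise ValueError("independent factors must lie strictly in (0, 1)")
    return 1.0 + f_ij / (f_i * f_j)


@dataclass
class ABCModelSpec:
    """Prior and sampler settings for the joint ABC model.

    ``draws`` is the total number of retained posterior draws (default
    20,000, i.e. ``chains`` groups of 5,000). ``sigma_abc`` fixes the
    Normal prior scale on log ABC; when None (default) it gets a
    half-normal hyperprior of scale ``sigma_abc_hyper_scale``, keeping the
    prior centred on ABC = 1 but letting the data set its tightness.
    """

    draws: int = 20_000
    warmup: int = 1_000
    chains: int = 4
    seed: int = 0
    thin: int = 5
    walkers: int | None = None  # default: 2*(ndim+1), rounded up to a multiple of chains
    sigma_abc: float | None = None
    sigma_abc_hyper_scale: float = 0.5
    kappa_hyper_scale: float = 10.0
    ci_level: float = 0.99
    hpdi_mass: float = 0.05
    rhat_warn: float = 1.01

    def __post_init__(self) -> None:
        if self.draws < 200:
            raise ValueError("need at least 200 retained draws")
        for name in ("sigma_abc_hyper_scale", "kappa_hyper_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.sigma_abc is not None and self.sigma_abc <= 0:
            raise ValueError("sigma_abc must be positive")


class AbcJointModel:
    """Joint log-density over {f_i} and {ABC_ij} given all pair tables.

    Unconstrained parameter vector layout:
    ``[logit f_1..f_P | u_12..u_(P-1)P | logit mu, log kappa (, log sigma)]``
    where each u maps through a scaled logistic onto the feasible p11
    interval for its pair, so the sampler never proposes an infeasible
    state. The Normal(0, sigma) prior on log ABC is applied through this
    transform (truncated to the feasible range by construction).
    """

    def __init__(self, tables: list[PairTable], spec: ABCModelSpec, p: int | None = None):
        ns = {t.n for t in tables}
        if len(ns) != 1:
            raise ValueError(f"inconsistent cohort sizes across pair tables: {sorted(ns)}")
        self.n = ns.pop()
        self.spec = spec
        self.pair_i = np.array([t.i for t in tables])
        self.pair_j = np.array([t.j for t in tables])
        self.p = int(max(self.pair_j.max() + 1, p or 0))
        self.a = np.array([t.a for t in tables], dtype=float)
        self.b = np.array([t.b for t in tables], dtype=float)
        self.c = np.array([t.c for t in tables], dtype=float)
        self.d = np.array([t.d for t in tables], dtype=float)
        self.n_pairs = len(tables)
        self.marginals = np.zeros(self.p)
        for t in tables:
            self.marginals[t.i] = t.n_i
            self.marginals[t.j] = t.n_j
        self.fixed_sigma = spec.sigma_abc
        self.n_hyper = 2 if self.fixed_sigma is not None else 3
        self.ndim = self.p + self.n_pairs + self.n_hyper

    # -- transforms --------------------------------------------------------
    def _unpack(self, theta: np.ndarray):
        f = expit(theta[:, : self.p])
        u = theta[:, self.p : self.p + self.n_pairs]
        hyper = theta[:, self.p + self.n_pairs :]
        return f, u, hyper

    def _p11(self, f: np.ndarray, u: np.ndarray):
        fi = f[:, self.pair_i]
        fj = f[:, self.pair_j]
        lo = np.maximum(fi + fj - 1.0, 0.0)
        hi = np.minimum(fi, fj)
        width = hi - lo
        su = expit(u)
        p11 = lo + width * su
        return fi, fj, lo, width, su, p11

    def log_prob(self, theta: np.ndarray) -> np.ndarray:
        """Vectorised unnormalised log posterior; theta is (walkers, ndim)
        or (ndim,). Non-finite rows map to -inf."""
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        with np.errstate(all="ignore"):
            lp = self._log_prob_inner(theta)
        lp = np.where(np.isfinite(lp), lp, -np.inf)
        return lp if theta.shape[0] > 1 else lp[0]

    def _log_prob_inner(self, theta: np.ndarray) -> np.ndarray:
        f, u, hyper = self._unpack(theta)
        m, lk = hyper[:, 0], hyper[:, 1]
        mu = expit(m)
        kappa = np.exp(np.clip(lk, -30, 30))
        if self.fixed_sigma is not None:
            sigma = np.full(theta.shape[0], self.fixed_sigma)
            lp = np.zeros(theta.shape[0])
        else:
            ls = hyper[:, 2]
            sigma = np.exp(np.clip(ls, -30, 30))
            # half-normal hyperprior on sigma, + log-jacobian of exp
            lp = -0.5 * (sigma / self.spec.sigma_abc_hyper_scale) ** 2 + ls
        # half-normal hyperprior on kappa, + jacobian; uniform mu, + jacobian
        lp += -0.5 * (kappa / self.spec.kappa_hyper_scale) ** 2 + lk
        lp += np.log(mu) + np.log1p(-mu)
        # Beta(mu*kappa, (1-mu)*kappa) prior on each f_i, + logit jacobians
        alpha, beta = mu * kappa, (1 - mu) * kappa
        lbeta = gammaln(alpha) + gammaln(beta) - gammaln(kappa)
        logf, log1mf = np.log(f), np.log1p(-f)
        lp += ((alpha - 1)[:, None] * logf + (beta - 1)[:, None] * log1mf).sum(axis=1)
        lp -= self.p * lbeta
        lp += (logf + log1mf).sum(axis=1)  # jacobian of logit(f)

        fi, fj, lo, width, su, p11 = self._p11(f, u)
        log_p11 = np.log(np.maximum(p11, _TINY))
        log_abc = log_p11 - np.log(fi) - np.log(fj)
        # Normal(0, sigma) prior on log ABC through the scaled-logistic
        # transform: jacobian d(logABC)/du = width*su*(1-su)/p11
        lp += (
            -0.5 * (log_abc / sigma[:, None]) ** 2
            - np.log(sigma)[:, None]
            - 0.5 * _LOG2PI
            + np.log(width)
            + np.log(su)
            + np.log1p(-su)
            - log_p11
        ).sum(axis=1)

        # multinomial likelihood over the four cells of each pair
        p10 = fi - p11
        p01 = fj - p11
        p00 = 1.0 - fi - fj + p11
        ll = self.a * log_p11
        ll += np.where(self.b > 0, self.b * np.log(np.maximum(p10, _TINY)), 0.0)
        ll += np.where(self.c > 0, self.c * np.log(np.maximum(p01, _TINY)), 0.0)
        ll += np.where(self.d > 0, self.d * np.log(np.maximum(p00, _TINY)), 0.0)
        lp += ll.sum(axis=1)
        return lp

    # -- derived quantities -------------------------------------------------
    def abc_draws(self, theta: np.ndarray) -> np.ndarray:
        """Map retained unconstrained draws to ABC_ij = p11/(f_i*f_j)."""
        f, u, _ = self._unpack(np.atleast_2d(theta))
        fi, fj, _, _, _, p11 = self._p11(f, u)
        return p11 / (fi * fj)

    def f_draws(self, theta: np.ndarray) -> np.ndarray:
        return expit(np.atleast_2d(theta)[:, : self.p])

    def initial_point(self) -> np.ndarray:
        """Empirical-moment start: f at smoothed prevalences, p11 at the
        smoothed joint frequency clipped inside its feasible interval."""
        f0 = np.clip((self.marginals + 1.0) / (self.n + 2.0), 1e-6, 1 - 1e-6)
        fi, fj = f0[self.pair_i], f0[self.pair_j]
        lo = np.maximum(fi + fj - 1.0, 0.0)
        hi = np.minimum(fi, fj)
        width = hi - lo
        p11_hat = np.clip(
            (self.a + 0.5) / (self.n + 2.0), lo + 1e-4 * width, hi - 1e-4 * width
        )
        u0 = logit((p11_hat - lo) / width)
        hyper = [logit(np.clip(f0.mean(), 1e-4, 1 - 1e-4)), np.log(5.0)]
        if self.fixed_sigma is None:
            hyper.append(np.log(0.3))
        return np.concatenate([logit(f0), u0, hyper])


@dataclass
class ABCPosterior:
    """Posterior draws and per-pair summaries from one model fit."""

    pair_i: np.ndarray
    pair_j: np.ndarray
    f_draws: np.ndarray  # (S, P)
    abc_draws: np.ndarray  # (S, n_pairs)
    summaries: pd.DataFrame  # per pair: mode, ci_low, ci_high, significant
    diagnostics: dict
    labels: tuple[str, ...] | None = None
    ci_level: float = 0.99

    @property
    def n_draws(self) -> int:
        return self.abc_draws.shape[0]

    def pair_column(self, i: int, j: int) -> np.ndarray:
        """Posterior draws of ABC for one unordered pair."""
        i, j = min(i, j), max(i, j)
        mask = (self.pair_i == i) & (self.pair_j == j)
        if not mask.any():
            raise KeyError(f"pair ({i}, {j}) not in posterior")
        return self.abc_draws[:, np.argmax(mask)]

    def draws_frame(self) -> pd.DataFrame:
        """Columnar draw table with parameter names f[i] and ABC[i,j]."""
        cols = {f"f[{k}]": self.f_draws[:, k] for k in range(self.f_draws.shape[1])}
        for k, (i, j) in enumerate(zip(self.pair_i, self.pair_j)):
            cols[f"ABC[{i},{j}]"] = self.abc_draws[:, k]
        return pd.DataFrame(cols)


def hpdi_mode(draws: np.ndarray, mass: float = 0.05) -> float:
    """Midpoint of the shortest contiguous interval holding ``mass`` of the
    draws — a robust sample-based mode estimate."""
    draws = np.sort(np.asarray(draws, dtype=float))
    n = len(draws)
    if n < 100:
        raise ValueError("need at least 100 draws for an HPDI mode")
    k = max(2, int(np.ceil(mass * n)))
    widths = draws[k - 1 :] - draws[: n - k + 1]
    start = int(np.argmin(widths))
    return float((draws[start] + draws[start + k - 1]) / 2)


def equal_tailed_ci(draws: np.ndarray, level: float = 0.99) -> tuple[float, float]:
    """Equal-tailed credible interval: e.g. the 0.5th and 99.5th percentiles
    at the default 99% level."""
    draws = np.asarray(draws, dtype=float)
    if len(draws) < 2 / (1 - level):
        raise ValueError(f"too few draws ({len(draws)}) for a {level:.0%} interval")
    tail = 100 * (1 - level) / 2
    lo, hi = np.percentile(draws, [tail, 100 - tail])
    return float(lo), float(hi)


def abc_significance(ci_low: float, ci_high: float) -> bool:
    """Significant iff the credible interval excludes ABC = 1."""
    return bool(ci_low > 1.0 or ci_high < 1.0)


def build_model(
    tables: list[PairTable], spec: ABCModelSpec | None = None, p: int | None = None
) -> AbcJointModel:
    """Assemble the joint model from one cohort's pair tables."""
    return AbcJointModel(tables, spec or ABCModelSpec(), p=p)


def _diagnostics(chain: np.ndarray, model: AbcJointModel, accept: float, spec: ABCModelSpec) -> dict:
    """Split-R-hat and bulk ESS over walker groups, on the ABC draws."""
    import arviz as az

    steps, walkers, _ = chain.shape
    groups = spec.chains
    per = walkers // groups
    # (chain, draw, n_pairs) with walker groups as chains
    abc = model.abc_draws(chain.reshape(-1, model.ndim)).reshape(steps, walkers, -1)
    # (walkers, steps, n_pairs) -> adjacent walker groups become chains
    abc = np.moveaxis(abc[:, : per * groups], 1, 0).reshape(groups, per * steps, -1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ds = az.convert_to_dataset(np.log(np.maximum(abc, _TINY)))
        rhat = float(az.rhat(ds).x.max())
        ess = float(az.ess(ds).x.min())
    return {
        "rhat_max": rhat,
        "ess_min": ess,
        "mean_acceptance": float(accept),
        "walkers": int(walkers),
        "retained_steps": int(steps),
    }


def fit(model: AbcJointModel, spec: ABCModelSpec | None = None) -> ABCPosterior:
    """Sample the joint posterior and summarise every pair.

    Reproducible under a fixed ``spec.seed``. Warns (never silently
    ignores) when split-R-hat exceeds ``spec.rhat_warn``.
    """
    import emcee

    spec = spec or model.spec
    ndim = model.ndim
    walkers = spec.walkers or max(2 * (ndim + 1), 4 * spec.chains)
    walkers += (-walkers) % spec.chains  # divisible into chain groups
    steps_retained = int(np.ceil(spec.draws * spec.thin / walkers))
    rng = np.random.RandomState(spec.seed)
    x0 = model.initial_point()
    p0 = x0[None, :] + 0.02 * rng.standard_normal((walkers, ndim))
    # differential-evolution moves mix far better than the default stretch
    # move at this dimensionality
    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
    sampler = emcee.EnsembleSampler(
        walkers, ndim, model.log_prob, vectorize=True, moves=moves
    )
    sampler.random_state = rng.get_state()
    sampler.run_mcmc(p0, spec.warmup + steps_retained * spec.thin, progress=False)
    chain = sampler.get_chain(discard=spec.warmup, thin=spec.thin)  # (steps, walkers, ndim)
    accept = sampler.acceptance_fraction.mean()
    diagnostics = _diagnostics(chain, model, accept, spec)
    flat = chain.reshape(-1, ndim)[: spec.draws]
    abc = model.abc_draws(flat)
    f = model.f_draws(flat)
    if diagnostics["rhat_max"] > spec.rhat_warn:
        warnings.warn(
            f"ABC fit may not have converged: max split-R-hat "
            f"{diagnostics['rhat_max']:.3f} > {spec.rhat_warn}; "
            f"min ESS {diagnostics['ess_min']:.0f}",
            RuntimeWarning,
            stacklevel=2,
        )
    rows = []
    for k in range(model.n_pairs):
        mode = hpdi_mode(abc[:, k], spec.hpdi_mass)
        lo, hi = equal_tailed_ci(abc[:, k], spec.ci_level)
        rows.append(
            {
                "i": int(model.pair_i[k]),
                "j": int(model.pair_j[k]),
                "mode": mode,
                "ci_low": lo,
                "ci_high": hi,
                "significant": abc_significance(lo, hi),
            }
        )
    return ABCPosterior(
        pair_i=model.pair_i.copy(),
        pair_j=model.pair_j.copy(),
        f_draws=f,
        abc_draws=abc,
        summaries=pd.DataFrame(rows),
        diagnostics=diagnostics,
        ci_level=spec.ci_level,
    )


def fit_cohort(cohort: CohortMatrix, spec: ABCModelSpec | None = None) -> ABCPosterior:
    """Fit the joint model to a whole cohort.

    Conditions with zero prevalence are dropped with a logged notice (their
    independent factor is unidentifiable); pair indices in the returned
    posterior refer to the original panel.
    """
    spec = spec or ABCModelSpec()
    counts = cohort.marginal_counts()
    keep = np.flatnonzero(counts > 0)
    dropped = [cohort.panel.labels[k] for k in np.flatnonzero(counts == 0)]
    if dropped:
        logger.warning(
            "dropping %d zero-prevalence condition(s) from the model: %s",
            len(dropped),
            dropped,
        )
    remap = {orig: new for new, orig in enumerate(keep)}
    tables = [
        t for t in pairwise_counts(cohort) if t.i in remap and t.j in remap
    ]
    remapped = [
        PairTable(i=remap[t.i], j=remap[t.j], n=t.n, n_i=t.n_i, n_j=t.n_j, n_ij=t.n_ij)
        for t in tables
    ]
    model = build_model(remapped, spec, p=len(keep))
    post = fit(model, spec)
    # restore original panel indices
    post.pair_i = keep[post.pair_i]
    post.pair_j = keep[post.pair_j]
    post.summaries["i"] = keep[post.summaries["i"].to_numpy()]
    post.summaries["j"] = keep[post.summaries["j"].to_numpy()]
    post.labels = cohort.panel.labels
    return post


def compare_groups(
    draws_a: np.ndarray, draws_b: np.ndarray, seed: int = 0
) -> float:
    """Posterior-overlap p-value for a between-stratum difference.

    Pairs shuffled draws from the two independent posteriors and returns
    p = 2 * min(Pr(A > B), Pr(B > A)) with ties split evenly. Length
    mismatches are handled by truncating both shuffles to the shorter
    length (fixed seed).
    """
    rng = np.random.default_rng(seed)
    a = np.asarray(draws_a, dtype=float)
    b = np.asarray(draws_b, dtype=float)
    s = min(len(a), len(b))
    a = rng.permutation(a)[:s]
    b = rng.permutation(b)[:s]
    p_a = float(np.mean(a > b) + 0.5 * np.mean(a == b))
    return min(1.0, 2 * min(p_a, 1 - p_a))
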