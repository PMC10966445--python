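"""Joint ABC model: density, posterior summaries, fitting behaviour."""

import math

import numpy as np
import pytest
from scipy.special import expit, logit

from abcmm import (
    ABCModelSpec,
    PairTable,
    abc_from_params,
    abc_significance,
    build_model,
    compare_groups,
    equal_tailed_ci,
    fit,
    fit_cohort,
    generate_cohort,
    generate_truth,
    hpdi_mode,
    pairwise_counts,
)
from abcmm.cohort import CohortMatrix, ConditionPanel


class TestAbcFromParams:
    def test_independence(self):
        assert abc_from_params(0.3, 0.2, 0.0) == pytest.approx(1.0)

    def test_direct_evaluation(self):
        # shared-mechanism co-occurrence equal to chance co-occurrence
        assert abc_from_params(0.1, 0.1, 0.01) == pytest.approx(2.0)

    def test_negative_excess_gives_abc_below_one(self):
        assert abc_from_params(0.2, 0.2, -0.01) < 1.0

    def test_zero_factor_rejected(self):
        with pytest.raises(ValueError):
            abc_from_params(0.0, 0.2, 0.01)


class TestJointDensity:
    def test_log_density_matches_hand_multinomial(self):
        """At a chosen feasible point the density equals the hand-computed
        multinomial log-likelihood plus hand-computed prior terms."""
        table = PairTable(i=0, j=1, n=100, n_i=30, n_j=20, n_ij=10)
        spec = ABCModelSpec(sigma_abc=0.5)  # fixed scale: 2 hyperparameters
        model = build_model([table], spec)
        f = np.array([0.3, 0.2])
        p11 = 0.08
        lo, hi = max(0.0, f.sum() - 1), min(f[0], f[1])
        su = (p11 - lo) / (hi - lo)
        mu, kappa = 0.4, 6.0
        theta = np.concatenate(
            [logit(f), [logit(su)], [logit(mu), np.log(kappa)]]
        )
        got = model.log_prob(theta)

        # multinomial likelihood over the four cells
        a, b, c, d = 10, 20, 10, 60
        cells = [p11, f[0] - p11, f[1] - p11, 1 - f[0] - f[1] + p11]
        expected = sum(k * math.log(q) for k, q in zip((a, b, c, d), cells))
        # Beta(mu*kappa, (1-mu)*kappa) prior on f, + logit jacobians
        from scipy.stats import beta as beta_dist, norm

        expected += sum(
            beta_dist.logpdf(x, mu * kappa, (1 - mu) * kappa) for x in f
        )
        expected += sum(math.log(x) + math.log(1 - x) for x in f)
        # Normal(0, sigma) prior on log ABC with transform jacobian
        log_abc = math.log(p11 / (f[0] * f[1]))
        expected += norm.logpdf(log_abc, 0, 0.5)
        expected += math.log(hi - lo) + math.log(su) + math.log(1 - su) - math.log(p11)
        # hyperpriors: uniform mu + jacobian, half-normal kappa + jacobian
        expected += math.log(mu) + math.log(1 - mu)
        expected += -0.5 * (kappa / 10.0) ** 2 + math.log(kappa)
        assert got == pytest.approx(expected, rel=1e-10)

    def test_unit_abc_gives_independence_cells(self):
        table = PairTable(i=0, j=1, n=1000, n_i=300, n_j=200, n_ij=60)
        model = build_model([table], ABCModelSpec(sigma_abc=1.0))
        f = np.array([[0.3, 0.2]])
        lo, hi = 0.0, 0.2
        p11_indep = 0.06  # f_i * f_j
        u = logit((p11_indep - lo) / (hi - lo))
        fi, fj, _, _, _, p11 = model._p11(f, np.array([[u]]))
        abc = p11 / (fi * fj)
        assert abc[0, 0] == pytest.approx(1.0, rel=1e-12)

    def test_density_finite_only_on_feasible_draws(self, recovery_fit):
        """Every retained draw satisfies the feasibility bounds on p11."""
        post = recovery_fit
        for k, (i, j) in enumerate(zip(post.pair_i, post.pair_j)):
            fi, fj = post.f_draws[:, i], post.f_draws[:, j]
            p11 = post.abc_draws[:, k] * fi * fj
            lo = np.maximum(fi + fj - 1, 0)
            hi = np.minimum(fi, fj)
            assert (p11 >= lo).all() and (p11 <= hi).all()
        assert ((post.f_draws > 0) & (post.f_draws < 1)).all()
        assert (post.abc_draws > 0).all()

    def test_inconsistent_cohort_sizes_rejected(self):
        t1 = PairTable(i=0, j=1, n=100, n_i=10, n_j=10, n_ij=2)
        t2 = PairTable(i=0, j=2, n=200, n_i=10, n_j=10, n_ij=2)
        with pytest.raises(ValueError, match="inconsistent"):
            build_model([t1, t2], ABCModelSpec())

    def test_nonfinite_theta_maps_to_minus_inf(self):
        table = PairTable(i=0, j=1, n=100, n_i=30, n_j=20, n_ij=10)
        model = build_model([table], ABCModelSpec(sigma_abc=0.5))
        theta = np.full(model.ndim, np.nan)
        assert model.log_prob(theta) == -np.inf


class TestPosteriorSummaries:
    def test_hpdi_mode_constant_draws(self):
        assert hpdi_mode(np.full(500, 3.2)) == pytest.approx(3.2)

    def test_hpdi_mode_matches_window_scan(self):
        rng = np.random.default_rng(0)
        draws = rng.lognormal(0.3, 0.4, size=2000)
        mass = 0.05
        # brute-force scan over every contiguous window of k sorted draws
        s = np.sort(draws)
        k = max(2, int(np.ceil(mass * len(s))))
        widths = [s[i + k - 1] - s[i] for i in range(len(s) - k + 1)]
        i_best = int(np.argmin(widths))
        expected = (s[i_best] + s[i_best + k - 1]) / 2
        assert hpdi_mode(draws, mass) == pytest.approx(expected)

    def test_hpdi_mode_integer_ramp(self):
        draws = np.arange(1.0, 101.0)
        # every 5-point window has width 4; the scan takes the first
        assert hpdi_mode(draws, 0.05) == pytest.approx(3.0)

    def test_hpdi_mode_within_range_and_min_draws(self):
        rng = np.random.default_rng(1)
        draws = rng.normal(size=300)
        assert draws.min() <= hpdi_mode(draws) <= draws.max()
        with pytest.raises(ValueError):
            hpdi_mode(draws[:50])

    def test_equal_tailed_ci_sorted_index_oracle(self):
        draws = np.arange(1.0, 1001.0)
        lo, hi = equal_tailed_ci(draws, 0.99)
        exp_lo, exp_hi = np.percentile(draws, [0.5, 99.5])
        assert lo == pytest.approx(exp_lo)
        assert hi == pytest.approx(exp_hi)
        assert lo == pytest.approx(5.995)
        assert hi == pytest.approx(995.005)

    def test_equal_tailed_ci_nesting_and_degenerate(self):
        rng = np.random.default_rng(2)
        draws = rng.normal(size=5000)
        lo99, hi99 = equal_tailed_ci(draws, 0.99)
        lo95, hi95 = equal_tailed_ci(draws, 0.95)
        assert lo99 < lo95 < hi95 < hi99
        lo, hi = equal_tailed_ci(np.full(1000, 2.0))
        assert lo == hi == 2.0
        with pytest.raises(ValueError):
            equal_tailed_ci(np.ones(50), 0.99)

    @pytest.mark.parametrize(
        "ci,expected",
        [((1.2, 1.8), True), ((0.8, 1.3), False), ((0.4, 0.9), True), ((1.0, 1.2), False)],
    )
    def test_significance_from_interval(self, ci, expected):
        assert abc_significance(*ci) is expected


class TestCompareGroups:
    def test_same_distribution_high_p(self):
        rng = np.random.default_rng(3)
        a = rng.normal(2, 0.1, size=20_000)
        b = rng.normal(2, 0.1, size=20_000)
        assert compare_groups(a, b, seed=0) > 0.5

    def test_disjoint_supports(self):
        assert compare_groups(np.full(500, 5.0), np.full(500, 1.0)) == 0.0

    def test_separated_normals_significant(self):
        rng = np.random.default_rng(4)
        a = rng.normal(2, 0.1, size=20_000)
        b = rng.normal(1, 0.1, size=20_000)
        # P(A < B) = Phi(-1/sqrt(0.02)) ~ 8e-13: far below 0.01
        assert compare_groups(a, b, seed=0) < 0.01

    def test_length_mismatch_resampled_deterministically(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=1500)
        b = rng.normal(size=1000)
        assert compare_groups(a, b, seed=7) == compare_groups(a, b, seed=7)

    def test_ties_split_evenly(self):
        a = np.full(1000, 1.0)
        assert compare_groups(a, a) == pytest.approx(1.0)


class TestFit:
    def test_parameter_recovery_two_conditions(self):
        truth = generate_truth(
            2, prevalences=np.array([0.2, 0.2]), associations={(0, 1): 2.0}, seed=21
        )
        cohort = generate_cohort(truth, 10_000, seed=22)
        spec = ABCModelSpec(draws=4_000, warmup=800, thin=3, seed=23)
        post = fit(build_model(pairwise_counts(cohort), spec), spec)
        mode = post.summaries.loc[0, "mode"]
        assert 1.8 <= mode <= 2.2

    def test_identical_seeds_identical_draws(self):
        table = PairTable(i=0, j=1, n=2000, n_i=300, n_j=250, n_ij=60)
        spec = ABCModelSpec(draws=500, warmup=200, thin=2, seed=5)
        p1 = fit(build_model([table], spec), spec)
        p2 = fit(build_model([table], spec), spec)
        assert (p1.abc_draws == p2.abc_draws).all()
        assert (p1.f_draws == p2.f_draws).all()

    def test_rare_pair_shrinks_while_rr_inflates(self):
        # prevalences 0.005 at N = 10,000 with only 2 co-occurrences:
        # empirical lift is 8, but the evidence is 2 patients
        table = PairTable(i=0, j=1, n=10_000, n_i=50, n_j=50, n_ij=2)
        spec = ABCModelSpec(draws=4_000, warmup=800, thin=3, seed=31)
        post = fit(build_model([table], spec), spec)
        row = post.summaries.iloc[0]
        rr = table.n * table.n_ij / (table.n_i * table.n_j)
        assert row.ci_low <= 1.0 <= row.ci_high  # not significant
        assert rr > row["mode"]  # prior pulls the mode toward 1

    def test_large_data_limit_matches_empirical_lift(self):
        # all cells >= 100 and a wide fixed prior: mode within 5% of lift
        table = PairTable(i=0, j=1, n=2_000, n_i=400, n_j=300, n_ij=120)
        spec = ABCModelSpec(draws=4_000, warmup=800, thin=3, seed=41, sigma_abc=5.0)
        post = fit(build_model([table], spec), spec)
        lift = table.n * table.n_ij / (table.n_i * table.n_j)
        assert post.summaries.loc[0, "mode"] == pytest.approx(lift, rel=0.05)

    def test_shrinkage_monotone_in_prior_scale(self):
        # fixed observed cells with empirical lift 3: widening the prior
        # moves the mode toward the lift, narrowing it toward 1
        table = PairTable(i=0, j=1, n=10_000, n_i=100, n_j=100, n_ij=3)
        modes = []
        for sigma in (0.05, 0.3, 2.0):
            spec = ABCModelSpec(
                draws=3_000, warmup=800, thin=3, seed=51, sigma_abc=sigma
            )
            post = fit(build_model([table], spec), spec)
            modes.append(post.summaries.loc[0, "mode"])
        assert modes[0] < modes[1] < modes[2]
        assert modes[0] == pytest.approx(1.0, abs=0.2)

    def test_symmetry_under_relabelling(self, recovery_cohort):
        """Swapping two condition columns leaves that pair's inference
        unchanged (up to the pair's identity)."""
        cohort = recovery_cohort
        perm = [1, 0, 2, 3, 4, 5]
        swapped = CohortMatrix(
            panel=ConditionPanel(tuple(cohort.panel.labels[k] for k in perm)),
            presence=cohort.presence[:, perm],
        )
        spec = ABCModelSpec(draws=2_000, warmup=600, thin=3, seed=61)
        post_a = fit(build_model(pairwise_counts(cohort), spec), spec)
        post_b = fit(build_model(pairwise_counts(swapped), spec), spec)
        mode_a = post_a.summaries.set_index(["i", "j"]).loc[(0, 1), "mode"]
        mode_b = post_b.summaries.set_index(["i", "j"]).loc[(0, 1), "mode"]
        # same pair, same data, independent MCMC runs
        assert mode_a == pytest.approx(mode_b, rel=0.05)

    def test_fit_cohort_drops_zero_prevalence_conditions(self, caplog):
        presence = np.array([[1, 0, 0], [1, 1, 0], [0, 1, 0], [1, 0, 0]] * 50)
        cohort = CohortMatrix(ConditionPanel(("A", "B", "Z")), presence)
        spec = ABCModelSpec(draws=500, warmup=200, thin=2, seed=71)
        with caplog.at_level("WARNING"):
            post = fit_cohort(cohort, spec)
        assert "zero-prevalence" in caplog.text
        # only the (A, B) pair remains, with original panel indices
        assert list(zip(post.pair_i, post.pair_j)) == [(0, 1)]

    def test_recovery_fixture_covers_truth(self, recovery_fit, recovery_truth):
        """99% CrIs from the 6-condition fixture cover every implied lift."""
        for row in recovery_fit.summaries.itertuples():
            truth_lift = recovery_truth.lifts[row.i, row.j]
            assert row.ci_low <= truth_lift <= row.ci_high

    def test_recovery_fixture_diagnostics(self, recovery_fit):
        assert recovery_fit.diagnostics["rhat_max"] < 1.05
        assert recovery_fit.diagnostics["ess_min"] > 200
        assert recovery_fit.n_draws == 4_000
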