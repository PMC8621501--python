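"""MR estimators against closed-form oracles and invariance properties."""

from dataclasses import replace

import numpy as np
import pytest
import statsmodels.api as sm

from lipidmr import (
    CollinearityError,
    MethodError,
    SimConfig,
    egger,
    ivw,
    multivariable_mr,
    mvmr_ivw,
    simulate_multi_exposure,
    to_odds_ratio,
    wald_ratio,
    weighted_median,
    weighted_mode,
)
from lipidmr.estimators import (
    ivw_arrays,
    weighted_median_estimate,
    weighted_mode_estimate,
)
from lipidmr.sumstats import harmonize

from conftest import make_pair, random_pairs


class TestWaldRatio:
    def test_arithmetic(self):
        est = wald_ratio(make_pair(beta_exp=0.1, beta_out=0.05, se_out=0.1))
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(1.0)
        assert wald_ratio(make_pair(beta_out=0.0)).beta == 0.0

    def test_pvalue_matches_normal_cdf(self):
        est = wald_ratio(make_pair(beta_exp=1.0, beta_out=1.96, se_out=1.0))
        assert est.pvalue == pytest.approx(0.0500, abs=2e-4)

    def test_zero_exposure_effect_rejected(self):
        with pytest.raises(MethodError):
            wald_ratio(make_pair(beta_exp=0.0))


class TestIVW:
    def test_homogeneous_ratios(self):
        pairs = [
            make_pair("rs1", 0.1, 0.01, 0.05, 0.02),
            make_pair("rs2", 0.2, 0.01, 0.10, 0.02),
        ]
        est, het = ivw(pairs, "random")
        assert est.beta == pytest.approx(0.5)
        assert het.Q == pytest.approx(0.0, abs=1e-20)
        assert het.i2 == 0.0

    def test_needs_two_variants(self):
        with pytest.raises(MethodError):
            ivw([make_pair()])

    def test_duplicated_variant_equals_wald(self):
        p = make_pair(beta_exp=0.1, beta_out=0.04, se_out=0.02)
        est, _ = ivw([p, p], "fixed")
        assert est.beta == pytest.approx(wald_ratio(p).beta, rel=1e-12)

    def test_matches_statsmodels_wls_oracle(self, rng):
        for _ in range(30):
            pairs = random_pairs(rng, int(rng.integers(5, 51)))
            bx = np.array([v.beta_exp for v in pairs])
            by = np.array([v.beta_out for v in pairs])
            sy = np.array([v.se_out for v in pairs])
            fit = sm.WLS(by, bx, weights=1 / sy**2).fit()
            est_f, _ = ivw(pairs, "fixed")
            assert est_f.beta == pytest.approx(fit.params[0], rel=1e-10)
            se_unscaled = fit.bse[0] / np.sqrt(fit.scale)
            assert est_f.se == pytest.approx(se_unscaled, rel=1e-10)

    def test_random_se_never_below_fixed(self, rng):
        pairs = random_pairs(rng, 20)
        est_f, _ = ivw(pairs, "fixed")
        est_r, _ = ivw(pairs, "random")
        assert est_r.se >= est_f.se
        assert est_r.beta == est_f.beta


class TestEgger:
    def test_exact_linear_fit_recovered(self):
        bx = np.linspace(0.05, 0.2, 6)
        pairs = [
            make_pair(f"rs{i}", bx[i], 0.01, 0.02 + 0.4 * bx[i], 0.02)
            for i in range(6)
        ]
        est, _ = egger(pairs)
        assert est.beta == pytest.approx(0.4, abs=1e-10)
        assert est.egger_intercept == pytest.approx(0.02, abs=1e-10)

    def test_matches_statsmodels_wls_oracle(self, rng):
        for _ in range(30):
            pairs = random_pairs(rng, int(rng.integers(5, 51)))
            bx = np.array([v.beta_exp for v in pairs])
            by = np.array([v.beta_out for v in pairs])
            sy = np.array([v.se_out for v in pairs])
            flip = np.sign(bx)
            X = sm.add_constant(bx * flip)
            fit = sm.WLS(by * flip, X, weights=1 / sy**2).fit()
            est, _ = egger(pairs)
            assert est.egger_intercept == pytest.approx(fit.params[0], rel=1e-10)
            assert est.beta == pytest.approx(fit.params[1], rel=1e-10)

    def test_needs_three_variants(self):
        with pytest.raises(MethodError):
            egger(random_pairs(np.random.default_rng(0), 2))


class TestWeightedMedian:
    def test_hand_interpolation_example(self):
        pairs = [
            make_pair("rs1", 1.0, 0.01, 0.2, 0.05),
            make_pair("rs2", 1.0, 0.01, 0.4, 0.05),
            make_pair("rs3", 1.0, 0.01, 0.6, 0.05),
        ]
        est = weighted_median(pairs, n_boot=0)
        assert est.beta == pytest.approx(0.4)

    def test_weighted_interpolation_formula(self):
        # hand evaluation: ratios (0.1, 0.3, 0.7), weights (1, 2, 1)
        # s = (0.5/4, (1 + 2/2)/4, (3 + 1/2)/4) = (0.125, 0.5, 0.875)
        assert weighted_median_estimate(
            np.array([0.1, 0.3, 0.7]), np.array([1.0, 2.0, 1.0])
        ) == pytest.approx(0.3)

    def test_identical_ratios_and_small_bootstrap_se(self):
        pairs = [
            make_pair(f"rs{i}", 0.1, 1e-5, 0.05, 1e-5) for i in range(4)
        ]
        est = weighted_median(pairs, n_boot=200, seed=1)
        assert est.beta == pytest.approx(0.5, rel=1e-3)
        assert est.se < 0.01

    def test_bootstrap_seed_reproducible(self, rng):
        pairs = random_pairs(rng, 10)
        a = weighted_median(pairs, n_boot=300, seed=42)
        b = weighted_median(pairs, n_boot=300, seed=42)
        c = weighted_median(pairs, n_boot=300, seed=43)
        assert a.se == b.se
        assert a.se != c.se


class TestWeightedMode:
    def test_degenerate_mode(self):
        pairs = [make_pair(f"rs{i}", 0.1, 0.01, 0.03, 0.02) for i in range(5)]
        est = weighted_mode(pairs, n_boot=50, seed=0)
        assert est.beta == pytest.approx(0.3, abs=1e-12)

    def test_mixture_argmax_near_majority_cluster(self, rng):
        ratios = np.concatenate([rng.normal(0.4, 0.01, 14), rng.normal(1.2, 0.01, 6)])
        pairs = [
            make_pair(f"rs{i}", 0.1, 0.001, 0.1 * ratios[i], 0.02)
            for i in range(20)
        ]
        est = weighted_mode(pairs, n_boot=0)
        assert est.beta == pytest.approx(0.4, abs=0.05)

    def test_grid_refinement_bounded_by_step(self, rng):
        pairs = random_pairs(rng, 15)
        bx = np.array([v.beta_exp for v in pairs])
        by = np.array([v.beta_out for v in pairs])
        sy = np.array([v.se_out for v in pairs])
        ratios = by / bx
        weights = (np.abs(bx) / sy) ** 2
        coarse = weighted_mode_estimate(ratios, weights, grid_size=10_000)
        fine = weighted_mode_estimate(ratios, weights, grid_size=100_000)
        step = 10 * np.std(ratios, ddof=1) / 9_999
        assert abs(coarse - fine) <= step

    def test_rejects_nonpositive_bandwidth_factor(self, rng):
        with pytest.raises(Exception):
            weighted_mode(random_pairs(rng, 5), phi=0.0)


class TestEquivariance:
    @pytest.mark.parametrize("method", ["ivw", "egger", "median", "mode"])
    def test_joint_negation_leaves_estimate_unchanged(self, rng, method):
        pairs = random_pairs(rng, 12)
        negated = [
            replace(v, beta_exp=-v.beta_exp, beta_out=-v.beta_out) for v in pairs
        ]
        est_a, est_b = self._run(method, pairs), self._run(method, negated)
        assert est_a.beta == pytest.approx(est_b.beta, rel=1e-9, abs=1e-12)

    @pytest.mark.parametrize("method", ["ivw", "egger", "median", "mode"])
    def test_outcome_negation_negates_estimate(self, rng, method):
        pairs = random_pairs(rng, 12)
        negated = [replace(v, beta_out=-v.beta_out) for v in pairs]
        est_a, est_b = self._run(method, pairs), self._run(method, negated)
        assert est_a.beta == pytest.approx(-est_b.beta, rel=1e-9, abs=1e-12)

    @staticmethod
    def _run(method, pairs):
        if method == "ivw":
            return ivw(pairs, "random")[0]
        if method == "egger":
            return egger(pairs)[0]
        if method == "median":
            return weighted_median(pairs, n_boot=0)
        return weighted_mode(pairs, n_boot=0)


class TestConvergence:
    def test_all_estimators_agree_with_valid_instruments(self):
        """At large sample sizes and no pleiotropy all estimators target
        the same causal effect."""
        means = {m: [] for m in ("ivw", "egger", "median", "mode")}
        for rep in range(10):
            config = SimConfig(
                m_variants=200, prop_instruments=1.0, n_exp=2e6, n_out=2e6,
                theta=0.3, seed=3000 + rep,
            )
            from lipidmr import simulate_pair

            exposure, outcome, _, _ = simulate_pair(config)
            pairs = harmonize(exposure, outcome)
            means["ivw"].append(ivw(pairs, "random")[0].beta)
            means["egger"].append(egger(pairs)[0].beta)
            means["median"].append(weighted_median(pairs, n_boot=0).beta)
            means["mode"].append(weighted_mode(pairs, n_boot=0).beta)
        avg = {m: np.mean(v) for m, v in means.items()}
        for a in avg.values():
            for b in avg.values():
                assert abs(a - b) < 0.02


class TestMultivariable:
    def test_k1_reduces_to_ivw(self, rng):
        pairs = random_pairs(rng, 15)
        bx = np.array([[v.beta_exp] for v in pairs])
        by = np.array([v.beta_out for v in pairs])
        sy = np.array([v.se_out for v in pairs])
        (est,) = mvmr_ivw(bx, by, sy)
        ref, _ = ivw(pairs, "random")
        assert est.beta == pytest.approx(ref.beta, rel=1e-10)
        assert est.se == pytest.approx(ref.se, rel=1e-10)

    def test_matches_statsmodels_oracle(self, rng):
        n, k = 40, 3
        X = rng.normal(0, 0.05, (n, k))
        by = rng.normal(0, 0.05, n)
        sy = rng.uniform(0.01, 0.05, n)
        fit = sm.WLS(by, X, weights=1 / sy**2).fit()
        ests = mvmr_ivw(X, by, sy)
        for i in range(k):
            assert ests[i].beta == pytest.approx(fit.params[i], rel=1e-10)

    def test_duplicated_exposure_is_collinear(self, rng):
        n = 20
        x = rng.normal(0, 0.05, n)
        X = np.column_stack([x, x])
        with pytest.raises(CollinearityError, match="exposure"):
            mvmr_ivw(X, rng.normal(size=n), np.full(n, 0.02))

    def test_recovers_joint_effects_with_correlated_exposures(self):
        """theta = (0.3, 0, 0.2) with effect correlation 0.5: each 95% CI
        should cover its truth in >= 90% of replicates."""
        thetas = (0.3, 0.0, 0.2)
        corr = np.full((3, 3), 0.5)
        np.fill_diagonal(corr, 1.0)
        config = SimConfig(m_variants=120, prop_instruments=1.0, seed=0)
        covered = np.zeros(3)
        n_reps = 200
        for rep in range(n_reps):
            exps, outcome, truth = simulate_multi_exposure(
                replace(config, seed=5000 + rep), 3, corr, thetas=thetas
            )
            ests = multivariable_mr(exps, outcome)
            for i, est in enumerate(ests):
                lo, hi = np.log(est.ci_low), np.log(est.ci_high)
                covered[i] += lo <= thetas[i] <= hi
        assert np.all(covered / n_reps >= 0.90)


class TestOddsRatio:
    def test_null_and_closed_form(self):
        or_, lo, hi = to_odds_ratio(0.0, 0.1)
        assert or_ == 1.0
        assert lo * hi == pytest.approx(1.0, rel=1e-12)
        or_, lo, hi = to_odds_ratio(0.3, 0.1)
        assert or_ == pytest.approx(1.3499, abs=1e-4)
        assert lo == pytest.approx(1.1097, abs=1e-4)
        assert hi == pytest.approx(1.6421, abs=1e-4)

    def test_negation_symmetry(self):
        or_pos, *_ = to_odds_ratio(0.3, 0.1)
        or_neg, *_ = to_odds_ratio(-0.3, 0.1)
        assert or_neg == pytest.approx(1 / or_pos, rel=1e-12)
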