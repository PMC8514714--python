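import dataclasses

import numpy as np
import pytest

from ylineage.pairwise import PairDifference, difference_vector
from ylineage.simulate import SimulationConfig, simulate_pair
from ylineage.tmrca import (
    MutationRateTable,
    WalshConfig,
    default_rates,
    generations_separating,
    iam_likelihood,
    smm_likelihood,
    tmrca_posterior,
    to_years,
)


def single_locus_diff(mismatch: int, step: float = None) -> PairDifference:
    d = step if step is not None else float(mismatch)
    return PairDifference("a", "b", ("L0",), (mismatch,), (d,))


def multi_locus_diff(iam, smm=None) -> PairDifference:
    loci = tuple(f"L{i}" for i in range(len(iam)))
    smm = smm or tuple(float(v) for v in iam)
    return PairDifference("a", "b", loci, tuple(iam), tuple(smm))


def uniform_rates(loci_count: int, mu: float) -> MutationRateTable:
    return MutationRateTable({f"L{i}": mu for i in range(loci_count)})


class TestIamLikelihood:
    def test_t0_certain_identity(self):
        rates = uniform_rates(3, 0.01)
        assert iam_likelihood(multi_locus_diff([0, 0, 0]), rates, 0) == 1.0

    def test_t0_mismatch_impossible(self):
        rates = uniform_rates(3, 0.01)
        assert iam_likelihood(multi_locus_diff([0, 1, 0]), rates, 0) == 0.0

    def test_single_locus_closed_form(self):
        rates = uniform_rates(1, 0.01)
        lik = iam_likelihood(single_locus_diff(1), rates, 10)
        assert lik == pytest.approx(1 - 0.99**20, rel=1e-12)

    def test_matches_monte_carlo_mutation_oracle(self):
        """A locus mismatches iff ≥1 of the 2t per-meiosis mutation draws
        fires (infinite alleles: every mutation is novel)."""
        rng = np.random.default_rng(2024)
        reps = 1_000_000
        for mu, t in [(0.01, 10), (0.002, 25), (0.012, 5)]:
            mc = float((rng.binomial(2 * t, mu, reps) > 0).mean())
            se = np.sqrt(mc * (1 - mc) / reps)
            lik = iam_likelihood(single_locus_diff(1), uniform_rates(1, mu), t)
            assert abs(lik - mc) <= 3 * se

    def test_non_increasing_in_t_for_all_match(self):
        rates = uniform_rates(5, 0.01)
        diff = multi_locus_diff([0] * 5)
        values = [iam_likelihood(diff, rates, t) for t in range(0, 200, 10)]
        assert all(a >= b for a, b in zip(values, values[1:]))
        assert values[-1] < 1e-3

    def test_uncovered_series_rejected(self):
        with pytest.raises(KeyError, match="L0"):
            iam_likelihood(single_locus_diff(0), MutationRateTable({"X": 0.01}), 5)


class TestSmmLikelihood:
    def test_zero_rate_limit(self):
        # with mu -> 0 no mutation can occur, so d=0 is certain
        rates = uniform_rates(1, 1e-9)
        lik = smm_likelihood(single_locus_diff(0, step=0.0), rates, 50)
        assert lik == pytest.approx(1.0, abs=1e-6)

    def test_parity_constraint(self):
        # an odd displacement needs an odd number of ±1 steps; at t=0 or
        # with even step counts only, probability is exactly 0
        rates = uniform_rates(1, 0.02)
        assert smm_likelihood(single_locus_diff(1, step=1.0), rates, 0) == 0.0

    def test_matches_monte_carlo_walk_oracle(self):
        """P(repeat difference d) via simulating m ~ Binomial(2t, μ)
        mutations, each stepping ±1 with equal probability."""
        rng = np.random.default_rng(99)
        reps = 1_000_000
        grid = [(0.02, 5, 1), (0.02, 5, 0), (0.05, 10, 2), (0.012, 20, -1),
                (0.08, 3, 0)]
        for mu, t, d in grid:
            m = rng.binomial(2 * t, mu, reps)
            disp = 2 * rng.binomial(m, 0.5) - m
            mc = float((disp == d).mean())
            se = np.sqrt(max(mc * (1 - mc), 1e-12) / reps)
            lik = smm_likelihood(single_locus_diff(int(d != 0), step=float(d)),
                                 uniform_rates(1, mu), t)
            assert abs(lik - mc) <= 3 * se, (mu, t, d, lik, mc)

    def test_smm_d0_at_least_iam_match(self):
        """With zero observed difference SMM ≥ IAM at the same (μ, t):
        the stepwise walk allows hidden back-mutation paths."""
        rates = uniform_rates(1, 0.01)
        for t in (1, 5, 20, 80):
            smm = smm_likelihood(single_locus_diff(0, step=0.0), rates, t)
            iam = iam_likelihood(single_locus_diff(0), rates, t)
            assert smm >= iam


class TestPosterior:
    def test_normalization(self):
        rates = uniform_rates(4, 0.01)
        for iam in ([0, 0, 0, 0], [1, 0, 0, 0], [1, 1, 1, 0]):
            post = tmrca_posterior(
                multi_locus_diff(iam), rates, WalshConfig(lambda_prior=100)
            )
            assert abs(post.mass.sum() - 1.0) < 1e-9

    def test_zero_rates_reduce_to_prior(self):
        rates = uniform_rates(3, 0.0)
        config = WalshConfig(lambda_prior=50, grid_max=2000)
        post = tmrca_posterior(multi_locus_diff([0, 0, 0]), rates, config)
        lam = 50.0
        prior = (1 / (lam + 1)) * (lam / (lam + 1)) ** post.support
        prior /= prior.sum()
        assert np.allclose(post.mass, prior, atol=1e-12)
        assert post.mode == 0.0

    def test_all_match_mode_zero_and_decreasing(self):
        rates = uniform_rates(27, 0.005)
        post = tmrca_posterior(multi_locus_diff([0] * 27), rates, WalshConfig())
        assert post.mode == 0.0
        assert np.all(np.diff(post.mass) <= 1e-15)

    def test_ci_nesting(self):
        rates = uniform_rates(10, 0.005)
        config = WalshConfig(ci_levels=(0.5, 0.8, 0.95))
        post = tmrca_posterior(
            multi_locus_diff([1, 1, 0, 0, 0, 0, 0, 0, 0, 0]), rates, config
        )
        lo50, hi50 = post.ci[0.5]
        lo80, hi80 = post.ci[0.8]
        lo95, hi95 = post.ci[0.95]
        assert lo95 <= lo80 <= lo50 and hi50 <= hi80 <= hi95

    def test_larger_lambda_shifts_posterior_up(self):
        """First-order stochastic dominance in the prior mean λ."""
        rates = uniform_rates(8, 0.004)
        diff = multi_locus_diff([1, 1, 0, 0, 0, 0, 0, 0])
        post_small = tmrca_posterior(diff, rates, WalshConfig(lambda_prior=100))
        post_big = tmrca_posterior(diff, rates, WalshConfig(lambda_prior=1000))
        n = min(len(post_small.mass), len(post_big.mass))
        cdf_small = np.cumsum(post_small.mass[:n])
        cdf_big = np.cumsum(post_big.mass[:n])
        assert np.all(cdf_big <= cdf_small + 1e-12)

    def test_dropping_matched_locus_widens_95ci(self):
        """Less information (a missing matched locus) weakly widens the
        interval."""
        rates = uniform_rates(27, 0.005)
        full = multi_locus_diff([1] * 2 + [0] * 25)
        reduced = PairDifference(
            "a", "b", full.loci[:-5], full.iam_vector[:-5], full.smm_vector[:-5]
        )
        post_full = tmrca_posterior(full, rates, WalshConfig())
        post_red = tmrca_posterior(reduced, rates, WalshConfig())
        w_full = post_full.ci[0.95][1] - post_full.ci[0.95][0]
        w_red = post_red.ci[0.95][1] - post_red.ci[0.95][0]
        assert w_red >= w_full

    def test_all_zero_likelihood_rejected(self):
        # a mismatch with zero mutation rate is impossible at every t
        rates = uniform_rates(1, 0.0)
        with pytest.raises(ValueError, match="grid_max"):
            tmrca_posterior(single_locus_diff(1), rates, WalshConfig(grid_max=50))

    def test_smm_posterior_runs_on_small_grid(self):
        rates = uniform_rates(3, 0.01)
        config = WalshConfig(model="SMM", lambda_prior=20, grid_max=200)
        post = tmrca_posterior(
            multi_locus_diff([1, 0, 0], smm=(1.0, 0.0, 0.0)), rates, config
        )
        assert abs(post.mass.sum() - 1.0) < 1e-9
        assert post.mode > 0


class TestScaling:
    def _posterior(self):
        rates = uniform_rates(5, 0.01)
        return tmrca_posterior(
            multi_locus_diff([1, 0, 0, 0, 0]), rates, WalshConfig(lambda_prior=100)
        )

    def test_generations_separating_doubles_everything(self):
        post = self._posterior()
        total = generations_separating(post)
        assert total.mean == pytest.approx(2 * post.mean)
        assert total.median == 2 * post.median
        assert total.mode == 2 * post.mode
        for level in post.ci:
            assert total.ci[level] == tuple(2 * v for v in post.ci[level])
        assert np.array_equal(total.mass, post.mass)

    def test_to_years_scales_by_generation_time(self):
        post = self._posterior()
        total = generations_separating(post)
        years = to_years(total, 33.0)
        assert years.mean == pytest.approx(33.0 * total.mean)
        years30 = to_years(total, 30.0)
        assert years30.median == pytest.approx(30.0 * total.median)
        for level in total.ci:
            lo, hi = total.ci[level]
            assert years.ci[level] == (pytest.approx(33 * lo), pytest.approx(33 * hi))


class TestCalibration:
    def test_mode_recovers_simulated_tmrca(self):
        """Posterior mode error stays small on pairs simulated at a known
        separation (27 series, default rates)."""
        config = SimulationConfig(seed=0)
        panel = config.panel
        rates = config.effective_rates()
        wconfig = WalshConfig()
        errors = []
        for rep in range(100):
            pair = simulate_pair(12, dataclasses.replace(config, seed=10_000 + rep))
            diff = difference_vector(pair.haplotype_a, pair.haplotype_b, panel)
            post = tmrca_posterior(diff, rates, wconfig)
            errors.append(abs(post.mode - pair.true_tmrca))
        assert np.median(errors) <= 5
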