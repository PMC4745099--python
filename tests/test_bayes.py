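"""Sequential beta-binomial updating, posterior medians and HDR intervals."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy.stats import beta as beta_dist

from claysub.bayes import (
    PosteriorState,
    equal_tailed_interval,
    hdr_interval,
    is_success,
    make_prior,
    posterior_median,
    run_substitution_inference,
    update_sequential,
)
from claysub.core import AnalysisConfig
from claysub.synth import SynthSpec, generate_dataset

from conftest import make_dataset, make_unit


class TestSuccessCriterion:
    def test_both_clauses_hold(self):
        u = make_unit(clay=70.0, initial_wood=3.44, leftover=1.0)
        assert is_success(u, mean_clay=58.9)

    def test_clay_equal_to_mean_is_failure(self):
        u = make_unit(clay=58.9, initial_wood=3.44, leftover=1.0)
        assert not is_success(u, mean_clay=58.9)

    def test_leftover_exactly_half_is_failure(self):
        u = make_unit(clay=70.0, initial_wood=3.44, leftover=1.72)
        assert not is_success(u, mean_clay=58.9)


class TestPriorsAndUpdating:
    def test_jeffreys_prior(self):
        p = make_prior("jeffreys")
        assert (p.alpha, p.beta) == (0.5, 0.5)

    def test_uniform_prior_and_median(self):
        p = make_prior("uniform")
        assert (p.alpha, p.beta) == (1.0, 1.0)
        assert posterior_median(p) == pytest.approx(0.5)

    def test_unknown_prior_rejected(self):
        with pytest.raises(ValueError):
            make_prior("haldane")

    def test_single_success_conjugacy(self):
        post = update_sequential(make_prior("jeffreys"), [True])
        assert (post.alpha, post.beta) == (1.5, 0.5)

    def test_thirteen_successes(self):
        post = update_sequential(make_prior("jeffreys"), [True] * 13)
        assert (post.alpha, post.beta) == (13.5, 0.5)

    def test_history_tracks_every_state(self):
        post = update_sequential(make_prior("uniform"), [True, False, True])
        assert post.history == ((1, 1), (2, 1), (2, 2), (3, 2))
        assert post.n_observed == 3
        assert post.alpha + post.beta == 2 + 3

    @settings(derandomize=True, max_examples=50)
    @given(hst.lists(hst.booleans(), max_size=40))
    def test_sequential_equals_batch_and_is_order_invariant(self, outcomes):
        prior = make_prior("jeffreys")
        seq = update_sequential(prior, outcomes)
        assert seq.alpha == prior.alpha + sum(outcomes)
        assert seq.beta == prior.beta + len(outcomes) - sum(outcomes)
        rev = update_sequential(prior, outcomes[::-1])
        assert (rev.alpha, rev.beta) == (seq.alpha, seq.beta)

    def test_adding_success_weakly_increases_median(self):
        state = make_prior("jeffreys")
        prev = posterior_median(state)
        for _ in range(10):
            state = update_sequential(state, [True])
            cur = posterior_median(state)
            assert cur >= prev
            prev = cur


class TestMedian:
    def test_beta_14_1_closed_form(self):
        assert posterior_median(PosteriorState(14, 1)) == pytest.approx(0.5 ** (1 / 14))

    @pytest.mark.parametrize("a,b", [(2, 5), (0.5, 0.5), (7, 3)])
    def test_reflection_symmetry(self, a, b):
        m1 = posterior_median(PosteriorState(a, b))
        m2 = posterior_median(PosteriorState(b, a))
        assert m1 == pytest.approx(1 - m2)


def grid_narrowest_interval(a, b, mass, resolution=1e-4):
    """Brute-force narrowest interval of the given mass on a quantile grid."""
    dist = beta_dist(a, b)
    lows = np.linspace(0.0, 1 - mass, int(round((1 - mass) / resolution)) + 1)
    lo_q = dist.ppf(lows)
    hi_q = dist.ppf(lows + mass)
    i = np.argmin(hi_q - lo_q)
    return lo_q[i], hi_q[i]


class TestHdrInterval:
    def test_monotone_increasing_density_closed_form(self):
        iv = hdr_interval(PosteriorState(14, 1), 0.99)
        assert iv.lower == pytest.approx(0.01 ** (1 / 14), abs=1e-12)
        assert iv.upper == 1.0

    def test_monotone_decreasing_density_closed_form(self):
        iv = hdr_interval(PosteriorState(1, 14), 0.99)
        assert iv.lower == 0.0
        assert iv.upper == pytest.approx(1 - 0.01 ** (1 / 14), abs=1e-12)

    def test_symmetric_posterior_symmetric_interval(self):
        iv = hdr_interval(PosteriorState(5, 5), 0.99)
        assert iv.lower + iv.upper == pytest.approx(1.0, abs=1e-7)

    @pytest.mark.parametrize("a,b,mass", [(5, 5, 0.99), (13.5, 0.5, 0.99), (3, 8, 0.95),
                                          (1.5, 20.5, 0.99), (22, 1, 0.99)])
    def test_contained_mass_exact(self, a, b, mass):
        iv = hdr_interval(PosteriorState(a, b), mass)
        d = beta_dist(a, b)
        assert d.cdf(iv.upper) - d.cdf(iv.lower) == pytest.approx(mass, abs=1e-6)

    @pytest.mark.parametrize("a,b", [(5, 5), (3, 8), (2.5, 17.5), (14, 2)])
    def test_never_wider_than_equal_tailed(self, a, b):
        s = PosteriorState(a, b)
        assert hdr_interval(s, 0.99).width <= equal_tailed_interval(s, 0.99).width + 1e-12

    @pytest.mark.parametrize("a,b,mass", [(5, 5, 0.99), (3, 8, 0.9), (17.5, 4.5, 0.99)])
    def test_matches_grid_search_oracle(self, a, b, mass):
        iv = hdr_interval(PosteriorState(a, b), mass)
        lo, hi = grid_narrowest_interval(a, b, mass)
        assert iv.width <= (hi - lo) + 1e-9
        assert iv.lower == pytest.approx(lo, abs=5e-3)

    def test_u_shaped_posterior_falls_back_with_warning(self):
        with pytest.warns(UserWarning, match="U-shaped"):
            iv = hdr_interval(PosteriorState(0.5, 0.5), 0.99)
        assert iv.method == "equal_tailed"

    def test_uniform_posterior_centred(self):
        iv = hdr_interval(PosteriorState(1, 1), 0.99)
        assert (iv.lower, iv.upper) == (pytest.approx(0.005), pytest.approx(0.995))

    def test_coverage_of_known_probability(self, rng):
        """99% HDR contains the true success probability in >= 97% of 500
        simulated 21-replicate experiments."""
        hits = 0
        n_sim = 500
        for _ in range(n_sim):
            p = rng.uniform(0.1, 0.9)
            outcomes = (rng.random(21) < p).tolist()
            post = update_sequential(make_prior("jeffreys"), outcomes)
            iv = hdr_interval(post, 0.99)
            hits += iv.lower <= p <= iv.upper
        assert hits / n_sim >= 0.97


class TestInferencePipeline:
    @staticmethod
    def _dataset(n, success_flags):
        """Replicates engineered so exactly the flagged ones are successes."""
        from claysub.core import ExperimentDataset, PairedReplicate, Scale

        reps = tuple(
            PairedReplicate(
                replicate_id=f"r{i}",
                unloaded=make_unit("unloaded", clay=40.0, leftover=0.4),
                loaded=make_unit(
                    clay=100.0 if flag else 10.0,
                    initial_wood=3.44,
                    leftover=0.2 if flag else 3.0,
                ),
                contacted_both=True,
            )
            for i, flag in enumerate(success_flags)
        )
        assert len(reps) == n
        return ExperimentDataset(scale=Scale.LAB, replicates=reps, duration_days=30)

    def test_all_success_sequence_matches_closed_form(self):
        """21 successes under a uniform prior -> Beta(22, 1), median 0.5^(1/22)."""
        post = update_sequential(make_prior("uniform"), [True] * 21)
        assert (post.alpha, post.beta) == (22.0, 1.0)
        assert posterior_median(post) == pytest.approx(0.5 ** (1 / 22))

    def test_no_success_dataset_has_small_median(self):
        ds = self._dataset(21, [False] * 21)
        cfg = AnalysisConfig(prior_kind="uniform")
        report = run_substitution_inference(ds, cfg)
        assert report.n_successes == 0
        assert report.median < 0.05

    def test_mixed_dataset_counts_and_trajectory(self):
        flags = [True] * 15 + [False] * 6
        ds = self._dataset(21, flags)
        report = run_substitution_inference(ds, AnalysisConfig(prior_kind="jeffreys"))
        assert report.n_successes == 15
        assert len(report.trajectory) == 22
        assert report.posterior.alpha == pytest.approx(0.5 + 15)
        assert report.interval.lower < report.median < report.interval.upper

    def test_substitution_signal_recovered_from_generator(self):
        """A strong substitution regime (tight clay spread, heavy consumption,
        strong negative coupling) yields a clearly higher posterior median
        than a null regime with no coupling and little consumption, for every
        one of 20 seeds."""
        for seed in range(20):
            strong = SynthSpec.lab_defaults(
                seed=seed, coupling_rho=-0.8, clay_sd_loaded=10.0, leftover_mean_loaded=0.3,
                leftover_sd_loaded=0.3,
            )
            null = SynthSpec.lab_defaults(
                seed=seed, coupling_rho=0.0, leftover_mean_loaded=3.0, leftover_sd_loaded=0.3,
            )
            m_strong = run_substitution_inference(generate_dataset(strong)).median
            m_null = run_substitution_inference(generate_dataset(null)).median
            assert m_strong > m_null
            assert m_strong > 0.3

    def test_empty_dataset_rejected(self):
        ds = make_dataset([False, False])
        with pytest.raises(ValueError, match="no included replicates"):
            run_substitution_inference(ds)
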