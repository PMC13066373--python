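"""Core thinning loop: time increments, candidate selection, acceptance,
bound management, renewal statistics and diagnostics."""

import math

import numpy as np
import pytest
from scipy import stats

from mosaicsim import (BoundViolationError, DiagnosticUnavailable,
                       EngineError, ExponentialIED, GammaIED, MosaicEngine,
                       ParameterError, ParetoIED, UnboundedHazardError,
                       WeibullIED, acceptance_probability,
                       draw_time_increment, interevent_emd, rejection_ratio,
                       renewal_density, run_renewal, select_candidate,
                       update_lambda_max)


class TestTimeIncrement:
    def test_known_values(self):
        assert draw_time_increment(math.exp(-1), 1, 1.0) == pytest.approx(1.0)
        assert draw_time_increment(1.0, 7, 3.0) == 0.0

    def test_mean_is_reciprocal_total_rate(self):
        rng = np.random.default_rng(0)
        u = 1.0 - rng.random(100_000)
        dts = np.log(1.0 / u) / (10 * 0.5)
        # analytic mean 1/(N*lambda_max) = 0.2; MC error ~ 0.2/sqrt(1e5)
        assert dts.mean() == pytest.approx(0.2, abs=0.005)

    def test_parameter_errors(self):
        with pytest.raises(ParameterError):
            draw_time_increment(0.5, 0, 1.0)
        with pytest.raises(ParameterError):
            draw_time_increment(0.5, 3, 0.0)
        with pytest.raises(ParameterError):
            draw_time_increment(0.0, 3, 1.0)


class TestCandidateSelection:
    def test_single_channel_always_chosen(self):
        eng = MosaicEngine(seed=0)
        eng.add_channel(ExponentialIED(1.0))
        assert all(select_candidate(eng.channels, eng.rng) == 0
                   for _ in range(20))

    def test_empty_registry(self):
        with pytest.raises(EngineError):
            select_candidate([], np.random.default_rng(0))

    def test_uniformity_four_channels(self):
        rng = np.random.default_rng(1)
        chans = [None] * 4
        draws = np.array([select_candidate(chans, rng) for _ in range(40_000)])
        freq = np.bincount(draws, minlength=4) / draws.size
        sigma = math.sqrt(0.25 * 0.75 / draws.size)
        assert np.all(np.abs(freq - 0.25) < 3 * sigma + 1e-12)

    def test_chi_square_uniformity_hundred_channels(self):
        rng = np.random.default_rng(2)
        chans = [None] * 100
        draws = np.array([select_candidate(chans, rng)
                          for _ in range(100_000)])
        counts = np.bincount(draws, minlength=100)
        assert stats.chisquare(counts).pvalue > 0.01


class TestAcceptance:
    def test_exponential_at_its_own_bound_always_fires(self):
        assert acceptance_probability(2.0, 2.0) == 1.0

    def test_pareto_ratio(self):
        par = ParetoIED(1.0, 0.8)
        # lambda(2*t_min)/lambda_max = t_min/t = 0.5
        assert acceptance_probability(par.rate(2.0), par.bound()) == \
            pytest.approx(0.5)

    def test_gamma_vanishes_at_origin(self):
        gam = GammaIED(3.0, 1.0)
        assert acceptance_probability(gam.rate(0.0), gam.bound()) == 0.0

    def test_bound_violation_is_hard_error(self):
        with pytest.raises(BoundViolationError):
            acceptance_probability(1.1, 1.0)


class TestStepAndRun:
    def test_single_exponential_channel_is_exact(self):
        res = run_renewal(ExponentialIED(0.7), n_events=5000, seed=3)
        assert stats.kstest(res["interevent_times"],
                            stats.expon(scale=1 / 0.7).cdf).pvalue > 0.01

    def test_rejected_step_changes_only_time(self):
        eng = MosaicEngine(seed=4, lambda_max=50.0)  # ~2% acceptance
        proc = eng.add_channel(ExponentialIED(1.0), payload={"x": 1})
        rec = eng.step()
        while rec is None or rec.accepted:
            rec = eng.step()
        assert proc.tau == 0.0 and proc.payload == {"x": 1}
        assert eng.T > 0.0

    def test_competing_exponentials_split_by_rate(self):
        eng = MosaicEngine(seed=5)
        a = eng.add_channel(ExponentialIED(3.0), kind="a")
        eng.add_channel(ExponentialIED(1.0), kind="b")
        wins = 0
        n = 5000
        accepted = 0
        while accepted < n:
            rec = eng.step()
            if rec is not None and rec.accepted:
                accepted += 1
                wins += rec.kind == "a"
        p = 3.0 / 4.0
        assert wins / n == pytest.approx(p, abs=3 * math.sqrt(p * (1 - p) / n))

    def test_same_seed_identical_logs(self):
        def one(seed):
            eng = MosaicEngine(seed=seed)
            eng.add_channel(GammaIED(3.0, 0.5))
            eng.add_channel(ExponentialIED(0.3))
            return eng.run(50.0)
        assert one(11) == one(11)
        assert one(11) != one(12)

    def test_zero_horizon_empty_log_and_negative_raises(self):
        eng = MosaicEngine(seed=0)
        eng.add_channel(ExponentialIED(1.0))
        assert eng.run(0.0) == []
        with pytest.raises(ParameterError):
            eng.run(-1.0)

    def test_pure_death_mean_extinction_time(self):
        """X -> 0 at unit rate from X0=100: E[T_ext] = H_100 (harmonic)."""
        h100 = sum(1.0 / k for k in range(1, 101))
        times = []
        rng = np.random.default_rng(6)
        for _ in range(1000):
            eng = MosaicEngine(rng=rng)
            for _ in range(100):
                eng.add_channel(ExponentialIED(1.0))
            eng.run(np.inf, on_fire=lambda p, e: e.remove_channel(p),
                    record=False)
            times.append(eng.T)
        # sd of T_ext ~ 1.28, so the mean over 1000 runs has se ~ 0.04
        assert np.mean(times) == pytest.approx(h100, abs=0.15)

    def test_registry_growth_reads_live_count(self):
        """N in the time-increment law follows the live registry."""
        eng = MosaicEngine(seed=7)
        eng.add_channel(ExponentialIED(1.0))
        for _ in range(4):
            eng.step(on_fire=lambda p, e: e.add_channel(ExponentialIED(1.0)))
        assert len(eng.channels) == 1 + eng.accepted


class TestLambdaMaxManagement:
    def test_fixed_bounds_per_family(self):
        eng = MosaicEngine(seed=0)
        eng.add_channel(GammaIED(3.0, 0.05))
        assert update_lambda_max(eng) == pytest.approx(0.15)
        eng.add_channel(ParetoIED(1.0, 0.76))
        assert update_lambda_max(eng) == pytest.approx(0.76)

    def test_bound_shrinks_after_removal(self):
        eng = MosaicEngine(seed=0)
        eng.add_channel(GammaIED(3.0, 0.05))
        p = eng.add_channel(ParetoIED(1.0, 0.76))
        eng.remove_channel(p)
        assert update_lambda_max(eng) == pytest.approx(0.15)

    def test_increasing_hazard_bound_tracks_oldest_clock(self):
        """Weibull shape>1: the managed bound always dominates the brute-
        force maximum over clocks, including right after the oldest fires."""
        eng = MosaicEngine(seed=8, debug_bounds=True)
        for k in range(5):
            eng.add_channel(WeibullIED(2.0, 5.0), tau=-k)  # staggered ages
        fired = 0
        while fired < 60:
            rec = eng.step()
            if rec is not None and rec.accepted:
                fired += 1
                assert eng.lambda_max(0.0) >= eng.true_max_rate() * (1 - 1e-9)

    def test_decreasing_hazard_refused_without_override(self):
        eng = MosaicEngine(seed=0)
        with pytest.raises(UnboundedHazardError):
            eng.add_channel(WeibullIED(0.5, 1.0))
        # explicit user bound overrides the refusal
        eng2 = MosaicEngine(seed=0, lambda_max=5.0)
        eng2.add_channel(WeibullIED(0.5, 1.0), tau=-1.0)
        eng2.step()


class TestDiagnostics:
    def test_renewal_density_formulas(self):
        lam = 0.7
        assert renewal_density(ExponentialIED(lam), 2.0) == \
            pytest.approx(lam * math.exp(-2 * lam))
        par = ParetoIED(1.5, 0.76)
        t = 4.0
        assert renewal_density(par, t) == \
            pytest.approx(0.76 * 1.5 ** 0.76 / t ** 1.76)

    def test_emd_requires_enough_events(self):
        with pytest.raises(DiagnosticUnavailable):
            interevent_emd(np.ones(50), ExponentialIED(1.0))

    def test_emd_shrinks_with_sample_size_on_exact_samples(self):
        ied = GammaIED(3.0, 0.05)
        small = interevent_emd(ied.sample(200, np.random.default_rng(0)), ied)
        large = interevent_emd(ied.sample(20000, np.random.default_rng(1)), ied)
        assert large < small

    def test_rejection_ratio_scales_linearly_with_bound(self):
        """r = lambda_max / lambda_0 exactly for a single channel."""
        ied = GammaIED(3.0, 1.0)
        rs = []
        mults = [1.0, 2.0, 4.0]
        for m in mults:
            res = run_renewal(ied, n_events=3000, seed=9,
                              lambda_max=m * ied.bound())
            rs.append(rejection_ratio(res["accepted"], res["rejected"]))
        slope = np.polyfit(np.log(mults), np.log(rs), 1)[0]
        assert slope == pytest.approx(1.0, abs=0.15)

    def test_candidate_cost_flat_in_system_size(self):
        """Candidates per accepted event do not grow with N (O(1) cost)."""
        rs = []
        for n in (4, 16, 64):
            eng = MosaicEngine(seed=10)
            for _ in range(n):
                eng.add_channel(GammaIED(3.0, 1.0))
            while eng.accepted < 2000:
                eng.step()
            rs.append(rejection_ratio(eng.accepted, eng.rejected))
        assert max(rs) / min(rs) < 1.3
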