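"""Node-driven temporal-network engine."""

import math

import numpy as np
import pytest
from scipy import stats

from mosaicsim import (ExponentialIED, ParameterError, ParetoIED,
                       TemporalNetworkSim, TNParams, biased_partner_selection,
                       interdurations, interevent_emd, lambda_max_tn,
                       run_facetoface)


class TestPairBound:
    def test_known_value(self):
        # alpha=1, t_min=1 -> node bound 1; /((2-1)*0.5) = 2
        assert lambda_max_tn(1.0, 1.0, 0.5, 2) == pytest.approx(2.0)

    def test_scales_inversely_with_population(self):
        b10 = lambda_max_tn(0.76, 1.0, 0.4, 10)
        b19 = lambda_max_tn(0.76, 1.0, 0.4, 19)
        assert b10 / b19 == pytest.approx(18.0 / 9.0)

    def test_invalid_parameters(self):
        with pytest.raises(ParameterError):
            lambda_max_tn(0.76, 1.0, 0.4, 1)


class TestKernel:
    def test_multiplicative_kernel_at_characteristic_rate(self):
        """When both hazards equal lam_A the kernel is lam_A/(N_A-1)."""
        params = TNParams(n_nodes=5, alpha_activity=1.5, rate_activity=0.5)
        sim = TemporalNetworkSim(params, seed=0)
        # Pareto hazard alpha/t equals lam_A at t = alpha/lam_A
        t_star = params.alpha_activity / params.rate_activity
        sim.T = t_star
        sim.tau[:] = 0.0
        assert sim.pair_kernel(0, 1) == pytest.approx(0.5 / 4.0)

    def test_two_node_candidate_is_always_the_single_pair(self):
        params = TNParams(n_nodes=2, alpha_activity=1.5, rate_activity=0.5)
        sim = TemporalNetworkSim(params, seed=1)
        ev = None
        while ev is None:
            ev = sim.step()
        assert ev[1:] == (0, 1)

    def test_clock_reset_on_formation(self):
        params = TNParams(n_nodes=6, alpha_activity=1.5, rate_activity=0.5)
        sim = TemporalNetworkSim(params, seed=2)
        while True:
            ev = sim.step()
            if ev is not None and ev[0] == "form":
                break
        _, i, j = ev
        assert sim.tau[i] == sim.T and sim.tau[j] == sim.T
        assert np.sum(sim.tau == sim.T) == 2


class TestPartnerMemory:
    def test_weight_one_is_uniform(self):
        rng = np.random.default_rng(3)
        draws = [biased_partner_selection(rng, 2, {5}, 10, 1.0)
                 for _ in range(20000)]
        counts = np.bincount(draws, minlength=10)
        assert counts[2] == 0
        assert stats.chisquare(np.delete(counts, 2)).pvalue > 0.01

    def test_single_prior_partner_weight_nine(self):
        """One previous partner among 10 candidates at w=9: chosen with
        probability 9/18 = 1/2."""
        rng = np.random.default_rng(4)
        hits = np.mean([biased_partner_selection(rng, 0, {7}, 11, 9.0) == 7
                        for _ in range(20000)])
        assert hits == pytest.approx(0.5, abs=0.015)

    def test_proposal_memory_is_cheaper_than_kernel_memory(self):
        """Pushing the same preference through the kernel under uniform
        proposals costs roughly w times more rejections (order of
        magnitude) than re-weighting the proposal."""
        _, st_prop = run_facetoface(n_nodes=30, t_end=600.0, w=9.4, seed=3,
                                    preference="proposal")
        _, st_kern = run_facetoface(n_nodes=30, t_end=600.0, w=9.4, seed=3,
                                    preference="kernel")
        ratio = st_kern["rejected"] / st_prop["rejected"]
        assert 3.0 < ratio < 30.0

    def test_weight_below_one_rejected(self):
        with pytest.raises(ParameterError):
            TNParams(w=0.5)


class TestFaceToFace:
    def test_same_seed_determinism(self):
        a, _ = run_facetoface(n_nodes=15, t_end=400.0, seed=5)
        b, _ = run_facetoface(n_nodes=15, t_end=400.0, seed=5)
        assert a.events == b.events

    def test_bound_safety_over_a_run(self):
        log, st = run_facetoface(n_nodes=25, t_end=800.0, seed=6)
        assert st["max_kernel_seen"] <= st["pair_bound"] * (1 + 1e-9)

    def test_contacts_respect_horizon_and_ordering(self):
        log, _ = run_facetoface(n_nodes=20, t_end=500.0, seed=7)
        for t0, t1, i, j in log.events:
            assert 0.0 <= t0 < t1 <= 500.0
            assert i != j

    def test_node_interduration_tail_is_heavy(self):
        """Empirical survival far exceeds the median-matched exponential
        deep in the tail (the burstiness signature)."""
        gaps = np.concatenate([
            interdurations(run_facetoface(n_nodes=100, t_end=3000.0,
                                          seed=s)[0], "node")
            for s in range(4)])
        med = np.median(gaps)
        emp = np.mean(gaps > 10 * med)
        assert emp > 5 * 2.0 ** -10  # matched exponential: 2^-10

    def test_exponential_activity_recovers_poisson_pairs(self):
        """Constant hazards make the node-driven loop equivalent to
        independent exponential edge clocks: with termination made
        instantaneous-ish, node interdurations are exponential with the
        nominal activity rate."""
        params = TNParams(n_nodes=8, alpha_activity=1.5, rate_activity=0.3,
                          alpha_term=1.4, rate_term=20.0)
        sim = TemporalNetworkSim(params, seed=8)
        lam = 0.3
        sim.activity = ExponentialIED(lam)
        sim.node_bound = lam
        sim.pair_bound = lam ** 2 / ((params.n_nodes - 1) * lam)
        log = sim.run(6000.0)
        gaps = interdurations(log, "node")
        assert gaps.size > 500
        assert stats.kstest(gaps, stats.expon(scale=1 / lam).cdf).pvalue > 0.01


def test_node_ied_approaches_prescribed_pareto_with_size():
    """The multiplicative kernel couples every node to the population
    average, so the marginal interduration law approaches the node's own
    Pareto as the network grows (EMD decreasing from small to moderate N)."""
    alpha, lam = 3.0, 0.5
    ied = ParetoIED.from_characteristic_rate(lam, alpha)
    emds = []
    for n in (5, 15):
        vals = []
        for s in range(3):
            log, _ = run_facetoface(n_nodes=n, t_end=1500.0,
                                    alpha_activity=alpha, rate_activity=lam,
                                    alpha_term=1.4, rate_term=3.0,
                                    seed=10 + s)
            vals.append(interevent_emd(interdurations(log, "node"), ied))
        emds.append(np.mean(vals))
    assert emds[1] < emds[0]


def test_two_node_kernel_renewal_density():
    """A single pair with synchronized clocks is a renewal process with
    hazard lam(t)^2/lam_A; the simulated gaps match that law."""
    from mosaicsim import PiecewiseHazard
    alpha, lam_a = 3.0, 0.5
    act = ParetoIED.from_characteristic_rate(lam_a, alpha)
    params = TNParams(n_nodes=2, alpha_activity=alpha, rate_activity=lam_a,
                      alpha_term=1.4, rate_term=20.0)
    sim = TemporalNetworkSim(params, seed=9)
    log = sim.run(3000.0)
    gaps = interdurations(log, "node")
    eff = PiecewiseHazard(
        lambda t: float(act.rate(t)) ** 2 / lam_a,
        bound=act.bound() ** 2 / lam_a)
    assert gaps.size > 300
    # subsample: the numeric inverse CDF is expensive per quantile
    sub = np.random.default_rng(0).choice(gaps, 300, replace=False)
    emd = interevent_emd(sub, eff)
    assert emd < 0.25 * eff.ppf(0.5)
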