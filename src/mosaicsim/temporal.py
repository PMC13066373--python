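"""Node-driven non-Markovian temporal networks.

Every node i carries a clock t_i = T - tau_i measuring the time since its
last interaction; pairwise encounters fire with a kernel rate built from
both nodes' instantaneous activity hazards,

    multiplicative:  L_ij = lam_i(t_i) * lam_j(t_j) / ((N_A - 1) * lam_A)
    additive:        L_ij = (lam_i(t_i) + lam_j(t_j)) / 2

so (multiplicatively) an encounter requires both participants to be
concurrently available.  Node activity follows a Pareto law -- hazard
alpha_A/t after t_min, monotonically decreasing -- so a constant global
bound  Lmax = (alpha_A/t_min)^2 / ((N_A - 1) * lam_A)  dominates every pair
for the whole run.  lam_A is the characteristic rate 1/t_med =
2^(-1/alpha_A)/t_min, finite even in the heavy-tailed regime alpha_A <= 1.

Edge termination is a second channel class: each active edge carries its own
Pareto clock (alpha_term, rate_term) and is removed when it fires.  Both
classes run in one thinning loop; the candidate-rate budget is
N_pairs * Lmax + n_edges * edge_bound, with pairs that already hold an
active edge proposed at rate zero (equivalent, under thinning, to excluding
them from the admissible set, and it keeps N = N_A(N_A-1)/2 constant).

Partner memory (variant "B"): after drawing node i, previous partners of i
are w >= 1 times more likely to be proposed than strangers.  The acceptance
rule is untouched -- the proposal re-weighting *is* the model change -- and
w = 1 recovers the memoryless variant "A".  For debugging, the same
preference can instead be pushed through the kernel (uniform proposals,
kernel multiplied by w for previous partners, bound inflated by w), which
simulates the same preference at roughly w times the rejection cost.

Node clocks reset on edge formation only (the clock records "time since the
last interaction"); terminations do not reset them.  Time is measured in
the resolution ticks of the contact data being emulated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .engine import BoundViolationError, ParameterError
from .hazards import ParetoIED
from .metrics import ContactLog

__all__ = [
    "TNParams", "TemporalNetworkSim", "lambda_max_tn",
    "biased_partner_selection", "run_facetoface",
]


@dataclass
class TNParams:
    n_nodes: int = 274
    alpha_activity: float = 0.76   # Pareto shape of node inter-event times
    rate_activity: float = 0.4     # characteristic (reciprocal-median) rate
    alpha_term: float = 1.4        # Pareto shape of edge lifetimes
    rate_term: float = 0.61        # characteristic rate of edge lifetimes
    w: float = 1.0                 # partner-memory weight (1 = no memory)
    kernel: str = "multiplicative"

    def __post_init__(self):
        if self.n_nodes < 2:
            raise ParameterError("need at least 2 nodes")
        if self.w < 1.0:
            raise ParameterError(f"w must be >= 1, got {self.w}")
        if self.kernel not in ("multiplicative", "additive"):
            raise ParameterError(f"unknown kernel {self.kernel!r}")


def lambda_max_tn(alpha_a: float, t_min: float, lam_a: float,
                  n_a: int) -> float:
    """Constant pair bound: (alpha_A/t_min)^2 / ((N_A - 1) * lam_A)."""
    if min(alpha_a, t_min, lam_a) <= 0 or n_a < 2:
        raise ParameterError("positive parameters and n_a >= 2 required")
    lam_max = alpha_a / t_min
    return lam_max ** 2 / ((n_a - 1) * lam_a)


def biased_partner_selection(rng: np.random.Generator, i: int,
                             partners: set, n: int, w: float) -> int:
    """Draw partner j != i; previous partners carry proposal weight w.

    Probability of a specific previous partner: w / (w*k + (n-1-k)) where
    k = |partners|; of a specific stranger: 1 / (w*k + (n-1-k)).
    """
    k = len(partners)
    if w == 1.0 or k == 0:
        j = int(rng.integers(n - 1))
        return j + 1 if j >= i else j
    total = w * k + (n - 1 - k)
    if rng.random() * total < w * k:
        return list(partners)[int(rng.integers(k))]
    while True:                      # k <= n-2 here, so this terminates
        j = int(rng.integers(n - 1))
        j = j + 1 if j >= i else j
        if j not in partners:
            return j


class TemporalNetworkSim:
    """Thinning loop over pair-formation and edge-termination channels."""

    def __init__(self, params: TNParams, seed: int,
                 preference: str = "proposal"):
        if preference not in ("proposal", "kernel"):
            raise ParameterError(f"unknown preference mode {preference!r}")
        self.p = params
        self.rng = np.random.default_rng(seed)
        self.preference = preference
        p = params
        self.activity = ParetoIED.from_characteristic_rate(
            p.rate_activity, p.alpha_activity)
        self.termination = ParetoIED.from_characteristic_rate(
            p.rate_term, p.alpha_term)
        self.node_bound = self.activity.bound()            # alpha_A / t_min
        self.pair_bound = lambda_max_tn(
            p.alpha_activity, self.activity.t_min, p.rate_activity, p.n_nodes)
        if p.kernel == "additive":
            self.pair_bound = self.node_bound
        if preference == "kernel":
            self.pair_bound *= p.w
        self.edge_bound = self.termination.bound()
        self.n_pairs = p.n_nodes * (p.n_nodes - 1) // 2

        self.T = 0.0
        self.tau = np.zeros(p.n_nodes)       # last-interaction time per node
        self.edges: list[tuple[int, int]] = []
        self.edge_start: list[float] = []
        self.edge_pos: dict[tuple[int, int], int] = {}
        self.partners: list[set] = [set() for _ in range(p.n_nodes)]
        self.contacts: list[tuple[float, float, int, int]] = []
        self.accepted = 0
        self.rejected = 0
        self.max_kernel_seen = 0.0
        self._t_end = math.inf

    # -- kernel ----------------------------------------------------------
    def node_rate(self, i: int) -> float:
        return float(self.activity.rate(self.T - self.tau[i]))

    def pair_kernel(self, i: int, j: int) -> float:
        li, lj = self.node_rate(i), self.node_rate(j)
        p = self.p
        if p.kernel == "multiplicative":
            lam = li * lj / ((p.n_nodes - 1) * p.rate_activity)
        else:
            lam = 0.5 * (li + lj)
        if self.preference == "kernel" and \
                (j in self.partners[i] or i in self.partners[j]):
            lam *= p.w
        return lam

    # -- one iteration ---------------------------------------------------
    def step(self) -> tuple | None:
        """Advance time; return ("form", i, j) / ("term", i, j) on an
        accepted event, None on a null step."""
        p = self.p
        n_e = len(self.edges)
        w_form = self.n_pairs * self.pair_bound
        w_term = n_e * self.edge_bound
        W = w_form + w_term
        self.T += self.rng.exponential(1.0 / W)
        if self.T >= self._t_end:
            # the proposal lands beyond the horizon: discard it
            return None
        if self.rng.random() * W < w_form:
            i = int(self.rng.integers(p.n_nodes))
            if self.preference == "proposal" and p.w > 1.0:
                j = biased_partner_selection(self.rng, i, self.partners[i],
                                             p.n_nodes, p.w)
            else:
                j = int(self.rng.integers(p.n_nodes - 1))
                j = j + 1 if j >= i else j
            key = (i, j) if i < j else (j, i)
            if key in self.edge_pos:
                lam = 0.0         # already interacting: inadmissible pair
            else:
                lam = self.pair_kernel(i, j)
            if lam > self.pair_bound * (1.0 + 1e-9):
                raise BoundViolationError(
                    f"pair kernel {lam} exceeds bound {self.pair_bound}")
            self.max_kernel_seen = max(self.max_kernel_seen, lam)
            if self.rng.random() * self.pair_bound < lam:
                self.accepted += 1
                self.tau[i] = self.T
                self.tau[j] = self.T
                self.edge_pos[key] = len(self.edges)
                self.edges.append(key)
                self.edge_start.append(self.T)
                self.partners[i].add(j)
                self.partners[j].add(i)
                return ("form", key[0], key[1])
        else:
            k = int(self.rng.integers(n_e))
            t_e = self.T - self.edge_start[k]
            lam = float(self.termination.rate(t_e))
            if lam > self.edge_bound * (1.0 + 1e-9):
                raise BoundViolationError(
                    f"termination hazard {lam} exceeds bound {self.edge_bound}")
            if self.rng.random() * self.edge_bound < lam:
                self.accepted += 1
                i, j = self.edges[k]
                self.contacts.append((self.edge_start[k], self.T, i, j))
                key_last = self.edges[-1]
                self.edges[k] = key_last
                self.edge_start[k] = self.edge_start[-1]
                self.edge_pos[key_last] = k
                self.edges.pop()
                self.edge_start.pop()
                del self.edge_pos[(i, j)]
                return ("term", i, j)
        self.rejected += 1
        return None

    def run(self, t_end: float) -> ContactLog:
        """Simulate until t_end; still-active edges are closed at t_end."""
        if t_end <= 0:
            raise ParameterError(f"t_end must be positive, got {t_end}")
        self._t_end = t_end
        while self.T < t_end:
            self.step()
        self.T = t_end
        for (i, j), start in zip(self.edges, self.edge_start):
            self.contacts.append((start, t_end, i, j))
        events = sorted(self.contacts)
        return ContactLog(events=events, n_nodes=self.p.n_nodes,
                          horizon=t_end)


def run_facetoface(n_nodes: int = 274, t_end: float = 7249.0,
                   alpha_activity: float = 0.76, rate_activity: float = 0.4,
                   alpha_term: float = 1.4, rate_term: float = 0.61,
                   w: float = 1.0, seed: int = 0,
                   preference: str = "proposal") -> tuple[ContactLog, dict]:
    """Face-to-face contact simulation on a fully connected population.

    Returns the contact log (start, end, i, j) plus run statistics
    (accepted / rejected counters and the largest kernel value realized,
    for bound-safety auditing).
    """
    params = TNParams(n_nodes=n_nodes, alpha_activity=alpha_activity,
                      rate_activity=rate_activity, alpha_term=alpha_term,
                      rate_term=rate_term, w=w)
    sim = TemporalNetworkSim(params, seed=seed, preference=preference)
    log = sim.run(t_end)
    stats = {"accepted": sim.accepted, "rejected": sim.rejected,
             "candidates": sim.accepted + sim.rejected,
             "max_kernel_seen": sim.max_kernel_seen,
             "pair_bound": sim.pair_bound, "edge_bound": sim.edge_bound}
    return log, stats
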