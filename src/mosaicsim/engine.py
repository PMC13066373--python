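"""Rejection-based (thinning) simulation loop over heterogeneous channels.

Each elementary stochastic process j is a channel carrying its own
inter-event-time distribution; only the timestamp tau_j of its last event is
stored, so the elapsed time is t_j = T - tau_j.  One iteration:

(i)   maintain a global dominating rate lambda_max >= max_j lambda_j(t_j);
(ii)  advance the global clock by dt = ln(1/u) / (N * lambda_max);
(iii) propose a candidate channel uniformly at random (probability 1/N);
(iv)  accept with probability lambda_j(t_j) / lambda_max, evaluated at the
      advanced time; on acceptance reset tau_j <- T and apply the model's
      state update.  A rejected iteration changes nothing but T.

Because the hazard is evaluated at the proposal time against a valid
dominating rate, the scheme is standard Lewis-Shedler/Ogata thinning and the
accepted events of each channel follow the renewal density
psi(t) = lambda(t) * exp(-int_0^t lambda) exactly; rejections only cost
compute, not accuracy.

The RNG draw order per iteration is fixed (time deviate, candidate index,
acceptance deviate) so that runs are bit-reproducible given a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Any, Callable, Optional, Sequence

import numpy as np

from .hazards import (BOUNDED, DECREASING, INCREASING, PIECEWISE, IED,
                      ExponentialIED, HazardError)

__all__ = [
    "MosaicError", "ParameterError", "EngineError", "BoundViolationError",
    "UnboundedHazardError", "DiagnosticUnavailable",
    "EventRecord", "Process", "MosaicEngine",
    "draw_time_increment", "select_candidate", "acceptance_probability",
    "update_lambda_max", "renewal_density", "run_renewal",
    "interevent_emd", "rejection_ratio",
]


class MosaicError(Exception):
    """Base class for engine errors."""


class ParameterError(MosaicError, ValueError):
    pass


class EngineError(MosaicError, RuntimeError):
    pass


class BoundViolationError(MosaicError, RuntimeError):
    """lambda_j(t_j) exceeded lambda_max: the bound is buggy.

    Never silently clipped -- clipping would bias the sampled waiting times.
    """


class UnboundedHazardError(MosaicError, ValueError):
    """A hazard whose rate decreases without bound was registered.

    No finite dominating rate exists near the origin for such families, so
    thinning would require an arbitrarily large lambda_max (bound-management
    scenario for unbounded decreasing rates).  Supply ``lambda_max``
    explicitly to override.
    """


class DiagnosticUnavailable(MosaicError, RuntimeError):
    """Too few events to compute a distributional diagnostic."""


@dataclass
class EventRecord:
    """One iteration outcome appended to the event log."""
    time: float
    channel_id: int
    kind: str
    accepted: bool
    payload: Any = None


class Process:
    """One elementary stochastic process: hazard, last-event time, payload."""

    __slots__ = ("id", "hazard", "tau", "kind", "payload", "modifier", "_idx")

    def __init__(self, id: int, hazard: IED, tau: float = 0.0,
                 kind: str = "event", payload: Any = None,
                 modifier: Optional[Callable[["MosaicEngine"], float]] = None):
        self.id = id
        self.hazard = hazard
        self.tau = tau
        self.kind = kind
        self.payload = payload
        self.modifier = modifier
        self._idx = -1  # position in the registry (swap-and-pop removal)

    def elapsed(self, T: float) -> float:
        return T - self.tau


def draw_time_increment(u: float, n: int, lambda_max: float) -> float:
    """Time to the next candidate event: ln(1/u) / (n * lambda_max)."""
    if n < 1:
        raise ParameterError(f"channel count must be >= 1, got {n}")
    if lambda_max <= 0:
        raise ParameterError(f"lambda_max must be positive, got {lambda_max}")
    if not (0.0 < u <= 1.0):
        raise ParameterError(f"u must lie in (0, 1], got {u}")
    return math.log(1.0 / u) / (n * lambda_max)


def select_candidate(channels: Sequence[Process], rng: np.random.Generator,
                     proposal: Optional[Callable] = None) -> int:
    """Uniform candidate index (probability 1/N each); ``proposal`` hook may
    replace the uniform draw (the acceptance step is then a model change)."""
    n = len(channels)
    if n == 0:
        raise EngineError("cannot select a candidate from an empty registry")
    if proposal is not None:
        return int(proposal(channels, rng))
    return int(rng.integers(n))


def acceptance_probability(rate: float, lambda_max: float,
                           rtol: float = 1e-9) -> float:
    """lambda_j(t_j)/lambda_max; a ratio above 1 is a hard error."""
    p = rate / lambda_max
    if p > 1.0 + rtol:
        raise BoundViolationError(
            f"instantaneous rate {rate} exceeds lambda_max {lambda_max}; "
            "the dominating bound is invalid")
    return min(p, 1.0)


class MosaicEngine:
    """The thinning loop over a live channel registry.

    ``lambda_max`` may be supplied explicitly (held fixed), otherwise the
    engine manages a dominating rate from each hazard family's declared
    bounding scenario:

    * bounded families contribute their fixed analytic bound (tracked as a
      multiset so removal is cheap);
    * increasing-unbounded families are dominated by the channel with the
      oldest clock, re-identified only when that channel fires (the bound
      value itself is re-evaluated each iteration at the oldest clock plus a
      short lookahead window; proposals falling beyond the window are
      discarded and the bound refreshed, which keeps thinning exact);
    * decreasing-unbounded families are refused outright;
    * piecewise/custom hazards carry their own user bound.
    """

    def __init__(self, seed: Optional[int] = None,
                 rng: Optional[np.random.Generator] = None,
                 lambda_max: Optional[float] = None,
                 proposal: Optional[Callable] = None,
                 debug_bounds: bool = False):
        self.rng = rng if rng is not None else np.random.default_rng(seed)
        self.T = 0.0
        self.channels: list[Process] = []
        self.accepted = 0
        self.rejected = 0
        self.bound_refreshes = 0
        self.user_lambda_max = lambda_max
        self.proposal = proposal
        self.debug_bounds = debug_bounds
        self._next_id = 0
        self._bound_values: dict[float, int] = {}
        self._bounded_max = 0.0
        self._increasing: list[Process] = []
        self._oldest: Optional[Process] = None

    # -- registry --------------------------------------------------------
    def add_channel(self, hazard: IED, kind: str = "event", payload: Any = None,
                    modifier: Optional[Callable] = None,
                    tau: Optional[float] = None) -> Process:
        if hazard.scenario == DECREASING and self.user_lambda_max is None:
            raise UnboundedHazardError(
                f"{hazard!r} has an unbounded, monotonically decreasing "
                "hazard; no finite lambda_max can be derived automatically. "
                "Pass lambda_max explicitly to override.")
        proc = Process(self._next_id, hazard, self.T if tau is None else tau,
                       kind, payload, modifier)
        self._next_id += 1
        proc._idx = len(self.channels)
        self.channels.append(proc)
        if self.user_lambda_max is None:
            if hazard.scenario in (BOUNDED, PIECEWISE):
                b = hazard.bound()
                self._bound_values[b] = self._bound_values.get(b, 0) + 1
                if b > self._bounded_max:
                    self._bounded_max = b
            elif hazard.scenario == INCREASING:
                self._increasing.append(proc)
                if self._oldest is None or proc.tau < self._oldest.tau:
                    self._oldest = proc
        return proc

    def remove_channel(self, proc: Process) -> None:
        idx = proc._idx
        last = self.channels[-1]
        self.channels[idx] = last
        last._idx = idx
        self.channels.pop()
        proc._idx = -1
        if self.user_lambda_max is None:
            hz = proc.hazard
            if hz.scenario in (BOUNDED, PIECEWISE):
                b = hz.bound()
                cnt = self._bound_values[b] - 1
                if cnt:
                    self._bound_values[b] = cnt
                else:
                    del self._bound_values[b]
                    if b == self._bounded_max:
                        self._bounded_max = max(self._bound_values, default=0.0)
            elif hz.scenario == INCREASING:
                self._increasing.remove(proc)
                if proc is self._oldest:
                    self._refresh_oldest()

    def _refresh_oldest(self) -> None:
        self._oldest = min(self._increasing, key=lambda p: p.tau, default=None)

    # -- rates and bounds ------------------------------------------------
    def rate(self, proc: Process) -> float:
        lam = float(proc.hazard.rate(self.T - proc.tau))
        if proc.modifier is not None:
            lam *= proc.modifier(self)
        return lam

    def true_max_rate(self) -> float:
        """Brute-force max_j lambda_j(t_j); debug/assertion use only."""
        return max((self.rate(p) for p in self.channels), default=0.0)

    def lambda_max(self, lookahead: float = 0.0) -> float:
        """Current dominating rate, valid over [T, T + lookahead]."""
        if self.user_lambda_max is not None:
            return self.user_lambda_max
        b = self._bounded_max
        if self._oldest is not None:
            t_old = self.T - self._oldest.tau + lookahead
            for p in self._increasing:
                # distinct increasing families may coexist; each is dominated
                # by its value at the globally oldest elapsed time
                b = max(b, float(p.hazard.rate(t_old)))
        if b <= 0.0:
            raise EngineError("no channel provides a positive rate bound")
        return b

    # -- the four-step iteration -----------------------------------------
    def step(self, on_fire: Optional[Callable] = None,
             t_end: float = math.inf) -> Optional[EventRecord]:
        """One iteration; returns the record, or None for a bound-refresh
        sub-step (increasing-unbounded hazards only) or for a proposal that
        lands beyond ``t_end`` (discarded before any state change)."""
        n = len(self.channels)
        if n == 0:
            raise EngineError("cannot step an engine with an empty registry")
        if self._increasing and self.user_lambda_max is None:
            # exact Ogata lookahead: the bound is only valid over a window
            guess = self.lambda_max(0.0)
            window = 4.0 / (n * guess)
            lmax = self.lambda_max(window)
            u = 1.0 - self.rng.random()
            dt = draw_time_increment(u, n, lmax)
            if dt > window:
                self.T += window
                self.bound_refreshes += 1
                return None
        else:
            lmax = self.lambda_max()
            u = 1.0 - self.rng.random()
            dt = draw_time_increment(u, n, lmax)
        self.T += dt
        if self.T >= t_end:
            return None
        j = select_candidate(self.channels, self.rng, self.proposal)
        proc = self.channels[j]
        lam = self.rate(proc)
        if self.debug_bounds and lmax < self.true_max_rate() * (1.0 - 1e-9):
            raise BoundViolationError(
                f"managed lambda_max {lmax} fell below the true maximum rate "
                f"{self.true_max_rate()}")
        p_acc = acceptance_probability(lam, lmax)
        if self.rng.random() < p_acc:
            self.accepted += 1
            was_oldest = proc is self._oldest
            proc.tau = self.T
            payload = on_fire(proc, self) if on_fire is not None else None
            if was_oldest and self._oldest is proc:
                self._refresh_oldest()
            return EventRecord(self.T, proc.id, proc.kind, True, payload)
        self.rejected += 1
        return EventRecord(self.T, proc.id, proc.kind, False, None)

    def run(self, t_end: float, on_fire: Optional[Callable] = None,
            record: bool = True,
            max_steps: Optional[int] = None) -> list[EventRecord]:
        """Advance until t_end; returns the time-ordered event log."""
        if t_end < 0:
            raise ParameterError(f"t_end must be >= 0, got {t_end}")
        log: list[EventRecord] = []
        steps = 0
        while self.T < t_end and self.channels:
            rec = self.step(on_fire, t_end=t_end)
            if self.T >= t_end:
                self.T = t_end
                break
            if record and rec is not None:
                log.append(rec)
            steps += 1
            if max_steps is not None and steps >= max_steps:
                break
        return log

    @property
    def candidates(self) -> int:
        return self.accepted + self.rejected


def update_lambda_max(engine: MosaicEngine) -> float:
    """Recompute and return the engine's current dominating rate."""
    return engine.lambda_max()


def renewal_density(hazard: IED, t):
    """psi(t) = lambda(t) * exp(-int_0^t lambda(s) ds).

    Analytic per family; custom piecewise hazards integrate by quadrature.
    """
    if np.ndim(t) == 0 and t < 0:
        raise ParameterError(f"t must be >= 0, got {t}")
    return hazard.density(t)


def run_renewal(hazard: IED, n_events: Optional[int] = None,
                t_end: Optional[float] = None, seed: Optional[int] = None,
                lambda_max: Optional[float] = None,
                rng: Optional[np.random.Generator] = None) -> dict:
    """Simulate a single renewal channel through the thinning loop.

    Returns the sampled inter-event times together with the
    accepted/rejected counters -- the basic validation harness for any IED.
    """
    eng = MosaicEngine(seed=seed, rng=rng, lambda_max=lambda_max)
    eng.add_channel(hazard, kind="renewal")
    samples: list[float] = []
    last = [0.0]

    def on_fire(proc, engine):
        samples.append(engine.T - last[0])
        last[0] = engine.T

    if n_events is not None:
        while len(samples) < n_events:
            eng.step(on_fire)
    else:
        if t_end is None:
            raise ParameterError("provide n_events or t_end")
        eng.run(t_end, on_fire, record=False)
    return {"interevent_times": np.asarray(samples),
            "accepted": eng.accepted, "rejected": eng.rejected,
            "candidates": eng.candidates, "T": eng.T}


def interevent_emd(samples: np.ndarray, hazard: IED,
                   min_events: int = 100) -> float:
    """1-D Earth Mover's Distance between an empirical inter-event-time
    sample and the analytic renewal density of ``hazard``.

    Computed as the mean absolute quantile discrepancy
    mean_i |x_(i) - ppf((i - 1/2)/n)|, the exact W1 between the empirical
    measure and the distribution discretized at matching quantiles.
    """
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    if n < min_events:
        raise DiagnosticUnavailable(
            f"need at least {min_events} events for the EMD diagnostic, "
            f"got {n}")
    q = (np.arange(1, n + 1) - 0.5) / n
    ref = np.asarray(hazard.ppf(q), dtype=float)
    return float(np.mean(np.abs(x - ref)))


def rejection_ratio(accepted: int, rejected: int) -> float:
    """Candidate iterations per accepted event, r = (acc + rej) / acc."""
    if accepted <= 0:
        raise DiagnosticUnavailable("no accepted events")
    return (accepted + rejected) / accepted
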