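"""Correctness references: direct Gillespie SSA and a delay-queue SSA.

``GillespieEngine`` runs the classic direct method over exponential channels
only, sharing the channel/event-log representation of the thinning engine so
the two can be compared distributionally on identical model definitions.

``delay_ssa_run`` implements the schedule-at-initiation strategy for the
Hes1 model: elongation completion times are drawn from the Gamma delay
distribution the moment a transcript is initiated and executed through a
priority queue.  Scheduled delays are immutable, so the method is exact only
when the delay law is state-independent (gamma = 0) -- which is precisely
what makes it the ground truth for validating the thinning engine in that
regime.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field
from typing import Any, Callable, Optional

import numpy as np

from .engine import (EngineError, EventRecord, MosaicError, ParameterError,
                     Process)
from .hazards import ExponentialIED, GammaIED, IED
from .hes1 import Hes1Params, Hes1Result

__all__ = [
    "NonExponentialChannelError", "GillespieEngine", "gillespie_run",
    "DelayQueue", "delay_ssa_run", "ensemble_mean", "rmsd_protocol",
]


class NonExponentialChannelError(MosaicError, TypeError):
    """The direct SSA only accepts constant-hazard (exponential) channels."""


class GillespieEngine:
    """Direct-method SSA over exponential channels.

    Statistically exact; same registry and log format as the thinning
    engine.  RNG order per step: time deviate, then channel-selection
    deviate.
    """

    def __init__(self, seed: Optional[int] = None,
                 rng: Optional[np.random.Generator] = None):
        self.rng = rng if rng is not None else np.random.default_rng(seed)
        self.T = 0.0
        self.channels: list[Process] = []
        self.accepted = 0
        self._next_id = 0

    def add_channel(self, hazard: IED, kind: str = "event", payload: Any = None,
                    modifier: Optional[Callable] = None) -> Process:
        if not isinstance(hazard, ExponentialIED):
            raise NonExponentialChannelError(
                f"direct Gillespie requires exponential channels, got "
                f"{type(hazard).__name__}")
        proc = Process(self._next_id, hazard, self.T, kind, payload, modifier)
        self._next_id += 1
        proc._idx = len(self.channels)
        self.channels.append(proc)
        return proc

    def remove_channel(self, proc: Process) -> None:
        idx = proc._idx
        last = self.channels[-1]
        self.channels[idx] = last
        last._idx = idx
        self.channels.pop()
        proc._idx = -1

    def _rates(self) -> np.ndarray:
        out = np.empty(len(self.channels))
        for i, p in enumerate(self.channels):
            lam = p.hazard.rate_constant
            if p.modifier is not None:
                lam *= p.modifier(self)
            out[i] = lam
        return out

    def step(self, on_fire: Optional[Callable] = None,
             t_end: float = math.inf) -> Optional[EventRecord]:
        if not self.channels:
            raise EngineError("cannot step an engine with an empty registry")
        rates = self._rates()
        total = rates.sum()
        if total <= 0:
            raise EngineError("total propensity vanished")
        self.T += self.rng.exponential(1.0 / total)
        if self.T >= t_end:
            return None
        j = int(np.searchsorted(np.cumsum(rates), self.rng.random() * total))
        proc = self.channels[j]
        proc.tau = self.T
        self.accepted += 1
        payload = on_fire(proc, self) if on_fire is not None else None
        return EventRecord(self.T, proc.id, proc.kind, True, payload)

    def run(self, t_end: float, on_fire: Optional[Callable] = None,
            record: bool = True) -> list[EventRecord]:
        if t_end < 0:
            raise ParameterError(f"t_end must be >= 0, got {t_end}")
        log: list[EventRecord] = []
        while self.T < t_end and self.channels:
            rates = self._rates()
            if rates.sum() <= 0:
                break
            rec = self.step(on_fire, t_end=t_end)
            if self.T >= t_end:
                self.T = t_end
                break
            if record and rec is not None:
                log.append(rec)
        return log


def gillespie_run(build: Callable[["GillespieEngine"], Callable],
                  t_end: float, seed: int) -> list[EventRecord]:
    """Convenience wrapper: ``build(engine)`` registers channels and returns
    the on_fire callback; the run's event log is returned."""
    eng = GillespieEngine(seed=seed)
    on_fire = build(eng)
    return eng.run(t_end, on_fire)


@dataclass(order=True)
class _Scheduled:
    time: float
    seq: int
    kind: str = field(compare=False)
    payload: Any = field(compare=False, default=None)


class DelayQueue:
    """Min-ordered queue of scheduled completions.

    Pops are non-decreasing in time; once scheduled a delay is immutable.
    """

    def __init__(self):
        self._heap: list[_Scheduled] = []
        self._seq = 0
        self._last_pop = -math.inf

    def push(self, time: float, kind: str, payload: Any = None) -> None:
        heapq.heappush(self._heap, _Scheduled(time, self._seq, kind, payload))
        self._seq += 1

    def peek_time(self) -> float:
        return self._heap[0].time if self._heap else math.inf

    def pop(self) -> _Scheduled:
        item = heapq.heappop(self._heap)
        assert item.time >= self._last_pop, "delay queue popped out of order"
        self._last_pop = item.time
        return item

    def __len__(self) -> int:
        return len(self._heap)


def delay_ssa_run(params: Hes1Params, t_end: float, seed: int,
                  record_grid: float = 1.0,
                  collect_delays: bool = False) -> Hes1Result:
    """Delay-queue SSA for the Hes1 model, exact for gamma = 0 only.

    Elongation completions are drawn from Gamma(shape alpha_elong, mean
    tau0) at initiation; the four Markovian channels run by the direct
    method in between scheduled completions.
    """
    if params.gamma != 0:
        raise ParameterError(
            "the delay-queue SSA fixes each delay at initiation and cannot "
            "express state-dependent elongation; gamma must be 0 "
            f"(got {params.gamma})")
    if t_end <= 0:
        raise ParameterError(f"t_end must be positive, got {t_end}")
    p = params
    rng = np.random.default_rng(seed)
    delay_dist = GammaIED(p.alpha_elong, 1.0 / p.tau0)

    queue = DelayQueue()
    n_n = 0
    n_m = 0
    n_p = 0
    T = 0.0
    delays: list[float] = []

    grid = np.arange(0.0, t_end + 0.5 * record_grid, record_grid)
    g_nn = np.zeros(grid.size, dtype=np.int64)
    g_nm = np.zeros(grid.size, dtype=np.int64)
    g_np = np.zeros(grid.size, dtype=np.int64)
    gi = 0
    events = 0

    while T < t_end:
        w_init = p.beta / (1.0 + (n_p / p.beta) ** p.h)
        w_tr = n_m * p.lam_trans
        w_dm = n_m * p.lam_degM
        w_dp = n_p * p.lam_degP
        W = w_init + w_tr + w_dm + w_dp
        t_next = T + rng.exponential(1.0 / W)
        if queue.peek_time() < t_next:
            item = queue.pop()
            T = item.time
            if T >= t_end:
                break
            n_n -= 1
            n_m += 1
        else:
            T = t_next
            if T >= t_end:
                break
            r = rng.random() * W
            if r < w_init:
                n_n += 1
                d = float(delay_dist.sample(1, rng)[0])
                if collect_delays:
                    delays.append(d)
                queue.push(T + d, "elongation")
            elif r < w_init + w_tr:
                n_p += 1
            elif r < w_init + w_tr + w_dm:
                n_m -= 1
            else:
                n_p -= 1
        events += 1
        while gi < grid.size and grid[gi] <= T:
            g_nn[gi] = n_n; g_nm[gi] = n_m; g_np[gi] = n_p
            gi += 1

    while gi < grid.size:
        g_nn[gi] = n_n; g_nm[gi] = n_m; g_np[gi] = n_p
        gi += 1
    return Hes1Result(grid, g_nn, g_nm, g_np, accepted=events,
                      candidates=events, mean_dt=T / max(events, 1),
                      elongation_ied=np.asarray(delays))


def ensemble_mean(results: list[Hes1Result]) -> np.ndarray:
    """Average (3, grid) species trajectories over replicates."""
    if not results:
        raise ParameterError("empty ensemble")
    return np.mean([r.species() for r in results], axis=0)


def rmsd_protocol(ensemble_a: list[Hes1Result], ensemble_b: list[Hes1Result],
                  beta: float, burn_in: float = 0.0) -> float:
    """RMSD between replicate-averaged, beta-normalized trajectories.

    Trajectories are binned on the recording grid (1-min default spacing),
    averaged over replicates, divided by beta, and compared by a pooled
    RMSD over the three species and all grid points past ``burn_in``.
    """
    a = ensemble_mean(ensemble_a) / beta
    b = ensemble_mean(ensemble_b) / beta
    keep = ensemble_a[0].times >= burn_in
    return float(np.sqrt(np.mean((a[:, keep] - b[:, keep]) ** 2)))
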