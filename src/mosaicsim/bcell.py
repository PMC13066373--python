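"""Germinal-center affinity maturation with rejection-based competition.

A population of B cells, each carrying its own receptor affinity in [0, 1],
competes for help from a small pool of interchangeable T cells through five
channels (time unit: hours):

* binding       B + T -> [BT]            rate lam_bt per (free B, free T)
* competition   [B1 T] + B2 -> [B2 T] + B1   proposed at lam_bt per
                (bound pair, free B); accepted only if the challenger's
                affinity strictly exceeds the incumbent's
* apoptosis     B -> 0                   rate lam_apop per free B (cells in
                a T-cell contact or awaiting division are protected)
* unbinding     [BT] -> B_div + T        rate lam_unbind per pair
* division      B_div -> B + B           rate lam_div; each daughter's
                affinity moves by (u - a_parent)/beta, u ~ U[0, 1]

The pairwise binding/competition processes are never enumerated: candidates
are drawn uniformly within each channel class and thinned, so the cost per
candidate is O(1) regardless of how many (B, T) pairs exist.  The
competition bound is held fixed at lam_bt for the whole run.

Affinities start at 0; clones are indexed by founder cell, and dominance is
the fraction of living B cells in the largest clonal family.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .engine import ParameterError

__all__ = [
    "GCParams", "GCResult", "competition_accept", "affinity_update",
    "dominance", "run_gc",
]

HOURS_PER_DAY = 24.0


@dataclass
class GCParams:
    beta: float = 10.0        # affinity-step scale of the division update
    lam_bt: float = 0.146     # binding / competition proposal rate [1/h]
    lam_unbind: float = 2.0   # unbinding after sufficient signal [1/h]
    lam_apop: float = 0.084   # apoptosis of unrescued free B cells [1/h]
    lam_div: float = 0.134    # division of licensed cells [1/h]

    def __post_init__(self):
        if min(self.beta, self.lam_bt, self.lam_unbind, self.lam_apop,
               self.lam_div) < 0 or self.beta <= 0:
            raise ParameterError("rates must be >= 0 and beta > 0")


@dataclass
class GCResult:
    times: np.ndarray           # recording grid [h]
    n_total: np.ndarray         # living B cells (free + bound + licensed)
    mean_affinity: np.ndarray   # population mean affinity on the grid
    dominance: np.ndarray       # largest-clone fraction on the grid
    final_affinities: np.ndarray
    clone_sizes: Counter        # founder id -> living descendants at the end
    accepted: int
    candidates: int
    extinct: bool               # all B cells died before t_end
    max_simultaneous_pairs: int = 0   # audit: never exceeds n_t
    clone_matrix: "object" = None  # optional time x clone DataFrame


def competition_accept(bound_affinity: float, challenger_affinity: float) -> bool:
    """A bound cell is displaced only by a strictly higher affinity."""
    return challenger_affinity > bound_affinity


def affinity_update(parent_affinity: float, u: float, beta: float) -> float:
    """Daughter affinity a_p + (u - a_p)/beta; stays inside [0, 1].

    The update contracts toward the uniform deviate u, so improving gets
    harder the higher the parent's affinity already is.
    """
    if not (0.0 <= parent_affinity <= 1.0):
        raise ParameterError(
            f"parent affinity must be in [0, 1], got {parent_affinity}")
    if beta <= 0:
        raise ParameterError(f"beta must be positive, got {beta}")
    return parent_affinity + (u - parent_affinity) / beta

def dominance(clone_sizes) -> float:
    """Fraction of the population inside the largest clonal family."""
    sizes = list(clone_sizes.values()) if isinstance(clone_sizes, dict) \
        else list(clone_sizes)
    total = sum(sizes)
    if total <= 0:
        raise ParameterError("dominance undefined for an empty population")
    return max(sizes) / total


class _Pool:
    """Index set with O(1) uniform sampling and swap-and-pop removal."""

    __slots__ = ("items", "pos")

    def __init__(self, items=()):
        self.items = list(items)
        self.pos = {c: i for i, c in enumerate(self.items)}

    def __len__(self):
        return len(self.items)

    def add(self, c):
        self.pos[c] = len(self.items)
        self.items.append(c)

    def remove(self, c):
        i = self.pos.pop(c)
        last = self.items[-1]
        self.items[i] = last
        self.items.pop()
        if last != c:
            self.pos[last] = i

    def sample(self, rng):
        return self.items[int(rng.random() * len(self.items))]


def run_gc(n_b: int = 1000, n_t: int = 10, t_end: float = 50 * HOURS_PER_DAY,
           seed: int = 0, params: GCParams | None = None,
           competition: bool = True, record_every: float = 12.0,
           method: str = "mosaic", clone_matrix: bool = False) -> GCResult:
    """Simulate ``t_end`` hours of affinity maturation.

    ``method="mosaic"`` uses the rejection scheme (pair channels sampled,
    never enumerated); ``method="gillespie"`` enumerates the exact
    competition propensity each step (O(n_bound * n_free) per event) as a
    correctness reference for small populations.  Both methods simulate the
    same stochastic process.

    The run ends early, flagged ``extinct``, if every B cell dies.
    """
    if n_b < 1 or n_t < 0 or t_end < 0:
        raise ParameterError("n_b >= 1, n_t >= 0 and t_end >= 0 required")
    if method not in ("mosaic", "gillespie"):
        raise ParameterError(f"unknown method {method!r}")
    p = params or GCParams()
    rng = np.random.default_rng(seed)

    aff: list[float] = [0.0] * n_b
    clone: list[int] = list(range(n_b))
    clone_count: Counter = Counter(clone)
    free = _Pool(range(n_b))
    bound: list[int] = []
    licensed = _Pool()

    grid = np.arange(0.0, t_end + 0.5 * record_every, record_every)
    g_tot = np.zeros(grid.size, dtype=np.int64)
    g_aff = np.zeros(grid.size)
    g_dom = np.zeros(grid.size)
    snapshots: list[Counter] = [] if clone_matrix else None
    gi = 0
    aff_sum = 0.0                     # running sum over living cells
    T = 0.0
    candidates = 0
    accepted = 0
    extinct = False
    max_pairs = 0
    uni = rng.random
    exp = rng.exponential

    def record_until(t_now):
        nonlocal gi
        n_alive = len(free) + len(bound) + len(licensed)
        while gi < grid.size and grid[gi] <= t_now:
            g_tot[gi] = n_alive
            g_aff[gi] = aff_sum / n_alive if n_alive else math.nan
            g_dom[gi] = (max(clone_count.values()) / n_alive) if n_alive \
                else math.nan
            if snapshots is not None:
                snapshots.append(Counter(clone_count))
            gi += 1

    def kill(c):
        nonlocal aff_sum
        aff_sum -= aff[c]
        clone_count[clone[c]] -= 1
        if clone_count[clone[c]] == 0:
            del clone_count[clone[c]]

    def birth(parent):
        nonlocal aff_sum
        ap = aff[parent]
        c = len(aff)
        a = affinity_update(ap, uni(), p.beta)
        aff.append(a)
        clone.append(clone[parent])
        clone_count[clone[parent]] += 1
        aff_sum += a
        free.add(c)

    while True:
        n_f, n_bd, n_lc = len(free), len(bound), len(licensed)
        if n_f + n_bd + n_lc == 0:
            extinct = True
            break
        n_tf = n_t - n_bd
        w_bind = p.lam_bt * n_f * n_tf
        if method == "mosaic":
            w_comp = p.lam_bt * n_bd * n_f if competition else 0.0
        else:
            # exact enumeration: only strictly-better challengers count
            valid = [sum(1 for c in free.items if aff[c] > aff[b])
                     for b in bound] if competition else []
            w_comp = p.lam_bt * sum(valid)
        w_apop = p.lam_apop * n_f
        w_unb = p.lam_unbind * n_bd
        w_div = p.lam_div * n_lc
        W = w_bind + w_comp + w_apop + w_unb + w_div
        if W <= 0:
            break
        T += exp(1.0 / W)
        if T >= t_end:
            break
        record_until(T)
        candidates += 1
        r = uni() * W
        if r < w_bind:
            c = free.sample(rng)
            free.remove(c)
            bound.append(c)
            max_pairs = max(max_pairs, len(bound))
            accepted += 1
        elif r < w_bind + w_comp:
            if method == "mosaic":
                bi = int(uni() * n_bd)
                ch = free.sample(rng)
                if competition_accept(aff[bound[bi]], aff[ch]):
                    incumbent = bound[bi]
                    free.remove(ch)
                    bound[bi] = ch
                    free.add(incumbent)   # displaced cell rejoins the free pool
                    accepted += 1
                # else: null step, nothing but T changed
            else:
                x = uni() * sum(valid)
                acc_v = 0.0
                for bi, v in enumerate(valid):
                    acc_v += v
                    if x < acc_v:
                        break
                better = [c for c in free.items if aff[c] > aff[bound[bi]]]
                ch = better[int(uni() * len(better))]
                incumbent = bound[bi]
                free.remove(ch)
                bound[bi] = ch
                free.add(incumbent)
                accepted += 1
        elif r < w_bind + w_comp + w_apop:
            c = free.sample(rng)
            free.remove(c)
            kill(c)
            accepted += 1
        elif r < w_bind + w_comp + w_apop + w_unb:
            bi = int(uni() * n_bd)
            c = bound[bi]
            bound[bi] = bound[-1]
            bound.pop()
            licensed.add(c)
            accepted += 1
        else:
            parent = licensed.sample(rng)
            licensed.remove(parent)
            kill(parent)           # the parent slot is replaced by daughters
            birth(parent)
            birth(parent)
            accepted += 1

    record_until(t_end + record_every)
    alive = free.items + bound + licensed.items
    final_aff = np.array([aff[c] for c in alive])
    matrix = None
    if clone_matrix:
        import pandas as pd
        matrix = pd.DataFrame(snapshots, index=grid[:len(snapshots)]).fillna(0)
        matrix.index.name = "time_h"
    return GCResult(grid, g_tot, g_aff, g_dom, final_aff,
                    Counter(clone_count), accepted, candidates, extinct,
                    max_pairs, matrix)
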