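"""Hes1 transcription/translation with delayed negative feedback.

Three species -- nascent RNA (N_N, one elongation clock per molecule),
mature mRNA (N_M) and protein (N_P) -- coupled by five channels:

* initiation   0 -> N        rate beta * G(N_P), Hill repression by protein
* elongation   N -> M        Gamma(shape alpha_elong, mean 1/lambda_0)
                             waiting time per molecule; lambda_0 shrinks as
                             transcripts accumulate (resource limitation)
* translation  M -> M + P    rate lambda_trans per mRNA
* mRNA decay   M -> 0        rate lambda_degM
* protein decay P -> 0       rate lambda_degP

The elongation hazard is re-evaluated at every proposal with the *current*
lambda_0 and the molecule's own elapsed clock (instantaneous-rate
semantics), which is exactly the state-dependent delay that
schedule-at-initiation delay queues cannot express.

Time unit: minutes.  All rate constants default to the reference
parameterization (tau_0 = 20 min, h = 4.1, lambda_trans = 0.01/min,
lambda_degM = 0.029/min, lambda_degP = 0.031/min).

The simulation uses the grouped form of the thinning loop: channels with a
common per-channel bound are proposed as a block (group weight = count *
bound) and the member drawn uniformly, which is statistically identical to
uniform selection under a global bound but keeps the candidate budget -- and
hence the rejection factor r -- independent of the system-size parameter
beta.  Exponential channels are their own bound, so only elongation
proposals can be rejected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal, special

from .engine import ParameterError
from .hazards import GammaIED, gamma_hazard

__all__ = [
    "Hes1Params", "Hes1Result", "hill_repression", "resource_limited_rate",
    "elongation_hazard", "strict_bound", "run_hes1", "oscillation_period",
]


@dataclass
class Hes1Params:
    beta: float = 100.0          # system-size / repression scale
    gamma: float = 0.0           # resource sensitivity (0 = unconstrained)
    h: float = 4.1               # Hill coefficient of the repression
    tau0: float = 20.0           # baseline mean elongation delay [min]
    alpha_elong: float = 3.0     # Gamma shape of the elongation time
    lam_trans: float = 0.01      # translation rate [1/min]
    lam_degM: float = 0.029      # mRNA degradation rate [1/min]
    lam_degP: float = 0.031      # protein degradation rate [1/min]
    strict: bool = False         # enforce the small-system time-step bound

    def __post_init__(self):
        if self.beta <= 0 or self.gamma < 0 or self.tau0 <= 0:
            raise ParameterError("beta > 0, gamma >= 0 and tau0 > 0 required")


@dataclass
class Hes1Result:
    times: np.ndarray            # recording grid [min]
    n_nascent: np.ndarray
    n_mrna: np.ndarray
    n_protein: np.ndarray
    accepted: int
    candidates: int
    mean_dt: float               # average candidate time step E[dt]
    elongation_ied: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def rejection_factor(self) -> float:
        return self.candidates / self.accepted

    def species(self) -> np.ndarray:
        """(3, grid) array in the order nascent, mRNA, protein."""
        return np.vstack([self.n_nascent, self.n_mrna, self.n_protein])


def hill_repression(n_p: float, beta: float, h: float = 4.1) -> float:
    """G(N_P) = 1 / (1 + (N_P/beta)^h), in (0, 1]."""
    if n_p < 0 or beta <= 0:
        raise ParameterError("n_p >= 0 and beta > 0 required")
    return 1.0 / (1.0 + (n_p / beta) ** h)


def resource_limited_rate(n_n: float, n_m: float, beta: float, gamma: float,
                          tau0: float = 20.0) -> float:
    """lambda_0 = tau0^-1 * (1 + gamma*(N_N + N_M)/beta)^-1.

    gamma = 0 recovers the constant baseline 1/tau0; gamma > 0 slows every
    nascent molecule's elongation instantaneously as transcripts pile up.
    """
    if n_n < 0 or n_m < 0:
        raise ParameterError("molecule counts must be non-negative")
    return (1.0 / tau0) / (1.0 + gamma * (n_n + n_m) / beta)


def elongation_hazard(t: float, lam0: float, alpha_elong: float = 3.0) -> float:
    """Gamma elongation hazard, bounded above by alpha_elong * lam0."""
    return gamma_hazard(t, alpha_elong, alpha_elong * lam0)


def strict_bound(n: int, lam0: float, alpha_elong: float = 3.0) -> float:
    """Per-channel elongation bound inflated so n * bound >= 20 * lam0.

    For small systems this caps the expected candidate time step at
    1/(20*lam0); for large n the plateau alpha_elong*lam0 already suffices
    and the bound is left unchanged.
    """
    if n < 1:
        raise ParameterError(f"n must be >= 1, got {n}")
    return max(alpha_elong * lam0, 20.0 * lam0 / n)


def run_hes1(params: Hes1Params, t_end: float, seed: int,
             record_grid: float = 1.0,
             collect_elongation: bool = False) -> Hes1Result:
    """Simulate the feedback loop from the empty state (all counts zero).

    Trajectories are sampled on a fixed grid of spacing ``record_grid``
    minutes (last-value interpolation between events).
    """
    if t_end <= 0:
        raise ParameterError(f"t_end must be positive, got {t_end}")
    p = params
    rng = np.random.default_rng(seed)
    alpha = p.alpha_elong
    lgam = special.gammaln(alpha)

    taus: list[float] = []       # initiation timestamp per nascent molecule
    n_m = 0
    n_p = 0
    T = 0.0
    candidates = 0
    accepted = 0
    elong_samples: list[float] = []

    grid = np.arange(0.0, t_end + 0.5 * record_grid, record_grid)
    g_nn = np.zeros(grid.size, dtype=np.int64)
    g_nm = np.zeros(grid.size, dtype=np.int64)
    g_np = np.zeros(grid.size, dtype=np.int64)
    gi = 0

    exp = rng.exponential
    uni = rng.random
    while True:
        n_n = len(taus)
        lam0 = (1.0 / p.tau0) / (1.0 + p.gamma * (n_n + n_m) / p.beta)
        b_el = strict_bound(max(1 + n_n + n_m + n_p, 1), lam0, alpha) \
            if p.strict else alpha * lam0
        w_init = p.beta / (1.0 + (n_p / p.beta) ** p.h)
        w_el = n_n * b_el
        w_tr = n_m * p.lam_trans
        w_dm = n_m * p.lam_degM
        w_dp = n_p * p.lam_degP
        W = w_init + w_el + w_tr + w_dm + w_dp
        ghost = 0.0
        if p.strict and W < 20.0 * lam0:
            # conservative floor on the candidate rate: E[dt] <= 1/(20*lam0)
            ghost = 20.0 * lam0 - W
            W += ghost
        T += exp(1.0 / W)
        if T >= t_end:
            break
        while gi < grid.size and grid[gi] <= T:
            g_nn[gi] = n_n; g_nm[gi] = n_m; g_np[gi] = n_p
            gi += 1
        candidates += 1
        r = uni() * W
        if r < w_init:
            taus.append(T)
            accepted += 1
        elif r < w_init + w_el:
            k = int(uni() * n_n)
            t_el = T - taus[k]
            rate = alpha * lam0
            x = rate * t_el
            if t_el <= 0.0:
                lam = 0.0
            elif x > 500.0:     # survival underflow: asymptotic hazard ratio
                lam = rate / (1.0 + (alpha - 1.0) / x
                              + (alpha - 1.0) * (alpha - 2.0) / (x * x))
            else:
                loglam = alpha * math.log(rate) \
                    + (alpha - 1.0) * math.log(t_el) - x - lgam \
                    - math.log(special.gammaincc(alpha, x))
                lam = math.exp(loglam)
            if uni() < lam / b_el:
                if collect_elongation:
                    elong_samples.append(t_el)
                taus[k] = taus[-1]
                taus.pop()
                n_m += 1
                accepted += 1
        elif r < w_init + w_el + w_tr:
            n_p += 1
            accepted += 1
        elif r < w_init + w_el + w_tr + w_dm:
            n_m -= 1
            accepted += 1
        elif r < w_init + w_el + w_tr + w_dm + w_dp:
            n_p -= 1
            accepted += 1
        # else: ghost candidate of the strict-bound floor -- null step

    while gi < grid.size:
        g_nn[gi] = len(taus); g_nm[gi] = n_m; g_np[gi] = n_p
        gi += 1
    return Hes1Result(grid, g_nn, g_nm, g_np, accepted, candidates,
                      mean_dt=T / max(candidates, 1),
                      elongation_ied=np.asarray(elong_samples))


def oscillation_period(times: np.ndarray, traj: np.ndarray,
                       burn_in: float = 500.0,
                       smooth_window: int = 41) -> float:
    """Mean peak-to-peak spacing of a (replicate-averaged) trajectory.

    The trajectory is smoothed with a moving average before peak detection;
    the burn-in transient is discarded.  Returns NaN when fewer than two
    peaks survive.
    """
    keep = times >= burn_in
    t = np.asarray(times)[keep]
    y = np.asarray(traj, dtype=float)[keep]
    if y.size < smooth_window + 2:
        return math.nan
    kernel = np.ones(smooth_window) / smooth_window
    ys = np.convolve(y, kernel, mode="same")
    span = ys.max() - ys.min()
    if span <= 0:
        return math.nan
    peaks, _ = signal.find_peaks(ys, prominence=0.1 * span,
                                 distance=smooth_window)
    if peaks.size < 2:
        return math.nan
    return float(np.mean(np.diff(t[peaks])))
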