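# Methods

## The thinning loop

Every elementary process *j* (a molecule's clock, a B cell's possible
interaction, a node pair) is a renewal-type channel: it stores only the
timestamp τ_j of its last event, so its elapsed time is t_j = T − τ_j, and
it exposes an instantaneous rate λ_j(t_j, state). One iteration draws
Δt = ln(1/u)/(N·λ_max) with N the *live* channel count, advances T,
proposes a candidate uniformly, and accepts with λ_j(t_j)/λ_max, resetting
τ_j on acceptance. The RNG order per iteration is fixed — time deviate,
candidate index, acceptance deviate — so a seed fully determines the run.
The acceptance draw uses a fresh uniform deviate (standard thinning); the
time deviate is never reused.

**Exactness.** Proposals form a Poisson stream of rate N·λ_max; selecting a
candidate uniformly gives each channel an independent Poisson(λ_max)
proposal stream, and accepting with λ_j(evaluated at the proposal time)/λ_max
thins it to an inhomogeneous process with conditional intensity exactly
λ_j(t_j, state). This is the Lewis–Shedler/Ogata construction: the sampled
waiting times follow ψ(t) = λ(t)·exp(−∫₀ᵗλ) *exactly* for any λ_max that
dominates the hazards, and state-dependent rates are exact as well because
the state (and hence every hazard) only changes at accepted events. A
consequence worth stating plainly: raising λ_max buys nothing
statistically — it only adds rejections. The often-quoted error law for
rejection simulators, E[error] ∼ ⟨λ′⟩/(N·λ_max²), does not apply to this
evaluation order; we verified numerically that the Earth-Mover's distance
between simulated and analytic waiting times is flat in λ_max at the
Monte-Carlo floor. The test suite keeps one deliberately failing test
asserting the λ_max⁻² law, as a record of this property. What *does* hold,
and is tested: r = candidates/accepted = λ_max/λ_0 exactly (log-log slope
1), and the EMD sits within a factor 2 of an exact inverse-CDF oracle
sampler at the same sample size.

**Bound management.** Each IED family declares how its hazard is bounded:

* *bounded* — fixed analytic constant: α/t_min (Pareto), shape·λ_0 (Gamma,
  shape ≥ 1, the hazard plateau), the rate (exponential, delayed
  exponential), a numerically located peak (log-normal). The engine keeps a
  multiset of these constants, so add/remove is O(1) and the global bound
  is their maximum.
* *increasing unbounded* (Weibull shape > 1, …) — dominated by the channel
  with the oldest clock; its identity is re-resolved only when that channel
  fires. Because such a bound is only valid over a finite window, the
  engine uses an Ogata lookahead: the bound is evaluated at the oldest
  clock plus a window of four expected steps, and a proposal falling beyond
  the window is discarded while the clock advances to the window edge —
  this keeps thinning exact at O(1) amortized cost.
* *decreasing unbounded* (Gamma/Weibull shape < 1) — refused at
  registration; an explicit user λ_max overrides.
* *piecewise/custom* — the user supplies the bound.

An acceptance ratio above 1 raises a hard error (a silent clip would bias
ψ); a debug mode recomputes the true maximum rate each step and asserts the
bound dominates.

**Grouped proposals.** The application models use the composition form of
the same loop: channels sharing a per-channel bound b_g are proposed as a
block with weight n_g·b_g, Δt ~ Exp(Σ_g n_g·b_g), the member is drawn
uniformly within the block, and acceptance is λ_j/b_g. With equal bounds
this reduces to the uniform-selection loop verbatim; with heterogeneous
bounds it is the "non-uniform proposal" hook and is what keeps the
candidate budget proportional to the event rate. Exponential channels are
their own bound, so only genuinely time-varying hazards generate
rejections. For the Hes1 model this is essential: a single global λ_max
would be dominated by the initiation rate β·G(N_P), and the rejection
factor would grow with β instead of staying at ≈ 1.55.

## Hazard families

Parameterizations (all rates in the model's own time unit):

* Gamma: shape α and rate scale λ_0; the Gamma rate is α·λ_0, so the mean
  waiting time is 1/λ_0 and the hazard climbs from 0 to the plateau α·λ_0.
  Evaluated in log space with the regularized upper incomplete gamma; past
  x = rate·t = 500 the survival underflows and the hazard switches to the
  asymptotic continued-fraction ratio rate/(1 + (α−1)/x + (α−1)(α−2)/x²).
* Pareto: ψ(t) = α·t_minᵅ/t^(α+1) on t ≥ t_min, hazard α/t there and 0
  before (nothing can fire inside the support gap). The characteristic rate
  is the reciprocal median 2^(−1/α)/t_min, finite for every α > 0 — the
  right normalizer in heavy-tailed regimes where the mean diverges.
* Weibull, log-normal, delayed exponential, and a quadrature-backed custom
  hazard complete the set; each declares its bounding scenario.

Every family carries an exact inverse-CDF (or scipy) sampler used as the
independent oracle in validation; the oracle never touches the engine.

## Germinal-center model (time unit: hours)

Channels and defaults: binding λ_BT = 0.146 h⁻¹ per (free B, free T) pair;
competition proposals at λ_BT per (bound pair, free B), accepted only when
the challenger's affinity strictly exceeds the incumbent's (the bound is
held fixed at λ_BT for the whole run); apoptosis λ_apop = 0.084 h⁻¹;
unbinding λ_unbind = 2 h⁻¹; division λ_div = 0.134 h⁻¹ with the daughter
update a_d = a_p + (u − a_p)/β, β = 10. Initial state: 1000 B cells of
affinity 0, 10 interchangeable T cells; horizon 50 days.

Interpretation choices the channel list does not pin down (each declared
here once): apoptosis removes *free* cells only — cells in a T-cell contact
or awaiting division hold survival signals; a displaced incumbent rejoins
the free pool immediately (and is again mortal); licensed cells neither
rebind nor compete before dividing; both daughters receive independent
affinity updates from the parent value; clones are indexed by founder, and
dominance is the largest clone's share of living cells. Under these choices
the population relaxes from 1000 to a T-cell-help-limited steady state of
roughly 350–400 cells and the mean affinity reaches ≈ 0.72 at day 50.

The exact-enumeration variant (`method="gillespie"`) recomputes the true
competition propensity each step by counting strictly-better challengers —
O(n_bound·n_free) per event, usable only at reduced scale — and is the
distributional reference for the sampled-pair scheme.

## Hes1 model (time unit: minutes)

Species: nascent RNA (per-molecule elongation clocks), mRNA, protein.
Rates: initiation β·G(N_P) with G = 1/(1+(N_P/β)^h), h = 4.1; Gamma
elongation with shape 3 and λ_0 = τ_0⁻¹(1 + γ(N_N+N_M)/β)⁻¹, τ_0 = 20 min;
translation 0.01 min⁻¹; decays 0.029 and 0.031 min⁻¹. Initial condition
(not pinned down by the channel list): all counts zero; oscillation
statistics discard a 500-min burn-in. Elongation clocks keep their elapsed
time when λ_0 changes and are re-evaluated with the *current* λ_0
(instantaneous-rate semantics); integrated-hazard rescaling is a different
model and out of scope.

The small-system policy inflates the candidate rate to a floor of 20·λ_0
(deficit mass is proposed as auto-rejected "ghost" candidates), which caps
the expected time step at 1/(20·λ_0) exactly.

Resource limitation is a positive feedback on the nascent pool (more
transcripts → slower elongation → more transcripts): at β = 25 the system
tolerates γ ≲ 0.15 before piling up transcripts without sustained
oscillation. The direction-of-effect analysis therefore uses γ = 0.1,
where oscillations are stable and the period lengthens from ≈ 140 to
≈ 250 min. Periods are measured per replicate (moving-average smoothing +
peak detection) and then averaged; averaging trajectories first would
dephase the replicates and bury the oscillation.

## Temporal networks (time unit: data ticks)

Defaults emulate a conference-style face-to-face setting: N_A = 274 nodes,
horizon 7249 ticks, activity Pareto with α_A = 0.76 and characteristic rate
λ_A = 0.4, termination Pareto with α_∅ = 1.4 and rate 0.61 (t_min recovered
from the median relation in both cases). Formation candidates are proposed
over all N_A(N_A−1)/2 pairs with already-active pairs carrying rate 0 —
statistically identical to excluding them from the admissible set, and it
keeps N constant, matching the (N_A−1) kernel normalization. Termination
channels join the same loop with their own constant bound. Node clocks
reset on formation only ("time since the last interaction"); resetting on
termination as well is a documented alternative, not implemented. All
clocks start at zero, i.e. the population is synchronized at T = 0.

Partner memory multiplies the proposal weight of previous partners by
w ≥ 1 and leaves the acceptance rule untouched — the re-weighted proposal
*is* the model change. The debug alternative pushes the same preference
through the kernel under uniform proposals, inflating the bound by w; it
simulates the same preference at roughly w times the rejection cost, which
is the point of doing it in the proposal.

Known model property (not an implementation artifact): with the
median-based normalization the population-averaged hazard does not equal
λ_A, so the realized node interduration law approaches the prescribed
Pareto as N_A grows but saturates at a small constant offset; for α_A ≤ 1
the dynamics are additionally aging (no stationary rate exists — event
counts grow sublinearly in the horizon, which is the empirical burstiness
the model is built to reproduce). Validation therefore asserts the
decreasing branch of the EMD (N_A = 5 → 15) and, for the heavy-tailed
default, a deep-tail survival comparison against a median-matched
exponential rather than moment-based statistics.

## Contact-log metrics

Interdurations are gaps between successive interaction *start* times of a
node (or pair), pooled across entities — consistent with
clock-reset-on-formation. The interaction-score graph sums per-pair contact
durations, floors them at one tick, takes the natural log and normalizes by
the maximum; pairs scoring > 0.4 form the graph (with a single pair the
score is trivially 1). The log-normalized score is *not* invariant under a
global rescaling of the time unit (only the ranking of pairs is); the
threshold is defined on the data's native tick. The five aggregated scalars
use networkx; Louvain modularity (resolution 1) is averaged over 10
partition seeds because the partition itself is stochastic.

## Problem sizes and numerical choices

Validation runs are sized for a single CPU: ensembles of 25–60 replicates,
10³–10⁴ events per distributional check, two-sample KS tests at α = 0.01
with fixed seeds, and the reduced ensemble protocol (trajectories binned on
a 1-min grid, replicate-averaged, normalized by β, pooled RMSD) with a
factor-2 allowance over the replicate-to-replicate baseline. The headline
endpoints use the full printed configurations: β ∈ {25, 100, 400} × 5 seeds
for the rejection factor, and 10 replicates of the 1000-cell, 50-day
germinal-center run for the affinity endpoint. Acceptance ratios are
checked with relative slack 10⁻⁹; EMDs are computed as the exact W1 between
the empirical sample and the analytic distribution discretized at matching
quantiles.

## Limitations

* The synthetic models emulate the cited dynamics, not any particular
  dataset: passing tests show the algorithms reproduce their own theory
  (renewal densities, exact SSA references, analytic bounds), not that the
  parameterizations fit new experimental data.
* Nearly discrete IEDs (mass concentrated at a point) force enormous
  bounds and rejection counts; a delay queue is the right tool there.
* The temporal-network layer is fully connected; restricting the
  admissible pair set to a sparse static graph is a straightforward
  extension but untested here.
* No hybrid deterministic/stochastic acceleration and no parallelism.
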