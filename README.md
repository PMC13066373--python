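# mosaicsim

Rejection-based (thinning) stochastic simulation for populations of
heterogeneous agents whose waiting times are **not** exponential and whose
rates may depend on individual traits and on the evolving system state.

The classical Gillespie stochastic simulation algorithm (SSA) is exact for
Markovian reaction networks, but it collapses identical particles into
channels with exponential clocks and pays O(N) per event once every agent or
pair needs its own propensity. This package implements the complementary
idea: every elementary process *j* keeps only the timestamp τ_j of its last
event and an inter-event-time distribution (IED) ψ_j with hazard
λ_j(t) = ψ_j(t)/(1 − F_j(t)), and one dominating rate λ_max replaces all
per-channel bookkeeping. Each iteration

1. maintains λ_max ≥ max_j λ_j(t_j) (per-family bounding rules: fixed
   analytic bounds for Pareto/Gamma-shape>1/log-normal/delayed-exponential,
   oldest-clock tracking for increasing unbounded hazards, refusal for
   decreasing unbounded ones),
2. advances the global clock by Δt = ln(1/u)/(N·λ_max),
3. proposes a candidate process uniformly (p_j = 1/N), and
4. accepts it with probability λ_j(t_j)/λ_max, evaluated at the advanced
   time; on acceptance τ_j ← T and the model's state update runs.

Because the hazard is evaluated at the proposal time against a valid bound,
this is standard Lewis–Shedler/Ogata thinning: accepted events of each
channel follow the renewal density ψ(t) = λ(t)·exp(−∫₀ᵗλ) exactly, and the
cost per candidate is O(1) — rejections cost compute, never accuracy. The
expected number of candidates per accepted event is r ∝ λ_max/λ_0, with λ_0
the mean event rate.

Three reference applications ship with the engine:

* **Germinal-center affinity maturation** (`mosaicsim.bcell`) — 1000 B cells
  with per-cell receptor affinities compete for 10 T cells through binding,
  displacement (accepted only for strictly higher affinity), apoptosis,
  unbinding and division with the affinity update Δ_aff = (u − a_parent)/β.
  Pair channels are sampled and thinned, never enumerated.
* **Hes1 delayed negative feedback** (`mosaicsim.hes1`) — Hill-repressed
  transcription initiation, per-molecule Gamma elongation clocks whose rate
  λ_0 = τ_0⁻¹(1 + γ(N_N+N_M)/β)⁻¹ responds instantaneously to transcript
  load (the state-dependent delay a schedule-at-initiation delay queue
  cannot express), translation and two exponential decays.
* **Non-Markovian temporal networks** (`mosaicsim.temporal`) — node-driven
  face-to-face contacts: each node carries a Pareto activity clock, pairs
  fire with the multiplicative kernel Λ_ij = λ_i(t_i)λ_j(t_j)/((N_A−1)λ_A),
  edges terminate by their own Pareto process, and partner memory (weight
  *w* for previous partners) enters through the proposal distribution.

Correctness references (`mosaicsim.baselines`) include a direct-method SSA
for exponential models and a delay-queue SSA that is exact for the Hes1
model at γ = 0, plus contact-log statistics and the interaction-score graph
pipeline (`mosaicsim.metrics`).

## Worked example

Push a single Gamma elongation channel (shape 3, mean 1/λ_0 = 20 min)
through the engine and compare against theory:

```
$ mosaic validate-ied --family gamma --shape 3 --rate 0.05 --n 20000 --seed 1
{
  "family": "gamma",
  "n_events": 20000,
  "sample_mean": 20.052218190134138,
  "sample_median": 17.856128359933564,
  "analytic_median": 17.827068758157058,
  "emd_vs_analytic": 0.0739263960590426,
  "rejection_factor": 3.0161
}
```

The simulated mean waiting time reproduces the 20-minute Gamma mean, the
Earth-Mover's distance to the analytic density is at the finite-sample
floor, and the rejection factor equals λ_max/λ_0 = (3·0.05)/0.05 = 3 as
predicted. The same models are scriptable from Python:

```python
from mosaicsim import Hes1Params, run_gc, run_hes1

gc = run_gc(n_b=1000, n_t=10, t_end=1200.0, seed=0)   # 50 days, hours
print(gc.mean_affinity[-1], gc.dominance[-1])          # 0.7229  0.7372

hes = run_hes1(Hes1Params(beta=100.0), t_end=2000.0, seed=0)
print(hes.rejection_factor)                            # 1.5517
```

Mean receptor affinity climbs from 0 to ≈ 0.72 after 50 days while in this
replicate the largest clone has taken over ≈ 74 % of the population, and
the Hes1 model's candidate-per-event ratio sits at ≈ 1.55 independent of
system size.

Model runs are also available from the shell, driven by a YAML config:

```
mosaic run --model hes1 --config hes1.yaml --seed 3 --out out/
mosaic metrics --contacts out/contacts.tsv
```

Every run writes a `manifest.json` (config, seed, package version)
sufficient to reproduce its outputs.

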