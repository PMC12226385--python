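# Methods

## Model

`cprnet` simulates `P` agents who repeatedly choose between low-effort
(`S_i = 1`) and high-effort (`S_i = 0`) extraction from a shared renewable
resource.  The resource state `n ∈ [0, 1]` follows

    n_t = n_{t-1} + (ε/P)(z_t − n_{t-1}),

where `z_t = Σ_i S_i W_i` is the impact-weighted low-effort share and
`W_i ∝ d_i^ν` are normalized degree-powered impact weights.  Dividing the
environmental rate by `P` puts the resource on the *generation* timescale:
`P` scheduler steps give each agent one expected action and close a fraction
`ε` of the gap between `n` and `z`.

Payoffs are affine in both the resource state and the low-effort share.  All
three parameterizations (matrix corners, corner incentives, affine surfaces)
are implemented with exact conversions in `payoff_model`; the advantage of
low effort is the bilinear form

    π_L − π_H = (1−n)(δ_L^0 z + δ_H^0 (1−z)) − n(Δ_L^1 z + Δ_H^1 (1−z)).

With the default incentives (δ_H^0 = 0.3, δ_L^0 = 0.05, Δ_L^1 = 0.7,
Δ_H^1 = 0.45) this reduces to `0.3 − 0.25 z − 0.75 n`.  The
**full-information equilibrium** (FIE) solves `π_L − π_H = 0` jointly with
the resource fixed point `n = z`; a quadratic in `n` solved in closed form,
selecting the root where the advantage is decreasing (the stabilizing one
under anti-coordination feedback).  The defaults give `n* = 0.3` exactly.

**Sign of δ_H^0.**  The default configuration requires a positive incentive
toward low effort in a fully depleted environment (`S0 − P0 > 0`); with
δ_H^0 = −0.3 the advantage is strictly negative on the whole state space and
no interior equilibrium exists, while +0.3 makes all four corner incentives
positive and yields the interior, stable FIE at 0.3.  The negative variant
remains available via `default_incentives(as_printed=True)` for exploring
the no-equilibrium regime.

**Gauge.**  Corner incentives determine payoff levels only up to constants
that never enter the advantage; `corners_from_incentives` fixes the
high-effort payoffs of the degraded matrix and the low-effort payoffs of the
prosperous matrix to zero, so the four remaining corners equal the
incentives directly.

## Schedule

Each global step: (1) one agent is drawn uniformly (probability `1/P`,
independent of history); (2) it takes a ledger snapshot, updates the fitness
of all four forecasting rules against it, re-draws its rule from the
inertia/softmax distribution, forecasts `z^e`, evaluates the high-effort
advantage at its own perceived resource state `n̂_i`, and draws its strategy
from the degree-sharpened logistic; (3) `z` is updated; (4) the resource
moves one step; (5) *every* agent's perception relaxes toward its current
local observation at rate `ε/P`.  Strategy changes are visible to neighbors
immediately (the ledger is a live view; a neighbor reading it at its own
next action sees the updated strategy).

## Observation

An agent's local observation is the impact-weighted low-effort share among
its neighbors:

    s_i = Σ_{j∈N(i)} S_j d_j^ν / Σ_{j∈N(i)} d_j^ν,

the neighborhood estimate of the *effective* extraction level `z` — the
quantity that actually drives the environment and that the forecasting rules
try to predict.  At `ν = 0` this is exactly the unweighted fraction of
low-effort neighbors, so the homogeneous-impact results do not depend on
this choice.  At `ν > 0` it is what makes impact inequality informative:
because high-degree agents are overrepresented in neighborhoods *and* carry
most of the impact, local estimates of `z` become more accurate as `ν`
grows, and the simulated outcomes collapse onto the FIE at high `ν` (the
impact-sweep test).  We verified the alternative (unweighted observation
throughout) and it behaves pathologically at high `ν`: hubs then track the
strategies of their impactless neighbors, never the true state, and the
system locks at `n ≈ 0` or `n ≈ 1` instead of the FIE.

The agent itself is excluded from its snapshot; graphs with isolated nodes
are rejected at initialization since such an agent could never observe
anyone.

## Expectation formation

Four forecasting rules over the agent's own snapshot history (lags index the
agent's successive *action events*, since snapshots are only taken when the
agent acts):

1. adaptive: `z^e = β1 z_{t-1} + (1−β1) z^e_prev` (its own previous
   forecast; a two-lag variant is available via
   `HsmParams.adaptive_two_lag`),
2. trend-chasing: `z^e = z_{t-1} + β2 (z_{t-1} − z_{t-2})`,
3. contrarian: same with β3 < 0,
4. anchoring: `z^e = 0.5 (z_ave + z_{t-1}) + (z_{t-1} − z_{t-2})`.

All four fitnesses are updated at every action event,
`f_h ← −(s − z^e_h)² + η f_h`, and all four forecasts are refreshed.  The
rule in use is redrawn with inertia ρ plus a softmax of intensity φ over the
fitnesses.  Forecasts are clipped to [0, 1] (the extrapolating rules can
leave the unit interval; `z` is a share).

Cold start: before an agent has two snapshots, both lags and the running
mean equal its initial local observation, all forecasts start there, all
fitnesses at zero, and the initial rule is uniform random.  This is an
unbiased start; long-run outcomes are insensitive to it (verified across
initial conditions).

## Parameters

| name | default | meaning |
|---|---|---|
| P | 1000 | population / nodes |
| T | 40000 | scheduler steps (= 40 generations at P = 1000) |
| λ (`lam`) | 250 | attachment count of the preferential-attachment generator |
| ν (`nu`) | 0 | impact-inequality exponent |
| ε (`epsilon`) | 0.25 | environmental speed per generation |
| σ (`sigma`) | 0.1 | logistic slope (multiplied by degree) |
| β1, β2, β3 | 0.63, 0.44, −0.44 | forecasting-rule coefficients |
| ρ, η, φ | 0.9, 0.7, 100 | rule inertia, fitness memory, choice intensity |
| n0, p_low0 | 0.5, 0.5 | initial resource state and low-effort probability |
| record_stride | 10 | trajectory thinning (classification uses an un-thinned trailing buffer) |

Networks are grown from λ edgeless nodes; each of the `P − λ` added nodes
attaches to λ distinct existing nodes chosen proportionally to degree (the
first one necessarily to all initial nodes).  Added nodes are flagged as
hubs; at λ = 950 they are the 50 nodes of degree ≥ 950 while the remaining
950 end up with ≈ 48–50 links.  Generation wraps networkx's
Barabási–Albert implementation with a deterministic relabeling to this
convention; edge count is always `λ(P − λ)`.  Degree skewness is reported as
Fisher–Pearson g1 (zero for regular graphs by convention).

## Numerical choices

- Single RNG stream per run (numpy PCG64 seeded from the config seed) covers
  network construction, initial conditions, scheduling, and decisions;
  ensembles use seeds `base + run_index`.  Replays are bitwise identical.
- Softmax is max-shifted (φ = 100 overflows raw exponentials); the logistic
  exponent is clipped at ±500 (hub degrees × large advantages overflow).
- `z` and the weighted neighbor sums are maintained incrementally (O(d)
  per strategy flip) and recomputed exactly every 4096 steps to cancel
  floating-point drift; snapshots are clamped to [0, 1].
- Outcome classification: a run is *scarce* if its mean `n` over the final
  100 un-strided steps is strictly below `n*`, *abundant* otherwise (ties →
  abundant).
- The replicator companion is integrated with an adaptive 4th/5th-order
  Runge–Kutta scheme (rtol 1e−8); `α` corresponds to the `1/P` factor of the
  discrete law of motion when comparing timescales with the simulation.

## What the simulations show — and a known limitation

The default configuration has two locally stable long-run states straddling
the FIE: an *abundant* state (`n ≈ 0.40`; high-degree agents on high effort,
positive effort–degree correlation) and a *scarce* state (`n ≈ 0.29`;
the mirror arrangement).  Both persist for tens of generations once
established, the correlation sign is constant over the final generations of
a run, and the abundant state exhibits a strong majority illusion (most
agents see a local majority opposite to the global one).  On complete
graphs the outcome is a single cluster within 0.05 of the FIE, and raising
ν on a skewed network collapses the outcomes onto the FIE.

Limitation: under the logistic *redraw* rule used here, which long-run
branch an unsorted population selects is not an even lottery.  An agent at
indifference redraws its strategy 50/50, so wherever decisions are weakly
signed the low-effort share drifts toward 0.5; holding `z` at an equilibrium
below 0.5 therefore requires the population-mean advantage to sit slightly
negative (≈ −0.85/(d̄σ), the logit balance at the typical degree).  On every
passage through the critical region that small negative mean advantage sorts
the sharpest responders — the highest-degree agents — onto high effort, so
ensembles started from unsorted initial conditions select the abundant
branch essentially always, for any initial `(n0, p_low0)`.  The scarce
branch is reachable from pre-sorted initial strategy assignments (verified
directly), but not spontaneously.  A revision protocol in which agents
instead reconsider only by comparison with an observed peer (whose
mean-field limit is the replicator equation, with no drift at indifference)
makes the branch choice genuinely stochastic; it is not the rule implemented
here, and under it the ensemble composition is also materially different.
Any quantitative claim about the *frequency* of the two branches is
therefore specific to the revision rule, and the ensemble split reported by
`scripts/acceptance.py` should be read with that in mind.

## Test and acceptance problem sizes

Unit and property tests run on small instances (P = 60–300, a few hundred
steps) plus targeted full-scale checks: the network-construction criterion
at (P, λ) = (1000, 950) over 10 seeds, a 50-run full-scale ensemble for the
bistability split, a 3 × 4-run impact sweep at λ = 950, and single
full-scale runs for correlation persistence and the majority-illusion
permutation test.  The acceptance script runs the full 100-seed ensemble at
the reference configuration.
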