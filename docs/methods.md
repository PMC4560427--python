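# Methods

## The model

`fluxadapt` models metabolic adaptation of a constraint-based network as a
stochastic process of *iterated reaction resilencing*. The biological
picture: after a perturbation, many latent pathways are transiently active
and growth is poor; during adaptation, non-essential reactions fall silent
one at a time, and phenotypes that recover growth faster out-compete the
rest. The package asks where this greedy, local process ends up — and the
central result it reproduces is that on the E. coli central-carbon network
the end-points concentrate on (the direction of) the parsimonious-FBA flux
vector.

The state of the chain at step *k* is the pair S_k = {v_k, Γ_k}, where

* Γ = {v : Sv = 0, l ≤ v ≤ u} is the steady-state flux polytope
  (stoichiometric matrix S, bounds l, u in mmol·gDW⁻¹·h⁻¹);
* growth is the linear functional g = ξᵀv (1/h), with ξ the indicator of
  the biomass reaction by default (arbitrary ξ supported);
* Γ_k is Γ with the so-far-silenced reactions pinned to l_i = u_i = 0.

One step:

1. **Candidates.** Every active reaction (|v_i| > ε, default ε = 10⁻⁶) that
   is not yet silenced is a candidate for resilencing. Silencing reaction
   *i* replaces Γ_k by Γ_{k,i} = Γ_k ∩ {l_i = u_i = 0}, and the phenotype's
   flux is the MOMA adjustment, the Euclidean projection
   v_{k,i} = argmin_{v∈Γ_{k,i}} ‖v − v_k‖. Staying put is the (n_k+1)-th
   candidate. Candidates whose reduced polytope is empty (a silencing that
   contradicts a forced throughput such as ATP maintenance) are dropped: a
   phenotype needs an existing steady state. Feasible zero-growth
   candidates are kept — they are the non-viable phenotypes with fitness 0.
2. **Selection.** Growth rates g_{k,i} act as fitness in a replicator
   equation ṗ = G p − φ(p) p over a selection interval Δt, whose solution
   is the Boltzmann distribution p_i ∝ exp(g_i·Δt) (uniform prior at the
   start of the interval). With an accumulated Boltzmann prior of inverse
   temperature β_k the solution is p_i ∝ exp(g_i·(β_k+Δt)); this mode is
   provided as an experimental option (β grows by Δt on every stay and
   resets on silencing) and the default is the uniform-prior form.
3. **Transition.** One candidate is drawn (inverse-CDF over the fixed
   candidate order: stay first, then ascending reaction index — for
   reproducibility). Silencings are irreversible, so the on/off projection
   of the chain has a triangular transition matrix and no cycles; a
   trajectory is declared absorbed after `stall_steps` = 5 consecutive
   stays.

Reported absorption time is the index of the last silencing step + 1, so
the statistic does not depend on the size of the stall window.

### Which reactions are silenceable

All active reactions are candidates, including the biomass pseudo-reaction
and exchanges: silencing an essential reaction simply produces a fitness-0
candidate that selection almost never picks, which keeps the candidate
count n_k faithful to "one candidate per active reaction". An
`internal_only` scope that excludes boundary (exchange) reactions is
available for sensitivity checks.

## Optimization kernels

* **FBA**: max ξᵀv over Γ, solved with HiGHS. Degenerate optimal faces are
  tolerated — any optimal vertex is accepted.
* **pFBA**: among growth-optimal fluxes, min Σ|v_i|, via the standard
  forward/backward split v = f − b, f,b ≥ 0. The growth floor
  ξᵀv ≥ g\* carries a 10⁻⁹-relative relief so LP round-off cannot make it
  infeasible. The pFBA flux is the analysis reference; it is computed once
  per network.
* **MOMA**: the strictly convex projection QP, solved with OSQP using a
  single factorisation per network (the constraint matrix [S; I] never
  changes along a chain — only bounds do) and warm starts.

### Numerical robustness of the projection

Deep into a silencing chain the reduced polytopes become nearly degenerate:
most fluxes are forced to a single value while the original box still spans
±1000. ADMM converges slowly there, so the projector uses a ladder:

1. warm-started solve (tolerance 10⁻⁶ within the chain, 10⁻⁸ for one-shot
   calls; polishing recovers near-machine precision when it succeeds);
2. an iteration-limited iterate is accepted if its actual KKT residuals
   are tight (primal < 10⁻⁶, dual < 10⁻⁴);
3. otherwise an LP feasibility probe settles emptiness, and a fresh solve
   on the flux-variability-tightened box (which pins forced coordinates
   and restores conditioning) resolves the remainder.

On networks with more than 20 reactions, every candidate QP in a state is
tightened up front with the parent polytope's flux-variability ranges
(computed once per state with warm-started GLPK simplex, falling back to
HiGHS). The parent ranges are valid outer bounds for every
one-more-silencing child, and they also give an exact feasibility screen:
silencing reaction *i* is feasible iff 0 lies in the parent range of
flux *i* (by convexity). Returned fluxes are clipped to the effective
bounds, and candidate growths are floored at 0.

## Initial conditions

Trajectories start from points drawn "uniformly" from Γ by hit-and-run on
the null-space parameterisation of Sv = 0 (burn-in 1000, thinning 100 by
default). Two practical points:

* Flux polytopes contain *blocked* reactions whose feasible range is a
  single value despite wide box bounds; a chord through such a coordinate
  has zero length and freezes the walk. A flux-variability sweep therefore
  pins zero-range coordinates as extra equalities first — the same device
  standard flux samplers use.
* The start point maximises the summed (capped) per-coordinate slack to
  the bounds, a Chebyshev-style LP that stays meaningful when some
  coordinates have no slack at all.

Hit-and-run is asymptotically uniform but autocorrelated at finite
thinning; the uniformity tests check box-moment and half-mass statistics at
the 3σ level, where the default thinning comfortably passes. Whether the
original study drew its initial conditions uniformly is unknown; this is an
assumption the ensemble statistics could be sensitive to.

## The selection interval Δt

Δt is the one load-bearing parameter the underlying study does not state,
and it is treated as the calibration parameter of the reproduction. The
default is Δt = 100 / g_FBA(Γ) (≈ 114 h for the core network). The
reasoning: candidate growths differ from the stay growth by a few percent
of g_FBA at most, so exponent gaps of order 100·Δg/g_FBA ≈ O(1–10) are
needed for selection to resolve them. Much weaker selection (e.g.
10 / g_FBA) makes the step distribution nearly uniform over ~90
candidates; trajectories then silence indiscriminately, collapse to zero
growth, and the growth-recovery phenomenology disappears entirely. With
the default calibration the scaled-down core ensembles land near the
reference statistics (absorption after ~24 steps, mean end-point growth
~0.76 g_FBA, mean correlation with the pFBA flux ~0.95) without any
further per-statistic tuning.

## Exact chain enumeration (small networks)

For networks with r ≤ 12 reactions, `enumerate_chain_exact` expands the
whole tree of silencing sequences and aggregates exact end-state
probabilities. Within a state, draws are i.i.d., so with stay probability
p₀ the state absorbs with probability p₀^stall_steps and otherwise exits
through silencing *i* with probability (1 − p₀^stall)·p_i/(1 − p₀); the
complement 1 − p₀ is computed as Σ_{i≥1} p_i, and a state whose silencing
mass underflows to zero is treated as absorbing. The enumerator assumes
the uniform prior mode (the accumulated mode's β depends on dwell time)
and no step cap; branch mass below 10⁻¹² is pruned. It doubles as the
oracle for the Monte-Carlo sampler and verifies the triangular (acyclic)
transition structure.

## Synthetic random networks

`make_random_network` builds small test networks with a guaranteed
positive FBA optimum: a linear uptake → conversions → biomass backbone,
plus random extra conversions/exports with random yields (0.5–2) and a
30% chance of reversibility per extra internal reaction; bounds 0/±10.
These are deliberately minimal stand-ins — they have none of the core
model's cofactor coupling, forced maintenance flux, or realistic
degeneracy structure — so passing tests on them validates the chain
mechanics, not genome-scale behaviour. The E. coli core model itself (the
copy distributed with cobrapy: 95 reactions, 72 metabolites, 49
irreversible reactions) is used wherever realistic structure matters.

## Problem sizes in tests and the acceptance script

The full-scale study uses ~10⁵ trajectories (≈10⁸ QPs). The package's own
reproduction runs scaled-down ensembles: 80 core trajectories (plus a
30-trajectory all-reversible control and 200 toy trajectories) in the
acceptance script, 50 in the test suite. At n = 80 the standard error of
the mean correlation is below 0.01 and of the mean growth ratio about
0.02, small compared to the ±15%-relative comparison bands used for the
scaled-down reproduction; fraction-type statistics carry sampling noise of
several percentage points and are reported rather than asserted.

## Known limitations

Two aspects of the full-scale reference results are *not* reproduced at
the default calibration, and are reported as computed rather than tuned
away. First, no scaled-down trajectory ends exactly at the FBA optimum
(growth ratio ≥ 0.999): the end-point growth distribution peaks just
below 0.85–0.9 without an atom at 1.0. Second, the all-reversible
control (every irreversible bound relaxed to −u) loses the correlation
with the pFBA direction — the expected effect — but also loses growth
instead of retaining it: with all bounds at ±1000 the sampled initial
fluxes and the projections live far from the biomass-optimal face, and
relative selection at the default Δt cannot climb there. Both suggest
the original study's selection pressure or initial-condition rule
differed in ways its description does not pin down.

Other limitations:

* The accumulated-prior mode implements one defensible bookkeeping (β
  accumulates over stays, resets on silencing); the original derivation of
  the non-uniform-prior case is not public, so this mode is labelled
  experimental and excluded from the exact enumerator.
* Hit-and-run uniformity is asymptotic; very elongated polytopes would
  need longer thinning than the default.
* The chain-level QP tolerance (10⁻⁶) bounds each projection's accuracy;
  on nearly degenerate polytopes accepted iterates can carry bound
  violations up to ~10⁻⁶, which is also the activity threshold. Statistics
  at the ensemble level are insensitive to this.
* Gene–protein–reaction rules, compartments, and thermodynamic (ΔG)
  constraints are out of scope; reaction reversibility is taken from the
  model file as ground truth.
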