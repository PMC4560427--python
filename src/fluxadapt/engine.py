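"""The metabolic-adaptation Markov chain.

State of the chain at step ``k`` is the pair ``S_k = {v_k, Gamma_k}``: the
current flux vector and the current (reduced) polytope.  One step proceeds
as

1. enumerate candidates: for each of the ``n_k`` active silenceable
   reactions, pin its bounds to zero and compute the MOMA projection of
   ``v_{k-1}`` onto the reduced polytope, yielding a candidate phenotype
   with growth ``g_{k,i}``; the (``i = 0``) *stay* candidate keeps the
   current phenotype and growth;
2. convert the growths into selection probabilities.  Solving the
   replicator equation ``dp/dt = G p - phi(p) p`` over a selection interval
   ``dt`` with the diagonal fitness matrix ``G = diag(g_{k,0..n_k})`` gives
   a Boltzmann distribution ``p_i ∝ exp(g_i dt)`` (uniform prior); with an
   accumulated Boltzmann prior of inverse temperature ``beta_k`` it gives
   ``p_i ∝ exp(g_i (beta_k + dt))``;
3. sample one candidate and move.

Silencings are irreversible, so the silenced set grows monotonically and
the chain projected on on/off patterns has a triangular transition matrix;
the chain is declared absorbed once no silencing occurs for ``stall_steps``
consecutive steps.  For tiny networks :func:`enumerate_chain_exact`
computes the exact end-state distribution by expanding the whole tree of
silencing sequences, and serves as an oracle for the Monte-Carlo sampler.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .analysis import flux_correlation
from .network import ConstraintSet, FluxVector, MetabolicNetwork
from .optimize import MomaProjector, flux_ranges, solve_fba, solve_pfba

logger = logging.getLogger(__name__)

#: QP tolerance for in-chain projections; selection only needs growth
#: differences resolved far above this level, and polishing recovers
#: near-machine precision on the returned flux whenever it succeeds
CHAIN_QP_TOL = 1e-6

__all__ = [
    "AdaptationConfig",
    "Candidate",
    "CandidateSet",
    "SelectionDistribution",
    "AdaptationState",
    "StepRecord",
    "Trajectory",
    "default_delta_t",
    "enumerate_candidates",
    "selection_probabilities",
    "advance_step",
    "run_trajectory",
    "run_ensemble",
    "enumerate_chain_exact",
    "ExactChainResult",
    "trajectories_to_frame",
]


# ---------------------------------------------------------------------------
# configuration and state containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AdaptationConfig:
    """Knobs of the adaptation chain.

    ``delta_t`` (h) is the duration of one selection interval; ``None``
    selects the default calibration ``100 / g_FBA`` of the network (see
    :func:`default_delta_t`).
    ``activity_epsilon`` is the flux magnitude below which a reaction is
    considered inactive (and hence not a silencing candidate).
    """

    delta_t: float | None = None
    prior_mode: str = "uniform"  # or "accumulated" (experimental)
    beta0: float = 0.0
    activity_epsilon: float = 1e-6
    stall_steps: int = 5
    max_steps: int = 200
    candidate_scope: str = "all_active"  # or "internal_only"
    seed: int = 0
    retain_fluxes: bool = False

    def __post_init__(self):
        if self.delta_t is not None and self.delta_t <= 0:
            raise ValueError("delta_t must be positive")
        if self.prior_mode not in ("uniform", "accumulated"):
            raise ValueError(f"unknown prior_mode {self.prior_mode!r}")
        if self.candidate_scope not in ("all_active", "internal_only"):
            raise ValueError(f"unknown candidate_scope {self.candidate_scope!r}")
        if self.stall_steps < 1:
            raise ValueError("stall_steps must be >= 1")
        if self.activity_epsilon <= 0:
            raise ValueError("activity_epsilon must be positive")
        if self.max_steps < 0:
            raise ValueError("max_steps must be >= 0")


def default_delta_t(network: MetabolicNetwork) -> float:
    """Default selection interval: 100 / g_FBA of the unreduced polytope.

    This calibration makes the fittest/least-fit exponent gap O(100), strong
    enough that the small growth differences between single-silencing
    phenotypes (typically a few percent of g_FBA) are resolved by selection;
    much weaker selection degenerates into near-uniform silencing that
    drives trajectories to zero growth.
    """
    res = solve_fba(network.constraints())
    if not res.ok or res.objective <= 0:
        raise ValueError("network has no positive FBA optimum; set delta_t explicitly")
    return 100.0 / res.objective


@dataclass(frozen=True)
class Candidate:
    """One possible phenotype at a step: stay, or silence one reaction."""

    action: str  # "stay" | "silence"
    reaction: int | None
    flux: FluxVector | None
    growth: float
    feasible: bool = True


@dataclass(frozen=True)
class CandidateSet:
    """The n_k + 1 phenotypes reachable in one step (stay entry first)."""

    entries: tuple[Candidate, ...]
    n_infeasible_dropped: int = 0

    def __post_init__(self):
        if not self.entries or self.entries[0].action != "stay":
            raise ValueError("entries must start with the stay candidate")

    @property
    def n_k(self) -> int:
        """Number of retained silencing candidates."""
        return len(self.entries) - 1

    @property
    def growths(self) -> np.ndarray:
        """The diagonal of the fitness matrix G_k."""
        return np.array([c.growth for c in self.entries])


@dataclass(frozen=True)
class SelectionDistribution:
    """Boltzmann selection probabilities over a candidate set."""

    probabilities: np.ndarray
    partition_value: float
    log_partition: float

    def __post_init__(self):
        p = np.asarray(self.probabilities, dtype=float)
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("probabilities must be non-negative and sum to 1")
        p.setflags(write=False)
        object.__setattr__(self, "probabilities", p)

    def average_fitness(self, candidates: CandidateSet) -> float:
        """phi(p) = sum_i g_i p_i, the replicator equation's mean fitness."""
        return float(self.probabilities @ candidates.growths)


@dataclass(frozen=True)
class AdaptationState:
    """S_k = {v_k, Gamma_k} plus the selection-interval bookkeeping."""

    k: int
    flux: FluxVector
    constraints: ConstraintSet
    beta: float = 0.0
    stall_count: int = 0
    #: candidates are a pure function of (flux, constraints); cached so a
    #: run of stay steps does not recompute n_k projections
    candidates: CandidateSet | None = field(default=None, compare=False)


@dataclass(frozen=True)
class StepRecord:
    k: int
    action: str
    silenced_reaction: str | None
    growth: float
    flux_norm: float
    n_active: int
    corr_ref: float


@dataclass
class Trajectory:
    """One realisation of the chain with its per-step summaries."""

    steps: list[StepRecord]
    absorbed: bool
    absorption_step: int  #: index of the last silencing step + 1 (0 if none)
    length: int  #: number of silencing events L
    final_state: AdaptationState
    fluxes: list[np.ndarray] | None = None  #: per-step fluxes if retained
    n_infeasible_dropped: int = 0
    n_zero_growth_selected: int = 0


# ---------------------------------------------------------------------------
# one step of the chain
# ---------------------------------------------------------------------------

def _scope_mask(network: MetabolicNetwork, config: AdaptationConfig) -> np.ndarray:
    # every active reaction is silenceable, the biomass reaction included:
    # suppressing an essential reaction simply yields a non-viable (g = 0)
    # candidate that selection almost never picks
    mask = np.ones(network.r, dtype=bool)
    if config.candidate_scope == "internal_only":
        mask &= ~network.is_exchange
    return mask


def enumerate_candidates(
    state: AdaptationState,
    config: AdaptationConfig,
    projector: MomaProjector | None = None,
) -> CandidateSet:
    """Build the n_k + 1 candidate phenotypes reachable from a state.

    A reaction is a silencing candidate when its flux magnitude exceeds
    ``activity_epsilon``, it is not already silenced, and it is within the
    configured scope.  Each candidate's flux is the MOMA projection of the
    current flux onto the reduced polytope; candidates whose reduced
    polytope is empty are dropped (a phenotype needs an existing steady
    state), while feasible zero-growth candidates are kept.
    """
    if state.candidates is not None:
        return state.candidates
    cs = state.constraints
    net = cs.network
    if projector is None:
        projector = MomaProjector(net, tol=CHAIN_QP_TOL)
    v = state.flux.values
    active = np.abs(v) > config.activity_epsilon
    mask = _scope_mask(net, config) & active
    if cs.silenced:
        mask[np.fromiter(cs.silenced, dtype=int)] = False
    # On larger networks, tighten every candidate QP with the parent
    # polytope's flux-variability ranges: silencing accumulates forced
    # fluxes that leave the original box badly conditioned, and the parent
    # ranges remain valid outer bounds for every one-more-silencing child.
    box = flux_ranges(cs) if net.r > 20 else None
    entries = [Candidate("stay", None, state.flux, state.flux.growth)]
    dropped = 0
    for i in np.flatnonzero(mask):
        reduced = cs.silence(int(i))
        try:
            res = projector.project(reduced, v, box=box)
        except RuntimeError as exc:
            # an unresolvable QP on one candidate must not kill the chain;
            # treat it like an infeasible reduced polytope, but say so
            logger.warning(
                "dropping candidate %s: %s", net.reaction_ids[int(i)], exc
            )
            dropped += 1
            continue
        if not res.ok:
            dropped += 1
            continue
        # non-viable phenotypes have growth 0; clip solver round-off
        g = max(res.flux.growth, 0.0)
        entries.append(Candidate("silence", int(i), res.flux, g))
    return CandidateSet(entries=tuple(entries), n_infeasible_dropped=dropped)


def selection_probabilities(
    candidates: CandidateSet,
    state: AdaptationState,
    config: AdaptationConfig,
) -> SelectionDistribution:
    """Boltzmann selection probabilities from the replicator equation.

    Uniform prior: ``p_i ∝ exp(g_i * delta_t)``; accumulated prior:
    ``p_i ∝ exp(g_i * (beta_k + delta_t))``.  Computed in log space with
    max subtraction; the reported partition value is
    ``Z = sum_i exp(g_i * horizon)`` (``inf`` if it overflows a float).
    """
    dt = config.delta_t if config.delta_t is not None else default_delta_t(
        state.constraints.network
    )
    horizon = dt + (state.beta if config.prior_mode == "accumulated" else 0.0)
    expo = candidates.growths * horizon
    log_z = float(logsumexp(expo))
    p = np.exp(expo - log_z)
    p /= p.sum()
    with np.errstate(over="ignore"):
        z = float(np.exp(log_z))
    return SelectionDistribution(probabilities=p, partition_value=z,
                                 log_partition=log_z)


def advance_step(
    state: AdaptationState,
    config: AdaptationConfig,
    rng: np.random.Generator,
    projector: MomaProjector | None = None,
) -> tuple[AdaptationState, Candidate]:
    """Sample one transition of the chain and return the successor state.

    Candidate choice uses inverse-CDF sampling over the candidate list in
    fixed order (stay first, then ascending reaction index) for
    reproducibility.  In accumulated-prior mode the inverse temperature
    grows by ``delta_t`` on a stay and resets to ``beta0`` on a silencing.
    """
    candidates = enumerate_candidates(state, config, projector)
    dist = selection_probabilities(candidates, state, config)
    u = rng.random()
    idx = int(np.searchsorted(np.cumsum(dist.probabilities), u, side="right"))
    idx = min(idx, len(candidates.entries) - 1)
    chosen = candidates.entries[idx]
    dt = config.delta_t if config.delta_t is not None else default_delta_t(
        state.constraints.network
    )
    if chosen.action == "stay":
        new = replace(
            state,
            k=state.k + 1,
            stall_count=state.stall_count + 1,
            beta=state.beta + dt if config.prior_mode == "accumulated" else state.beta,
            candidates=candidates,
        )
    else:
        new = AdaptationState(
            k=state.k + 1,
            flux=chosen.flux,
            constraints=state.constraints.silence(chosen.reaction),
            beta=config.beta0 if config.prior_mode == "accumulated" else state.beta,
            stall_count=0,
            candidates=None,
        )
    return new, chosen


# ---------------------------------------------------------------------------
# trajectories and ensembles
# ---------------------------------------------------------------------------

def _n_active(values: np.ndarray, silenced: frozenset, eps: float) -> int:
    active = np.abs(values) > eps
    if silenced:
        active[np.fromiter(silenced, dtype=int)] = False
    return int(np.sum(active))


def run_trajectory(
    network: MetabolicNetwork,
    v0: FluxVector,
    config: AdaptationConfig,
    reference: FluxVector | None = None,
    projector: MomaProjector | None = None,
    rng: np.random.Generator | None = None,
) -> Trajectory:
    """Iterate the chain from ``v0`` until absorption or the step cap.

    Absorption means ``stall_steps`` consecutive stays; the reported
    absorption time is the index of the last silencing step + 1, so the
    statistic does not depend on the stall window.  ``reference`` (normally
    the network's pFBA flux) is used for the per-step correlation record.
    """
    cs = network.constraints()
    if not v0.is_feasible(cs):
        raise ValueError("initial flux vector is not feasible in Gamma")
    if config.delta_t is None:
        config = replace(config, delta_t=default_delta_t(network))
    if projector is None:
        projector = MomaProjector(network, tol=CHAIN_QP_TOL)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    ref = reference.values if reference is not None else None

    def record(state, action, reaction):
        rid = network.reaction_ids[reaction] if reaction is not None else None
        corr = flux_correlation(state.flux.values, ref) if ref is not None else float("nan")
        return StepRecord(
            k=state.k,
            action=action,
            silenced_reaction=rid,
            growth=state.flux.growth,
            flux_norm=state.flux.norm,
            n_active=_n_active(state.flux.values, state.constraints.silenced,
                               config.activity_epsilon),
            corr_ref=corr,
        )

    state = AdaptationState(k=0, flux=v0, constraints=cs, beta=config.beta0)
    steps = [record(state, "init", None)]
    fluxes = [v0.values.copy()] if config.retain_fluxes else None
    last_silencing = -1
    length = 0
    dropped = 0
    zero_growth = 0
    while state.stall_count < config.stall_steps and state.k < config.max_steps:
        if state.candidates is None:
            cands = enumerate_candidates(state, config, projector)
            dropped += cands.n_infeasible_dropped
            state = replace(state, candidates=cands)
        state, chosen = advance_step(state, config, rng, projector)
        if chosen.action == "silence":
            length += 1
            last_silencing = state.k - 1
            if chosen.growth <= 0.0:
                zero_growth += 1
        steps.append(record(state, chosen.action, chosen.reaction))
        if config.retain_fluxes:
            fluxes.append(state.flux.values.copy())
    return Trajectory(
        steps=steps,
        absorbed=state.stall_count >= config.stall_steps,
        absorption_step=last_silencing + 1,
        length=length,
        final_state=state,
        fluxes=fluxes,
        n_infeasible_dropped=dropped,
        n_zero_growth_selected=zero_growth,
    )


def run_ensemble(
    network: MetabolicNetwork,
    n_traj: int,
    sampler_config,
    adaptation_config: AdaptationConfig,
    reference: FluxVector | None = None,
    progress_every: int = 1000,
) -> list[Trajectory]:
    """Run ``n_traj`` independent trajectories from sampled initial points.

    Trajectory ``j`` uses the seeded random stream ``base_seed + j``, so
    results are reproducible and independent of execution order.  The
    correlation reference defaults to the network's pFBA flux.
    """
    from .sampling import sample_interior_points

    if n_traj == 0:
        return []
    if reference is None:
        pfba = solve_pfba(network.constraints())
        if not pfba.ok:
            raise ValueError("network is infeasible: cannot compute pFBA reference")
        reference = pfba.flux
    config = adaptation_config
    if config.delta_t is None:
        config = replace(config, delta_t=default_delta_t(network))
    sampler_config = replace(sampler_config, n_samples=n_traj)
    v0s = sample_interior_points(network.constraints(), sampler_config)
    projector = MomaProjector(network, tol=CHAIN_QP_TOL)
    out = []
    for j, v0 in enumerate(v0s):
        rng = np.random.default_rng(config.seed + j)
        try:
            out.append(
                run_trajectory(network, v0, config, reference=reference,
                               projector=projector, rng=rng)
            )
        except Exception as exc:
            raise RuntimeError(f"trajectory {j} failed: {exc}") from exc
        if progress_every and (j + 1) % progress_every == 0:
            logger.info("ensemble progress: %d/%d trajectories", j + 1, n_traj)
    return out


def trajectories_to_frame(
    trajectories: list[Trajectory], g_fba: float | None = None
) -> pd.DataFrame:
    """Tidy per-step table of an ensemble (one row per trajectory step)."""
    rows = []
    for tid, tr in enumerate(trajectories):
        for s in tr.steps:
            rows.append(
                {
                    "trajectory_id": tid,
                    "step": s.k,
                    "action": s.action,
                    "silenced_reaction_id": s.silenced_reaction or "",
                    "growth": s.growth,
                    "growth_ratio": s.growth / g_fba if g_fba else float("nan"),
                    "corr_pfba": s.corr_ref,
                    "n_active": s.n_active,
                    "flux_norm": s.flux_norm,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# exact enumeration (small-network oracle)
# ---------------------------------------------------------------------------

@dataclass
class ExactChainResult:
    """Exact end-state distribution of the chain from one initial flux.

    Keys are frozensets of silenced reaction indices.  ``fluxes`` and
    ``growths`` hold probability-weighted means over the paths reaching
    each end state.  ``triangular`` records the verified acyclicity of the
    transition structure (silenced sets strictly grow along every edge).
    """

    probabilities: dict[frozenset, float]
    fluxes: dict[frozenset, np.ndarray]
    growths: dict[frozenset, float]
    triangular: bool

    @property
    def total_mass(self) -> float:
        return float(sum(self.probabilities.values()))


def enumerate_chain_exact(
    network: MetabolicNetwork,
    v0: FluxVector,
    config: AdaptationConfig,
    max_reactions: int = 12,
    prune_mass: float = 1e-12,
) -> ExactChainResult:
    """Exact absorbing distribution by expanding all silencing sequences.

    Within a state the chain draws i.i.d. candidates until either a
    silencing occurs or ``stall_steps`` consecutive stays absorb it, so with
    stay probability ``p0`` the state absorbs with probability
    ``p0**stall_steps`` and otherwise exits through silencing ``i`` with
    probability ``(1 - p0**stall_steps) * p_i / (1 - p0)``.  Only the
    uniform prior mode admits this per-state closed form (the accumulated
    mode's beta depends on the in-state dwell time), and no step cap is
    applied.  Restricted to small networks; branch mass below
    ``prune_mass`` is discarded (and reported as missing mass).
    """
    if network.r > max_reactions:
        raise ValueError(
            f"exact enumeration limited to r <= {max_reactions} "
            f"(network has r = {network.r})"
        )
    if config.prior_mode != "uniform":
        raise ValueError("exact enumeration supports only the uniform prior mode")
    if config.delta_t is None:
        config = replace(config, delta_t=default_delta_t(network))
    cs = network.constraints()
    if not v0.is_feasible(cs):
        raise ValueError("initial flux vector is not feasible in Gamma")
    projector = MomaProjector(network, tol=CHAIN_QP_TOL)
    probs: dict[frozenset, float] = {}
    flux_acc: dict[frozenset, np.ndarray] = {}
    growth_acc: dict[frozenset, float] = {}
    triangular = True

    def absorb(key, mass, flux):
        probs[key] = probs.get(key, 0.0) + mass
        flux_acc[key] = flux_acc.get(key, 0.0) + mass * flux.values
        growth_acc[key] = growth_acc.get(key, 0.0) + mass * flux.growth

    def expand(state: AdaptationState, mass: float):
        nonlocal triangular
        if mass < prune_mass:
            return
        cands = enumerate_candidates(state, config, projector)
        key = frozenset(state.constraints.silenced)
        if cands.n_k == 0:
            absorb(key, mass, state.flux)
            return
        dist = selection_probabilities(cands, state, config)
        p = dist.probabilities
        p0 = p[0]
        p_absorb = p0 ** config.stall_steps
        absorb(key, mass * p_absorb, state.flux)
        exit_mass = mass * (1.0 - p_absorb)
        denom = float(np.sum(p[1:]))  # exact complement of the stay mass
        if denom <= 0.0 or exit_mass <= 0.0:
            # stay dominates to machine precision: the state is absorbing
            absorb(key, exit_mass, state.flux)
            return
        for cand, pi in zip(cands.entries[1:], p[1:]):
            child = state.constraints.silence(cand.reaction)
            if not child.silenced > state.constraints.silenced:
                triangular = False
            expand(
                AdaptationState(
                    k=state.k + 1,
                    flux=cand.flux,
                    constraints=child,
                ),
                exit_mass * pi / denom,
            )

    expand(AdaptationState(k=0, flux=v0, constraints=cs), 1.0)
    fluxes = {k: flux_acc[k] / probs[k] for k in probs if probs[k] > 0}
    growths = {k: growth_acc[k] / probs[k] for k in probs if probs[k] > 0}
    return ExactChainResult(
        probabilities=probs, fluxes=fluxes, growths=growths, triangular=triangular
    )
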