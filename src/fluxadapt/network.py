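"""Constraint-based metabolic network model and constraint-set transformations.

The central object is the flux polytope

    Gamma = { v : S v = 0,  l <= v <= u }

defined by a stoichiometric matrix ``S`` and per-reaction flux bounds.
Growth is the linear functional ``g = xi . v`` where ``xi`` is, by default,
the indicator of the biomass reaction (arbitrary linear combinations are
supported).  A :class:`ConstraintSet` couples a network with a set of
*silenced* reactions whose effective bounds are pinned to ``(0, 0)``;
silencing is the elementary, irreversible move of the adaptation chain.
"""

from __future__ import annotations

import gzip
import json
import math
import os
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "MetabolicNetwork",
    "ConstraintSet",
    "FluxVector",
    "load_bigg_json",
    "load_sbml",
    "load_ecoli_core",
    "write_bigg_json",
    "make_toy_network",
    "make_random_network",
    "relax_irreversibility",
    "silence_reaction",
]

#: default steady-state / bound tolerance (mmol gDW^-1 h^-1)
STEADY_STATE_TOL = 1e-6


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------

@dataclass(frozen=True, eq=False)
class MetabolicNetwork:
    """A stoichiometric model with bounds and a growth functional.

    Parameters
    ----------
    reaction_ids, metabolite_ids
        Unique string identifiers; reaction order is significant and
        preserved from the source file.
    S
        Metabolite-by-reaction stoichiometric matrix (dense, dimensionless).
    lower_bounds, upper_bounds
        Per-reaction flux bounds in mmol gDW^-1 h^-1.
    biomass_coeffs
        The growth functional ``xi``; growth is ``xi . v`` (1/h).  For a
        plain biomass reaction this is its indicator vector.
    subsystems
        Optional per-reaction pathway labels ('' when unknown).
    is_exchange
        Per-reaction boundary-transport flag.
    """

    reaction_ids: tuple[str, ...]
    metabolite_ids: tuple[str, ...]
    S: np.ndarray
    lower_bounds: np.ndarray
    upper_bounds: np.ndarray
    biomass_coeffs: np.ndarray
    subsystems: tuple[str, ...] = ()
    is_exchange: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        object.__setattr__(self, "reaction_ids", tuple(self.reaction_ids))
        object.__setattr__(self, "metabolite_ids", tuple(self.metabolite_ids))
        S = np.asarray(self.S, dtype=float)
        if S.ndim != 2:
            raise ValueError("S must be a 2-D metabolite-by-reaction matrix")
        object.__setattr__(self, "S", S)
        r = S.shape[1]
        if len(self.reaction_ids) != r:
            raise ValueError(
                f"S has {r} reaction columns but {len(self.reaction_ids)} reaction ids"
            )
        if len(set(self.reaction_ids)) != r:
            raise ValueError("reaction ids are not unique")
        if S.shape[0] != len(self.metabolite_ids):
            raise ValueError(
                f"S has {S.shape[0]} metabolite rows but "
                f"{len(self.metabolite_ids)} metabolite ids"
            )
        if len(set(self.metabolite_ids)) != len(self.metabolite_ids):
            raise ValueError("metabolite ids are not unique")
        for name in ("lower_bounds", "upper_bounds", "biomass_coeffs"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (r,):
                raise ValueError(f"{name} must have length r = {r}")
            object.__setattr__(self, name, arr)
        if np.any(self.lower_bounds > self.upper_bounds):
            bad = int(np.argmax(self.lower_bounds > self.upper_bounds))
            raise ValueError(
                f"lower bound exceeds upper bound for reaction "
                f"{self.reaction_ids[bad]!r}"
            )
        if not np.any(self.biomass_coeffs):
            raise ValueError("biomass_coeffs (xi) is identically zero: no objective")
        subs = tuple(self.subsystems) if self.subsystems else ("",) * r
        if len(subs) != r:
            raise ValueError("subsystems must have length r")
        object.__setattr__(self, "subsystems", subs)
        if self.is_exchange is None:
            object.__setattr__(self, "is_exchange", self._detect_exchanges())
        else:
            ex = np.asarray(self.is_exchange, dtype=bool)
            if ex.shape != (r,):
                raise ValueError("is_exchange must have length r")
            object.__setattr__(self, "is_exchange", ex)
        self.S.setflags(write=False)
        self.lower_bounds.setflags(write=False)
        self.upper_bounds.setflags(write=False)
        self.biomass_coeffs.setflags(write=False)
        self.is_exchange.setflags(write=False)

    def __eq__(self, other) -> bool:
        if not isinstance(other, MetabolicNetwork):
            return NotImplemented
        return (
            self.reaction_ids == other.reaction_ids
            and self.metabolite_ids == other.metabolite_ids
            and self.subsystems == other.subsystems
            and np.array_equal(self.S, other.S)
            and np.array_equal(self.lower_bounds, other.lower_bounds)
            and np.array_equal(self.upper_bounds, other.upper_bounds)
            and np.array_equal(self.biomass_coeffs, other.biomass_coeffs)
            and np.array_equal(self.is_exchange, other.is_exchange)
        )

    def _detect_exchanges(self) -> np.ndarray:
        # standard convention: a boundary reaction has a single nonzero
        # stoichiometric entry, or carries the "EX_" id prefix
        single = (np.count_nonzero(self.S, axis=0) <= 1)
        prefixed = np.array(
            [rid.startswith("EX_") for rid in self.reaction_ids], dtype=bool
        )
        return single | prefixed

    # -- derived quantities -------------------------------------------------

    @property
    def r(self) -> int:
        """Number of reactions."""
        return self.S.shape[1]

    @property
    def n_metabolites(self) -> int:
        return self.S.shape[0]

    @property
    def irreversible_mask(self) -> np.ndarray:
        """A reaction is irreversible iff its lower bound is >= 0."""
        return self.lower_bounds >= 0

    @property
    def n_irreversible(self) -> int:
        return int(np.sum(self.irreversible_mask))

    @property
    def biomass_index(self) -> int:
        """Index of the primary biomass reaction (largest xi coefficient)."""
        return int(np.argmax(self.biomass_coeffs))

    def index(self, reaction_id: str) -> int:
        try:
            return self.reaction_ids.index(reaction_id)
        except ValueError:
            raise KeyError(f"unknown reaction id {reaction_id!r}") from None

    def growth(self, values: np.ndarray) -> float:
        return float(self.biomass_coeffs @ np.asarray(values, dtype=float))

    def constraints(self) -> "ConstraintSet":
        """The unreduced polytope Gamma (nothing silenced)."""
        return ConstraintSet(self, frozenset())


@dataclass(frozen=True)
class ConstraintSet:
    """A flux polytope: a network plus a set of silenced reaction indices.

    Effective bounds are ``(l_i, u_i)`` for unsilenced reactions and
    ``(0, 0)`` for silenced ones.  Silenced sets only ever grow along an
    adaptation chain.
    """

    network: MetabolicNetwork
    silenced: frozenset[int] = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "silenced", frozenset(self.silenced))
        r = self.network.r
        for i in self.silenced:
            if not (0 <= i < r):
                raise ValueError(f"silenced index {i} out of range for r = {r}")

    def effective_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = self.network.lower_bounds.copy()
        hi = self.network.upper_bounds.copy()
        if self.silenced:
            idx = np.fromiter(self.silenced, dtype=int)
            lo[idx] = 0.0
            hi[idx] = 0.0
        return lo, hi

    def silence(self, reaction: int | str) -> "ConstraintSet":
        return silence_reaction(self, reaction)

    def contains(self, values: np.ndarray, tol: float = STEADY_STATE_TOL) -> bool:
        v = np.asarray(values, dtype=float)
        lo, hi = self.effective_bounds()
        if np.any(v < lo - tol) or np.any(v > hi + tol):
            return False
        return bool(np.max(np.abs(self.network.S @ v), initial=0.0) <= tol)


@dataclass(frozen=True)
class FluxVector:
    """A point in flux space, with its growth rate ``g = xi . v``."""

    values: np.ndarray
    growth: float

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        v.setflags(write=False)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "growth", float(self.growth))

    @classmethod
    def from_values(cls, network: MetabolicNetwork, values) -> "FluxVector":
        values = np.asarray(values, dtype=float)
        return cls(values=values, growth=network.growth(values))

    @property
    def norm(self) -> float:
        """Euclidean norm of the flux vector."""
        return float(np.linalg.norm(self.values))

    def is_feasible(self, cs: ConstraintSet, tol: float = STEADY_STATE_TOL) -> bool:
        return cs.contains(self.values, tol=tol)


# ---------------------------------------------------------------------------
# transformations
# ---------------------------------------------------------------------------

def silence_reaction(cs: ConstraintSet, reaction: int | str) -> ConstraintSet:
    """Pin one reaction's bounds to zero: Gamma -> Gamma ∩ {l_i = u_i = 0}.

    Silencing is irreversible along a chain; silencing an already-silenced
    reaction is a contract violation and raises ``ValueError``.
    """
    i = cs.network.index(reaction) if isinstance(reaction, str) else int(reaction)
    if not (0 <= i < cs.network.r):
        raise ValueError(f"reaction index {i} out of range")
    if i in cs.silenced:
        raise ValueError(
            f"reaction {cs.network.reaction_ids[i]!r} is already silenced"
        )
    return ConstraintSet(cs.network, cs.silenced | {i})


def relax_irreversibility(
    network: MetabolicNetwork, fraction: float, seed: int
) -> MetabolicNetwork:
    """Make a random subset of the irreversible reactions reversible.

    ``ceil(fraction * n_irreversible)`` irreversible reactions, drawn
    uniformly with the given seed, get their lower bound set to ``-u_i``
    (magnitudes stay model-consistent).  The input network is unmodified.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError(f"fraction must lie in [0, 1], got {fraction}")
    irr = np.flatnonzero(network.irreversible_mask)
    n_pick = math.ceil(fraction * len(irr))
    if n_pick == 0:
        return network
    rng = np.random.default_rng(seed)
    picked = rng.choice(irr, size=n_pick, replace=False)
    lo = network.lower_bounds.copy()
    lo[picked] = -network.upper_bounds[picked]
    return replace(network, lower_bounds=lo)


# ---------------------------------------------------------------------------
# built-in networks
# ---------------------------------------------------------------------------

def make_toy_network(branched: bool = False) -> MetabolicNetwork:
    """Deterministic toy pathway used throughout the tests.

    Linear variant (3 reactions, one metabolite A):

    * ``R1``: uptake -> A, bounds (0, 10)
    * ``R2``: A -> biomass, bounds (0, 10); xi is the indicator of R2
    * ``R3``: A -> waste, bounds (0, 10)

    so mass balance reads ``v1 = v2 + v3``.  The branched variant adds
    ``R4``: A -> half-yield biomass equivalent, realised as ``xi_4 = 0.5``.
    """
    if branched:
        return MetabolicNetwork(
            reaction_ids=("R1", "R2", "R3", "R4"),
            metabolite_ids=("A",),
            S=np.array([[1.0, -1.0, -1.0, -1.0]]),
            lower_bounds=np.zeros(4),
            upper_bounds=np.full(4, 10.0),
            biomass_coeffs=np.array([0.0, 1.0, 0.0, 0.5]),
            subsystems=("uptake", "biomass", "waste", "biomass"),
        )
    return MetabolicNetwork(
        reaction_ids=("R1", "R2", "R3"),
        metabolite_ids=("A",),
        S=np.array([[1.0, -1.0, -1.0]]),
        lower_bounds=np.zeros(3),
        upper_bounds=np.full(3, 10.0),
        biomass_coeffs=np.array([0.0, 1.0, 0.0]),
        subsystems=("uptake", "biomass", "waste"),
    )


def make_random_network(
    n_reactions: int = 5,
    seed: int = 0,
    reversible_prob: float = 0.3,
    uptake_limit: float = 10.0,
) -> MetabolicNetwork:
    """Generate a small random network with guaranteed positive growth.

    The construction lays a linear backbone (uptake -> M1 -> ... -> Mm ->
    biomass) so the FBA optimum is always strictly positive, then spends the
    remaining reactions on random conversions, bypasses or exports with
    random yields; each extra internal reaction is reversible with
    probability ``reversible_prob``.  Deterministic for a given seed.
    """
    if n_reactions < 3:
        raise ValueError("need at least uptake, one conversion target and biomass")
    rng = np.random.default_rng(seed)
    n_backbone = min(n_reactions - 2, max(1, n_reactions // 2))
    n_mets = n_backbone + 1
    r = n_reactions
    S = np.zeros((n_mets, r))
    lo = np.zeros(r)
    hi = np.full(r, uptake_limit)
    xi = np.zeros(r)
    ids = []
    subsystems = []
    # uptake of the first metabolite
    S[0, 0] = 1.0
    ids.append("UPT")
    subsystems.append("uptake")
    # backbone conversions M_j -> M_{j+1}
    for j in range(n_backbone):
        k = 1 + j
        S[j, k] = -1.0
        S[j + 1, k] = float(rng.choice([0.5, 1.0, 1.0, 2.0]))
        ids.append(f"B{j + 1}")
        subsystems.append("backbone")
    # biomass drains the last backbone metabolite
    kb = 1 + n_backbone
    S[n_mets - 1, kb] = -1.0
    xi[kb] = 1.0
    ids.append("BIO")
    subsystems.append("biomass")
    # extra reactions: random conversion, bypass or export
    for e in range(r - 2 - n_backbone):
        k = kb + 1 + e
        kind = rng.choice(["convert", "export"], p=[0.7, 0.3])
        src = int(rng.integers(0, n_mets))
        if kind == "convert":
            dst = int(rng.integers(0, n_mets))
            while dst == src:
                dst = int(rng.integers(0, n_mets))
            S[src, k] = -1.0
            S[dst, k] = float(rng.choice([0.5, 1.0, 2.0]))
            if rng.random() < reversible_prob:
                lo[k] = -uptake_limit
        else:
            S[src, k] = -1.0
        ids.append(f"X{e + 1}")
        subsystems.append("extra")
    return MetabolicNetwork(
        reaction_ids=tuple(ids),
        metabolite_ids=tuple(f"M{j}" for j in range(n_mets)),
        S=S,
        lower_bounds=lo,
        upper_bounds=hi,
        biomass_coeffs=xi,
        subsystems=tuple(subsystems),
    )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_REQUIRED_REACTION_FIELDS = ("id", "metabolites", "lower_bound", "upper_bound")


def load_bigg_json(path: str | os.PathLike) -> MetabolicNetwork:
    """Read a BiGG-style JSON constraint-based model.

    The model's objective reaction(s) define ``xi`` through their
    ``objective_coefficient`` entries; a model without any objective is
    rejected.
    """
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValueError(f"{path}: not valid JSON: {exc}") from exc
    for key in ("reactions", "metabolites"):
        if key not in doc:
            raise ValueError(f"{path}: malformed model, missing field {key!r}")
    met_ids = [m["id"] for m in doc["metabolites"]]
    met_pos = {mid: i for i, mid in enumerate(met_ids)}
    rxns = doc["reactions"]
    for rx in rxns:
        for fld in _REQUIRED_REACTION_FIELDS:
            if fld not in rx:
                rid = rx.get("id", "<unnamed>")
                raise ValueError(
                    f"{path}: reaction {rid!r} missing field {fld!r}"
                )
    r = len(rxns)
    S = np.zeros((len(met_ids), r))
    lo = np.empty(r)
    hi = np.empty(r)
    xi = np.zeros(r)
    subs = []
    for k, rx in enumerate(rxns):
        for mid, coeff in rx["metabolites"].items():
            if mid not in met_pos:
                raise ValueError(
                    f"{path}: reaction {rx['id']!r} references unknown "
                    f"metabolite {mid!r}"
                )
            S[met_pos[mid], k] = float(coeff)
        lo[k] = float(rx["lower_bound"])
        hi[k] = float(rx["upper_bound"])
        xi[k] = float(rx.get("objective_coefficient", 0.0))
        subs.append(rx.get("subsystem") or "")
    if not np.any(xi):
        raise ValueError(f"{path}: model declares no objective reaction")
    return MetabolicNetwork(
        reaction_ids=tuple(rx["id"] for rx in rxns),
        metabolite_ids=tuple(met_ids),
        S=S,
        lower_bounds=lo,
        upper_bounds=hi,
        biomass_coeffs=xi,
        subsystems=tuple(subs),
    )


def write_bigg_json(network: MetabolicNetwork, path: str | os.PathLike) -> None:
    """Write a network in the same JSON dialect ``load_bigg_json`` reads."""
    mets = [{"id": mid} for mid in network.metabolite_ids]
    rxns = []
    for k, rid in enumerate(network.reaction_ids):
        col = network.S[:, k]
        entry = {
            "id": rid,
            "metabolites": {
                network.metabolite_ids[j]: col[j] for j in np.flatnonzero(col)
            },
            "lower_bound": network.lower_bounds[k],
            "upper_bound": network.upper_bounds[k],
        }
        if network.biomass_coeffs[k]:
            entry["objective_coefficient"] = network.biomass_coeffs[k]
        if network.subsystems[k]:
            entry["subsystem"] = network.subsystems[k]
        rxns.append(entry)
    with open(path, "w") as fh:
        json.dump({"metabolites": mets, "reactions": rxns, "genes": []}, fh)


def load_sbml(path: str | os.PathLike) -> MetabolicNetwork:
    """Read an SBML Level 3 + FBC model (via cobrapy).

    Produces the same network as :func:`load_bigg_json` would from an
    equivalent file.  Models without FBC bounds or objective are rejected.
    """
    from cobra.io import read_sbml_model

    try:
        model = read_sbml_model(str(path))
    except Exception as exc:  # cobra raises several types for broken files
        raise ValueError(f"{path}: cannot read SBML/FBC model: {exc}") from exc
    return _from_cobra(model, source=str(path))


def _from_cobra(model, source: str = "<model>") -> MetabolicNetwork:
    from cobra.util.array import create_stoichiometric_matrix

    if not model.reactions:
        raise ValueError(f"{source}: model has no reactions")
    S = create_stoichiometric_matrix(model)
    lo = np.array([rx.lower_bound for rx in model.reactions], dtype=float)
    hi = np.array([rx.upper_bound for rx in model.reactions], dtype=float)
    xi = np.array(
        [rx.objective_coefficient for rx in model.reactions], dtype=float
    )
    if not np.any(xi):
        raise ValueError(f"{source}: model declares no objective (FBC) reaction")
    return MetabolicNetwork(
        reaction_ids=tuple(rx.id for rx in model.reactions),
        metabolite_ids=tuple(m.id for m in model.metabolites),
        S=S,
        lower_bounds=lo,
        upper_bounds=hi,
        biomass_coeffs=xi,
        subsystems=tuple(rx.subsystem or "" for rx in model.reactions),
    )


def load_ecoli_core() -> MetabolicNetwork:
    """The E. coli central-carbon core model (95 reactions, 72 metabolites).

    Loaded from the SBML copy distributed with cobrapy, so no network access
    is needed.  This is the network on which the adaptation chain's headline
    ensemble statistics are computed.
    """
    import cobra

    path = os.path.join(os.path.dirname(cobra.__file__), "data", "textbook.xml.gz")
    return load_sbml(path)
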