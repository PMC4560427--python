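"""Uniform-ish sampling of initial flux vectors from the polytope Gamma.

Adaptation trajectories start from random interior points of the admissible
flux polytope.  Points are drawn by hit-and-run on the null-space
parameterisation of ``S v = 0`` (directions confined to the steady-state
subspace, chord endpoints determined by the box bounds), the standard
asymptotically uniform sampler for flux polytopes.

Genome-scale-style polytopes contain *blocked* reactions whose feasible
flux range is a single value (usually 0) even though their box bounds are
wide; a direction with a component on such a reaction has a zero-length
chord.  As flux samplers customarily do, the feasible range of every
reaction is first computed by flux variability LPs and zero-range reactions
are pinned as extra equality constraints, so the walk lives in the
subspace where the polytope has genuine extent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import null_space
from scipy.optimize import linprog

from .network import ConstraintSet, FluxVector, STEADY_STATE_TOL

__all__ = ["SamplerConfig", "sample_interior_points", "samples_to_csv"]

_RANGE_TOL = 1e-9


@dataclass(frozen=True)
class SamplerConfig:
    """Hit-and-run settings; identical seeds give identical sample sets."""

    n_samples: int
    seed: int = 0
    burn_in: int = 1000
    thinning: int = 100
    #: reactions silenced before sampling (models pathological initial
    #: conditions missing some reactions); indices into the network
    presilenced: tuple[int, ...] = ()

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError("n_samples must be positive")
        if self.burn_in < 0 or self.thinning < 1:
            raise ValueError("burn_in must be >= 0 and thinning >= 1")


def _flux_ranges(S, lo, hi):
    """Feasible [min, max] of each flux over {Sv = 0, lo <= v <= hi}."""
    r = len(lo)
    b_eq = np.zeros(S.shape[0])
    vmin = np.empty(r)
    vmax = np.empty(r)
    bounds = list(zip(lo, hi))
    for i in range(r):
        c = np.zeros(r)
        c[i] = 1.0
        res = linprog(c, A_eq=S, b_eq=b_eq, bounds=bounds, method="highs")
        if res.status == 2:
            raise ValueError("polytope is empty: no feasible flux vector")
        if res.status != 0:
            raise RuntimeError(f"flux-range LP failed: {res.message}")
        vmin[i] = res.fun
        res = linprog(-c, A_eq=S, b_eq=b_eq, bounds=bounds, method="highs")
        if res.status != 0:
            raise RuntimeError(f"flux-range LP failed: {res.message}")
        vmax[i] = -res.fun
    return vmin, vmax


def _interior_start(A_eq, b_eq, lo, hi, caps):
    """Maximise the total per-coordinate slack to the bounds (capped)."""
    r = len(lo)
    free = caps > 0
    nf = int(free.sum())
    if nf == 0:
        res = linprog(np.zeros(r), A_eq=A_eq, b_eq=b_eq,
                      bounds=list(zip(lo, hi)), method="highs")
        if res.status == 2:
            raise ValueError("polytope is empty: no feasible flux vector")
        if res.status != 0:
            raise RuntimeError(f"interior-point LP failed: {res.message}")
        return res.x
    # variables (v, s_free): max sum s, with lo_i + s_i <= v_i <= hi_i - s_i
    c = np.concatenate([np.zeros(r), -np.ones(nf)])
    sel = np.eye(r)[free]
    A_ub = np.block([
        [-sel, np.eye(nf)],
        [sel, np.eye(nf)],
    ])
    b_ub = np.concatenate([-lo[free], hi[free]])
    A = np.hstack([A_eq, np.zeros((A_eq.shape[0], nf))])
    bounds = list(zip(lo, hi)) + [(0.0, c_) for c_ in caps[free]]
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A, b_eq=b_eq,
                  bounds=bounds, method="highs")
    if res.status == 2:
        raise ValueError("polytope is empty: no feasible flux vector")
    if res.status != 0:
        raise RuntimeError(f"interior-point LP failed: {res.message}")
    return res.x[:r]


def sample_interior_points(
    cs: ConstraintSet, config: SamplerConfig
) -> list[FluxVector]:
    """Draw ``n_samples`` points from the effective polytope of ``cs``.

    Every returned point satisfies ``S v = 0`` and the effective bounds to
    within the steady-state tolerance.  Reproducible from ``config.seed``.
    """
    net = cs.network
    work = cs
    for i in config.presilenced:
        work = work.silence(i)
    lo, hi = work.effective_bounds()
    vmin, vmax = _flux_ranges(net.S, lo, hi)
    width = vmax - vmin
    pinned = width < _RANGE_TOL
    pin_values = (vmin + vmax) / 2.0
    A_eq = net.S
    b_eq = np.zeros(net.n_metabolites)
    if pinned.any():
        A_eq = np.vstack([net.S, np.eye(net.r)[pinned]])
        b_eq = np.concatenate([b_eq, pin_values[pinned]])
    caps = np.where(pinned, 0.0, np.minimum(1.0, width / 2.0))
    x = _interior_start(A_eq, b_eq, lo, hi, caps)
    N = null_space(A_eq)
    if N.shape[1] == 0:
        # the polytope is a single point
        return [FluxVector.from_values(net, x)] * config.n_samples
    rng = np.random.default_rng(config.seed)
    x0 = x.copy()
    moves = 0

    def advance(x):
        nonlocal moves
        z = rng.standard_normal(N.shape[1])
        d = N @ z
        nd = np.linalg.norm(d)
        if nd < 1e-14:
            return x  # degenerate direction (still counts as a move)
        d = d / nd
        t_lo, t_hi = -np.inf, np.inf
        for i in np.flatnonzero(np.abs(d) > 1e-11):
            a = (lo[i] - x[i]) / d[i]
            b = (hi[i] - x[i]) / d[i]
            if a > b:
                a, b = b, a
            t_lo = max(t_lo, a)
            t_hi = min(t_hi, b)
        if np.isfinite(t_lo) and np.isfinite(t_hi) and t_hi > t_lo:
            x = x + rng.uniform(t_lo, t_hi) * d
        moves += 1
        if moves % 1000 == 0:
            # kill numerical drift off the affine subspace
            x = x0 + N @ (N.T @ (x - x0))
            np.clip(x, lo, hi, out=x)
        return x

    for _ in range(config.burn_in):
        x = advance(x)
    samples: list[FluxVector] = []
    while len(samples) < config.n_samples:
        for _ in range(config.thinning):
            x = advance(x)
        pt = np.clip(x, lo, hi)
        assert np.max(np.abs(net.S @ pt), initial=0.0) <= STEADY_STATE_TOL
        samples.append(FluxVector.from_values(net, pt))
    return samples


def samples_to_csv(samples: list[FluxVector], network, path) -> None:
    """Write samples as CSV, one row per point, reaction ids as header."""
    df = pd.DataFrame(
        [s.values for s in samples], columns=list(network.reaction_ids)
    )
    df.to_csv(path, index=False)
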