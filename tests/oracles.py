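"""Independent brute-force oracles for the optimization kernels.

These deliberately avoid the package's solver paths: linear programs are
checked against exhaustive vertex enumeration, and the Euclidean projection
against exhaustive active-set enumeration.  Both are exact on the tiny
networks they are used with (r <= 5), at the cost of combinatorial blowup.
"""

from itertools import combinations, product

import numpy as np


def polytope_vertices(A_eq, b_eq, lo, hi, tol=1e-9):
    """All vertices of {A_eq v = b_eq, lo <= v <= hi} by basis enumeration.

    A vertex is determined by the equalities plus enough active bounds to
    pin down the remaining degrees of freedom.
    """
    A_eq = np.atleast_2d(A_eq)
    r = len(lo)
    rank = np.linalg.matrix_rank(A_eq) if A_eq.size else 0
    n_extra = r - rank
    verts = []
    for idx in combinations(range(r), n_extra):
        for sides in product((0, 1), repeat=n_extra):
            rows = [A_eq] if A_eq.size else []
            rhs = [np.atleast_1d(b_eq)] if A_eq.size else []
            for i, s in zip(idx, sides):
                e = np.zeros(r)
                e[i] = 1.0
                rows.append(e[None, :])
                rhs.append(np.array([hi[i] if s else lo[i]]))
            A = np.vstack(rows)
            b = np.concatenate(rhs)
            if np.linalg.matrix_rank(A) < r:
                continue
            v, *_ = np.linalg.lstsq(A, b, rcond=None)
            if np.max(np.abs(A @ v - b)) > tol:
                continue
            if np.all(v >= lo - tol) and np.all(v <= hi + tol):
                verts.append(np.clip(v, lo, hi))
    return verts


def fba_oracle(S, lo, hi, xi):
    """Max growth over the polytope via vertex enumeration."""
    verts = polytope_vertices(S, np.zeros(S.shape[0]), lo, hi)
    if not verts:
        return None, None
    growths = [float(xi @ v) for v in verts]
    k = int(np.argmax(growths))
    return growths[k], verts[k]


def pfba_oracle(S, lo, hi, xi, tol=1e-7):
    """Min total absolute flux among growth optima, by vertex enumeration.

    The L1 optimum lies at a vertex of the polytope intersected with the
    optimal-growth hyperplane.
    """
    g_star, _ = fba_oracle(S, lo, hi, xi)
    A = np.vstack([S, xi[None, :]])
    b = np.concatenate([np.zeros(S.shape[0]), [g_star]])
    verts = polytope_vertices(A, b, lo, hi)
    costs = [float(np.sum(np.abs(v))) for v in verts]
    k = int(np.argmin(costs))
    return costs[k], verts[k]


def moma_oracle(S, lo, hi, ref, tol=1e-9):
    """Euclidean projection by exhaustive active-set enumeration.

    For every subset of bounds held at equality, solve the resulting
    equality-constrained least-distance problem in closed form and keep the
    feasible candidate of minimum distance; the true projection's active
    set is among the subsets, so the minimum is exact.
    """
    S = np.atleast_2d(S)
    r = len(lo)
    best = None
    best_d = np.inf
    for nact in range(r + 1):
        for idx in combinations(range(r), nact):
            for sides in product((0, 1), repeat=nact):
                rows = [S]
                rhs = [np.zeros(S.shape[0])]
                for i, s in zip(idx, sides):
                    e = np.zeros(r)
                    e[i] = 1.0
                    rows.append(e[None, :])
                    rhs.append(np.array([hi[i] if s else lo[i]]))
                C = np.vstack(rows)
                d = np.concatenate(rhs)
                # argmin ||v - ref|| s.t. Cv = d
                v = ref - C.T @ np.linalg.pinv(C @ C.T) @ (C @ ref - d)
                if np.max(np.abs(C @ v - d)) > 1e-7:
                    continue  # inconsistent constraint combination
                if np.any(v < lo - 1e-8) or np.any(v > hi + 1e-8):
                    continue
                dist = float(np.linalg.norm(v - ref))
                if dist < best_d - 1e-12:
                    best_d = dist
                    best = np.clip(v, lo, hi)
    return best, best_d
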