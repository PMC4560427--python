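"""FBA, pFBA and MOMA solvers over a :class:`~fluxadapt.network.ConstraintSet`.

Three mathematical programs drive the adaptation chain:

* **FBA** — the linear program ``max xi . v`` over Gamma; degenerate optima
  are tolerated (any optimal vertex is acceptable).
* **pFBA** — among growth-optimal fluxes, minimise total absolute flux
  ``sum_i |v_i|`` (enzyme-parsimony tie-break), via the standard splitting
  of each flux into non-negative forward/backward parts.
* **MOMA** — the Euclidean projection ``argmin_{v in Gamma'} ||v - v_ref||``
  of a reference flux onto a reduced polytope; strictly convex, hence with
  a unique minimiser.

LPs are solved with HiGHS (scipy.optimize.linprog); the projection QP with
OSQP.  Infeasibility of a reduced polytope is a first-class result
(status ``"infeasible"``), not an error: the adaptation engine consumes it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linprog

from .network import ConstraintSet, FluxVector

__all__ = ["OptResult", "solve_fba", "solve_pfba", "moma_project", "MomaProjector"]

#: feasibility / optimality tolerance passed to the solvers
SOLVER_TOL = 1e-8

STATUS_OPTIMAL = "optimal"
STATUS_INFEASIBLE = "infeasible"
STATUS_UNBOUNDED = "unbounded"


@dataclass(frozen=True)
class OptResult:
    """Outcome of one FBA/pFBA/MOMA solve.

    ``objective`` is the solved program's own objective: the growth rate for
    FBA, the total absolute flux for pFBA, and the Euclidean distance to the
    reference for MOMA.  ``flux`` is ``None`` unless status is optimal.
    """

    status: str
    objective: float
    flux: FluxVector | None = None

    @property
    def ok(self) -> bool:
        return self.status == STATUS_OPTIMAL


_LP_STATUS = {0: STATUS_OPTIMAL, 2: STATUS_INFEASIBLE, 3: STATUS_UNBOUNDED}


def _lp(c, A_eq, b_eq, bounds, A_ub=None, b_ub=None):
    res = linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=bounds,
        method="highs",
        options={"primal_feasibility_tolerance": SOLVER_TOL,
                 "dual_feasibility_tolerance": SOLVER_TOL},
    )
    if res.status not in _LP_STATUS:
        raise RuntimeError(f"LP solver failure: {res.message}")
    return res


def solve_fba(cs: ConstraintSet) -> OptResult:
    """Maximise growth ``xi . v`` over the effective polytope.

    Any optimal vertex is acceptable; the optimum value is unique even when
    the optimal face is degenerate.
    """
    net = cs.network
    lo, hi = cs.effective_bounds()
    res = _lp(-net.biomass_coeffs, net.S, np.zeros(net.n_metabolites),
              list(zip(lo, hi)))
    status = _LP_STATUS[res.status]
    if status != STATUS_OPTIMAL:
        return OptResult(status=status, objective=float("nan"))
    flux = FluxVector.from_values(net, res.x)
    return OptResult(status=STATUS_OPTIMAL, objective=flux.growth, flux=flux)


def solve_pfba(cs: ConstraintSet, optimality_fraction: float = 1.0) -> OptResult:
    """Minimise total absolute flux among (near-)growth-optimal solutions.

    Solves ``min sum_i |v_i|`` subject to the polytope constraints and
    ``xi . v >= optimality_fraction * g*`` with ``g*`` the FBA optimum.
    ``objective`` reports ``sum_i |v_i|``.
    """
    if not (0.0 < optimality_fraction <= 1.0):
        raise ValueError("optimality_fraction must lie in (0, 1]")
    parent = solve_fba(cs)
    if not parent.ok:
        return OptResult(status=parent.status, objective=float("nan"))
    g_star = parent.objective
    net = cs.network
    lo, hi = cs.effective_bounds()
    r = net.r
    # v = f - b with f, b >= 0; the L1 objective makes f_i * b_i = 0 at optimum
    f_lo, f_hi = np.maximum(lo, 0.0), np.maximum(hi, 0.0)
    b_lo, b_hi = np.maximum(-hi, 0.0), np.maximum(-lo, 0.0)
    A_eq = np.hstack([net.S, -net.S])
    b_eq = np.zeros(net.n_metabolites)
    xi = net.biomass_coeffs
    A_ub = -np.concatenate([xi, -xi])[None, :]
    # tiny relief keeps the growth floor feasible against LP round-off
    b_ub = np.array([-(optimality_fraction * g_star
                       - 1e-9 * max(1.0, abs(g_star)))])
    c = np.ones(2 * r)
    bounds = list(zip(f_lo, f_hi)) + list(zip(b_lo, b_hi))
    res = _lp(c, A_eq, b_eq, bounds, A_ub=A_ub, b_ub=b_ub)
    status = _LP_STATUS[res.status]
    if status != STATUS_OPTIMAL:
        return OptResult(status=status, objective=float("nan"))
    v = res.x[:r] - res.x[r:]
    flux = FluxVector.from_values(net, v)
    return OptResult(status=STATUS_OPTIMAL, objective=float(np.sum(np.abs(v))),
                     flux=flux)


def _ranges_glpk(S, lo, hi):
    """Per-flux min/max by GLPK simplex with warm-started bases.

    One problem object serves all 2r solves; after the first solve each
    re-optimisation starts from the previous basis, which makes
    variability analysis an order of magnitude faster than cold solves.
    """
    import swiglpk as glp

    m, r = S.shape
    lp = glp.glp_create_prob()
    try:
        glp.glp_add_rows(lp, m)
        for j in range(m):
            glp.glp_set_row_bnds(lp, j + 1, glp.GLP_FX, 0.0, 0.0)
        glp.glp_add_cols(lp, r)
        for i in range(r):
            if lo[i] == hi[i]:
                glp.glp_set_col_bnds(lp, i + 1, glp.GLP_FX, lo[i], hi[i])
            else:
                glp.glp_set_col_bnds(lp, i + 1, glp.GLP_DB, lo[i], hi[i])
        rows, cols = np.nonzero(S)
        n = len(rows)
        ia = glp.intArray(n + 1)
        ja = glp.intArray(n + 1)
        ar = glp.doubleArray(n + 1)
        for k in range(n):
            ia[k + 1] = int(rows[k]) + 1
            ja[k + 1] = int(cols[k]) + 1
            ar[k + 1] = float(S[rows[k], cols[k]])
        glp.glp_load_matrix(lp, n, ia, ja, ar)
        parm = glp.glp_smcp()
        glp.glp_init_smcp(parm)
        parm.msg_lev = glp.GLP_MSG_OFF
        # degenerate LPs can make the simplex stall; bail out and let the
        # caller fall back to cold HiGHS solves instead of spinning
        parm.it_lim = 20_000
        parm.tm_lim = 2_000  # ms per solve
        vmin = np.empty(r)
        vmax = np.empty(r)
        first = True
        for i in range(r):
            glp.glp_set_obj_coef(lp, i + 1, 1.0)
            for sense, out in ((glp.GLP_MIN, vmin), (glp.GLP_MAX, vmax)):
                glp.glp_set_obj_dir(lp, sense)
                if first:
                    glp.glp_adv_basis(lp, 0)
                    first = False
                ret = glp.glp_simplex(lp, parm)
                if ret != 0 or glp.glp_get_status(lp) not in (
                    glp.GLP_OPT, glp.GLP_FEAS
                ):
                    # infeasibility is only proven on a clean simplex exit;
                    # after an iteration/time limit nothing can be trusted
                    if ret == 0 and glp.glp_get_status(lp) == glp.GLP_NOFEAS:
                        raise ValueError(
                            "polytope is empty: no feasible flux vector"
                        )
                    raise RuntimeError("flux-range LP failed (glpk)")
                out[i] = glp.glp_get_obj_val(lp)
            glp.glp_set_obj_coef(lp, i + 1, 0.0)
        return vmin, vmax
    finally:
        glp.glp_delete_prob(lp)


def _ranges(S, lo, hi):
    b_eq = np.zeros(S.shape[0])
    bounds = list(zip(lo, hi))
    r = S.shape[1]
    vmin = np.empty(r)
    vmax = np.empty(r)
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
        if res.status == 2:
            raise ValueError("polytope is empty: no feasible flux vector")
        if res.status != 0:
            raise RuntimeError(f"flux-range LP failed: {res.message}")
        vmax[i] = -res.fun
    return vmin, vmax


def flux_ranges(cs: ConstraintSet) -> tuple[np.ndarray, np.ndarray]:
    """Feasible [min, max] of each flux over the effective polytope (FVA).

    The interval of reaction ``i`` is exact by convexity: a value ``c`` is
    attainable by some feasible flux vector iff ``vmin_i <= c <= vmax_i``.
    """
    lo, hi = cs.effective_bounds()
    try:
        return _ranges_glpk(cs.network.S, lo, hi)
    except (ImportError, RuntimeError, ValueError):
        # GLPK unavailable, its simplex lost its footing, or it called a
        # marginally feasible polytope empty: redo the sweep with HiGHS,
        # whose feasibility tolerance matches the rest of the pipeline
        return _ranges(cs.network.S, lo, hi)


class MomaProjector:
    """Warm-started Euclidean projector onto the polytopes of one network.

    The constraint matrix ``A = [S; I]`` never changes along a silencing
    chain — only the box part of the bounds does — so a single OSQP
    factorisation serves every projection for a given network.
    """

    def __init__(self, network, tol: float = SOLVER_TOL, max_iter: int = 50_000):
        import osqp

        self.network = network
        m, r = network.n_metabolites, network.r
        self._nm = m
        P = sp.eye(r, format="csc") * 2.0  # osqp minimises 1/2 v'Pv + q'v
        A = sp.vstack([sp.csc_matrix(network.S), sp.eye(r)], format="csc")
        self._prob = osqp.OSQP()
        self._prob.setup(
            P, np.zeros(r), A,
            np.concatenate([np.zeros(m), network.lower_bounds]),
            np.concatenate([np.zeros(m), network.upper_bounds]),
            verbose=False, polishing=True,
            eps_abs=tol, eps_rel=tol,
            eps_prim_inf=1e-6, eps_dual_inf=1e-6,
            max_iter=max_iter,
        )
        self._tol = tol
        self._max_iter = max_iter

    @staticmethod
    def _residuals_ok(res, pri_tol: float = 1e-6, dua_tol: float = 1e-4) -> bool:
        """Accept an iteration-limited iterate whose KKT residuals are tight.

        On nearly degenerate polytopes the ADMM iterate converges in practice
        long before the solver can certify the requested tolerance.
        """
        if res.x is None or np.any(np.isnan(res.x)):
            return False
        info = res.info
        return info.prim_res < pri_tol and info.dual_res < dua_tol

    def _tightened_solve(self, q, lo, hi):
        """Re-solve with the box shrunk to the true per-flux feasible ranges.

        Nearly degenerate reduced polytopes (most fluxes forced to a single
        value while the box still says +/-1000) defeat the ADMM iteration.
        Flux-variability LPs recover the ranges; pinning zero-width
        coordinates leaves the feasible set unchanged but restores
        conditioning, after which the QP solves in a handful of iterations.
        """
        import osqp

        net = self.network
        m, r = net.n_metabolites, net.r
        try:
            vmin, vmax = _ranges_glpk(net.S, lo, hi)
        except (ImportError, RuntimeError, ValueError):
            vmin, vmax = _ranges(net.S, lo, hi)
        mid = (vmin + vmax) / 2.0
        pin = (vmax - vmin) < 1e-9
        vmin[pin] = mid[pin]
        vmax[pin] = mid[pin]
        prob = osqp.OSQP()
        prob.setup(
            sp.eye(r, format="csc") * 2.0, q,
            sp.vstack([sp.csc_matrix(net.S), sp.eye(r)], format="csc"),
            np.concatenate([np.zeros(m), vmin]),
            np.concatenate([np.zeros(m), vmax]),
            verbose=False, polishing=True,
            eps_abs=self._tol, eps_rel=self._tol, max_iter=400_000,
        )
        return prob.solve()

    def project(
        self,
        cs: ConstraintSet,
        reference: np.ndarray,
        box: tuple[np.ndarray, np.ndarray] | None = None,
    ) -> OptResult:
        """Project ``reference`` onto the effective polytope of ``cs``.

        ``box`` optionally supplies pre-tightened per-flux bounds (e.g. from
        :func:`flux_ranges` of a parent polytope) that are known not to cut
        the feasible set; tighter boxes dramatically improve conditioning on
        nearly degenerate polytopes.
        """
        net = self.network
        if cs.network is not net:
            raise ValueError("constraint set belongs to a different network")
        ref = np.asarray(reference, dtype=float)
        if ref.shape != (net.r,):
            raise ValueError(
                f"reference has shape {ref.shape}, expected ({net.r},)"
            )
        lo, hi = cs.effective_bounds()
        if box is not None:
            lo = np.maximum(lo, box[0])
            hi = np.minimum(hi, box[1])
            if np.any(lo > hi + 1e-7):
                # a supplied range excludes a pinned value: empty polytope
                return OptResult(status=STATUS_INFEASIBLE, objective=float("nan"))
            np.minimum(lo, hi, out=lo)  # absorb LP round-off inversions
        q = -2.0 * ref
        try:
            self._prob.update_data_vec(
                q=q,
                l=np.concatenate([np.zeros(self._nm), lo]),
                u=np.concatenate([np.zeros(self._nm), hi]),
            )
        except AttributeError:  # osqp < 1.0 API
            self._prob.update(
                q=q,
                l=np.concatenate([np.zeros(self._nm), lo]),
                u=np.concatenate([np.zeros(self._nm), hi]),
            )
        res = self._prob.solve()
        status = res.info.status.lower()
        if "infeasible" in status:
            return OptResult(status=STATUS_INFEASIBLE, objective=float("nan"))
        if not status.startswith("solved") and not self._residuals_ok(res):
            # iteration limit without a usable iterate: settle feasibility by
            # LP, then re-solve on the variability-tightened box
            probe = _lp(np.zeros(net.r), net.S, np.zeros(net.n_metabolites),
                        list(zip(lo, hi)))
            if _LP_STATUS[probe.status] == STATUS_INFEASIBLE:
                return OptResult(status=STATUS_INFEASIBLE, objective=float("nan"))
            try:
                res = self._tightened_solve(q, lo, hi)
            except ValueError:
                # the variability sweep certified emptiness after all
                # (marginally feasible polytope)
                return OptResult(status=STATUS_INFEASIBLE, objective=float("nan"))
            status = res.info.status.lower()
            if not status.startswith("solved") and not self._residuals_ok(res):
                raise RuntimeError(f"QP solver failure: {res.info.status}")
        v = np.asarray(res.x, dtype=float)
        # pin exact zeros on silenced reactions and clip solver round-off
        v = np.clip(v, lo, hi)
        flux = FluxVector.from_values(net, v)
        return OptResult(
            status=STATUS_OPTIMAL,
            objective=float(np.linalg.norm(v - ref)),
            flux=flux,
        )


def moma_project(cs: ConstraintSet, reference) -> OptResult:
    """Project a reference flux onto a (possibly reduced) polytope.

    One-shot convenience wrapper around :class:`MomaProjector`; code that
    projects repeatedly on the same network should hold a projector.
    ``objective`` reports the Euclidean distance ``||v - v_ref||``.
    """
    values = reference.values if isinstance(reference, FluxVector) else reference
    return MomaProjector(cs.network).project(cs, values)
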