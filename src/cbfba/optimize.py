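"""Flux optimization: cbFBA, pFBA, fixed-optimum variability, projection sampling.

cbFBA minimizes the total absolute activity of reaction complexes,
``sum_i |A_i.v|``, over the steady-state flux space — approximating the
maximization of the number of balanced complexes. pFBA minimizes total flux
``sum_i |v_i|`` (= ``sum_i v_i`` on an irreversible network). Both are plain
LPs after linearizing absolute values with auxiliary variables t_i >= ±A_i.v.

Variability analysis fixes the optimal budget (within a relative tolerance
``tau``) and computes per-reaction flux minima/maxima; sampling draws random
points in the flux box and projects them onto the budget-constrained
steady-state space by a quadratic program.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._lp import solve_lp
from .complexes import complex_activity
from .errors import InfeasibleProblemError, SolverError

#: default relative slack on the fixed optimum: budget <= z * (1 + tau)
DEFAULT_BUDGET_TOL = 1e-6

OBJECTIVE_KINDS = ("cbfba", "pfba")


@dataclass
class FluxDistribution:
    """A single steady-state flux distribution with its objective budget."""

    v: np.ndarray
    reaction_ids: list
    objective_kind: str
    budget: float
    activities: Optional[np.ndarray] = None

    def merged(self, split_map):
        """Net fluxes on the original (pre-split) reaction ids."""
        from .model import merge_split_fluxes
        return merge_split_fluxes(self.v, split_map)

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"reaction_id": self.reaction_ids, "flux": self.v})


@dataclass
class FluxRanges:
    """Per-reaction (min, max) flux at a fixed objective budget."""

    reaction_ids: list
    minimum: np.ndarray
    maximum: np.ndarray
    objective_kind: str
    budget: float

    def __post_init__(self):
        if np.any(self.minimum > self.maximum + 1e-9):
            raise ValueError("flux range with min > max")

    def as_dict(self):
        return {rid: (self.minimum[j], self.maximum[j])
                for j, rid in enumerate(self.reaction_ids)}

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"reaction_id": self.reaction_ids,
                             "min": self.minimum, "max": self.maximum})


@dataclass
class SampleSet:
    """Flux samples from the budget-constrained steady-state space.

    ``V`` has one sample per row. ``audit`` records, per sample, the
    steady-state residual, worst bound violation and realized budget, so the
    feasibility of every sample can be checked after the fact.
    """

    V: np.ndarray
    reaction_ids: list
    objective_kind: str
    budget: float
    seed: Optional[int] = None
    audit: Optional[dict] = None

    @property
    def n(self):
        return self.V.shape[0]


def _lifted_cbfba_parts(model, decomp):
    """Equality/inequality blocks for problems over (v, t) with t >= |A v|."""
    c, r = decomp.A.shape
    A_eq = np.hstack([model.S, np.zeros((model.n_metabolites, c))])
    A_ub = np.vstack([np.hstack([decomp.A, -np.eye(c)]),
                      np.hstack([-decomp.A, -np.eye(c)])])
    bounds = model.bounds + [(0, None)] * c
    return A_eq, A_ub, bounds


def solve_cbfba(model, decomp):
    """Solve cbFBA (minimize total absolute complex activity).

    Returns a :class:`FluxDistribution` whose ``budget`` is the recomputed
    ``sum_i |A_i.v|`` at the optimum.
    """
    c, r = decomp.A.shape
    A_eq, A_ub, bounds = _lifted_cbfba_parts(model, decomp)
    obj = np.concatenate([np.zeros(r), np.ones(c)])
    x, _ = solve_lp(obj, A_eq=A_eq, b_eq=np.zeros(model.n_metabolites),
                    A_ub=A_ub, b_ub=np.zeros(2 * c), bounds=bounds)
    v = x[:r]
    act = complex_activity(decomp, v)
    return FluxDistribution(v, list(model.reaction_ids), "cbfba",
                            float(np.sum(np.abs(act))), act)


def solve_pfba(model, decomp=None):
    """Solve pFBA (minimize total flux) on an irreversible model."""
    if not model.is_irreversible:
        raise ValueError("pFBA requires an irreversible (split) model")
    r = model.n_reactions
    v, z = solve_lp(np.ones(r), A_eq=model.S,
                    b_eq=np.zeros(model.n_metabolites), bounds=model.bounds)
    act = complex_activity(decomp, v) if decomp is not None else None
    return FluxDistribution(v, list(model.reaction_ids), "pfba",
                            float(np.sum(v)), act)


def solve(model, decomp, objective_kind):
    """Dispatch to :func:`solve_cbfba` or :func:`solve_pfba`."""
    if objective_kind == "cbfba":
        return solve_cbfba(model, decomp)
    if objective_kind == "pfba":
        return solve_pfba(model, decomp)
    raise ValueError(f"unknown objective kind {objective_kind!r}")


def _budget_problem(model, decomp, objective_kind, budget, budget_tol):
    """LP blocks for the flux space intersected with the budget constraint."""
    r = model.n_reactions
    cap = budget * (1.0 + budget_tol)
    if objective_kind == "pfba":
        A_eq = model.S
        A_ub = np.ones((1, r))
        b_ub = np.array([cap])
        bounds = model.bounds
        n_aux = 0
    elif objective_kind == "cbfba":
        c = decomp.A.shape[0]
        A_eq, lin, bounds = _lifted_cbfba_parts(model, decomp)
        A_ub = np.vstack([lin, np.concatenate([np.zeros(r), np.ones(c)])[None, :]])
        b_ub = np.concatenate([np.zeros(2 * c), [cap]])
        n_aux = c
    else:
        raise ValueError(f"unknown objective kind {objective_kind!r}")
    return A_eq, A_ub, b_ub, bounds, n_aux


def fva(model, decomp, objective_kind, budget, budget_tol=DEFAULT_BUDGET_TOL,
        reactions=None):
    """Flux variability at the fixed optimum (2 LPs per reaction).

    The optimal budget from the corresponding solve is enforced as
    ``<= budget * (1 + budget_tol)``; exact equality would be numerically
    brittle and the budget is the minimum of its constraint set, so the lower
    side is automatic.
    """
    if reactions is None:
        reactions = list(model.reaction_ids)
    A_eq, A_ub, b_ub, bounds, n_aux = _budget_problem(
        model, decomp, objective_kind, budget, budget_tol)
    b_eq = np.zeros(model.n_metabolites)
    r = model.n_reactions
    mins = np.zeros(len(reactions))
    maxs = np.zeros(len(reactions))
    try:
        for k, rid in enumerate(reactions):
            obj = np.zeros(r + n_aux)
            obj[model.reaction_index(rid)] = 1.0
            _, mins[k] = solve_lp(obj, A_eq=A_eq, b_eq=b_eq, A_ub=A_ub,
                                  b_ub=b_ub, bounds=bounds)
            _, maxs[k] = solve_lp(obj, A_eq=A_eq, b_eq=b_eq, A_ub=A_ub,
                                  b_ub=b_ub, bounds=bounds, maximize=True)
    except InfeasibleProblemError as exc:
        raise InfeasibleProblemError(
            f"budget constraint infeasible at tolerance {budget_tol}; "
            f"retry with a larger budget_tol (e.g. {budget_tol * 100})") from exc
    # clamp the tiny negative overshoot HiGHS can leave on active bounds
    mask = mins > maxs
    mins[mask] = maxs[mask] = (mins[mask] + maxs[mask]) / 2
    return FluxRanges(list(reactions), mins, maxs, objective_kind, budget)


# ---------------------------------------------------------------------------
# Projection sampling (QP)
# ---------------------------------------------------------------------------

def _osqp_project(model, decomp, objective_kind, cap, w):
    """Euclidean projection of w onto the budget-constrained flux space."""
    import osqp
    import scipy.sparse as sp

    r = model.n_reactions
    m = model.n_metabolites
    lb, ub = model.lower_bounds, model.upper_bounds
    if objective_kind == "pfba":
        n = r
        Acon = sp.vstack([sp.csc_matrix(model.S), sp.eye(r),
                          sp.csc_matrix(np.ones((1, r)))], format="csc")
        l = np.concatenate([np.zeros(m), lb, [-np.inf]])
        u = np.concatenate([np.zeros(m), ub, [cap]])
        P = sp.diags(np.full(r, 2.0), format="csc")
        q = -2.0 * w
    else:
        c = decomp.A.shape[0]
        n = r + c
        Acon = sp.vstack([
            sp.csc_matrix(np.hstack([model.S, np.zeros((m, c))])),
            sp.eye(n),
            sp.csc_matrix(np.hstack([decomp.A, -np.eye(c)])),
            sp.csc_matrix(np.hstack([-decomp.A, -np.eye(c)])),
            sp.csc_matrix(np.concatenate([np.zeros(r), np.ones(c)])[None, :]),
        ], format="csc")
        l = np.concatenate([np.zeros(m), lb, np.zeros(c),
                            np.full(2 * c, -np.inf), [-np.inf]])
        u = np.concatenate([np.zeros(m), ub, np.full(c, np.inf),
                            np.zeros(2 * c), [cap]])
        P = sp.diags(np.concatenate([np.full(r, 2.0), np.zeros(c)]),
                     format="csc")
        q = np.concatenate([-2.0 * w, np.zeros(c)])
    solver = osqp.OSQP()
    solver.setup(P=P, q=q, A=Acon, l=l, u=u, verbose=False,
                 eps_abs=1e-10, eps_rel=1e-10, max_iter=200_000,
                 polishing=True, polish_refine_iter=10)
    res = solver.solve(raise_error=False)
    status = res.info.status.strip()
    if status not in ("solved", "solved inaccurate"):
        raise InfeasibleProblemError(
            f"projection QP failed with status {status!r}; "
            "check the budget tolerance") if "infeasible" in status else \
            SolverError(f"projection QP failed with status {status!r}")
    return np.asarray(res.x[:r], dtype=float)


def _active_set_refine(model, decomp, objective_kind, cap, w, v, tol=1e-7):
    """Re-solve the projection on the active set of an approximate solution.

    Given an approximate projection ``v``, builds the locally active equality
    system (steady state, bounds at their limits, zero-activity complexes and,
    if tight, the budget hyperplane linearized with the local activity signs)
    and solves the equality-constrained least-squares projection exactly. The
    refined point is accepted only if it is feasible and at least as close to
    ``w``; otherwise the input is returned unchanged.
    """
    r = model.n_reactions
    lb, ub = model.lower_bounds, model.upper_bounds
    rows = [model.S]
    rhs = [np.zeros(model.n_metabolites)]
    for j in range(r):
        if v[j] <= lb[j] + tol:
            e = np.zeros(r); e[j] = 1.0
            rows.append(e[None, :]); rhs.append([lb[j]])
        elif v[j] >= ub[j] - tol:
            e = np.zeros(r); e[j] = 1.0
            rows.append(e[None, :]); rhs.append([ub[j]])
    if objective_kind == "pfba":
        load = float(np.sum(v))
        if load >= cap - tol:
            rows.append(np.ones((1, r))); rhs.append([cap])
    else:
        act = complex_activity(decomp, v)
        load = float(np.sum(np.abs(act)))
        zero_rows = np.abs(act) <= tol
        if np.any(zero_rows):
            rows.append(decomp.A[zero_rows])
            rhs.append(np.zeros(int(zero_rows.sum())))
        if load >= cap - tol and not np.all(zero_rows):
            sgn = np.sign(act)
            sgn[zero_rows] = 0.0
            rows.append((sgn @ decomp.A)[None, :]); rhs.append([cap])
    C = np.vstack(rows)
    d = np.concatenate([np.atleast_1d(np.asarray(x, float)) for x in rhs])
    # min ||v - w||^2 s.t. C v = d  via KKT: v = w - C^T y, C C^T y = C w - d
    CCt = C @ C.T
    y, *_ = np.linalg.lstsq(CCt, C @ w - d, rcond=None)
    v_ref = w - C.T @ y
    # accept only if feasible and not farther from w
    if np.max(np.abs(model.S @ v_ref)) > 1e-9:
        return v
    if np.any(v_ref < lb - 1e-9) or np.any(v_ref > ub + 1e-9):
        return v
    if objective_kind == "pfba":
        new_load = float(np.sum(v_ref))
    else:
        new_load = float(np.sum(np.abs(complex_activity(decomp, v_ref))))
    if new_load > cap + 1e-9:
        return v
    if np.linalg.norm(v_ref - w) > np.linalg.norm(v - w) + 1e-7:
        return v
    return v_ref


def audit_sample(model, decomp, objective_kind, budget, budget_tol, v):
    """Feasibility report (residual, bound violation, budget) for one sample."""
    resid = float(np.max(np.abs(model.S @ v)))
    bound_viol = float(max(np.max(model.lower_bounds - v, initial=0.0),
                           np.max(v - model.upper_bounds, initial=0.0)))
    if objective_kind == "pfba":
        load = float(np.sum(v))
    else:
        load = float(np.sum(np.abs(complex_activity(decomp, v))))
    ok = (resid <= 1e-9 and bound_viol <= 1e-9
          and load <= budget * (1.0 + budget_tol) + 1e-9)
    return {"residual": resid, "bound_violation": bound_viol,
            "budget_value": load, "ok": ok}


def sample_fluxes(model, decomp, objective_kind, budget, n=1000, seed=None,
                  budget_tol=DEFAULT_BUDGET_TOL, rand_fn=None):
    """Sample the budget-constrained steady-state space by Euclidean projection.

    Each sample is the projection of an independent random point ``v_rand``
    (componentwise uniform on [lb, ub] by default; pluggable via ``rand_fn``
    taking ``(rng, lb, ub)``) onto ``{v : S v = 0, lb <= v <= ub,
    budget <= z*(1+budget_tol)}``. Identical seeds give identical sample sets.
    Requires finite bounds.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lb, ub = model.lower_bounds, model.upper_bounds
    if not (np.all(np.isfinite(lb)) and np.all(np.isfinite(ub))):
        raise ValueError("sampling requires finite flux bounds")
    cap = budget * (1.0 + budget_tol)
    rng = np.random.default_rng(seed)
    if rand_fn is None:
        W = rng.uniform(lb, ub, size=(n, model.n_reactions))
    else:
        W = np.stack([rand_fn(rng, lb, ub) for _ in range(n)])
    V = np.zeros_like(W)
    audits = []
    for k in range(n):
        v = _osqp_project(model, decomp, objective_kind, cap, W[k])
        v = _active_set_refine(model, decomp, objective_kind, cap, W[k], v)
        V[k] = v
        audits.append(audit_sample(model, decomp, objective_kind, budget,
                                   budget_tol, v))
    audit = {key: np.array([a[key] for a in audits]) for key in audits[0]}
    return SampleSet(V, list(model.reaction_ids), objective_kind, budget,
                     seed, audit)


def robust_mean(samples, trim=0.0):
    """Per-reaction trimmed mean of a sample set (trim=0 gives the plain mean)."""
    from scipy.stats import trim_mean

    V = samples.V if isinstance(samples, SampleSet) else np.asarray(samples)
    if V.size == 0 or V.shape[0] == 0:
        raise ValueError("empty sample set")
    if trim == 0.0:
        return V.mean(axis=0)
    return trim_mean(V, proportiontocut=trim, axis=0)
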