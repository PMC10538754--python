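"""Thin wrapper around scipy's HiGHS interface used by every LP stage.

All linear programs in this package (flux minimization, variability,
balanced-complex identification, blocked-reaction detection) go through
:func:`solve_lp`, so solver options and error translation live in one place.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog

from .errors import InfeasibleProblemError, SolverError

#: primal feasibility tolerance used across all stages
FEASIBILITY_TOL = 1e-9


def solve_lp(c, *, A_eq=None, b_eq=None, A_ub=None, b_ub=None, bounds,
             maximize=False):
    """Solve ``min (or max) c.x`` subject to equalities, inequalities and box bounds.

    Parameters
    ----------
    c : array-like
        Objective coefficients.
    bounds : sequence of (lo, hi)
        Per-variable box bounds; ``None`` entries mean unbounded.
    maximize : bool
        Flip the objective sense (the reported optimum keeps the caller's sense).

    Returns
    -------
    (x, fun) : (ndarray, float)
        Optimal point and optimal objective value in the caller's sense.

    Raises
    ------
    InfeasibleProblemError
        If HiGHS reports primal infeasibility.
    SolverError
        On unboundedness or any other solver failure.
    """
    c = np.asarray(c, dtype=float)
    sign = -1.0 if maximize else 1.0
    res = linprog(
        sign * c,
        A_eq=A_eq, b_eq=b_eq, A_ub=A_ub, b_ub=b_ub,
        bounds=bounds, method="highs",
        options={"primal_feasibility_tolerance": FEASIBILITY_TOL,
                 "dual_feasibility_tolerance": FEASIBILITY_TOL},
    )
    if res.status == 2:
        raise InfeasibleProblemError(f"LP infeasible: {res.message}")
    if res.status == 3:
        raise SolverError(f"LP unbounded: {res.message}")
    if res.status != 0:
        raise SolverError(f"LP solver failure (status {res.status}): {res.message}")
    return res.x, sign * res.fun
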