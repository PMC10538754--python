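"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's LP/QP machinery: candidate optima are
enumerated with plain linear algebra (least-squares solves of active-set
systems), so agreement with the HiGHS-based solvers is a genuine dual-route
check.

The key fact: a convex piecewise-linear function (such as the total absolute
complex activity) restricted to a bounded polyhedron attains its minimum at a
vertex of the subdivision of the polyhedron by the function's kink
hyperplanes. Every such vertex is a feasible point where the steady-state
equalities plus a full-rank selection of active bounds / kink hyperplanes
hold, so enumerating all active-set selections covers all candidates.
"""

from __future__ import annotations

import itertools

import numpy as np

FEAS_TOL = 1e-9
CONSISTENCY_TOL = 1e-8


def candidate_vertices(S, lb, ub, hyperplanes=None):
    """All feasible candidate vertices of {S v = 0, lb <= v <= ub} refined by
    the given kink hyperplanes (rows h with kink at h.v = 0).

    Returns an array of points (possibly with duplicates).
    """
    S = np.atleast_2d(np.asarray(S, dtype=float))
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    H = np.zeros((0, lb.size)) if hyperplanes is None else \
        np.atleast_2d(np.asarray(hyperplanes, dtype=float))
    r = lb.size
    rank_S = np.linalg.matrix_rank(S) if S.size else 0
    need = r - rank_S
    pool = [("b", j) for j in range(r)] + [("h", i) for i in range(len(H))]
    points = []

    def try_system(C_extra, d_extra):
        C = np.vstack([S] + C_extra) if C_extra else S
        d = np.concatenate([np.zeros(S.shape[0])] + d_extra) if d_extra \
            else np.zeros(S.shape[0])
        x, *_ = np.linalg.lstsq(C, d, rcond=None)
        if np.max(np.abs(C @ x - d)) > CONSISTENCY_TOL:
            return
        if np.any(x < lb - FEAS_TOL) or np.any(x > ub + FEAS_TOL):
            return
        points.append(np.clip(x, lb, ub))

    if need <= 0:
        try_system([], [])
        return np.array(points)
    for combo in itertools.combinations(pool, need):
        bound_slots = [j for kind, j in combo if kind == "b"]
        hyper_slots = [i for kind, i in combo if kind == "h"]
        for values in itertools.product(*[(lb[j], ub[j]) for j in bound_slots]):
            C_extra, d_extra = [], []
            for j, val in zip(bound_slots, values):
                e = np.zeros(r)
                e[j] = 1.0
                C_extra.append(e[None, :])
                d_extra.append(np.array([val]))
            if hyper_slots:
                C_extra.append(H[hyper_slots])
                d_extra.append(np.zeros(len(hyper_slots)))
            try_system(C_extra, d_extra)
    if not points:
        raise RuntimeError("oracle found no feasible candidate point")
    return np.array(points)


def pfba_optimum_oracle(model):
    """Minimum total flux over the flux polytope, by vertex enumeration."""
    pts = candidate_vertices(model.S, model.lower_bounds, model.upper_bounds)
    return float(np.min(pts.sum(axis=1)))


def cbfba_optimum_oracle(model, A):
    """Minimum total absolute complex activity, by enumeration of the
    vertices of the arrangement cells cut out by the kinks {A_i v = 0}."""
    pts = candidate_vertices(model.S, model.lower_bounds, model.upper_bounds,
                             hyperplanes=A)
    return float(np.min(np.abs(pts @ A.T).sum(axis=1)))


def feasible_points_from_vertices(model, n, seed):
    """Random feasible steady states as convex combinations of polytope
    vertices (an independent feasible-point generator for balance checks)."""
    verts = candidate_vertices(model.S, model.lower_bounds, model.upper_bounds)
    rng = np.random.default_rng(seed)
    weights = rng.dirichlet(np.ones(len(verts)), size=n)
    return weights @ verts
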