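"""Complex graph of a metabolic network: decomposition S = Y.A and balance analysis.

Every reaction has a substrate complex (its left-hand side) and a product
complex (its right-hand side); both are non-negative linear combinations of
metabolites. Writing Y for the metabolite-by-complex composition matrix and A
for the complex-by-reaction incidence matrix of the directed complex graph,
the stoichiometric matrix factorizes exactly as S = Y.A. The *activity* of
complex i under a flux distribution v is A_i.v — total flux producing the
complex minus total flux consuming it. A complex is *balanced* over a flux
space when its activity is zero at every feasible steady state, and balanced
*in* a particular distribution v when |A_i.v| is below threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._lp import FEASIBILITY_TOL, solve_lp
from .errors import InfeasibleProblemError

#: activity magnitude below which a complex counts as balanced
#: (mmol gDW^-1 h^-1; same scale as the blocked-reaction threshold)
ACTIVITY_EPSILON = 1e-6

#: tolerance for deciding that two complex composition vectors are identical
COMPLEX_MATCH_TOL = 1e-9

#: label used for the (unique) empty complex representing the environment
ENVIRONMENT_LABEL = "O"


@dataclass
class ComplexDecomposition:
    """Factorization S = Y.A with the complex catalogue.

    Attributes
    ----------
    Y : ndarray, shape (m, c)
        Non-negative composition matrix; column i gives the stoichiometry of
        complex i. The all-zero column (at most one) is the environment node
        shared by every exchange reaction.
    A : ndarray, shape (c, r)
        Incidence matrix of the complex graph; each non-excluded column has
        exactly one -1 (substrate complex) and one +1 (product complex).
    complex_catalogue : list of dict
        Per complex, metabolite id -> positive coefficient (empty = environment).
    labels : list of str
        Human-readable complex names, e.g. ``"B+C"`` or ``"O"``.
    metabolite_ids, reaction_ids : list of str
        Copied from the decomposed model.
    excluded_reactions : list of str
        Reactions whose substrate complex equals their product complex
        (all-zero stoichiometry columns); their A column is zero.
    """

    Y: np.ndarray
    A: np.ndarray
    complex_catalogue: list
    labels: list
    metabolite_ids: list
    reaction_ids: list
    excluded_reactions: list = field(default_factory=list)

    @property
    def n_complexes(self):
        return self.A.shape[0]

    def label_index(self, label):
        return self.labels.index(label)

    def reconstruct_S(self):
        return self.Y @ self.A


def _complex_label(composition, metabolite_order):
    if not composition:
        return ENVIRONMENT_LABEL
    parts = []
    for mid in metabolite_order:
        if mid in composition:
            coeff = composition[mid]
            parts.append(mid if np.isclose(coeff, 1.0) else f"{coeff:g} {mid}")
    return "+".join(parts)


def decompose(model):
    """Decompose a model's stoichiometric matrix into Y and A.

    Walks the reaction columns of S; the substrate complex of reaction j
    collects |S[i, j]| over negative entries, the product complex the positive
    entries. Identical left/right-hand sides across reactions map to a single
    shared complex node (coefficient comparison with tolerance
    ``COMPLEX_MATCH_TOL`` for float stoichiometries), so all exchange
    reactions share one empty environment complex.

    Reactions whose substrate complex equals their product complex (only
    possible for an all-zero column) are excluded with a warning; their A
    column is zero and S = Y.A still holds.
    """
    m, r = model.S.shape
    columns = []          # composition vectors, one per complex
    catalogue = []        # dicts metabolite -> coefficient
    sub_idx = np.zeros(r, dtype=int)
    prod_idx = np.zeros(r, dtype=int)
    excluded = []

    def find_or_append(vec):
        for k, col in enumerate(columns):
            if np.max(np.abs(col - vec)) <= COMPLEX_MATCH_TOL * max(
                    1.0, np.max(np.abs(col)), np.max(np.abs(vec)) if vec.size else 1.0):
                return k
        columns.append(vec)
        catalogue.append({model.metabolite_ids[i]: float(vec[i])
                          for i in np.nonzero(vec)[0]})
        return len(columns) - 1

    for j in range(r):
        col = model.S[:, j]
        head = np.where(col < 0, -col, 0.0)   # substrate complex composition
        tail = np.where(col > 0, col, 0.0)    # product complex composition
        hi = find_or_append(head)
        ti = find_or_append(tail)
        if hi == ti:
            warnings.warn(
                f"reaction {model.reaction_ids[j]} has identical substrate and "
                "product complexes (null transformation); excluded from the "
                "complex graph", stacklevel=2)
            excluded.append(model.reaction_ids[j])
            sub_idx[j] = prod_idx[j] = -1
            continue
        sub_idx[j] = hi
        prod_idx[j] = ti

    c = len(columns)
    Y = np.column_stack(columns) if c else np.zeros((m, 0))
    A = np.zeros((c, r))
    for j in range(r):
        if sub_idx[j] >= 0:
            A[sub_idx[j], j] = -1.0
            A[prod_idx[j], j] = +1.0
    labels = [_complex_label(comp, model.metabolite_ids) for comp in catalogue]
    return ComplexDecomposition(Y, A, catalogue, labels,
                                list(model.metabolite_ids),
                                list(model.reaction_ids), excluded)


def complex_activity(decomp, v):
    """Activity vector A.v (length c) of a flux distribution."""
    v = np.asarray(v, dtype=float)
    if v.shape[-1] != decomp.A.shape[1]:
        raise ValueError(
            f"flux vector has {v.shape[-1]} entries, decomposition has "
            f"{decomp.A.shape[1]} reactions")
    return v @ decomp.A.T if v.ndim > 1 else decomp.A @ v


def structurally_never_balanced(decomp):
    """Complexes whose incident reactions are all incoming or all outgoing.

    Such complexes have nonzero activity in every strictly positive flux
    distribution; the classification is purely topological.
    """
    out = set()
    for i in range(decomp.n_complexes):
        row = decomp.A[i]
        has_in = np.any(row > 0)
        has_out = np.any(row < 0)
        if (has_in or has_out) and not (has_in and has_out):
            out.add(i)
    return out


@dataclass
class BalancedSet:
    """Result of a balance classification.

    ``balanced`` holds complex indices; ``activity_ranges`` the per-complex
    (min, max) activity over the queried flux space (``None`` for the
    single-distribution basis); ``basis`` records how the classification was
    obtained (``"structural"``, ``"flux-space"`` or ``"single-distribution"``).
    """

    balanced: set
    basis: str
    epsilon: float
    activity_ranges: Optional[np.ndarray] = None
    labels: Optional[list] = None

    def balanced_labels(self):
        return {self.labels[i] for i in self.balanced} if self.labels else None


def _budget_rows(decomp, objective_kind):
    """Auxiliary-variable rows enforcing sum of |activities| (cbfba) or
    sum of fluxes (pfba) below a budget; returns (A_ub, b_ub, n_aux, budget_row).

    Variables are ordered (v, t). For cbfba: t_i >= ±A_i.v and sum t <= B.
    For pfba (irreversible model), the budget is linear: sum v <= B.
    """
    c, r = decomp.A.shape
    if objective_kind == "pfba":
        return np.ones((1, r)), 0
    if objective_kind != "cbfba":
        raise ValueError(f"unknown objective kind {objective_kind!r}")
    # rows: [A, -I; -A, -I] t-linearization, then [0, 1^T] budget row
    top = np.hstack([decomp.A, -np.eye(c)])
    bot = np.hstack([-decomp.A, -np.eye(c)])
    budget = np.hstack([np.zeros(r), np.ones(c)])
    return np.vstack([top, bot, budget]), c


def balanced_over_space(model, decomp, epsilon=ACTIVITY_EPSILON,
                        objective_kind=None, budget=None, budget_tol=1e-6,
                        extra_bounds=None):
    """Identify complexes balanced over a flux space via 2c LPs.

    The space is ``{v : S v = 0, lb <= v <= ub}``, optionally intersected with
    per-reaction interval constraints (``extra_bounds``: reaction id ->
    (lo, hi), e.g. experimental confidence intervals) and/or an activity or
    flux budget (``objective_kind`` in {"cbfba", "pfba"} with ``budget`` the
    corresponding optimum; the budget is enforced as <= budget*(1+budget_tol)).

    Complex i is balanced iff its activity range is within ``±epsilon``.
    """
    work = model
    if extra_bounds:
        from .model import ScenarioConstraints, apply_scenario
        work = apply_scenario(model, ScenarioConstraints("extra", dict(extra_bounds)))
    c, r = decomp.A.shape
    b_eq = np.zeros(work.n_metabolites)

    if objective_kind is None:
        A_eq = work.S
        A_ub = None
        b_ub = None
        bounds = work.bounds
        n_aux = 0
    elif objective_kind == "pfba":
        if budget is None:
            raise ValueError("a budget is required with objective_kind")
        A_eq = work.S
        A_ub = np.ones((1, r))
        b_ub = np.array([budget * (1.0 + budget_tol)])
        bounds = work.bounds
        n_aux = 0
    else:
        if budget is None:
            raise ValueError("a budget is required with objective_kind")
        rows, n_aux = _budget_rows(decomp, "cbfba")
        A_ub = rows
        b_ub = np.concatenate([np.zeros(2 * c),
                               [budget * (1.0 + budget_tol)]])
        A_eq = np.hstack([work.S, np.zeros((work.n_metabolites, n_aux))])
        bounds = work.bounds + [(0, None)] * n_aux
    ranges = np.zeros((c, 2))
    for i in range(c):
        obj = np.concatenate([decomp.A[i], np.zeros(n_aux)])
        _, lo = solve_lp(obj, A_eq=A_eq, b_eq=b_eq, A_ub=A_ub, b_ub=b_ub,
                         bounds=bounds)
        _, hi = solve_lp(obj, A_eq=A_eq, b_eq=b_eq, A_ub=A_ub, b_ub=b_ub,
                         bounds=bounds, maximize=True)
        ranges[i] = (lo, hi)
    balanced = {i for i in range(c)
                if ranges[i, 0] >= -epsilon and ranges[i, 1] <= epsilon}
    return BalancedSet(balanced, "flux-space", epsilon, ranges, list(decomp.labels))


def balanced_in_distribution(decomp, v, epsilon=ACTIVITY_EPSILON,
                             feasibility_tol=1e-6):
    """Complexes balanced in a single steady-state flux distribution.

    Returns ``{i : |A_i.v| <= epsilon}`` after checking that v is a steady
    state of the reconstructed S = Y.A (``||S v||_inf <= feasibility_tol``).
    """
    v = np.asarray(v, dtype=float)
    resid = np.max(np.abs(decomp.Y @ (decomp.A @ v))) if decomp.Y.size else 0.0
    if resid > feasibility_tol:
        raise ValueError(
            f"v is not a steady state: ||S v||_inf = {resid:.3e} > "
            f"{feasibility_tol}")
    act = complex_activity(decomp, v)
    balanced = {i for i in range(decomp.n_complexes) if abs(act[i]) <= epsilon}
    return BalancedSet(balanced, "single-distribution", epsilon,
                       labels=list(decomp.labels))


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------

def write_complex_graph(decomp, path):
    """Write the complex graph as an edge-list TSV (from, to, reaction_id)."""
    import pandas as pd

    rows = []
    for j, rid in enumerate(decomp.reaction_ids):
        col = decomp.A[:, j]
        sub = np.where(col < 0)[0]
        prod = np.where(col > 0)[0]
        if sub.size and prod.size:
            rows.append((decomp.labels[sub[0]], decomp.labels[prod[0]], rid))
    pd.DataFrame(rows, columns=["complex_from", "complex_to", "reaction_id"]
                 ).to_csv(path, sep="\t", index=False)


def write_matrices(decomp, y_path, a_path):
    """Write Y and A as MatrixMarket sparse files."""
    import scipy.io
    import scipy.sparse as sp

    scipy.io.mmwrite(str(y_path), sp.csr_matrix(decomp.Y))
    scipy.io.mmwrite(str(a_path), sp.csr_matrix(decomp.A))
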