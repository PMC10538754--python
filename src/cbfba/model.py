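"""Model input and preprocessing.

Reads genome-scale or toy metabolic models from SBML, applies scenario
constraints (measured uptake/secretion/growth rates), splits reversible
reactions into irreversible pairs, and prunes dead-end metabolites and
blocked reactions so that downstream stages operate on an irreversible
network in which every reaction can carry flux.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from ._lp import FEASIBILITY_TOL, solve_lp
from .errors import CbfbaError, InfeasibleProblemError, InfeasibleScenarioError

#: cap applied to unbounded / infinite SBML flux bounds (mmol gDW^-1 h^-1)
DEFAULT_BOUND_CAP = 1000.0

#: flux magnitude below which a reaction counts as blocked (mmol gDW^-1 h^-1)
BLOCKED_THRESHOLD = 1e-6

#: suffix appended to the reverse part of a split reversible reaction
REVERSE_SUFFIX = "__rev"


@dataclass
class MetabolicModel:
    """A stoichiometric model with flux bounds.

    Attributes
    ----------
    metabolite_ids, reaction_ids : list of str
        Ordered identifiers; rows and columns of ``S`` respectively.
    S : ndarray, shape (m, r)
        Stoichiometric matrix (substrates negative, products positive).
    lower_bounds, upper_bounds : ndarray, shape (r,)
        Flux bounds in mmol gDW^-1 h^-1.
    subsystems : dict, optional
        reaction id -> pathway label.
    biomass_reaction : str, optional
        Designated growth reaction (receives scenario growth-rate bounds).
    """

    metabolite_ids: list
    reaction_ids: list
    S: np.ndarray
    lower_bounds: np.ndarray
    upper_bounds: np.ndarray
    subsystems: Optional[dict] = None
    biomass_reaction: Optional[str] = None

    def __post_init__(self):
        self.S = np.asarray(self.S, dtype=float)
        self.lower_bounds = np.asarray(self.lower_bounds, dtype=float)
        self.upper_bounds = np.asarray(self.upper_bounds, dtype=float)
        m, r = self.S.shape
        if len(self.metabolite_ids) != m or len(self.reaction_ids) != r:
            raise ValueError(
                f"S is {m}x{r} but {len(self.metabolite_ids)} metabolites / "
                f"{len(self.reaction_ids)} reactions were given")
        if self.lower_bounds.shape != (r,) or self.upper_bounds.shape != (r,):
            raise ValueError("bound vectors must have one entry per reaction")
        bad = np.where(self.lower_bounds > self.upper_bounds)[0]
        if bad.size:
            raise ValueError(
                "lower bound exceeds upper bound for reactions "
                + ", ".join(self.reaction_ids[j] for j in bad[:5]))
        if len(set(self.reaction_ids)) != r:
            raise ValueError("duplicate reaction ids")
        self._rxn_index = {rid: j for j, rid in enumerate(self.reaction_ids)}
        self._met_index = {mid: i for i, mid in enumerate(self.metabolite_ids)}

    # -- basic accessors -------------------------------------------------
    @property
    def n_metabolites(self):
        return self.S.shape[0]

    @property
    def n_reactions(self):
        return self.S.shape[1]

    @property
    def is_irreversible(self):
        return bool(np.all(self.lower_bounds >= 0))

    def reaction_index(self, reaction_id):
        return self._rxn_index[reaction_id]

    def metabolite_index(self, metabolite_id):
        return self._met_index[metabolite_id]

    @property
    def bounds(self):
        """Per-reaction (lower, upper) tuples, as consumed by the LP layer."""
        return list(zip(self.lower_bounds, self.upper_bounds))

    def copy(self):
        return MetabolicModel(
            list(self.metabolite_ids), list(self.reaction_ids), self.S.copy(),
            self.lower_bounds.copy(), self.upper_bounds.copy(),
            dict(self.subsystems) if self.subsystems else None,
            self.biomass_reaction)

    def with_bounds(self, lower, upper):
        return MetabolicModel(
            list(self.metabolite_ids), list(self.reaction_ids), self.S.copy(),
            np.asarray(lower, float), np.asarray(upper, float),
            dict(self.subsystems) if self.subsystems else None,
            self.biomass_reaction)


@dataclass
class ScenarioConstraints:
    """Measured bounds for one strain/condition.

    ``bounds`` maps reaction id -> (lower, upper); ``growth_rate`` (h^-1) is
    applied to the model's designated biomass reaction.
    """

    strain_id: str = "scenario"
    bounds: dict = field(default_factory=dict)
    growth_rate: Optional[tuple] = None

    def __post_init__(self):
        for rid, (lo, hi) in self.bounds.items():
            if lo > hi:
                raise ValueError(f"scenario bound for {rid} has lower > upper")
        if self.growth_rate is not None and self.growth_rate[0] > self.growth_rate[1]:
            raise ValueError("growth rate lower bound exceeds upper bound")


@dataclass
class SplitMap:
    """Book-keeping for reversible-reaction splitting.

    ``pairs`` maps each original reaction id to ``(forward_id, reverse_id)``
    with ``reverse_id is None`` for reactions that were already irreversible.
    Net flux of the original reaction is forward minus reverse.
    """

    original_reaction_ids: list
    split_reaction_ids: list
    pairs: dict

    @property
    def is_identity(self):
        return all(rev is None for (_, rev) in self.pairs.values())


# ---------------------------------------------------------------------------
# SBML / cobra interop
# ---------------------------------------------------------------------------

def from_cobra(cobra_model, bound_cap=DEFAULT_BOUND_CAP):
    """Convert a :class:`cobra.Model` into a :class:`MetabolicModel`.

    Infinite or out-of-range bounds are capped at ``±bound_cap`` so every
    LP/QP stage and the sampler work on a finite box.
    """
    import cobra.util.array as cua

    metabolite_ids = [m.id for m in cobra_model.metabolites]
    reaction_ids = [r.id for r in cobra_model.reactions]
    S = cua.create_stoichiometric_matrix(cobra_model, array_type="dense")
    lb = np.array([r.lower_bound for r in cobra_model.reactions], dtype=float)
    ub = np.array([r.upper_bound for r in cobra_model.reactions], dtype=float)
    lb = np.clip(lb, -bound_cap, bound_cap)
    ub = np.clip(ub, -bound_cap, bound_cap)
    subsystems = {r.id: r.subsystem for r in cobra_model.reactions if r.subsystem}
    biomass = None
    try:
        from cobra.util.solver import linear_reaction_coefficients
        coeffs = linear_reaction_coefficients(cobra_model)
        if coeffs:
            biomass = max(coeffs, key=lambda rxn: abs(coeffs[rxn])).id
    except Exception:  # objective may be unset/nonlinear; biomass stays None
        pass
    return MetabolicModel(metabolite_ids, reaction_ids, S, lb, ub,
                          subsystems or None, biomass)


def to_cobra(model, model_id="cbfba_model"):
    """Convert a :class:`MetabolicModel` to a :class:`cobra.Model` (for SBML export)."""
    import cobra

    cm = cobra.Model(model_id)
    mets = {mid: cobra.Metabolite(mid, compartment="c") for mid in model.metabolite_ids}
    cm.add_metabolites(list(mets.values()))
    reactions = []
    for j, rid in enumerate(model.reaction_ids):
        rxn = cobra.Reaction(rid)
        rxn.lower_bound = float(model.lower_bounds[j])
        rxn.upper_bound = float(model.upper_bounds[j])
        if model.subsystems and rid in model.subsystems:
            rxn.subsystem = model.subsystems[rid]
        reactions.append(rxn)
    cm.add_reactions(reactions)
    for j, rid in enumerate(model.reaction_ids):
        col = model.S[:, j]
        stoich = {mets[model.metabolite_ids[i]]: float(col[i])
                  for i in np.nonzero(col)[0]}
        cm.reactions.get_by_id(rid).add_metabolites(stoich)
    if model.biomass_reaction is not None:
        cm.objective = model.biomass_reaction
    return cm


def read_model(path, bound_cap=DEFAULT_BOUND_CAP):
    """Read an SBML (L2/L3, FBC) model file into a :class:`MetabolicModel`.

    Identifiers are preserved verbatim. Missing or infinite flux bounds are
    signalled with a warning and replaced by ``±bound_cap``.
    """
    import cobra.io

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cobra_model = cobra.io.read_sbml_model(str(path))
    except Exception as exc:  # noqa: BLE001 - translate into package error
        raise CbfbaError(f"could not read SBML model from {path!r}: {exc}") from exc
    raw_lb = np.array([r.lower_bound for r in cobra_model.reactions], dtype=float)
    raw_ub = np.array([r.upper_bound for r in cobra_model.reactions], dtype=float)
    n_capped = int(np.sum(raw_lb < -bound_cap) + np.sum(raw_ub > bound_cap))
    if n_capped:
        warnings.warn(
            f"{n_capped} flux bounds exceeded ±{bound_cap} and were capped",
            stacklevel=2)
    return from_cobra(cobra_model, bound_cap=bound_cap)


def write_model(model, path):
    """Write a :class:`MetabolicModel` to SBML."""
    import cobra.io

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cobra.io.write_sbml_model(to_cobra(model), str(path))


def read_scenario(path, strain_id=None, growth_rate=None):
    """Read a scenario constraint table (CSV/TSV: reaction_id, lower, upper)."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    required = {"reaction_id", "lower", "upper"}
    if not required.issubset(df.columns):
        raise CbfbaError(
            f"scenario table {path!r} must have columns {sorted(required)}, "
            f"found {list(df.columns)}")
    bounds = {str(row.reaction_id): (float(row.lower), float(row.upper))
              for row in df.itertuples()}
    return ScenarioConstraints(strain_id or "scenario", bounds, growth_rate)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def apply_scenario(model, scenario):
    """Intersect model bounds with scenario bounds (tightest of the two).

    Idempotent; raises :class:`InfeasibleScenarioError` if any intersection
    is empty, and :class:`KeyError` if a scenario reaction is unknown.
    """
    lb = model.lower_bounds.copy()
    ub = model.upper_bounds.copy()
    items = dict(scenario.bounds)
    if scenario.growth_rate is not None:
        if model.biomass_reaction is None:
            raise CbfbaError("scenario sets a growth rate but the model has "
                             "no designated biomass reaction")
        items[model.biomass_reaction] = scenario.growth_rate
    violations = []
    for rid, (lo, hi) in items.items():
        j = model.reaction_index(rid)  # KeyError for unknown reactions
        lb[j] = max(lb[j], lo)
        ub[j] = min(ub[j], hi)
        if lb[j] > ub[j]:
            violations.append((rid, lb[j], ub[j]))
    if violations:
        raise InfeasibleScenarioError(
            "empty bound intersection for "
            + ", ".join(f"{rid} [{lo}, {hi}]" for rid, lo, hi in violations),
            forced_constraints=violations)
    return model.with_bounds(lb, ub)


def split_reversible(model):
    """Split every reversible reaction into a forward/reverse irreversible pair.

    The forward column keeps the original id and stoichiometry with bounds
    ``(max(0, lb), max(0, ub))``; the reverse column is the negated
    stoichiometry with bounds ``(max(0, -ub), -lb)``. Net flux of the original
    reaction is forward minus reverse.

    Returns
    -------
    (MetabolicModel, SplitMap)
    """
    cols, ids, lbs, ubs = [], [], [], []
    pairs = {}
    for j, rid in enumerate(model.reaction_ids):
        lo, hi = model.lower_bounds[j], model.upper_bounds[j]
        col = model.S[:, j]
        if lo >= 0:
            cols.append(col); ids.append(rid)
            lbs.append(lo); ubs.append(hi)
            pairs[rid] = (rid, None)
        else:
            rev_id = rid + REVERSE_SUFFIX
            cols.append(col); ids.append(rid)
            lbs.append(0.0); ubs.append(max(0.0, hi))
            cols.append(-col); ids.append(rev_id)
            lbs.append(max(0.0, -hi)); ubs.append(-lo)
            pairs[rid] = (rid, rev_id)
    subsystems = None
    if model.subsystems:
        subsystems = {}
        for rid, (fwd, rev) in pairs.items():
            if rid in model.subsystems:
                subsystems[fwd] = model.subsystems[rid]
                if rev is not None:
                    subsystems[rev] = model.subsystems[rid]
    split = MetabolicModel(
        list(model.metabolite_ids), ids, np.column_stack(cols),
        np.array(lbs), np.array(ubs), subsystems, model.biomass_reaction)
    return split, SplitMap(list(model.reaction_ids), ids, pairs)


def merge_split_fluxes(v_split, split_map):
    """Map a flux vector on the split model back to net fluxes on the original.

    ``net = forward - reverse`` per original reaction.
    """
    v_split = np.asarray(v_split, dtype=float)
    if v_split.shape[-1] != len(split_map.split_reaction_ids):
        raise ValueError(
            f"flux vector has {v_split.shape[-1]} entries, split model has "
            f"{len(split_map.split_reaction_ids)} reactions")
    idx = {rid: j for j, rid in enumerate(split_map.split_reaction_ids)}
    out = np.zeros(v_split.shape[:-1] + (len(split_map.original_reaction_ids),))
    for k, rid in enumerate(split_map.original_reaction_ids):
        fwd, rev = split_map.pairs[rid]
        if fwd is not None:  # a pruned direction contributes zero net flux
            out[..., k] = v_split[..., idx[fwd]]
        if rev is not None:
            out[..., k] = out[..., k] - v_split[..., idx[rev]]
    return out


def _assert_feasible(model):
    """Raise InfeasibleScenarioError if the flux space is empty."""
    try:
        solve_lp(np.zeros(model.n_reactions), A_eq=model.S,
                 b_eq=np.zeros(model.n_metabolites), bounds=model.bounds)
    except InfeasibleProblemError as exc:
        forced = [(rid, model.lower_bounds[j], model.upper_bounds[j])
                  for j, rid in enumerate(model.reaction_ids)
                  if model.lower_bounds[j] > 0 or model.upper_bounds[j] < 0]
        raise InfeasibleScenarioError(
            f"no steady state satisfies the scenario bounds ({exc}); "
            f"forced constraints: {forced}", forced_constraints=forced) from exc


def flux_extrema(model, reactions=None):
    """Per-reaction (min, max) flux over the steady-state flux space.

    This is plain flux variability over ``{v : S v = 0, lb <= v <= ub}`` and
    is used for blocked-reaction detection.
    """
    if reactions is None:
        reactions = list(model.reaction_ids)
    b_eq = np.zeros(model.n_metabolites)
    out = {}
    for rid in reactions:
        j = model.reaction_index(rid)
        c = np.zeros(model.n_reactions)
        c[j] = 1.0
        _, lo = solve_lp(c, A_eq=model.S, b_eq=b_eq, bounds=model.bounds)
        _, hi = solve_lp(c, A_eq=model.S, b_eq=b_eq, bounds=model.bounds,
                         maximize=True)
        out[rid] = (lo, hi)
    return out


def prune(model, scenario=None, blocked_tol=BLOCKED_THRESHOLD):
    """Remove dead-end metabolites and blocked reactions for a scenario.

    Iterates to a fixed point: a metabolite with no producing or no consuming
    reaction is removed together with its incident reactions; a reaction whose
    flux cannot exceed ``blocked_tol`` in magnitude in any feasible steady
    state is removed. Reactions with a strictly positive lower bound encode
    measurements and are never removed.

    Raises
    ------
    InfeasibleScenarioError
        If the (scenario-constrained) flux space is empty.
    """
    if scenario is not None:
        model = apply_scenario(model, scenario)
    else:
        model = model.copy()
    _assert_feasible(model)

    keep_r = np.ones(model.n_reactions, dtype=bool)
    keep_m = np.ones(model.n_metabolites, dtype=bool)
    forced = model.lower_bounds > 0

    def submodel():
        subs = None
        if model.subsystems:
            subs = {rid: model.subsystems[rid]
                    for j, rid in enumerate(model.reaction_ids)
                    if keep_r[j] and rid in model.subsystems}
        biomass = model.biomass_reaction
        if biomass is not None and not keep_r[model.reaction_index(biomass)]:
            biomass = None
        return MetabolicModel(
            [mid for i, mid in enumerate(model.metabolite_ids) if keep_m[i]],
            [rid for j, rid in enumerate(model.reaction_ids) if keep_r[j]],
            model.S[np.ix_(keep_m, keep_r)],
            model.lower_bounds[keep_r], model.upper_bounds[keep_r],
            subs, biomass)

    changed = True
    while changed:
        changed = False
        # topological pass: dead-end metabolites and their incident reactions
        topo = True
        while topo:
            topo = False
            S = model.S
            for i in np.nonzero(keep_m)[0]:
                row = S[i, keep_r]
                # a reversible column could act as producer or consumer; after
                # splitting all lb >= 0, so sign of the entry decides the role
                if not (np.any(row > 0) and np.any(row < 0)):
                    dead_rxns = np.nonzero(np.abs(S[i, :]) > 0)[0]
                    if forced[dead_rxns].any() and np.any(np.abs(row) > 0):
                        raise InfeasibleScenarioError(
                            f"dead-end metabolite {model.metabolite_ids[i]} "
                            "is incident to a reaction with forced flux")
                    keep_m[i] = False
                    if np.any(keep_r[dead_rxns]):
                        keep_r[dead_rxns] = False
                        topo = True
                    changed = True
        # LP pass: blocked reactions
        sub = submodel()
        extrema = flux_extrema(sub)
        sub_ids = sub.reaction_ids
        for rid in sub_ids:
            lo, hi = extrema[rid]
            j = model.reaction_index(rid)
            if max(abs(lo), abs(hi)) < blocked_tol and not forced[j]:
                keep_r[j] = False
                changed = True
    return submodel()
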