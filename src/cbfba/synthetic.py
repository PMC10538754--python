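"""Bundled toy fixture and synthetic network generators.

The toy fixture is a six-metabolite, nine-reaction irreversible network with
an environment node O: an uptake E1 feeds metabolite A, which can either be
split into B and C (R1) and drained separately (E2, E3, and C->F via R5), or
routed through the linear chain A->D->E->F (R2..R4) and secreted (E4). Its
complex graph has exactly eight complexes {O, A, B, C, D, E, F, B+C}; the
complexes A, D, E, F are balanced over the whole flux cone (each of those
metabolites occurs in exactly one complex, so the complex activity coincides
with the metabolite's steady-state constraint), while B+C has only incoming
reactions and is therefore never balanced in a strictly positive flux
distribution. With the uptake fixed, total-flux minimization (pFBA) picks the
short split route and balances only {A, D, E, F}, whereas minimizing total
complex activity (cbFBA) picks the chain route, whose activity budget is
zero, balancing in addition B, C and O.

The random generators construct feasibility by design: reactions are laid
down along closed walks in a complex pool, so the superposition of the walk
indicator vectors is a strictly positive steady-state witness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .complexes import balanced_in_distribution, balanced_over_space, decompose
from .model import MetabolicModel, ScenarioConstraints, apply_scenario


@dataclass
class ToyFixture:
    """The toy network with its scenario and the expected balance structure."""

    model: MetabolicModel
    scenario: ScenarioConstraints
    n_complexes: int = 8
    expected_cone_balanced: frozenset = frozenset({"A", "D", "E", "F"})
    expected_pfba_balanced: frozenset = frozenset({"A", "D", "E", "F"})
    #: the cbFBA optimum balances at least these complexes (metabolite
    #: conservation ties the activity of B+C to those of B and C, so the
    #: zero-activity optimum balances the whole catalogue)
    expected_cbfba_balanced_superset: frozenset = frozenset(
        {"A", "B", "C", "D", "E", "F", "O"})
    expected_structural_never_balanced: frozenset = frozenset({"B+C"})

    def verify(self):
        """Run the pipeline on the fixture and check every expected statement.

        Raises ``AssertionError`` on any mismatch, so an incorrect
        transcription fails loudly rather than being silently adjusted.
        """
        from .optimize import solve_cbfba, solve_pfba

        constrained = apply_scenario(self.model, self.scenario)
        dec = decompose(constrained)
        assert dec.n_complexes == self.n_complexes, \
            f"expected {self.n_complexes} complexes, got {dec.n_complexes}"
        cone = balanced_over_space(self.model, dec)
        assert cone.balanced_labels() == set(self.expected_cone_balanced), \
            f"cone-balanced set is {cone.balanced_labels()}"
        from .complexes import structurally_never_balanced
        structural = {dec.labels[i] for i in structurally_never_balanced(dec)}
        assert self.expected_structural_never_balanced <= structural, \
            f"structural never-balanced set is {structural}"
        pfba = solve_pfba(constrained, dec)
        pfba_bal = balanced_in_distribution(dec, pfba.v).balanced_labels()
        assert pfba_bal == set(self.expected_pfba_balanced), \
            f"pFBA balanced set is {pfba_bal}"
        cb = solve_cbfba(constrained, dec)
        cb_bal = balanced_in_distribution(dec, cb.v).balanced_labels()
        assert set(self.expected_cbfba_balanced_superset) <= cb_bal, \
            f"cbFBA balanced set is {cb_bal}"
        assert len(cb_bal) > len(pfba_bal), \
            "cbFBA must balance strictly more complexes than pFBA"
        return True


def toy_network():
    """Build the toy fixture (six metabolites, nine irreversible reactions).

    Reactions E1..E4 are exchanges with the environment, R1..R5 internal;
    the scenario fixes the uptake E1 to 1 mmol gDW^-1 h^-1.
    """
    metabolites = ["A", "B", "C", "D", "E", "F"]
    #                E1   E2   E3   E4   R1   R2   R3   R4   R5
    S = np.array([
        [1,   0,   0,   0,  -1,  -1,   0,   0,   0],   # A
        [0,  -1,   0,   0,   1,   0,   0,   0,   0],   # B
        [0,   0,  -1,   0,   1,   0,   0,   0,  -1],   # C
        [0,   0,   0,   0,   0,   1,  -1,   0,   0],   # D
        [0,   0,   0,   0,   0,   0,   1,  -1,   0],   # E
        [0,   0,   0,  -1,   0,   0,   0,   1,   1],   # F
    ], dtype=float)
    reactions = ["E1", "E2", "E3", "E4", "R1", "R2", "R3", "R4", "R5"]
    lb = np.zeros(9)
    ub = np.full(9, 1000.0)
    model = MetabolicModel(metabolites, reactions, S, lb, ub)
    scenario = ScenarioConstraints("toy", {"E1": (1.0, 1.0)})
    return ToyFixture(model, scenario)


def toy_sbml_path():
    """Path to the bundled SBML copy of the toy network."""
    from importlib.resources import files
    return files("cbfba").joinpath("data/toy_network.xml")


def toy_scenario_path():
    """Path to the bundled scenario constraint table of the toy network."""
    from importlib.resources import files
    return files("cbfba").joinpath("data/toy_scenario.tsv")


# ---------------------------------------------------------------------------
# Random feasible networks
# ---------------------------------------------------------------------------

@dataclass
class SyntheticSpec:
    """Parameters of the random-network generator.

    ``m`` metabolites and ``r`` reactions; ``exchange_fraction`` steers how
    often closed walks pass through the environment complex; complexes have
    at most ``max_complex_size`` metabolites with integer coefficients up to
    ``max_coefficient`` (small integers keep the decomposition exact);
    ``bound_upper`` is the common flux upper bound.
    """

    m: int = 6
    r: int = 10
    seed: int = 0
    exchange_fraction: float = 0.3
    max_complex_size: int = 2
    max_coefficient: int = 3
    bound_upper: float = 10.0

    def __post_init__(self):
        if self.m < 2 or self.r < 2:
            raise ValueError("need m >= 2 metabolites and r >= 2 reactions "
                             "(a closed flow needs at least two reactions)")


def random_network(spec):
    """Generate a random feasible irreversible network.

    Reactions are the edges of random closed walks over a pool of complexes
    (singletons, a few random pairs, and the environment complex). Each walk
    contributes one unit of flux to every edge it traverses, so the summed
    indicator vector is an explicit positive steady-state witness and the
    model is feasible by construction. Identical seeds give identical models.

    Returns
    -------
    (MetabolicModel, ndarray)
        The model and its steady-state witness vector (``S @ witness == 0``).
    """
    rng = np.random.default_rng(spec.seed)
    met_ids = [f"M{i}" for i in range(spec.m)]
    # complex pool: environment + singletons + random small multi-metabolite
    pool = [np.zeros(spec.m)]
    for i in range(spec.m):
        e = np.zeros(spec.m)
        e[i] = 1.0
        pool.append(e)
    n_multi = max(1, spec.m // 2)
    for _ in range(8 * n_multi):
        if len(pool) >= 1 + spec.m + n_multi:
            break
        size = int(rng.integers(2, spec.max_complex_size + 1)) \
            if spec.max_complex_size >= 2 else 1
        members = rng.choice(spec.m, size=min(size, spec.m), replace=False)
        vec = np.zeros(spec.m)
        vec[members] = rng.integers(1, spec.max_coefficient + 1,
                                    size=len(members)).astype(float)
        if not any(np.array_equal(vec, p) for p in pool):
            pool.append(vec)

    # every reaction belongs to exactly one closed walk carrying unit flux,
    # so the all-ones vector is a positive steady-state witness; walks may
    # revisit nodes (parallel reactions are distinct columns)
    order = []   # list of (substrate complex idx, product complex idx)

    def add_walk(nodes):
        for a, b in zip(nodes, nodes[1:] + nodes[:1]):
            order.append((a, b))

    def random_walk_nodes(length):
        use_env = rng.random() < spec.exchange_fraction
        nodes = [0 if use_env else int(rng.integers(1, len(pool)))]
        while len(nodes) < length:
            nxt = int(rng.integers(len(pool)))
            if nxt == nodes[-1]:
                continue
            if len(nodes) == length - 1 and nxt == nodes[0]:
                continue
            nodes.append(nxt)
        return nodes

    remaining = spec.r
    if spec.r >= spec.m + 1:
        # covering walk guarantees every metabolite appears
        nodes = [0] + list(int(x) for x in rng.permutation(
            np.arange(1, spec.m + 1)))
        if spec.r - len(nodes) == 1:  # avoid a leftover of one (min walk is 2)
            candidates = [i for i in range(1, len(pool)) if i != nodes[-1]]
            nodes.append(int(rng.choice(candidates)))
        add_walk(nodes)
        remaining = spec.r - len(nodes)
    while remaining > 0:
        length = remaining if remaining <= 5 else (4 if remaining == 6 else 5)
        add_walk(random_walk_nodes(length))
        remaining = spec.r - len(order)

    S = np.column_stack([pool[b] - pool[a] for (a, b) in order])
    witness = np.ones(len(order))
    used = np.any(S != 0, axis=1)
    S = S[used]
    met_ids = [mid for mid, u in zip(met_ids, used) if u]
    rxn_ids = [f"R{j}" for j in range(len(order))]
    ub = max(spec.bound_upper, 2.0 * float(witness.max()))
    model = MetabolicModel(met_ids, rxn_ids, S, np.zeros(len(order)),
                          np.full(len(order), ub))
    assert np.max(np.abs(model.S @ witness)) < 1e-12
    return model, witness


def planted_balanced_network(k_chains, seed=0):
    """Build chains whose middle metabolite occurs in exactly one complex.

    Each chain is O -> X_i -> D_i -> Y_i -> O; metabolite D_i appears only in
    the singleton complex D_i, whose activity therefore coincides with the
    steady-state constraint of D_i — the complex is balanced over the whole
    flux cone by construction. A distractor motif O -> G -> P+Q with separate
    drains for P and Q contributes complexes (P+Q, P, Q) that are never
    balanced in positive flux distributions.

    Returns
    -------
    (MetabolicModel, set of str)
        The model and the labels of the planted cone-balanced complexes.
    """
    if k_chains < 1:
        raise ValueError("k_chains must be >= 1")
    rng = np.random.default_rng(seed)
    mets = []
    cols = []
    rxn_ids = []

    def met_index(name):
        if name not in mets:
            mets.append(name)
        return mets.index(name)

    def add_reaction(rid, consumed, produced):
        rxn_ids.append(rid)
        cols.append((dict(consumed), dict(produced)))

    planted = set()
    for i in range(1, k_chains + 1):
        x, d, y = f"X{i}", f"D{i}", f"Y{i}"
        add_reaction(f"Ein{i}", {}, {x: 1})
        add_reaction(f"Ra{i}", {x: 1}, {d: 1})
        add_reaction(f"Rb{i}", {d: 1}, {y: 1})
        add_reaction(f"Eout{i}", {y: 1}, {})
        planted.add(d)
    add_reaction("Eg", {}, {"G": 1})
    add_reaction("Rg", {"G": 1}, {"P": 1, "Q": 1})
    add_reaction("Ep", {"P": 1}, {})
    add_reaction("Eq", {"Q": 1}, {})
    for rid, (consumed, produced) in zip(rxn_ids, cols):
        for name in list(consumed) + list(produced):
            met_index(name)
    S = np.zeros((len(mets), len(rxn_ids)))
    for j, (consumed, produced) in enumerate(cols):
        for name, coeff in consumed.items():
            S[met_index(name), j] -= coeff
        for name, coeff in produced.items():
            S[met_index(name), j] += coeff
    ub = float(rng.uniform(5.0, 15.0))
    model = MetabolicModel(mets, rxn_ids, S, np.zeros(len(rxn_ids)),
                          np.full(len(rxn_ids), ub))
    return model, planted
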