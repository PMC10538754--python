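import numpy as np
import pytest

import cbfba as cb


@pytest.fixture(scope="session")
def toy():
    return cb.toy_network()


@pytest.fixture(scope="session")
def toy_constrained(toy):
    """Toy model with the uptake scenario applied, plus its decomposition."""
    model = cb.apply_scenario(toy.model, toy.scenario)
    return model, cb.decompose(model)


@pytest.fixture(scope="session")
def toy_solutions(toy_constrained):
    model, dec = toy_constrained
    return {"cbfba": cb.solve_cbfba(model, dec),
            "pfba": cb.solve_pfba(model, dec)}


def small_random_models(n, max_r=8, start_seed=0):
    """Seeded random models small enough for the enumeration oracles."""
    out = []
    for seed in range(start_seed, start_seed + n):
        m = 3 + seed % 3
        r = min(max_r, 5 + seed % 4)
        model, witness = cb.random_network(cb.SyntheticSpec(m=m, r=r, seed=seed))
        out.append((seed, model, witness))
    return out


@pytest.fixture(scope="session")
def oracle_suite():
    return small_random_models(12)
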