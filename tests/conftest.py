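import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import bymmap as bm

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_strata(rows):
    """Build a StrataTable from (area, band, gender, pop, deaths) tuples."""
    return bm.StrataTable(
        pd.DataFrame(
            rows, columns=["area_id", "age_band", "gender", "population", "deaths"]
        )
    )


def random_strata(rng, n_areas=4, n_bands=3, max_pop=500):
    """A random valid strata table (deaths <= population, some zeros)."""
    rows = []
    for a in range(n_areas):
        for b in range(n_bands):
            for g in bm.GENDERS:
                pop = int(rng.integers(0, max_pop))
                deaths = int(rng.integers(0, pop + 1)) if pop else 0
                rows.append((f"A{a:02d}", b, g, pop, deaths))
    return make_strata(rows)


@pytest.fixture(scope="session")
def path_graph():
    """Three areas in a path A-B-C."""
    return bm.AdjacencyGraph(("A", "B", "C"), ((0, 1), (1, 2)))


@pytest.fixture(scope="session")
def medium_sim():
    """A 10x10 simulated dataset with a moderately long default-prior fit,
    shared by summary/shrinkage-style tests."""
    spec = bm.SimulationSpec(
        seed=42, rows=10, cols=10, regime="uniform", alpha_true=0.3,
        tau_u_true=4.0, tau_v_true=25.0, e_range=(50.0, 150.0),
    )
    sim = bm.simulate_dataset(spec)
    cfg = bm.MCMCConfig(seed=7, n_iter=12_000, burn_in=3_000, thin=3)
    chain = bm.run_mcmc(sim.areas, sim.graph, cfg)
    return sim, chain
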