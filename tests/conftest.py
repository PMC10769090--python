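import numpy as np
import pandas as pd
import pytest

from reefscale import FoodWeb, SCMConfig, generate_scm_table


def make_web(S, links):
    """FoodWeb from (prey, predator) index pairs."""
    adj = np.zeros((S, S), dtype=bool)
    for j, i in links:
        adj[j, i] = True
    return FoodWeb(adjacency=adj, niche_values=np.linspace(0.1, 0.9, S))


@pytest.fixture(scope="session")
def chain_web():
    """A -> B -> C feeding chain (A basal)."""
    return make_web(3, [(0, 1), (1, 2)])


@pytest.fixture(scope="session")
def scm_sample():
    """One faithful SCM draw at n=10^4 with its ground truth."""
    cfg = SCMConfig(seed=0)
    data, truth = generate_scm_table(cfg)
    return cfg, data, truth


@pytest.fixture()
def toy_survey():
    """Three site-years: (1 survey, 8 spp), (2 surveys, 4 spp), (2 surveys, 6 spp)."""
    rows = []

    def add(site, survey, n_spp):
        for sp in range(n_spp):
            mass = 2.0 ** (sp + 1)
            rows.append(
                dict(site=site, year=2020, survey=survey, species=f"s{sp}",
                     mass=mass, abundance=10.0, biomass=10.0 * mass)
            )

    add("A", "v1", 8)
    add("B", "v1", 4)
    add("B", "v2", 4)
    add("C", "v1", 6)
    add("C", "v2", 6)
    return pd.DataFrame(rows)
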