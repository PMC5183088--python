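import numpy as np
import pytest
from hypothesis import settings

import occudyn as od
from occudyn.model import ModelParameters

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_lattice():
    """4 x 5 rook lattice with a 2-quadrat gap block."""
    return od.build_adjacency(4, 5, gap_ids={"q7", "q8"})


@pytest.fixture(scope="session")
def small_dataset():
    """Small synthetic scenario: 6 species on a 4 x 5 lattice."""
    cfg = od.ScenarioConfig(
        n_rows=4, n_cols=5, n_species=6, n_gap_quadrats=4, seed=11
    )
    return od.generate_dataset(cfg)


@pytest.fixture(scope="session")
def default_dataset():
    """Study-sized scenario: 42 species, 200 quadrats, 20 gap quadrats."""
    return od.generate_dataset(od.ScenarioConfig(seed=2))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_posterior(small_dataset):
    """A short but real MCMC run on the small scenario."""
    survey, lattice, _ = small_dataset
    cfg = od.SamplerConfig(n_chains=2, n_iter=600, burn_in=200, thin=4, seed=5)
    return od.run_chains(survey, lattice, cfg)


def random_params(n_species, n_quadrats, rng, scale=2.0):
    """A random in-bounds parameter state for oracle comparisons."""
    kw = {b: float(rng.uniform(-scale, scale)) for b in
          ("beta_o", "beta_s", "beta_sg", "beta_c", "beta_cg")}
    kw.update({s: float(rng.uniform(0.3, 3.0)) for s in
               ("sigma_o", "sigma_s", "sigma_sg", "sigma_c", "sigma_cg", "sigma_r")})
    for fam in ("o", "s", "sg", "c", "cg"):
        kw[f"eps_{fam}"] = rng.uniform(-scale, scale, n_species)
    r = rng.uniform(-1, 1, n_quadrats)
    kw["r"] = r - r.mean()
    return ModelParameters(**kw)
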