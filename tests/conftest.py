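import numpy as np
import pytest

from epibayes.model import CovariateGroup, GroupedDesign, standardize, standardize_phenotype
from epibayes.sampler import run_chain
from epibayes.simulate import MethylSimParams, simulate_methylation, simulate_sparse_phenotype


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_design(n=120, m=30, n_causal=4, ve=0.5, seed=7, C=(0.001, 0.01, 0.1)):
    """Small random design with a sparse linear signal, for sampler tests."""
    r = np.random.default_rng(seed)
    Z = standardize(r.normal(size=(n, m)))
    beta = np.zeros(m)
    idx = r.choice(m, size=n_causal, replace=False)
    beta[idx] = r.normal(0, np.sqrt(ve / n_causal), size=n_causal)
    g = Z @ beta
    e = r.normal(size=n)
    y = standardize_phenotype(g + e * np.sqrt(max(1 - ve, 1e-3)) / e.std())
    design = GroupedDesign(y=y, groups=[CovariateGroup("probes", Z, C)])
    return design, idx, beta


@pytest.fixture(scope="session")
def small_sim():
    """A small methylation dataset with a sparse phenotype."""
    params = MethylSimParams(n=150, m=120, k=4, p=0.3, tau=0.07, sp=1000.0,
                             vartheta=0.01, n_causal=6, ve=0.5, seed=3)
    ds = simulate_methylation(params)
    return simulate_sparse_phenotype(ds, seed=4)


@pytest.fixture(scope="session")
def small_chain(small_sim):
    """A short chain on the small simulated dataset (shared across tests)."""
    Z = standardize(small_sim.O)
    y = standardize_phenotype(small_sim.y)
    design = GroupedDesign(
        y=y, groups=[CovariateGroup("probes", Z, (0.0001, 0.001, 0.01, 0.1))]
    )
    store = run_chain(design, iterations=800, burn_in=400, thin=2, seed=9)
    return design, store
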