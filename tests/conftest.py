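import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from thermadapt import simulate
from thermadapt.genotypes import GenotypeMatrix

settings.register_profile("suite", max_examples=25, deadline=None,
                          derandomize=True)
settings.load_profile("suite")


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_matrix(calls, pops, positions=None, chroms=None, tags=None):
    """Build a small GenotypeMatrix from explicit codes and labels."""
    calls = np.asarray(calls, dtype=np.int8)
    n_ind, n_loci = calls.shape
    individuals = pd.DataFrame({
        "individual_id": [f"f{i:02d}" for i in range(n_ind)],
        "population": pops,
        "ecotype": pops,
    })
    loci = pd.DataFrame({
        "locus_id": [f"L{j:04d}" for j in range(n_loci)],
        "tag_id": tags if tags is not None else [f"t{j:04d}" for j in range(n_loci)],
        "chrom": chroms if chroms is not None else ["chr1"] * n_loci,
        "pos_bp": positions if positions is not None else np.arange(n_loci) * 1000,
        "ref": ["A"] * n_loci,
        "alt": ["C"] * n_loci,
    })
    return GenotypeMatrix(calls=calls, individuals=individuals, loci=loci)


@pytest.fixture()
def two_deme_matrix():
    """Two diverged demes, 12 fish each, 60 loci, deterministic."""
    rng = np.random.default_rng(7)
    p = np.column_stack([rng.uniform(0.1, 0.4, 60), rng.uniform(0.6, 0.9, 60)])
    calls = np.vstack([
        rng.binomial(2, p[:, 0], size=(12, 60)),
        rng.binomial(2, p[:, 1], size=(12, 60)),
    ])
    return make_matrix(calls, ["north"] * 12 + ["south"] * 12)


@pytest.fixture(scope="session")
def default_simulation():
    """One mid-size simulation with planted clines shared across tests."""
    truth = simulate.default_truth(n_loci=3000, n_causal=15, seed=11)
    g, truth = simulate.simulate_island_genotypes(n_loci=3000, truth=truth)
    return g, truth
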