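import numpy as np
import pandas as pd
import pytest

from cycadiv.genodata import MISSING, GenotypeMatrix


def make_gm(calls, species, pops=None, locus_ids=None, positions=None, depth=None):
    """Assemble a small GenotypeMatrix from plain lists."""
    calls = np.asarray(calls, dtype=np.int8)
    n_ind, n_sites = calls.shape
    individuals = [f"I{i}" for i in range(n_ind)]
    pops = pops or list(species)
    locus_ids = locus_ids or [f"L{j}" for j in range(n_sites)]
    positions = positions or [1] * n_sites
    loci = pd.DataFrame({
        "locus_id": locus_ids,
        "pos": positions,
        "ref": ["A"] * n_sites,
        "alt": ["T"] * n_sites,
    })
    return GenotypeMatrix(
        individuals=individuals,
        loci=loci,
        calls=calls,
        pop_of=dict(zip(individuals, pops)),
        species_of=dict(zip(individuals, species)),
        depth=None if depth is None else np.asarray(depth, float),
    )


@pytest.fixture
def toy_gm():
    """4 diploids (2 CR in pop P1, 2 CT in pop P2), 3 single-SNP loci."""
    calls = [
        [0, 0, 2],
        [1, 0, 2],
        [1, MISSING, 0],
        [2, 1, 0],
    ]
    return make_gm(calls, species=["CR", "CR", "CT", "CT"],
                   pops=["P1", "P1", "P2", "P2"])


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
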