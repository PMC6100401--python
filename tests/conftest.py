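import numpy as np
import pytest

from scfp.chem_graph import key_set_from_pairs, parse_molecule
from scfp.synthetic import (fingerprint_dataset, generate_benchmark_set,
                            generate_connectivity_isomers)


@pytest.fixture(scope="session")
def keys3():
    """Amine / carbonyl / hydroxyl keys: the basic connectivity fixture."""
    return key_set_from_pairs(
        [("amine", "[NX3;H2]"), ("carbonyl", "[CX3]=[OX1]"),
         ("hydroxyl", "[OX2H]")],
        name="k3",
    )


@pytest.fixture(scope="session")
def glycine_like(keys3):
    """NCC(=O)CO: amine and hydroxyl separated by an in-chain carbonyl."""
    return parse_molecule("NCC(=O)CO", "smiles", source_id="glycine_like")


@pytest.fixture(scope="session")
def isomer_pool():
    """Shared pool of small generated molecules for fuzz/oracle tests."""
    ds, keys = generate_connectivity_isomers(60, seed=7, max_spacer=2)
    mols = [parse_molecule(s, "smiles", source_id=i)
            for s, i in zip(ds.smiles, ds.ids)]
    return mols, keys


@pytest.fixture(scope="session")
def benchmark_200():
    """The 100/100 benchmark set (seed 42) plus both representations."""
    ds = generate_benchmark_set(100, 100, rule="amine_carbonyl", seed=42)
    X_plain, X_scfp, y = fingerprint_dataset(ds)
    return ds, X_plain, X_scfp, y


@pytest.fixture(scope="session")
def separable_fixture():
    """Linearly separable binary fingerprints: 200 samples, 20 bits."""
    rng = np.random.default_rng(123)
    n = 100
    a = (rng.random((n, 20)) < np.r_[np.full(10, 0.9), np.full(10, 0.1)]).astype(np.uint8)
    b = (rng.random((n, 20)) < np.r_[np.full(10, 0.1), np.full(10, 0.9)]).astype(np.uint8)
    X = np.vstack([a, b])
    y = np.r_[np.ones(n, dtype=int), np.zeros(n, dtype=int)]
    return X, y


@pytest.fixture(scope="session")
def null_fixture(separable_fixture):
    """Same features, labels randomly permuted: no signal by construction."""
    X, y = separable_fixture
    rng = np.random.default_rng(321)
    return X, rng.permutation(y)
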