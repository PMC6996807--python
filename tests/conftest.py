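import numpy as np
import pytest

from rrgp import (RRMSpec, SyntheticConfig, TimeGrid, legendre_basis,
                  simulate_dataset)


@pytest.fixture(scope="session")
def basis20():
    return legendre_basis(TimeGrid(tuple(range(1, 21))), 2)


@pytest.fixture(scope="session")
def st_spec():
    return RRMSpec(traits=("WU",))


@pytest.fixture(scope="session")
def mt_spec():
    return RRMSpec(traits=("WU", "PSA"))


@pytest.fixture(scope="session")
def small_dataset():
    """60 related accessions x 20 days x 2 traits, default regime."""
    cfg = SyntheticConfig(n_accessions=60, n_markers=400, n_founders=20, seed=7)
    geno, grm, phenos, truth = simulate_dataset(cfg)
    return cfg, geno, grm, phenos, truth
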