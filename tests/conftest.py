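import numpy as np
import pandas as pd
import pytest

from surfaceqtl.surfaces import DEFAULT_GRID
from surfaceqtl.synthetic import (
    build_design,
    compute_kinship,
    simulate_genotypes,
    simulate_phenotypes,
)
from surfaceqtl.tables import EXAMPLE_DOMED_PARAMS, EXAMPLE_TROUGH_PARAMS


@pytest.fixture(scope="session")
def grid():
    return DEFAULT_GRID


@pytest.fixture(scope="session")
def small_population():
    """A compact simulated population shared across tests: 60 lines,
    3 chromosomes x 8 markers, default design, planted QTL at m02_004."""
    genotypes = simulate_genotypes(
        60, chromosomes=((8, 120.0), (8, 120.0), (8, 120.0)), seed=11
    )
    kinship = compute_kinship(genotypes)
    design = build_design()
    phenotypes = simulate_phenotypes(
        genotypes, design,
        causal_spec={"m02_004": (EXAMPLE_DOMED_PARAMS, EXAMPLE_TROUGH_PARAMS)},
        sigma_line=2.0, sigma_resid=3.0, kinship=kinship, seed=12,
    )
    return genotypes, kinship, design, phenotypes
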