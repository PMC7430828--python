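import warnings

import numpy as np
import pandas as pd
import pytest

from roegen.containers import Pedigree
from roegen.simdata import GenomeMap, MatingDesign, TraitModel, simulate_study

warnings.filterwarnings("ignore", category=RuntimeWarning)


@pytest.fixture(scope="session")
def small_study():
    """A compact two-cohort population with 1% missing genotypes."""
    return simulate_study(
        seed=11,
        design=MatingDesign.default(total_offspring=400),
        genome=GenomeMap.uniform(5, 80, 25.0),
        missing_rate=0.01,
    )


@pytest.fixture(scope="session")
def complete_study():
    """Same population scale with complete genotypes (no missingness)."""
    return simulate_study(
        seed=23,
        design=MatingDesign.default(total_offspring=800),
        genome=GenomeMap.uniform(6, 100, 25.0),
        missing_rate=0.0,
    )


@pytest.fixture(scope="session")
def large_study():
    """Study-sized population (~2000 offspring) for parameter-recovery checks."""
    return simulate_study(
        seed=37,
        design=MatingDesign.default(total_offspring=2000),
        genome=GenomeMap.uniform(6, 100, 25.0),
        missing_rate=0.0,
    )


@pytest.fixture
def toy_pedigree():
    """Two unrelated parents and two full-sib offspring."""
    return Pedigree(
        pd.DataFrame(
            {
                "id": ["s", "d", "o1", "o2"],
                "sire": ["0", "0", "s", "s"],
                "dam": ["0", "0", "d", "d"],
                "cohort": ["F0", "F0", "C1", "C1"],
            }
        )
    )


def single_trait_model(h2: float = 0.3) -> TraitModel:
    """Intercept-only single-trait model on a unit phenotypic scale."""
    return TraitModel(
        traits=["T"],
        Vg=np.array([[h2]]),
        Ve=np.array([[1.0 - h2]]),
        means=np.array([0.0]),
        overmature_prevalence=0.0,
    )
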