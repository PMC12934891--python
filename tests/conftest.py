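import numpy as np
import pandas as pd
import pytest

import prera
from prera import synthetic as syn
from prera.io import RiskCoefficientTable


@pytest.fixture(scope="session")
def small_cohort():
    """10+10 subjects, 400 cells/sample, no planted effects."""
    return prera.generate_cohort(
        prera.CohortSpec(n_subjects_per_group=10, cells_per_sample=400,
                         seed=11))


@pytest.fixture(scope="session")
def coefficients():
    return syn.generate_coefficients(seed=5)


@pytest.fixture
def tiny_coeffs():
    """Hand-built coefficient fixture for exact scoring checks."""
    return RiskCoefficientTable({(12, 3, "R"): 0.5, (12, 5, "K"): -0.2})


@pytest.fixture
def cell_frame():
    def make(n=3, **over):
        base = pd.DataFrame({
            "cell_id": [f"c{i}" for i in range(n)],
            "sample_id": "s1",
            "subject_id": "C000",
            "visit": "V0",
            "modality": "citeseq",
            "batch": "b0",
            "lineage": "T",
            "cluster": "Tph",
        })
        for k, v in over.items():
            base[k] = v
        return base
    return make


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
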