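import numpy as np
import pytest

from bloodaudit import synthetic as syn


@pytest.fixture(scope="session")
def small_cohort():
    """Default-structure cohort at a size unit tests can afford."""
    cfg = syn.SyntheticCohortConfig(n_subjects=120, n_genes=400,
                                    n_replicate_subjects=15, seed=42)
    return syn.generate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """No disease effect, no batch effect, no composition shift."""
    cfg = syn.SyntheticCohortConfig(n_subjects=120, n_genes=400,
                                    n_replicate_subjects=0, seed=43).null()
    return syn.generate_cohort(cfg)


@pytest.fixture(scope="session")
def signature():
    return syn.generate_signature_matrix(
        n_genes=200, n_cell_types=5, markers_per_type=20, marker_fold=8, seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
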