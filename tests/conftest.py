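import numpy as np
import pytest

from dosagecomp.synthetic_transcriptome import StudyDesign, TruthConfig, generate


@pytest.fixture
def rng():
    return np.random.Generator(np.random.PCG64(12345))


@pytest.fixture(scope="session")
def small_dataset():
    """One-tissue dataset shared by pipeline tests (default 4 replicates)."""
    design = StudyDesign(
        tissues=("liver",),
        n_autosomal=400,
        n_z=200,
        low_expressed_frac=0.05,
        mean_libsize=1.6e6,
    )
    return generate(design, TruthConfig(), seed=77)


@pytest.fixture(scope="session")
def recovery_dataset():
    """Well-replicated liver-regime dataset for parameter-recovery tests."""
    design = StudyDesign(
        tissues=("liver",),
        n_autosomal=600,
        n_z=450,
        n_replicates=12,
        low_expressed_frac=0.0,
        mean_libsize=1.6e6,
    )
    return generate(design, TruthConfig(), seed=11)
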