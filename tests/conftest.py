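import numpy as np
import pytest

from lncdbn.data_io import assemble_dataset
from lncdbn.evaluation import CVSpec, PipelineConfig
from lncdbn.synthetic import SyntheticSpec, generate_synthetic_study


@pytest.fixture(scope="session")
def tiny_spec():
    """Small planted-signal study: fast to generate and to cross-validate."""
    return SyntheticSpec(
        n_lncrna=80,
        n_genes=40,
        n_panel_genes=16,
        cancers=(("cancer_a", 25),),
        n_linked_genes=6,
        p_in=0.8,
        p_bg=0.15,
        expr_shift=2.0,
        n_shift_tissues=3,
        filler_disease_size=10,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_tables(tiny_spec):
    return generate_synthetic_study(tiny_spec)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_tables):
    assoc, targets, expr, _ = tiny_tables
    return assemble_dataset(assoc, targets, expr, min_positives=20)


@pytest.fixture(scope="session")
def fast_cv():
    """Few folds so stratification still works with ~25 positives."""
    return CVSpec(k=4, experiment_seed=3)


@pytest.fixture(scope="session")
def fast_config():
    """Short trainings: unit tests check contracts, not peak accuracy."""
    return PipelineConfig(dbn_epochs=20, clf_epochs=40)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
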