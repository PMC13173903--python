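import warnings

import numpy as np
import pytest

from scstates.pipeline import PipelineConfig, run_cohort_pipeline
from scstates.synthetic import build_gene_universe, default_states, generate_cohort


@pytest.fixture(scope="session")
def gene_universe():
    return build_gene_universe(seed=7)


@pytest.fixture(scope="session")
def small_cohort(gene_universe):
    """5 samples x 600 cells, 4 planted states at log2 effect 2."""
    states = default_states(gene_universe, n_states=4, markers_per_state=60,
                            log2_effect=2.0, seed=7)
    adatas, truth = generate_cohort(
        n_samples=5, states=states, cells_per_sample=600, batch_sd=0.2,
        seed=7, doublet_rate=0.02,
    )
    return adatas, truth, states


@pytest.fixture(scope="session")
def small_pipeline(small_cohort):
    adatas, truth, states = small_cohort
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = run_cohort_pipeline(adatas, PipelineConfig(seed=7), truth)
    return result


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
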