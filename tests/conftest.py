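import numpy as np
import pytest

from ekaryo.synthetic import CohortSpec, make_genome, simulate_cohort


@pytest.fixture(scope="session")
def small_genome():
    """5 chromosomes x 300 genes x 8 bands — fast but large enough for
    50-gene aberration-size thresholds."""
    return make_genome(5, 300, 8, seed=0)


@pytest.fixture(scope="session")
def tiny_genome():
    return make_genome(2, 40, 4, seed=0)


@pytest.fixture(scope="session")
def aberrant_cohort(small_genome):
    """Cohort with ~50% whole-chromosome events, default shifts, and its truth."""
    spec = CohortSpec(n_samples=60, aberration_prevalence=0.5,
                      gene_noise_sd=0.2, gain_shift=0.4, loss_shift=0.4,
                      model_label="mA", seed=11)
    return simulate_cohort(small_genome, spec)


@pytest.fixture(scope="session")
def diploid_cohort(small_genome):
    spec = CohortSpec(n_samples=30, aberration_prevalence=0.0,
                      gene_noise_sd=0.2, tissue_class="normal",
                      model_label="ctrl", seed=7)
    cohort, _ = simulate_cohort(small_genome, spec)
    return cohort
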