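import pytest

from driverscan.io_formats import filter_pathogenic
from driverscan.matrices import build_dataset, build_mutation_matrix
from driverscan.synthetic_data import SimulationConfig, simulate_multi_cancer


@pytest.fixture(scope="session")
def small_config():
    """A small but fully structured 3-cohort study."""
    return SimulationConfig(n_cohorts=3, n_samples=60, n_genes=120,
                            n_shared_mutated_genes=20, n_planted_drivers=5,
                            driver_mutation_frequency=0.2,
                            passenger_mutation_frequency=0.01,
                            targets_per_driver=10, effect_size_delta=2.0,
                            noise_sd=1.0, seed=11)


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_multi_cancer(small_config)


def datasets_from(cohorts):
    """Filter records, build matrices, align and z-score each cohort."""
    out = []
    for c, (mut, expr, records) in enumerate(cohorts):
        kept = filter_pathogenic(records)
        mm = build_mutation_matrix(kept, samples=expr.samples)
        out.append(build_dataset(f"cohort{c + 1}", mm, expr.values))
    return out


@pytest.fixture(scope="session")
def small_datasets(small_study):
    cohorts, _ = small_study
    return datasets_from(cohorts)
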