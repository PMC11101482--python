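import pytest

from radclust import GeneratorConfig, build_catalog, generate_cohort, harmonize


@pytest.fixture(scope="session")
def catalog():
    return build_catalog()


@pytest.fixture(scope="session")
def small_bundle():
    """Fast 40-patient cohort with 24 generic features."""
    return generate_cohort(GeneratorConfig(
        n_patients=40, n_features=24, n_informative_features=6,
        cluster_separation=3.0, seed=11,
    ))


@pytest.fixture(scope="session")
def full_bundle():
    """Full 293-feature cohort at the default 132-patient template."""
    return generate_cohort(GeneratorConfig(seed=7))


@pytest.fixture(scope="session")
def harmonized_full(full_bundle, catalog):
    matrix, result = harmonize(full_bundle.feature_matrix,
                               full_bundle.protocol_table, catalog)
    return matrix, result
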