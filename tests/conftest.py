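import pytest

from mvldkit.fixtures import FixtureConfig, generate_entities, generate_fixtures, worked_example


@pytest.fixture(scope="session")
def worked():
    """(MVLD record, assertion bundle) of the predictive worked example."""
    return worked_example()


@pytest.fixture(scope="session")
def clean_set():
    """A moderate all-valid fixture set."""
    return generate_entities(
        FixtureConfig(seed=7, n_variants=30, n_evidence_per_variant=3, n_assertions=20)
    )


@pytest.fixture(scope="session")
def edge_set():
    """Fixture set with a 20% labeled-invalid fraction."""
    return generate_entities(
        FixtureConfig(
            seed=11, n_variants=50, n_evidence_per_variant=3,
            n_assertions=50, edge_case_rate=0.2,
        )
    )


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """An on-disk clean fixture set (mvld.tsv, civic.json, registry cache)."""
    out = tmp_path_factory.mktemp("fixtures")
    generate_fixtures(
        FixtureConfig(seed=7, n_variants=30, n_evidence_per_variant=3, n_assertions=20), out
    )
    return out
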