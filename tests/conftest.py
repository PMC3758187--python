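import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def eleven_species_run():
    """One 11-species simulation shared across evidence/metrics tests."""
    from ervclock.synthetic_data import eleven_species_config, simulate

    seqs, aln, truth = simulate(eleven_species_config(), seed=11)
    return seqs, aln, truth


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    from ervclock.synthetic_data import fixture_suite

    out = tmp_path_factory.mktemp("fixture")
    paths = fixture_suite(out, seed=11)
    return paths
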