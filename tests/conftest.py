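import pytest

from quadclone import io as qio
from quadclone.genome import GenomeModel
from quadclone.pipeline import PipelineConfig, analyze_matrix


@pytest.fixture(scope="session")
def genome():
    return GenomeModel.default(4000)


@pytest.fixture(scope="session")
def fixture_matrices(genome):
    return qio.load_table2_matrices(genome)


@pytest.fixture(scope="session")
def fixture_statuses():
    return qio.load_table1_samples()


@pytest.fixture(scope="session")
def fixture_results(fixture_matrices, fixture_statuses):
    """Event-level pipeline results for the three published heterogeneous
    cases, under default configuration."""
    config = PipelineConfig()
    return {
        case: analyze_matrix(
            matrix,
            [s for s in fixture_statuses if s.case_id == case],
            config,
        )
        for case, matrix in fixture_matrices.items()
    }
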