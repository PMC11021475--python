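import pandas as pd
import pytest

import umiskit as uk


@pytest.fixture(scope="session")
def default_config() -> uk.CohortConfig:
    return uk.CohortConfig(seed=1)


@pytest.fixture(scope="session")
def default_cohort(default_config):
    """Bulk counts plus ground truth for the default synthetic cohort."""
    counts, truth = uk.simulate_bulk_counts(default_config)
    return counts, truth


@pytest.fixture(scope="session")
def normalized_cohort(default_cohort):
    """(log matrix, TPM matrix, truth) derived from the default cohort."""
    counts, truth = default_cohort
    log_matrix = uk.log_stabilize(uk.normalize_by_size_factors(counts))
    tpm = uk.compute_tpm(counts)
    return log_matrix, tpm, truth


@pytest.fixture(scope="session")
def discovery_result(normalized_cohort, default_config):
    """Full discovery run on the default cohort."""
    from umiskit.synthetic import IMMUNE_FIXTURE_SET_NAMES, build_fixture_genesets

    log_matrix, tpm, truth = normalized_cohort
    sets = build_fixture_genesets(truth, default_config)
    return uk.discover_signature(log_matrix, tpm, sets, IMMUNE_FIXTURE_SET_NAMES)


@pytest.fixture(scope="session")
def umis_scores(normalized_cohort, discovery_result) -> pd.Series:
    _, tpm, _ = normalized_cohort
    scores = uk.umis(tpm, discovery_result.signature)
    return pd.Series({s.sample_id: s.score for s in scores}, name="umis")


@pytest.fixture(scope="session")
def default_cells(default_cohort, default_config):
    counts, truth = default_cohort
    cells, meta = uk.simulate_cells(default_config, truth)
    return cells, meta
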