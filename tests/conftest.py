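import pytest

from gliomapairs.simulate import CohortConfig, simulate_cohort
from gliomapairs.temporal import H3_IDH1_MUTANT, H3_IDH1_WILDTYPE, NF1_GERMLINE

THREE_GROUPS = {
    H3_IDH1_MUTANT: 0.5,
    H3_IDH1_WILDTYPE: 0.25,
    NF1_GERMLINE: 0.25,
}


def small_config(**overrides) -> CohortConfig:
    """Desk-scale noisy cohort covering all three molecular groups."""
    defaults = dict(
        n_pairs=4,
        group_spec=dict(THREE_GROUPS),
        n_shared_passengers=4,
        n_primary_private=2,
        n_recurrence_private=3,
        hypermutator_pairs={},
        n_germline_snps=5,
        germline_pairs=(0, 3),
        n_baf_sites=600,
        n_probes=1200,
        seed=11,
    )
    defaults.update(overrides)
    return CohortConfig(**defaults)


@pytest.fixture(scope="session")
def small_run(tmp_path_factory):
    """One simulated noisy cohort shared across tests that only read it."""
    run_dir = tmp_path_factory.mktemp("cohort")
    paths, truth = simulate_cohort(small_config(), run_dir)
    return run_dir, paths, truth
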