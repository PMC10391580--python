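import pytest


@pytest.fixture(scope="session")
def classifier_report():
    """Behavior classifier trained once on the synthetic labeled cohort."""
    from kage.pipeline import classifier_benchmark
    model, report = classifier_benchmark(seed=0, days=2, cap_per_class=8000,
                                         n_iter=4)
    return report


@pytest.fixture(scope="session")
def recovery_results():
    """Clustering recovery over ten seeded four-group cohorts."""
    from kage.pipeline import clustering_recovery
    return clustering_recovery(master_seed=0, n_cohorts=10, n_per_group=5,
                               duration_days=30, n_sims=120)
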