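import pytest

from editpeaks import SimConfig, analyze_experiment, simulate_experiment, simulate_reference


def small_full_config(seed: int = 11) -> SimConfig:
    """A compact multi-condition design: 6 genes, 6 inosine peaks (two per
    dependency category), 2 m6A peaks, two replicates per condition."""
    return SimConfig(
        seed=seed,
        contig_length=20_000,
        n_genes=6,
        n_peaks=6,
        n_m6a_peaks=2,
        background_depth=25.0,
    )


@pytest.fixture(scope="session")
def experiment():
    """One simulated multi-condition experiment shared across tests."""
    config = small_full_config()
    genome, annotation = simulate_reference(config)
    reads, spike_counts, truth = simulate_experiment(config, genome, annotation)
    return {
        "config": config,
        "genome": genome,
        "annotation": annotation,
        "reads": reads,
        "spike_counts": spike_counts,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def experiment_result(experiment):
    return analyze_experiment(
        experiment["reads"],
        experiment["spike_counts"],
        experiment["genome"],
        experiment["annotation"],
    )
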