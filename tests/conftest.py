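import pytest

from cistrans.simulate import SimConfig, simulate_counts


@pytest.fixture(scope="session")
def small_dataset():
    """A 600-gene mixed-category dataset shared by read-only tests."""
    cfg = SimConfig(n_genes=600, seed=42, condition_label="unit")
    counts, truth = simulate_counts(cfg)
    return counts, truth, cfg


@pytest.fixture(scope="session")
def read_fixture(tmp_path_factory):
    """Simulated error-free reads for 15 genes, 2 replicates."""
    cfg = SimConfig(n_genes=15, seed=11)
    _, truth = simulate_counts(cfg)
    out = tmp_path_factory.mktemp("reads")
    from cistrans.simulate import simulate_reads

    paths, snp_table, true_counts = simulate_reads(
        truth, out, depth=120, seed=13, n_replicates=2
    )
    return paths, snp_table, true_counts, truth
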