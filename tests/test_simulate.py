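"""Generator contracts: determinism, planted structure, mean laws."""

import numpy as np
import pytest

from cistrans.errors import ConfigurationError
from cistrans.simulate import (
    SimConfig,
    simulate_counts,
    simulate_motif_hits,
    simulate_reads,
)


def test_degenerate_mixture_has_no_effects():
    cfg = SimConfig(
        n_genes=200, seed=5, category_proportions={"conserved": 1.0}
    )
    _, truth = simulate_counts(cfg)
    assert (truth.table["cis_log2"] == 0).all()
    assert (truth.table["trans_log2"] == 0).all()


def test_effect_zero_structure_by_category():
    cfg = SimConfig(n_genes=400, seed=6)
    _, truth = simulate_counts(cfg)
    t = truth.table
    assert (t.loc[t["category"].isin(["conserved", "trans_only"]), "cis_log2"] == 0).all()
    assert (t.loc[t["category"].isin(["conserved", "cis_only"]), "trans_log2"] == 0).all()
    assert (t.loc[t["category"] == "cis_only", "cis_log2"] != 0).all()
    assert (t.loc[t["category"] == "cis_trans", "trans_log2"] != 0).all()


def test_same_seed_bitwise_identical():
    cfg = SimConfig(n_genes=150, seed=9)
    a, ta = simulate_counts(cfg)
    b, tb = simulate_counts(cfg)
    for ch in a.channels:
        assert np.array_equal(a.channels[ch], b.channels[ch])
    assert ta.table.equals(tb.table)


def test_category_proportions_are_apportioned_exactly():
    cfg = SimConfig(n_genes=1000, seed=1)
    _, truth = simulate_counts(cfg)
    vc = truth.table["category"].value_counts()
    assert vc["conserved"] == 800 and vc["cis_only"] == 100
    assert vc["trans_only"] == 70 and vc["cis_trans"] == 30


def test_mean_ratio_law_of_large_numbers():
    # dispersion -> 0, fixed cis=1, trans=0, huge baseline: count ratios -> 2
    cfg = SimConfig(
        n_genes=50,
        seed=3,
        dispersion=0.0,
        category_proportions={"cis_only": 1.0},
        cis_effect_log2=1.0,
        baseline_log2_mean=np.log2(2e5),
        baseline_log2_sd=0.0,
        size_factor_range=(1.0, 1.0),
    )
    counts, truth = simulate_counts(cfg)
    sign = np.sign(truth.table["cis_log2"].to_numpy())
    f1_ratio = counts.channels["F1_B"].sum(1) / counts.channels["F1_A"].sum(1)
    f0_ratio = counts.channels["F0_B"].sum(1) / counts.channels["F0_A"].sum(1)
    assert f1_ratio == pytest.approx(2.0**sign, rel=0.01)
    assert f0_ratio == pytest.approx(2.0**sign, rel=0.01)


def test_f1_allelic_ratio_excludes_trans_effect():
    # per-gene log2(F1_B/F1_A) ~ cis only; log2(F0_B/F0_A) ~ cis + trans
    cfg = SimConfig(
        n_genes=80,
        seed=4,
        dispersion=0.0,
        baseline_log2_mean=np.log2(5e4),
        baseline_log2_sd=0.0,
        size_factor_range=(1.0, 1.0),
    )
    counts, truth = simulate_counts(cfg)
    f1 = np.log2(counts.channels["F1_B"].sum(1) / counts.channels["F1_A"].sum(1))
    f0 = np.log2(counts.channels["F0_B"].sum(1) / counts.channels["F0_A"].sum(1))
    t = truth.table
    assert np.abs(f1 - t["cis_log2"]).max() < 0.05
    assert np.abs(f0 - (t["cis_log2"] + t["trans_log2"])).max() < 0.05


def test_f1_alleles_share_their_library_size_factor():
    _, truth = simulate_counts(SimConfig(n_genes=50, seed=2))
    assert np.array_equal(
        truth.size_factors["F1_A"], truth.size_factors["F1_B"]
    )


@pytest.mark.parametrize(
    "kwargs",
    [
        {"category_proportions": {"conserved": 0.5}},
        {"dispersion": -1.0},
        {"size_factor_range": (0.0, 1.0)},
        {"cis_effect_log2": -2.0},
        {"n_genes": 0},
    ],
)
def test_invalid_config_rejected(kwargs):
    with pytest.raises(ConfigurationError):
        simulate_counts(SimConfig(seed=0, **kwargs))


class TestReads:
    def test_zero_depth_is_empty(self, tmp_path):
        _, truth = simulate_counts(SimConfig(n_genes=5, seed=1))
        paths, _, true_counts = simulate_reads(truth, tmp_path, depth=0, seed=1)
        assert (true_counts[["count_A", "count_B"]] == 0).all().all()
        assert paths[0].read_text() == ""

    def test_balanced_gene_planted_exactly(self, tmp_path):
        cfg = SimConfig(n_genes=1, seed=2, category_proportions={"conserved": 1.0})
        _, truth = simulate_counts(cfg)
        _, _, true_counts = simulate_reads(truth, tmp_path, depth=100, seed=3)
        assert true_counts.loc[0, "count_A"] == 50
        assert true_counts.loc[0, "count_B"] == 50

    def test_reads_conserve_truth_totals(self, read_fixture):
        paths, _, true_counts, _ = read_fixture
        n_reads = sum(p.read_text().count("\n") // 4 for p in paths)
        assert n_reads == int(true_counts[["count_A", "count_B"]].sum().sum())

    def test_window_longer_than_read_rejected(self, tmp_path):
        _, truth = simulate_counts(SimConfig(n_genes=3, seed=1))
        with pytest.raises(ConfigurationError):
            simulate_reads(truth, tmp_path, read_length=20, window_length=30, seed=1)


class TestMotifHits:
    def test_null_multiplier_is_exchangeable(self):
        fg, bg = simulate_motif_hits(
            300, 300, ["m1", "m2"], "m1", fg_rate_multiplier=1.0, seed=8
        )
        for m in ("m1", "m2"):
            # same Poisson rate in both sets: means agree within noise
            assert fg[m].mean() == pytest.approx(bg[m].mean(), abs=0.3)

    def test_zero_length_means_zero_hits(self):
        fg, bg = simulate_motif_hits(10, 10, ["m1"], None, seq_len=0, seed=1)
        assert (fg["m1"] == 0).all() and (bg["m1"] == 0).all()

    def test_planted_motif_is_hotter_in_foreground_only(self):
        fg, bg = simulate_motif_hits(
            500, 500, ["m1", "m2"], "m2", fg_rate_multiplier=10.0, seed=9
        )
        assert fg["m2"].mean() > 5 * bg["m2"].mean()
        assert fg["m1"].mean() == pytest.approx(bg["m1"].mean(), abs=0.3)
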