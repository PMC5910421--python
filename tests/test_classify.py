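"""Category assignment logic and the fitted model interface."""

import numpy as np
import pandas as pd
import pytest

from cistrans.classify import build_test_records, classify_genes
from cistrans.errors import ConfigurationError
from cistrans.model import CisTransModel
from cistrans.simulate import CHANNELS, SimConfig, simulate_counts


def _classify_single(f0, f1, alpha=0.01):
    rec = build_test_records(["g"], *[np.array([v]) for v in (*f0, *f1)])
    table, _ = classify_genes(rec, alpha=alpha)
    return table.loc[0]


class TestDecisionScheme:
    def test_matched_imbalance_is_cis_only(self):
        row = _classify_single((1000, 100), (500, 50))
        assert row["category"] == "cis_only" and row["collapsed"] == "cis"

    def test_f0_only_imbalance_is_trans_only(self):
        row = _classify_single((1000, 100), (500, 500))
        assert row["category"] == "trans_only" and row["collapsed"] == "trans"

    def test_all_null_is_conserved(self):
        row = _classify_single((100, 100), (100, 100))
        assert row["category"] == "conserved"
        assert row["collapsed"] == "not_divergent"

    def test_opposing_effects_are_compensatory(self):
        # F0 balanced, F1 strongly imbalanced, ratios heterogeneous
        row = _classify_single((1000, 1000), (200, 800))
        assert row["category"] == "compensatory"
        assert row["collapsed"] == "not_divergent"

    def test_reinforcing_cis_trans_is_enhancing(self):
        # F0 ratio exceeds F1 ratio, same direction
        row = _classify_single((4000, 250), (1000, 500))
        assert row["category"] == "cis_trans_enhancing"
        assert row["collapsed"] == "cis_trans"

    def test_alpha_must_be_a_probability(self):
        rec = build_test_records(["g"], *[np.array([10])] * 4)
        with pytest.raises(ConfigurationError):
            classify_genes(rec, alpha=1.5)

    def test_nan_tests_never_significant(self):
        rec = build_test_records(
            ["g1", "g2"],
            np.array([0, 50]),
            np.array([0, 5]),
            np.array([30, 40]),
            np.array([2, 4]),
        )
        assert np.isnan(rec.loc[0, "p_f0"])
        table, _ = classify_genes(rec)
        assert table.loc[0, "category"] == "ambiguous"


class TestRecords:
    def test_pseudocount_only_in_log_ratios(self):
        rec = build_test_records(
            ["g"], np.array([0]), np.array([8]), np.array([4]), np.array([4])
        )
        assert np.isfinite(rec.loc[0, "log2_f0_ratio"])
        assert rec.loc[0, "log2_f0_ratio"] == pytest.approx(np.log2(8.5 / 0.5))
        assert rec.loc[0, "log2_f1_ratio"] == pytest.approx(0.0)

    def test_q_dominates_p_per_family(self):
        counts, _ = simulate_counts(SimConfig(n_genes=300, seed=17))
        table = CisTransModel(counts).fit().table
        for fam in ("f0", "f1", "ct"):
            ok = ~table[f"p_{fam}"].isna()
            assert (table.loc[ok, f"q_{fam}"] >= table.loc[ok, f"p_{fam}"] - 1e-12).all()


class TestModel:
    def test_label_swap_symmetry(self, small_dataset):
        counts, _, _ = small_dataset
        res = CisTransModel(counts).fit()
        swapped = type(counts)(
            gene_ids=counts.gene_ids,
            channels={
                "F0_A": counts.channels["F0_B"],
                "F0_B": counts.channels["F0_A"],
                "F1_A": counts.channels["F1_B"],
                "F1_B": counts.channels["F1_A"],
            },
            condition_label=counts.condition_label,
        )
        res2 = CisTransModel(swapped).fit()
        a, b = res.table, res2.table
        for fam in ("f0", "f1", "ct"):
            assert a[f"p_{fam}"].to_numpy() == pytest.approx(
                b[f"p_{fam}"].to_numpy(), abs=1e-9, nan_ok=True
            )
        assert (a["category"] == b["category"]).all()
        assert a["log2_f0_ratio"].to_numpy() == pytest.approx(
            -b["log2_f0_ratio"].to_numpy(), abs=1e-9
        )

    def test_scatter_geometry_of_true_categories(self, small_dataset):
        # cis genes concentrate on the diagonal, trans genes on the x-axis
        counts, truth, _ = small_dataset
        res = CisTransModel(counts).fit()
        merged = res.table.merge(truth.table, on="gene_id", suffixes=("", "_true"))
        cis = merged[merged["category_true"] == "cis_only"]
        trans = merged[merged["category_true"] == "trans_only"]
        diag_resid = np.abs(cis["log2_f1_ratio"] - cis["log2_f0_ratio"]).mean()
        axis_resid = np.abs(trans["log2_f1_ratio"]).mean()
        off_diag = np.abs(trans["log2_f1_ratio"] - trans["log2_f0_ratio"]).mean()
        assert diag_resid < 0.25
        assert axis_resid < 0.25
        assert off_diag > 4 * axis_resid

    def test_summary_contains_headline_fields(self, small_dataset):
        counts, _, _ = small_dataset
        res = CisTransModel(counts).fit()
        text = str(res.summary())
        assert "divergent" in text and "cis" in text
        assert set(res.summary_dict) == {
            "n_universe",
            "n_divergent",
            "pct_divergent",
            "pct_cis",
            "pct_trans",
            "pct_cis_trans",
        }

    def test_expression_filter_shrinks_universe(self, small_dataset):
        counts, _, _ = small_dataset
        res_low = CisTransModel(counts, min_count=0).fit()
        res_high = CisTransModel(counts, min_count=10).fit()
        assert res_high.n_universe <= res_low.n_universe == counts.n_genes

    def test_plot_scatter_returns_axes(self, small_dataset):
        import matplotlib

        matplotlib.use("Agg")
        counts, _, _ = small_dataset
        ax = CisTransModel(counts).fit().plot_scatter()
        assert ax.get_xlabel().startswith("log2 F0")
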