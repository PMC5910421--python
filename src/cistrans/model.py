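"""Model/Results interface for the cis/trans classification pipeline.

``CisTransModel`` wraps one condition's four-channel count set together
with the analysis options (expression threshold, normalization toggle,
FDR level); ``fit()`` runs filter -> normalize -> pool -> exact tests ->
BH-FDR -> categorise and returns a ``CisTransResults`` carrying the
per-gene table, the condition summary and plotting/export helpers.

Example
-------
>>> from cistrans import SimConfig, simulate_counts, CisTransModel
>>> counts, truth = simulate_counts(SimConfig(n_genes=500, seed=1))
>>> res = CisTransModel(counts).fit()
>>> res.summary()  # doctest: +SKIP
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import build_test_records, classify_genes
from .errors import ConfigurationError
from .io import read_counts, write_table
from .normalize import NormalizedCountSet, expression_filter, normalize_counts
from .simulate import CHANNELS, AlleleCountSet

__all__ = ["CisTransModel", "CisTransResults"]

_CATEGORY_COLORS = {
    "conserved": "#bbbbbb",
    "cis_only": "#d62728",
    "trans_only": "#1f77b4",
    "cis_trans_enhancing": "#9467bd",
    "cis_trans_compensating": "#8c564b",
    "compensatory": "#2ca02c",
    "ambiguous": "#e7ba52",
}


class CisTransModel:
    """Cis/trans regulatory-divergence model for one condition.

    Parameters
    ----------
    counts : AlleleCountSet
        Raw four-channel counts (F0_A, F0_B, F1_A, F1_B) per replicate.
    alpha : float
        FDR level applied within each of the three test families.
    min_count : float
        Expression filter: a gene is analysed when at least one channel
        mean strictly exceeds this raw-count threshold.
    normalize : bool
        Median-of-ratios normalization of every channel-replicate column
        before pooling; disable only for pre-normalized input.
    pseudocount : float
        Added to pooled counts for the display log ratios only.
    """

    def __init__(
        self,
        counts: AlleleCountSet,
        alpha: float = 0.01,
        min_count: float = 10,
        normalize: bool = True,
        pseudocount: float = 0.5,
        allow_pseudo_reference: bool = False,
    ) -> None:
        if not 0.0 < alpha < 1.0:
            raise ConfigurationError(f"alpha={alpha} outside (0, 1)")
        if min_count < 0:
            raise ConfigurationError("min_count must be >= 0")
        self.counts = counts
        self.alpha = alpha
        self.min_count = min_count
        self.normalize = normalize
        self.pseudocount = pseudocount
        self.allow_pseudo_reference = allow_pseudo_reference

    @classmethod
    def from_tsv(cls, path: str | Path, condition_label: str = "", **kwargs):
        """Build a model from a tab-separated count table (see io.read_counts)."""
        return cls(read_counts(path, condition_label=condition_label), **kwargs)

    def fit(self) -> "CisTransResults":
        """Run the full classification and return the results object."""
        counts = self.counts
        mask, n_retained = expression_filter(counts, threshold=self.min_count)
        if n_retained == 0:
            raise ConfigurationError(
                "no gene passes the expression filter; lower --min-count"
            )
        if self.normalize:
            norm = normalize_counts(
                counts, allow_pseudo_reference=self.allow_pseudo_reference
            )
            working = norm.rounded()
        else:
            norm = None
            working = {ch: counts.channels[ch] for ch in CHANNELS}

        gene_ids = [g for g, keep in zip(counts.gene_ids, mask) if keep]
        pooled = {ch: working[ch][mask].sum(axis=1) for ch in CHANNELS}
        records = build_test_records(
            gene_ids,
            pooled["F0_A"],
            pooled["F0_B"],
            pooled["F1_A"],
            pooled["F1_B"],
            pseudocount=self.pseudocount,
        )
        table, summary = classify_genes(records, alpha=self.alpha)
        return CisTransResults(
            model=self,
            table=table,
            summary_dict=summary,
            expressed_mask=mask,
            normalized=norm,
        )


class CisTransResults:
    """Fitted per-gene classifications, proportions and export helpers."""

    def __init__(
        self,
        model: CisTransModel,
        table: pd.DataFrame,
        summary_dict: dict,
        expressed_mask: np.ndarray,
        normalized: NormalizedCountSet | None,
    ) -> None:
        self.model = model
        self.table = table
        self.summary_dict = dict(summary_dict)
        self.expressed_mask = expressed_mask
        self.normalized = normalized
        self.condition_label = model.counts.condition_label

    # -- reporting ---------------------------------------------------------

    @property
    def n_universe(self) -> int:
        return self.summary_dict["n_universe"]

    @property
    def n_divergent(self) -> int:
        return self.summary_dict["n_divergent"]

    def gene_ids_by_collapsed(self, label: str) -> set[str]:
        """Gene identifiers with the given collapsed label (cis/trans/...)."""
        sel = self.table.loc[self.table["collapsed"] == label, "gene_id"]
        return set(sel)

    def category_counts(self) -> pd.Series:
        return self.table["category"].value_counts()

    def summary(self):
        """Human-readable summary table (statsmodels SimpleTable)."""
        from statsmodels.iolib.table import SimpleTable

        s = self.summary_dict
        rows = [
            ["condition", self.condition_label or "-"],
            ["genes in universe", f"{s['n_universe']}"],
            ["divergent genes", f"{s['n_divergent']}"],
            ["% divergent", f"{s['pct_divergent']:.1f}"],
            ["% cis (of divergent)", f"{s['pct_cis']:.1f}"],
            ["% trans (of divergent)", f"{s['pct_trans']:.1f}"],
            ["% cis-trans (of divergent)", f"{s['pct_cis_trans']:.1f}"],
            ["FDR level per family", f"{self.model.alpha}"],
        ]
        return SimpleTable(
            rows,
            headers=["", "value"],
            title="Cis/trans regulatory divergence classification",
        )

    # -- export ------------------------------------------------------------

    def scatter_data(self) -> pd.DataFrame:
        """(log2 F0 ratio, log2 F1 ratio) per gene with its category."""
        return self.table[
            ["gene_id", "log2_f0_ratio", "log2_f1_ratio", "category", "collapsed"]
        ].copy()

    def plot_scatter(self, ax=None):
        """Parental-ratio vs allelic-ratio scatter, colored by category.

        Cis-regulated genes fall on the diagonal (the imbalance is
        preserved between the F1 alleles); trans-regulated genes on the
        horizontal axis (parental divergence, balanced alleles).
        """
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        for cat, grp in self.table.groupby("category"):
            ax.scatter(
                grp["log2_f0_ratio"],
                grp["log2_f1_ratio"],
                s=6,
                alpha=0.6,
                label=cat,
                color=_CATEGORY_COLORS.get(cat, "black"),
            )
        lim = max(
            1.0,
            float(np.nanmax(np.abs(self.table[["log2_f0_ratio", "log2_f1_ratio"]]))),
        )
        ax.plot([-lim, lim], [-lim, lim], lw=0.5, color="k", zorder=0)
        ax.axhline(0, lw=0.5, color="k", zorder=0)
        ax.set_xlabel("log2 F0 ratio (B/A)")
        ax.set_ylabel("log2 F1 allelic ratio (B/A)")
        ax.set_title(self.condition_label or "cis/trans classification")
        ax.legend(fontsize=6, markerscale=2)
        return ax

    def to_dir(self, out_dir: str | Path) -> None:
        """Write classification.tsv, scatter.tsv and summary.json."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_table(self.table, out_dir / "classification.tsv")
        write_table(self.scatter_data(), out_dir / "scatter.tsv")
        payload = dict(self.summary_dict)
        if self.condition_label:
            payload["condition_label"] = self.condition_label
        if self.normalized is not None:
            payload["size_factors"] = {
                ch: [round(float(v), 6) for v in vals]
                for ch, vals in self.normalized.size_factors.items()
            }
        with open(out_dir / "summary.json", "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
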