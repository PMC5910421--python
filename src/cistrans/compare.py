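"""Cross-condition contrasts of regulatory architecture.

Given fitted classifications for two conditions (e.g. two brain
regions, or unstressed vs stressed), this module computes
condition-unique trans gene sets, per-category proportion ratios and a
two-proportion Fisher exact test per category.  The significance test
is an addition of this implementation — the proportion shift itself is
the quantity of interest — and is labelled as such in the output.

Set operations require a common gene universe; :func:`harmonize`
rebuilds both summaries on the genes retained by both conditions'
expression filters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classify import classify_genes
from .errors import ConfigurationError
from .model import CisTransResults
from .stats import bh_fdr, fisher_ratio_test

__all__ = [
    "ConditionSummary",
    "summarize_condition",
    "harmonize",
    "unique_trans_sets",
    "proportion_contrast",
]

_CATEGORIES = ("cis", "trans", "cis_trans")


@dataclass
class ConditionSummary:
    """Per-condition classification summary with gene-identifier sets."""

    condition_label: str
    n_universe: int
    n_divergent: int
    pct_cis: float
    pct_trans: float
    pct_cis_trans: float
    cis_gene_ids: set[str] = field(default_factory=set)
    trans_gene_ids: set[str] = field(default_factory=set)
    cis_trans_gene_ids: set[str] = field(default_factory=set)
    universe_gene_ids: set[str] = field(default_factory=set)

    def n_category(self, category: str) -> int:
        return len(getattr(self, f"{category}_gene_ids"))


def summarize_condition(results: CisTransResults) -> ConditionSummary:
    """Build a ConditionSummary from a fitted CisTransResults."""
    s = results.summary_dict
    return ConditionSummary(
        condition_label=results.condition_label,
        n_universe=s["n_universe"],
        n_divergent=s["n_divergent"],
        pct_cis=s["pct_cis"],
        pct_trans=s["pct_trans"],
        pct_cis_trans=s["pct_cis_trans"],
        cis_gene_ids=results.gene_ids_by_collapsed("cis"),
        trans_gene_ids=results.gene_ids_by_collapsed("trans"),
        cis_trans_gene_ids=results.gene_ids_by_collapsed("cis_trans"),
        universe_gene_ids=set(results.table["gene_id"]),
    )


def harmonize(
    a: CisTransResults, b: CisTransResults
) -> tuple[ConditionSummary, ConditionSummary]:
    """Summaries restricted to the genes expressed in both conditions.

    Each condition's test records are re-thresholded (categories and
    percentages recomputed) on the shared universe so set operations
    and proportion contrasts are well-defined.
    """
    shared = set(a.table["gene_id"]) & set(b.table["gene_id"])
    if not shared:
        raise ConfigurationError("conditions share no expressed genes")

    out = []
    for res in (a, b):
        sub = (
            res.table[res.table["gene_id"].isin(shared)]
            .drop(columns=["category", "collapsed"])
            .reset_index(drop=True)
        )
        for fam in ("f0", "f1", "ct"):  # FDR is universe-dependent: re-adjust
            sub[f"q_{fam}"] = bh_fdr(sub[f"p_{fam}"].to_numpy())
        table, summary = classify_genes(sub, alpha=res.model.alpha)
        tmp = CisTransResults(
            model=res.model,
            table=table,
            summary_dict=summary,
            expressed_mask=res.expressed_mask,
            normalized=res.normalized,
        )
        tmp.condition_label = res.condition_label
        out.append(summarize_condition(tmp))
    return out[0], out[1]


def unique_trans_sets(
    a: ConditionSummary, b: ConditionSummary
) -> tuple[set[str], set[str], set[str]]:
    """Condition-unique and shared trans-regulated gene sets.

    Returns ``(a_only, b_only, shared)``; their disjoint union
    reconstructs each input set.  Requires matching gene universes.
    """
    if a.universe_gene_ids != b.universe_gene_ids:
        raise ConfigurationError(
            "gene universes differ between conditions; run harmonize() first"
        )
    shared = a.trans_gene_ids & b.trans_gene_ids
    return a.trans_gene_ids - shared, b.trans_gene_ids - shared, shared


def proportion_contrast(a: ConditionSummary, b: ConditionSummary) -> dict:
    """Per-category fold ratios (a/b) with a two-proportion Fisher test.

    Ratios are of percentages over each condition's divergent genes; a
    zero denominator reports ``inf`` with a flag.  The Fisher test
    contrasts [category vs not] x [condition a vs b] over divergent
    genes and is an added uncertainty measure, not part of the original
    classification scheme (flagged in the output).
    """
    if a.n_divergent <= 0 or b.n_divergent <= 0:
        raise ConfigurationError("both conditions need divergent genes")
    out: dict = {
        "condition_a": a.condition_label,
        "condition_b": b.condition_label,
        "note": "fisher test added by this implementation, not part of the "
        "original classification scheme",
        "categories": {},
    }
    for cat in _CATEGORIES:
        pa = getattr(a, f"pct_{cat}")
        pb = getattr(b, f"pct_{cat}")
        ka, kb = a.n_category(cat), b.n_category(cat)
        infinite = pb == 0
        ratio = float("inf") if infinite else pa / pb
        p = fisher_ratio_test(
            (ka, a.n_divergent - ka), (kb, b.n_divergent - kb)
        )
        out["categories"][cat] = {
            "pct_a": pa,
            "pct_b": pb,
            "fold_ratio_a_over_b": ratio,
            "infinite_ratio": bool(infinite),
            "fisher_p": p,
        }
    return out
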