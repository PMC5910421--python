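"""Regulatory-category assignment from per-gene exact tests.

Following the McManus-style decision scheme, three significance calls
are made per gene at FDR < alpha within each test family:

    S0 — F0 divergence       (binomial exact, parental counts)
    S1 — F1 allelic imbalance (binomial exact, hybrid allele counts)
    SC — ratio heterogeneity  (Fisher exact, F0 vs F1 ratio)

and combined into categories:

    S0  S1  SC   category
    1   1   0    cis_only
    1   0   1    trans_only
    1   1   1    cis_trans (enhancing / compensating subtypes)
    0   1   1    compensatory (cis and trans cancel in F0)
    0   0   0    conserved
    other        ambiguous

The collapsed reporting scheme maps cis_only -> cis, trans_only ->
trans, both cis_trans subtypes -> cis_trans, and everything else ->
not_divergent.  Summary percentages are taken over the classified
divergent genes (S0 true, ambiguous excluded).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .stats import bh_fdr, binomial_exact_test_vec, fisher_ratio_test_vec

__all__ = ["build_test_records", "classify_genes", "COLLAPSE_MAP"]

COLLAPSE_MAP = {
    "cis_only": "cis",
    "trans_only": "trans",
    "cis_trans_enhancing": "cis_trans",
    "cis_trans_compensating": "cis_trans",
    "compensatory": "not_divergent",
    "conserved": "not_divergent",
    "ambiguous": "not_divergent",
}

_DIVERGENT = ("cis_only", "trans_only", "cis_trans_enhancing", "cis_trans_compensating")


def build_test_records(
    gene_ids: list[str],
    f0_a: np.ndarray,
    f0_b: np.ndarray,
    f1_a: np.ndarray,
    f1_b: np.ndarray,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-gene p-values, q-values and log ratios from pooled counts.

    Counts are the replicate-pooled (normalized, rounded) totals per
    channel.  The pseudocount enters the display log ratios only, never
    the tests.  Genes whose binomial total is zero get NaN p-values that
    propagate through the FDR adjustment.
    """
    f0_a = np.asarray(f0_a, dtype=np.int64)
    f0_b = np.asarray(f0_b, dtype=np.int64)
    f1_a = np.asarray(f1_a, dtype=np.int64)
    f1_b = np.asarray(f1_b, dtype=np.int64)

    p_f0 = binomial_exact_test_vec(f0_a, f0_a + f0_b)
    p_f1 = binomial_exact_test_vec(f1_a, f1_a + f1_b)
    p_ct = fisher_ratio_test_vec(f0_a, f0_b, f1_a, f1_b)

    rec = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "f0_A": f0_a,
            "f0_B": f0_b,
            "f1_A": f1_a,
            "f1_B": f1_b,
            "p_f0": p_f0,
            "p_f1": p_f1,
            "p_ct": p_ct,
            "q_f0": bh_fdr(p_f0),
            "q_f1": bh_fdr(p_f1),
            "q_ct": bh_fdr(p_ct),
            "log2_f0_ratio": np.log2(f0_b + pseudocount)
            - np.log2(f0_a + pseudocount),
            "log2_f1_ratio": np.log2(f1_b + pseudocount)
            - np.log2(f1_a + pseudocount),
        }
    )
    return rec


def classify_genes(
    records: pd.DataFrame, alpha: float = 0.01
) -> tuple[pd.DataFrame, dict]:
    """Assign regulatory categories and summarise their proportions.

    Returns the records frame extended with ``category`` and
    ``collapsed`` columns, plus a summary dict with the universe size,
    divergent count and cis/trans/cis_trans percentages over the
    classified divergent genes.  Significance is strict: q < alpha.
    """
    if not 0.0 < alpha < 1.0:
        raise ConfigurationError(f"alpha={alpha} outside (0, 1)")
    q0 = records["q_f0"].to_numpy()
    q1 = records["q_f1"].to_numpy()
    qc = records["q_ct"].to_numpy()
    with np.errstate(invalid="ignore"):
        s0 = q0 < alpha  # NaN compares False
        s1 = q1 < alpha
        sc = qc < alpha

    l0 = records["log2_f0_ratio"].to_numpy()
    l1 = records["log2_f1_ratio"].to_numpy()
    same_sign = l0 * l1 > 0
    enhancing = same_sign & (np.abs(l0) > np.abs(l1))

    category = np.select(
        [
            s0 & s1 & ~sc,
            s0 & ~s1 & sc,
            s0 & s1 & sc & enhancing,
            s0 & s1 & sc & ~enhancing,
            ~s0 & s1 & sc,
            ~s0 & ~s1 & ~sc,
        ],
        [
            "cis_only",
            "trans_only",
            "cis_trans_enhancing",
            "cis_trans_compensating",
            "compensatory",
            "conserved",
        ],
        default="ambiguous",
    )
    out = records.copy()
    out["category"] = category
    out["collapsed"] = [COLLAPSE_MAP[c] for c in category]

    n_universe = len(out)
    div_mask = np.isin(category, _DIVERGENT)
    n_div = int(div_mask.sum())

    def _pct(name: str) -> float:
        if n_div == 0:
            return float("nan")
        if name == "cis_trans":
            k = int(
                np.isin(
                    category, ("cis_trans_enhancing", "cis_trans_compensating")
                ).sum()
            )
        else:
            k = int((category == name).sum())
        return 100.0 * k / n_div

    summary = {
        "n_universe": n_universe,
        "n_divergent": n_div,
        "pct_divergent": 100.0 * n_div / n_universe if n_universe else float("nan"),
        "pct_cis": _pct("cis_only"),
        "pct_trans": _pct("trans_only"),
        "pct_cis_trans": _pct("cis_trans"),
    }
    return out, summary
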