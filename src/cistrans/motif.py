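"""Dual-statistic transcription-factor-site enrichment (oPOSSUM-style).

For each motif, two statistics compare a foreground gene set (e.g.
trans-regulated genes) against a background set using pre-computed
hit tables:

* **Z-score** — nucleotide-level binomial test: with background hit
  rate p = bg_hits / bg_length, the expected foreground hit count is
  mu = fg_length * p and

      z = (fg_hits - mu) / sqrt(fg_length * p * (1 - p)).

* **Fisher score** — gene-level one-tailed Fisher exact test (toward
  enrichment) on genes-with-at-least-one-hit, reported as -ln(p).

A motif is significantly enriched when z > 10 AND fisher score > 7
(strict, the conventional oPOSSUM cutoffs); results are ranked by
Fisher score, descending.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigurationError

__all__ = ["z_score", "fisher_score", "enrich"]

Z_CUTOFF = 10.0
FISHER_CUTOFF = 7.0


def z_score(fg_hits: float, fg_len: float, bg_hits: float, bg_len: float) -> float:
    """Nucleotide-level binomial Z-score of foreground vs background hit rate.

    A background with zero hits uses a half-hit continuity correction
    (p = 0.5 / bg_len) so the statistic stays finite.
    """
    if fg_len <= 0 or bg_len <= 0:
        raise ConfigurationError("scanned lengths must be positive")
    if fg_hits < 0 or bg_hits < 0:
        raise ConfigurationError("hit counts must be nonnegative")
    p = bg_hits / bg_len
    if p <= 0.0:
        p = 0.5 / bg_len
    if p >= 1.0:
        p = 1.0 - 0.5 / bg_len
    mu = fg_len * p
    sd = math.sqrt(fg_len * p * (1.0 - p))
    return (fg_hits - mu) / sd


def fisher_score(
    fg_genes_with_hit: int, fg_total: int, bg_genes_with_hit: int, bg_total: int
) -> float:
    """-ln of the one-tailed (enrichment) Fisher exact p-value.

    Table: [[fg_with, fg_without], [bg_with, bg_without]]; the
    alternative is a higher with-hit proportion in the foreground.
    """
    if fg_total <= 0 or bg_total <= 0:
        raise ConfigurationError("gene-set totals must be positive")
    if not 0 <= fg_genes_with_hit <= fg_total:
        raise ConfigurationError("fg_genes_with_hit outside [0, fg_total]")
    if not 0 <= bg_genes_with_hit <= bg_total:
        raise ConfigurationError("bg_genes_with_hit outside [0, bg_total]")
    # one-tailed hypergeometric upper tail: P(X >= fg_with)
    n = fg_total + bg_total
    k = fg_genes_with_hit + bg_genes_with_hit
    p = float(sps.hypergeom.sf(fg_genes_with_hit - 1, n, k, fg_total))
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    return -math.log(p)


def enrich(
    fg: pd.DataFrame,
    bg: pd.DataFrame,
    z_cut: float = Z_CUTOFF,
    f_cut: float = FISHER_CUTOFF,
) -> pd.DataFrame:
    """Dual-statistic enrichment over all motifs of a fg/bg table pair.

    Both frames need columns gene_id, scanned_length and one hit-count
    column per motif (same motif set in both).  Returns one row per
    motif with z_score, fisher_score, the underlying counts and the
    ``significant`` flag (z > z_cut and fisher > f_cut, strict), sorted
    by fisher_score descending.
    """
    meta = {"gene_id", "scanned_length"}
    fg_motifs = [c for c in fg.columns if c not in meta]
    bg_motifs = [c for c in bg.columns if c not in meta]
    if fg_motifs != bg_motifs:
        raise ConfigurationError(
            "foreground and background motif sets differ: "
            f"{sorted(set(fg_motifs) ^ set(bg_motifs))}"
        )
    if not fg_motifs:
        raise ConfigurationError("no motif columns")
    fg_len = float(fg["scanned_length"].sum())
    bg_len = float(bg["scanned_length"].sum())
    if fg_len <= 0 or bg_len <= 0:
        raise ConfigurationError("total scanned length must be positive")
    fg_total, bg_total = len(fg), len(bg)

    rows = []
    for m in fg_motifs:
        fg_hits = float(fg[m].sum())
        bg_hits = float(bg[m].sum())
        fg_with = int((fg[m] > 0).sum())
        bg_with = int((bg[m] > 0).sum())
        z = z_score(fg_hits, fg_len, bg_hits, bg_len)
        f = fisher_score(fg_with, fg_total, bg_with, bg_total)
        rows.append(
            {
                "motif": m,
                "fg_hits": fg_hits,
                "bg_hits": bg_hits,
                "fg_genes_with_hit": fg_with,
                "bg_genes_with_hit": bg_with,
                "z_score": z,
                "fisher_score": f,
                "significant": bool(z > z_cut and f > f_cut),
            }
        )
    out = pd.DataFrame(rows).sort_values(
        "fisher_score", ascending=False, kind="mergesort"
    )
    return out.reset_index(drop=True)
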