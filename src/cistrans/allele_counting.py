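"""Read-level allele counting and the allelic-balance t-test.

Emulates the targeted-amplicon validation step: each gene has two
equal-length allele-discriminating windows (one per parental
haplotype); a FASTQ read is credited to allele A of gene g when the A
window occurs as an exact substring of the read (the reverse complement
of the read is also searched by default, since amplicon sequencing
reads both strands).  Per-gene allele fractions across replicate files
are then tested against 0.5 with a one-sample two-tailed t-test.

Counting uses a k-mer lookup per window length rather than per-window
substring scans, so runtime is O(reads x read_length), independent of
the number of genes.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy import stats as sps

from .errors import ConfigurationError, InputFormatError

__all__ = [
    "validate_snp_table",
    "count_alleles",
    "allelic_balance_test",
    "AlleleCountReport",
    "AlleleFractionResult",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def validate_snp_table(table: pd.DataFrame) -> None:
    """Check window well-formedness; warn on cross-gene substring clashes."""
    if table.empty:
        raise ConfigurationError("empty SNP window table")
    seqs = []
    for _, row in table.iterrows():
        a, b = str(row["allele_A_seq"]), str(row["allele_B_seq"])
        if len(a) != len(b) or a == b:
            raise ConfigurationError(
                f"gene {row['gene_id']}: windows must be equal length and differ"
            )
        if set(a) - set("ACGT") or set(b) - set("ACGT"):
            raise ConfigurationError(
                f"gene {row['gene_id']}: windows must be uppercase ACGT"
            )
        seqs.append((row["gene_id"], a, b))
    for gid, a, b in seqs:
        for gid2, a2, b2 in seqs:
            if gid == gid2:
                continue
            for w in (a, b):
                if w in a2 or w in b2:
                    warnings.warn(
                        f"window of gene {gid} is a substring of gene {gid2}'s "
                        "windows; counts may be inflated",
                        stacklevel=2,
                    )


@dataclass
class AlleleCountReport:
    """Per-gene, per-replicate allele counts plus read accounting."""

    gene_ids: list[str]
    counts_a: np.ndarray  # genes x replicates
    counts_b: np.ndarray
    total_reads: int
    matched: int
    conflicts: int  # reads matching both alleles of one gene (discarded)
    unmatched: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for gi, gid in enumerate(self.gene_ids):
            for rep in range(self.counts_a.shape[1]):
                rows.append(
                    {
                        "gene_id": gid,
                        "replicate": rep + 1,
                        "count_A": int(self.counts_a[gi, rep]),
                        "count_B": int(self.counts_b[gi, rep]),
                    }
                )
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        return {
            "total_reads": self.total_reads,
            "matched": self.matched,
            "conflicts": self.conflicts,
            "unmatched": self.unmatched,
        }


def _open_fastq(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def _iter_reads(path: Path):
    with _open_fastq(path) as fh:
        try:
            for rec in SeqIO.parse(fh, "fastq"):
                yield str(rec.seq).upper()
        except ValueError as exc:
            raise InputFormatError(f"{path}: malformed FASTQ record: {exc}") from exc


def count_alleles(
    fastq_paths: list[str | Path],
    table: pd.DataFrame,
    search_revcomp: bool = True,
) -> AlleleCountReport:
    """Count allele-discriminating windows in one FASTQ file per replicate.

    A read matching both alleles of the same gene is discarded and
    tallied as a conflict; a read matching windows of two different
    genes is counted for both (each gene's amplicon count is
    independent) with a warning.
    """
    validate_snp_table(table)
    gene_ids = [str(g) for g in table["gene_id"]]
    n_genes = len(gene_ids)
    n_reps = len(fastq_paths)
    if n_reps == 0:
        raise ConfigurationError("no FASTQ files given")

    # window -> list of (gene index, allele index); grouped by window length
    lookup: dict[int, dict[str, list[tuple[int, int]]]] = {}
    for gi, row in enumerate(table.itertuples(index=False)):
        for ai, win in enumerate((row.allele_A_seq, row.allele_B_seq)):
            lookup.setdefault(len(win), {}).setdefault(win, []).append((gi, ai))

    counts = np.zeros((n_genes, 2, n_reps), dtype=np.int64)
    total = matched = conflicts = unmatched = 0
    warned_multi = False

    for rep, path in enumerate(fastq_paths):
        for seq in _iter_reads(Path(path)):
            total += 1
            hits: set[tuple[int, int]] = set()
            variants = (seq, _revcomp(seq)) if search_revcomp else (seq,)
            for wlen, windows in lookup.items():
                for s in variants:
                    if len(s) < wlen:
                        continue
                    for off in range(len(s) - wlen + 1):
                        kmer = s[off : off + wlen]
                        if kmer in windows:
                            hits.update(windows[kmer])
            if not hits:
                unmatched += 1
                continue
            genes_hit = {gi for gi, _ in hits}
            if len(genes_hit) > 1 and not warned_multi:
                warnings.warn(
                    "a read matched windows of multiple genes; counted for each",
                    stacklevel=2,
                )
                warned_multi = True
            conflict = False
            for gi in genes_hit:
                alleles = {ai for g, ai in hits if g == gi}
                if len(alleles) == 2:
                    conflict = True
                else:
                    counts[gi, alleles.pop(), rep] += 1
            if conflict:
                conflicts += 1
            else:
                matched += 1
    return AlleleCountReport(
        gene_ids=gene_ids,
        counts_a=counts[:, 0, :],
        counts_b=counts[:, 1, :],
        total_reads=total,
        matched=matched,
        conflicts=conflicts,
        unmatched=unmatched,
    )


@dataclass
class AlleleFractionResult:
    """Allelic-balance test for one gene across replicates."""

    gene_id: str
    counts_a: np.ndarray
    counts_b: np.ndarray
    fraction_a: np.ndarray = field(default_factory=lambda: np.array([]))
    t_statistic: float = float("nan")
    p_value: float = float("nan")
    verdict: str = "insufficient_data"


def allelic_balance_test(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    gene_id: str = "",
    biased_p: float = 0.001,
    balanced_p: float = 0.05,
) -> AlleleFractionResult:
    """One-sample two-tailed t-test of replicate allele-A fractions vs 0.5.

    Replicates with zero total are dropped; fewer than two usable
    replicates gives verdict ``insufficient_data``.  Zero-variance
    fractions make the t statistic undefined: by convention p = 1 when
    the common fraction equals 0.5 and p = 0 otherwise (continuity of
    the decision rule).  Verdicts: ``allele_biased`` for p < 0.001 (the
    displayed significance level), ``balanced`` for p >= 0.05 and
    ``indeterminate`` between.
    """
    ca = np.asarray(counts_a, dtype=float)
    cb = np.asarray(counts_b, dtype=float)
    tot = ca + cb
    usable = tot > 0
    if usable.sum() < 2:
        return AlleleFractionResult(gene_id, ca.astype(int), cb.astype(int))
    frac = ca[usable] / tot[usable]
    if np.allclose(frac.std(ddof=1), 0.0):
        t = float("nan")
        p = 1.0 if np.isclose(frac.mean(), 0.5) else 0.0
    else:
        t, p = sps.ttest_1samp(frac, 0.5)
        t, p = float(t), float(p)
    if p < biased_p:
        verdict = "allele_biased"
    elif p >= balanced_p:
        verdict = "balanced"
    else:
        verdict = "indeterminate"
    return AlleleFractionResult(
        gene_id=gene_id,
        counts_a=ca.astype(int),
        counts_b=cb.astype(int),
        fraction_a=frac,
        t_statistic=t,
        p_value=p,
        verdict=verdict,
    )
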