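"""Tab-separated file contracts shared by all pipeline stages.

Every table is TSV with a single header row; floats are serialized with
six significant digits; gene order is preserved from input.  Schema
violations raise :class:`InputFormatError` naming the file and, where
determinable, the offending column or line.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputFormatError
from .simulate import CHANNELS, AlleleCountSet

__all__ = [
    "read_counts",
    "write_counts",
    "read_snp_table",
    "write_snp_table",
    "write_table",
    "read_motif_hits",
]

_REP_RE = re.compile(r"^(F0_A|F0_B|F1_A|F1_B)_rep(\d+)$")


def _read_tsv(path: str | Path, what: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputFormatError(f"{path}: {what} file not found")
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # pandas raises several parser error types
        raise InputFormatError(f"{path}: cannot parse as TSV: {exc}") from exc
    if df.empty and df.columns.size == 0:
        raise InputFormatError(f"{path}: empty {what} file")
    return df


def read_counts(path: str | Path, condition_label: str = "") -> AlleleCountSet:
    """Read a four-channel count matrix (gene_id + <channel>_rep<k> columns)."""
    df = _read_tsv(path, "count")
    if "gene_id" not in df.columns:
        raise InputFormatError(f"{path}: missing required column 'gene_id'")
    by_channel: dict[str, dict[int, str]] = {ch: {} for ch in CHANNELS}
    for col in df.columns:
        if col == "gene_id":
            continue
        m = _REP_RE.match(col)
        if not m:
            raise InputFormatError(
                f"{path}: column '{col}' does not match <channel>_rep<k>"
            )
        by_channel[m.group(1)][int(m.group(2))] = col
    reps = {ch: sorted(cols) for ch, cols in by_channel.items()}
    lens = {ch: len(r) for ch, r in reps.items()}
    if min(lens.values()) == 0:
        missing = [ch for ch, n in lens.items() if n == 0]
        raise InputFormatError(f"{path}: no replicate columns for {missing}")
    if len(set(lens.values())) != 1:
        raise InputFormatError(f"{path}: unequal replicate counts per channel: {lens}")

    channels = {}
    for ch in CHANNELS:
        cols = [by_channel[ch][k] for k in reps[ch]]
        block = df[cols]
        for col in cols:
            vals = block[col]
            if not np.issubdtype(vals.dtype, np.number):
                raise InputFormatError(f"{path}: column '{col}' is not numeric")
            if vals.isna().any():
                line = int(vals.isna().idxmax()) + 2  # header is line 1
                raise InputFormatError(
                    f"{path}: missing value in column '{col}', line {line}"
                )
            if (vals < 0).any():
                line = int((vals < 0).idxmax()) + 2
                raise InputFormatError(
                    f"{path}: negative count in column '{col}', line {line}"
                )
            if not np.allclose(vals, np.round(vals)):
                raise InputFormatError(
                    f"{path}: non-integer count in column '{col}'"
                )
        channels[ch] = block.to_numpy(dtype=np.int64)
    return AlleleCountSet(
        gene_ids=[str(g) for g in df["gene_id"]],
        channels=channels,
        condition_label=condition_label,
    )


def write_counts(counts: AlleleCountSet, path: str | Path) -> None:
    counts.to_frame().to_csv(path, sep="\t", index=False)


def read_snp_table(path: str | Path) -> pd.DataFrame:
    """SNP window table: gene_id, allele_A_seq, allele_B_seq."""
    df = _read_tsv(path, "SNP window")
    for col in ("gene_id", "allele_A_seq", "allele_B_seq"):
        if col not in df.columns:
            raise InputFormatError(f"{path}: missing required column '{col}'")
    for idx, row in df.iterrows():
        a, b = str(row["allele_A_seq"]), str(row["allele_B_seq"])
        line = int(idx) + 2
        if not re.fullmatch(r"[ACGT]+", a) or not re.fullmatch(r"[ACGT]+", b):
            raise InputFormatError(
                f"{path}: non-ACGT window at line {line} ({row['gene_id']})"
            )
        if len(a) != len(b):
            raise InputFormatError(
                f"{path}: unequal window lengths at line {line} ({row['gene_id']})"
            )
        if a == b:
            raise InputFormatError(
                f"{path}: identical allele windows at line {line} ({row['gene_id']})"
            )
    return df


def write_snp_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """TSV writer used for all derived tables (6 significant digits)."""
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_motif_hits(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a combined motif-hit table and split it by set_label.

    Expected columns: gene_id, set_label (foreground/background),
    scanned_length, then one nonnegative-integer column per motif.
    """
    df = _read_tsv(path, "motif-hit")
    for col in ("gene_id", "set_label", "scanned_length"):
        if col not in df.columns:
            raise InputFormatError(f"{path}: missing required column '{col}'")
    labels = set(df["set_label"])
    if labels != {"foreground", "background"}:
        raise InputFormatError(
            f"{path}: set_label must be foreground/background, found {sorted(labels)}"
        )
    motif_cols = [
        c for c in df.columns if c not in ("gene_id", "set_label", "scanned_length")
    ]
    if not motif_cols:
        raise InputFormatError(f"{path}: no motif columns")
    fg = df[df["set_label"] == "foreground"].drop(columns="set_label")
    bg = df[df["set_label"] == "background"].drop(columns="set_label")
    return fg.reset_index(drop=True), bg.reset_index(drop=True)
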