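"""Synthetic F0/F1 allele-specific expression data with planted ground truth.

Generative model
----------------
Each gene g has a baseline expression level mu_g (log2-normal across
genes), a regulatory category and two log2 effect sizes:

* ``cis_log2`` — an allele-linked effect, carried by the B allele and
  therefore visible both between the parental strains and between the
  two alleles of the F1 hybrid;
* ``trans_log2`` — a diffusible-regulator effect, acting on whichever
  genome it finds itself in: it separates the parental strains but is
  shared by both alleles inside the F1 nucleus and so cancels from the
  F1 allelic ratio.

Channel means per replicate library (s_j = planted library size factor):

    F0_A : s * mu
    F0_B : s * mu * 2**(cis + trans)
    F1_A : s * mu / 2
    F1_B : s * (mu / 2) * 2**cis

F1 per-allele baselines are mu/2 so total F1 depth matches an F0
library.  Counts are negative binomial with variance mu + alpha * mu**2
(alpha = 0 degenerates to Poisson).  Three independent RNG streams
(counts, reads, motifs) are spawned from the master seed at fixed
offsets so enlarging one simulation never perturbs another.

The read simulator emits error-free FASTQ whose reads each embed one
allele's SNP window, together with the window table and exact per-allele
truth counts, so substring counting can be validated as a round trip.
The motif simulator plants a single enriched transcription-factor site
into a foreground gene set over a Poisson background.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = [
    "CHANNELS",
    "CATEGORIES",
    "SimConfig",
    "SimTruth",
    "AlleleCountSet",
    "simulate_counts",
    "simulate_reads",
    "simulate_motif_hits",
]

CHANNELS = ("F0_A", "F0_B", "F1_A", "F1_B")
CATEGORIES = ("conserved", "cis_only", "trans_only", "cis_trans")

_BASES = np.frombuffer(b"ACGT", dtype="S1")

# stream offsets: counts, reads, motifs
_STREAM_COUNTS, _STREAM_READS, _STREAM_MOTIFS = 0, 1, 2


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


@dataclass
class SimConfig:
    """Study-design parameters of the count simulator.

    Defaults mirror the F1-hybrid brain design being emulated: three
    replicate libraries per group and roughly 20% of genes carrying some
    regulatory divergence, predominantly cis.  Effect magnitudes are
    drawn uniformly from a (low, high) range in log2 units with random
    sign; a scalar fixes the magnitude and randomises only the sign.
    """

    n_genes: int = 2000
    n_replicates: int = 3
    category_proportions: dict[str, float] = field(
        default_factory=lambda: {
            "conserved": 0.80,
            "cis_only": 0.10,
            "trans_only": 0.07,
            "cis_trans": 0.03,
        }
    )
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 2.0
    dispersion: float = 0.001
    cis_effect_log2: float | tuple[float, float] = (0.5, 2.0)
    trans_effect_log2: float | tuple[float, float] = (0.5, 2.0)
    size_factor_range: tuple[float, float] = (0.7, 1.3)
    seed: int = 0
    condition_label: str = "condition"

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_replicates < 1:
            raise ConfigurationError("n_genes and n_replicates must be >= 1")
        props = self.category_proportions
        unknown = set(props) - set(CATEGORIES)
        if unknown:
            raise ConfigurationError(f"unknown categories: {sorted(unknown)}")
        if any(v < 0 for v in props.values()):
            raise ConfigurationError("category proportions must be nonnegative")
        if abs(sum(props.values()) - 1.0) > 1e-9:
            raise ConfigurationError("category proportions must sum to 1")
        if self.baseline_log2_sd < 0 or self.dispersion < 0:
            raise ConfigurationError("scale parameters must be nonnegative")
        lo, hi = self.size_factor_range
        if not (0 < lo <= hi):
            raise ConfigurationError("size_factor_range must be positive and ordered")
        for name in ("cis_effect_log2", "trans_effect_log2"):
            eff = getattr(self, name)
            if np.isscalar(eff):
                if eff <= 0:
                    raise ConfigurationError(f"{name} must be positive")
            else:
                lo, hi = eff
                if not (0 < lo <= hi):
                    raise ConfigurationError(f"{name} range must be positive, ordered")


@dataclass
class SimTruth:
    """Planted per-gene ground truth plus the planted library size factors.

    ``cis_log2`` is zero for conserved and trans-only genes; ``trans_log2``
    is zero for conserved and cis-only genes.  ``size_factors`` maps each
    channel to its per-replicate planted scaling.
    """

    table: pd.DataFrame  # gene_id, category, cis_log2, trans_log2, baseline_mean
    size_factors: dict[str, np.ndarray] = field(default_factory=dict)

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SimTruth":
        return cls(table=pd.read_csv(path, sep="\t"))


@dataclass
class AlleleCountSet:
    """Four-channel gene x replicate count tensor with group labels."""

    gene_ids: list[str]
    channels: dict[str, np.ndarray]  # channel -> (n_genes, n_replicates) int64
    condition_label: str = ""

    def __post_init__(self) -> None:
        shapes = {ch: m.shape for ch, m in self.channels.items()}
        if set(self.channels) != set(CHANNELS):
            raise ConfigurationError(f"channels must be exactly {CHANNELS}")
        if len(set(shapes.values())) != 1:
            raise ConfigurationError(f"channel shapes differ: {shapes}")
        n_genes = next(iter(shapes.values()))[0]
        if n_genes != len(self.gene_ids):
            raise ConfigurationError("gene_ids length does not match matrices")
        for ch, m in self.channels.items():
            if (np.asarray(m) < 0).any():
                raise ConfigurationError(f"negative counts in channel {ch}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_replicates(self) -> int:
        return self.channels[CHANNELS[0]].shape[1]

    def to_matrix(self) -> tuple[np.ndarray, list[str]]:
        """Stack the four channels into a (genes x libraries) matrix.

        Column order is F0_A_rep1..k, F0_B_rep1..k, F1_A_rep1..k, F1_B_rep1..k.
        """
        cols: list[str] = []
        blocks = []
        for ch in CHANNELS:
            blocks.append(self.channels[ch])
            cols += [f"{ch}_rep{j + 1}" for j in range(self.n_replicates)]
        return np.hstack(blocks), cols

    def to_frame(self) -> pd.DataFrame:
        mat, cols = self.to_matrix()
        df = pd.DataFrame(mat, columns=cols)
        df.insert(0, "gene_id", self.gene_ids)
        return df


def _effect_magnitudes(eff, size: int, rng: np.random.Generator) -> np.ndarray:
    if np.isscalar(eff):
        mag = np.full(size, float(eff))
    else:
        mag = rng.uniform(eff[0], eff[1], size=size)
    sign = rng.choice([-1.0, 1.0], size=size)
    return mag * sign


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    if alpha == 0.0:
        return rng.poisson(mean).astype(np.int64)
    shape = 1.0 / alpha
    p = shape / (shape + mean)
    return rng.negative_binomial(shape, p).astype(np.int64)


def simulate_counts(config: SimConfig) -> tuple[AlleleCountSet, SimTruth]:
    """Draw a four-channel count set and its ground truth from ``config``."""
    config.validate()
    rng = _rng(config.seed, _STREAM_COUNTS)
    n = config.n_genes

    # deterministic apportionment of category counts, then shuffle
    props = [config.category_proportions.get(c, 0.0) for c in CATEGORIES]
    counts = [int(np.floor(p * n)) for p in props]
    rem = n - sum(counts)
    frac_order = np.argsort([-(p * n - np.floor(p * n)) for p in props], kind="stable")
    for i in range(rem):
        counts[frac_order[i % len(counts)]] += 1
    cats = np.repeat(CATEGORIES, counts)
    rng.shuffle(cats)

    baseline = 2.0 ** rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, n)
    cis = np.zeros(n)
    trans = np.zeros(n)
    has_cis = np.isin(cats, ("cis_only", "cis_trans"))
    has_trans = np.isin(cats, ("trans_only", "cis_trans"))
    cis[has_cis] = _effect_magnitudes(config.cis_effect_log2, int(has_cis.sum()), rng)
    trans[has_trans] = _effect_magnitudes(
        config.trans_effect_log2, int(has_trans.sum()), rng
    )

    # one factor per sequencing library: each F0 strain replicate is its
    # own library, while an F1 library contains both alleles at once
    sf_f1 = rng.uniform(*config.size_factor_range, size=config.n_replicates)
    sf = {
        "F0_A": rng.uniform(*config.size_factor_range, size=config.n_replicates),
        "F0_B": rng.uniform(*config.size_factor_range, size=config.n_replicates),
        "F1_A": sf_f1,
        "F1_B": sf_f1,
    }
    ch_mean = {
        "F0_A": baseline,
        "F0_B": baseline * 2.0 ** (cis + trans),
        "F1_A": baseline / 2.0,
        "F1_B": (baseline / 2.0) * 2.0**cis,
    }
    channels = {}
    for ch in CHANNELS:
        mean = ch_mean[ch][:, None] * sf[ch][None, :]
        channels[ch] = _nb_draw(rng, mean, config.dispersion)

    gene_ids = [f"g{i + 1:05d}" for i in range(n)]
    truth = SimTruth(
        table=pd.DataFrame(
            {
                "gene_id": gene_ids,
                "category": cats,
                "cis_log2": cis,
                "trans_log2": trans,
                "baseline_mean": baseline,
            }
        ),
        size_factors=sf,
    )
    acs = AlleleCountSet(
        gene_ids=gene_ids, channels=channels, condition_label=config.condition_label
    )
    return acs, truth


# ---------------------------------------------------------------------------
# read-level simulation


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def simulate_reads(
    truth: SimTruth,
    out_dir: str | Path,
    snps_per_gene: int = 2,
    read_length: int = 100,
    depth: int = 100,
    seed: int = 0,
    n_replicates: int = 1,
    window_length: int = 24,
) -> tuple[list[Path], pd.DataFrame, pd.DataFrame]:
    """Emit error-free F1 FASTQ reads carrying allele-discriminating SNPs.

    Per gene a pair of equal-length windows is built differing at
    ``snps_per_gene`` positions; each read embeds exactly one allele's
    window in random flanking sequence.  Allele B receives a share of
    ``depth`` reads of round(depth * 2**cis / (1 + 2**cis)), i.e. the
    allelic ratio implied by the planted cis effect, planted exactly.

    Returns (fastq paths, SNP window table, true per-replicate counts
    with columns gene_id, replicate, count_A, count_B).
    """
    if snps_per_gene < 1 or depth < 0 or n_replicates < 1:
        raise ConfigurationError("snps_per_gene, n_replicates >= 1 and depth >= 0")
    if window_length > read_length:
        raise ConfigurationError(
            f"SNP window ({window_length}) longer than read ({read_length})"
        )
    if snps_per_gene > window_length:
        raise ConfigurationError("more SNPs than window positions")
    rng = _rng(seed, _STREAM_READS)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    genes = truth.table
    n = len(genes)
    win_a, win_b = [], []
    for _ in range(n):
        wa = _random_seq(rng, window_length)
        wb = wa.copy()
        pos = rng.choice(window_length, size=snps_per_gene, replace=False)
        for pidx in pos:
            cur = wb[pidx]
            alt = _BASES[rng.integers(0, 3)]
            if alt == cur:  # pick a different base deterministically
                alt = _BASES[(np.where(_BASES == cur)[0][0] + 1) % 4]
            wb[pidx] = alt
        win_a.append(wa.tobytes().decode())
        win_b.append(wb.tobytes().decode())
    snp_table = pd.DataFrame(
        {"gene_id": genes["gene_id"], "allele_A_seq": win_a, "allele_B_seq": win_b}
    )

    p_b = 2.0 ** genes["cis_log2"].to_numpy()
    p_b = p_b / (1.0 + p_b)
    n_b = np.rint(depth * p_b).astype(int)
    n_a = depth - n_b

    paths: list[Path] = []
    rows = []
    for rep in range(1, n_replicates + 1):
        path = out_dir / f"reads_rep{rep}.fastq"
        records = []
        for gi in range(n):
            for allele, win, count in (("A", win_a[gi], n_a[gi]), ("B", win_b[gi], n_b[gi])):
                for ridx in range(count):
                    off = int(rng.integers(0, read_length - window_length + 1))
                    seq = _random_seq(rng, read_length)
                    seq[off : off + window_length] = np.frombuffer(
                        win.encode(), dtype="S1"
                    )
                    records.append(
                        (f"{genes['gene_id'].iloc[gi]}_{allele}_r{rep}_{ridx}",
                         seq.tobytes().decode())
                    )
            rows.append(
                {
                    "gene_id": genes["gene_id"].iloc[gi],
                    "replicate": rep,
                    "count_A": int(n_a[gi]),
                    "count_B": int(n_b[gi]),
                }
            )
        order = rng.permutation(len(records))
        with open(path, "w") as fh:
            for i in order:
                name, seq = records[i]
                fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")
        paths.append(path)
    true_counts = pd.DataFrame(rows)
    return paths, snp_table, true_counts


# ---------------------------------------------------------------------------
# motif-hit simulation


def simulate_motif_hits(
    n_fg: int,
    n_bg: int,
    motif_ids: list[str],
    planted_motif: str | None,
    fg_rate_multiplier: float = 10.0,
    bg_hit_rate: float = 2e-4,
    seq_len: int = 5000,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Poisson motif-hit tables for a foreground and a background gene set.

    Every motif hits at ``bg_hit_rate`` per scanned base; in the
    foreground set only, ``planted_motif`` hits ``fg_rate_multiplier``
    times faster.  Returns two frames with columns gene_id,
    scanned_length and one hit-count column per motif.
    """
    if bg_hit_rate < 0 or fg_rate_multiplier <= 0 or seq_len < 0:
        raise ConfigurationError("rates must be nonnegative, multiplier positive")
    if planted_motif is not None and planted_motif not in motif_ids:
        raise ConfigurationError(f"planted motif {planted_motif!r} not in motif_ids")
    rng = _rng(seed, _STREAM_MOTIFS)

    def _table(n_genes: int, prefix: str, planted: bool) -> pd.DataFrame:
        data = {"gene_id": [f"{prefix}{i + 1:05d}" for i in range(n_genes)],
                "scanned_length": np.full(n_genes, seq_len, dtype=int)}
        for m in motif_ids:
            rate = bg_hit_rate * seq_len
            if planted and m == planted_motif:
                rate *= fg_rate_multiplier
            hits = rng.poisson(rate, size=n_genes)
            data[m] = np.minimum(hits, seq_len)
        return pd.DataFrame(data)

    fg = _table(n_fg, "fg", planted=True)
    bg = _table(n_bg, "bg", planted=False)
    return fg, bg
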