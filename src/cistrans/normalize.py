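"""Median-of-ratios library normalization and the expressed-gene filter.

Size factors follow the DESeq median-of-ratios construction: each
library's factor is the median over reference genes (rows positive in
every library) of the ratio between that library's count and the
gene's geometric mean across libraries.  Factors are then rescaled to
geometric mean 1 so normalization is depth-relative only.

In the four-channel design, factors are estimated per sequencing
library within two separate normalization groups:

* the six F0 libraries (parental strains A and B, all replicates) get
  one factor each, jointly estimated so the F0 binomial null of 0.5
  reflects equal expression rather than unequal depth;
* the F1 libraries get one factor each — shared by both allele
  channels, because both alleles of a hybrid are sequenced in the same
  library — estimated from the per-library allele-summed totals.

Each group is rescaled to geometric mean 1 on its own.  The groups are
deliberately not placed on a common scale: every downstream statistic
is within-group (F0 binomial, F1 binomial) or ratio-based (the Fisher
test conditions on its row totals), and rescaling counts by a constant
far from 1 would distort their sampling variance relative to their
magnitude, invalidating the exact tests.

The expressed-gene filter retains a gene when at least one channel's
mean raw count across replicates strictly exceeds the threshold
(default 10 reads), defining the analysis universe.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .simulate import CHANNELS, AlleleCountSet

__all__ = [
    "size_factors",
    "expression_filter",
    "normalize_counts",
    "NormalizedCountSet",
]


def size_factors(
    count_matrix: np.ndarray, allow_pseudo_reference: bool = False
) -> np.ndarray:
    """Per-library size factors (geometric mean 1) for a genes x libraries matrix.

    Parameters
    ----------
    count_matrix : ndarray
        Nonnegative counts, genes in rows, libraries in columns.
    allow_pseudo_reference : bool
        When no gene is positive in every library, fall back to per-gene
        geometric means over the positive entries only (otherwise raise).
    """
    m = np.asarray(count_matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 1 or m.shape[1] < 1:
        raise ConfigurationError("count matrix must be 2-D and nonempty")
    if (m < 0).any():
        raise ConfigurationError("negative counts")
    if m.shape[1] == 1:
        return np.ones(1)

    with np.errstate(divide="ignore"):
        logm = np.log(m)
    all_pos = np.isfinite(logm).all(axis=1)
    if all_pos.any():
        ref = logm[all_pos].mean(axis=1)  # log geometric mean per gene
        log_ratios = logm[all_pos] - ref[:, None]
    elif allow_pseudo_reference:
        pos = np.isfinite(logm)
        usable = pos.any(axis=1)
        if not usable.any():
            raise ConfigurationError("all-zero count matrix")
        ref = np.where(pos[usable], logm[usable], 0.0).sum(axis=1) / pos[usable].sum(
            axis=1
        )
        log_ratios = np.where(
            pos[usable], logm[usable] - ref[:, None], np.nan
        )
    else:
        raise ConfigurationError(
            "no gene has positive counts in every library; rerun with "
            "allow_pseudo_reference=True (CLI: --pseudo-reference)"
        )
    log_sf = np.nanmedian(log_ratios, axis=0)
    log_sf = log_sf - log_sf.mean()  # geometric mean 1
    return np.exp(log_sf)


def expression_filter(
    counts: AlleleCountSet, threshold: float = 10
) -> tuple[np.ndarray, int]:
    """Boolean mask of expressed genes and the retained-universe size.

    A gene is expressed when, in at least one of the four strain
    channels, its mean raw count across replicates strictly exceeds
    ``threshold``.
    """
    if threshold < 0:
        raise ConfigurationError("threshold must be nonnegative")
    means = np.column_stack(
        [counts.channels[ch].mean(axis=1) for ch in CHANNELS]
    )
    mask = (means > threshold).any(axis=1)
    return mask, int(mask.sum())


@dataclass
class NormalizedCountSet:
    """An AlleleCountSet plus per-column size factors and normalized values."""

    counts: AlleleCountSet
    size_factors: dict[str, np.ndarray]  # channel -> per-replicate factor
    normalized: dict[str, np.ndarray]  # channel -> float matrix raw / factor

    def rounded(self) -> dict[str, np.ndarray]:
        """Normalized counts rounded half-to-even to integers.

        Downstream exact tests require integer counts; banker's rounding
        avoids systematic upward bias.
        """
        return {
            ch: np.rint(mat).astype(np.int64) for ch, mat in self.normalized.items()
        }


def normalize_counts(
    counts: AlleleCountSet, allow_pseudo_reference: bool = False
) -> NormalizedCountSet:
    """Per-library median-of-ratios normalization in two groups.

    F0 factors come from the six parental libraries jointly; F1 factors
    come from the per-library allele totals and are shared by the two
    allele channels of each library (see module docstring).
    """
    f0 = np.hstack([counts.channels["F0_A"], counts.channels["F0_B"]])
    sf_f0 = size_factors(f0, allow_pseudo_reference=allow_pseudo_reference)
    k = counts.n_replicates
    f1_totals = counts.channels["F1_A"] + counts.channels["F1_B"]
    sf_f1 = size_factors(f1_totals, allow_pseudo_reference=allow_pseudo_reference)
    sf_by_channel = {
        "F0_A": sf_f0[:k],
        "F0_B": sf_f0[k:],
        "F1_A": sf_f1,
        "F1_B": sf_f1,
    }
    normalized = {
        ch: counts.channels[ch] / sf_by_channel[ch][None, :] for ch in CHANNELS
    }
    return NormalizedCountSet(
        counts=counts, size_factors=sf_by_channel, normalized=normalized
    )
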