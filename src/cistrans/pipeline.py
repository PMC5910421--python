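"""End-to-end orchestration with stable file contracts and logging."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ConfigurationError
from .io import read_counts, write_counts, write_snp_table, write_table
from .model import CisTransModel
from .simulate import SimConfig, simulate_counts, simulate_reads

__all__ = ["RunConfig", "run_pipeline", "setup_logging"]

log = logging.getLogger("cistrans")


def setup_logging(out_dir: Path | None = None, level: str = "INFO") -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        handlers.append(logging.FileHandler(out_dir / "run.log", mode="w"))
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )


@dataclass
class RunConfig:
    """Options for a classification run on one condition."""

    counts_path: str | Path
    out_dir: str | Path
    condition_label: str = ""
    alpha: float = 0.01
    min_count: float = 10
    normalize: bool = True
    allow_pseudo_reference: bool = False
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError(f"alpha={self.alpha} outside (0, 1)")
        if self.min_count < 0:
            raise ConfigurationError("min_count must be >= 0")


def run_pipeline(config: RunConfig):
    """Classify one condition's counts and write the run directory.

    Outputs: classification.tsv, scatter.tsv, summary.json, run.log.
    Deterministic given identical inputs.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    setup_logging(out_dir, config.log_level)
    log.info(
        "classify: counts=%s alpha=%g min_count=%g normalize=%s",
        config.counts_path,
        config.alpha,
        config.min_count,
        config.normalize,
    )
    counts = read_counts(config.counts_path, condition_label=config.condition_label)
    log.info(
        "loaded %d genes x %d replicates per channel", counts.n_genes,
        counts.n_replicates,
    )
    model = CisTransModel(
        counts,
        alpha=config.alpha,
        min_count=config.min_count,
        normalize=config.normalize,
        allow_pseudo_reference=config.allow_pseudo_reference,
    )
    results = model.fit()
    log.info(
        "universe %d genes, %d divergent (%.1f%%)",
        results.n_universe,
        results.n_divergent,
        results.summary_dict["pct_divergent"],
    )
    results.to_dir(out_dir)
    return results


def simulate_to_dir(config: SimConfig, out_dir: str | Path, reads: bool = False):
    """Generate a synthetic dataset and write its files to ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    counts, truth = simulate_counts(config)
    write_counts(counts, out_dir / "counts.tsv")
    truth.to_tsv(out_dir / "truth.tsv")
    with open(out_dir / "sim_summary.json", "w") as fh:
        json.dump(
            {
                "n_genes": config.n_genes,
                "n_replicates": config.n_replicates,
                "seed": config.seed,
                "condition_label": config.condition_label,
            },
            fh,
            indent=2,
        )
        fh.write("\n")
    if reads:
        paths, snp_table, true_counts = simulate_reads(
            truth, out_dir, seed=config.seed
        )
        write_snp_table(snp_table, out_dir / "snps.tsv")
        write_table(true_counts, out_dir / "true_allele_counts.tsv")
    return counts, truth
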