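"""Synthetic densitometry tables and variant lists.

The densitometry generator emulates quantification of supernatant/pellet
western-blot bands for a wild-type construct and aggregating mutants: a
construct's ``solubility_shift`` moves the stated fraction of its expected
supernatant signal into the pellet (signal is conserved, never created).
Multiplicative Gaussian noise with a configurable coefficient of variation
models blot-to-blot variability; ``noise_cv = 0`` returns the exact
expected means.

The variant-list generator produces a small VCF-shaped cohort with gene
symbols, population allele frequencies and pass-through predictor scores
for exercising the prioritization filters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..variants import VariantRecord

__all__ = ["DensitometryConfig", "simulate_densitometry", "simulate_variant_table"]

FRACTIONS = ("supernatant", "pellet")


@dataclass(frozen=True)
class DensitometryConfig:
    """Defaults mirror a three-experiment triplicate design (n = 9 per
    construct and fraction) with WT mostly soluble."""

    constructs: tuple[str, ...] = ("WT", "P7T", "A13V", "P27A", "S78N")
    n_experiments: int = 3
    replicates_per_experiment: int = 3
    wt_sup_mean: float = 1000.0
    wt_pel_mean: float = 400.0
    solubility_shift: dict | None = None   # construct -> fraction moved to pellet
    noise_cv: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.n_experiments < 1 or self.replicates_per_experiment < 1:
            raise ValueError("counts must be >= 1")
        if self.wt_sup_mean <= 0 or self.wt_pel_mean < 0:
            raise ValueError("WT band means must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be nonnegative")
        for k, v in (self.solubility_shift or {}).items():
            if not 0 <= v <= 1:
                raise ValueError(f"solubility_shift[{k!r}] must be in [0, 1]")

    def shift_for(self, construct: str) -> float:
        default_shifts = {"P7T": 0.6, "A13V": 0.5, "P27A": 0.15, "S78N": 0.15}
        table = self.solubility_shift if self.solubility_shift is not None else default_shifts
        return float(table.get(construct, 0.0))


def simulate_densitometry(config: DensitometryConfig) -> pd.DataFrame:
    """One row per (construct, experiment, replicate, fraction).

    Expected supernatant mean of a construct is
    ``wt_sup_mean * (1 - shift)``; the shifted signal is added to the
    pellet so supernatant + pellet totals match WT for every construct.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    rows = []
    for construct in config.constructs:
        shift = config.shift_for(construct)
        expected = {
            "supernatant": config.wt_sup_mean * (1.0 - shift),
            "pellet": config.wt_pel_mean + config.wt_sup_mean * shift,
        }
        for exp in range(1, config.n_experiments + 1):
            for rep in range(1, config.replicates_per_experiment + 1):
                for fraction in FRACTIONS:
                    mean = expected[fraction]
                    noise = rng.normal(0.0, config.noise_cv) if config.noise_cv > 0 else 0.0
                    rows.append(
                        dict(
                            construct=construct,
                            experiment=exp,
                            replicate=rep,
                            fraction=fraction,
                            band_intensity=max(mean * (1.0 + noise), 0.0),
                            total_protein=1.0,
                        )
                    )
    return pd.DataFrame(rows)


def simulate_variant_table(
    n_variants: int = 10,
    gene_list=("SMPX", "TTN", "DES", "MYOT", "FLNC"),
    n_pass: int = 3,
    seed: int = 0,
) -> list[VariantRecord]:
    """A toy cohort: ``n_pass`` variants are rare and in-list; the rest
    fail either the frequency or the gene-list filter."""
    rng = np.random.default_rng(seed)
    genes_in = list(gene_list)
    genes_out = ["BRCA2", "CFTR", "APOE", "HBB", "OT1"]
    bases = np.array(list("ACGT"))
    records = []
    for i in range(n_variants):
        ref, alt = rng.choice(bases, size=2, replace=False)
        if i < n_pass:
            gene = genes_in[i % len(genes_in)]
            af = {"gnomAD_AF": float(rng.uniform(0, 5e-4))} if rng.random() < 0.7 else {}
        elif i % 2 == 0:
            gene = genes_in[i % len(genes_in)]
            af = {"gnomAD_AF": float(rng.uniform(2e-3, 0.2))}
        else:
            gene = genes_out[i % len(genes_out)]
            af = {"gnomAD_AF": float(rng.uniform(0, 5e-4))}
        records.append(
            VariantRecord(
                chrom="chrX",
                pos=int(rng.integers(1e6, 5e7)),
                ref=str(ref),
                alt=str(alt),
                gene=gene,
                cds_pos=int(rng.integers(1, 270)),
                population_af=af,
                external_scores={"CADD": float(rng.uniform(0, 35))},
            )
        )
    return records
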