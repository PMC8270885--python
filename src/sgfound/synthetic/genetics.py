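"""Synthetic hemizygous X-chromosome genotype panels with a planted
identity-by-descent segment.

All individuals are hemizygous males (one allele per marker).  Carriers
share one haplotype over a planted physical interval; immediately outside
each end they are forced discordant (at least two carriers differ at the
first flanking marker) so the shared segment is exactly recoverable.
Markers are placed at the planted interval's endpoints so the recovered
outermost-concordant-marker boundaries coincide with the planted ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["GenotypePanelConfig", "simulate_genotype_panel", "DEFAULT_MAP_POINTS"]

#: Default (bp, cM) anchor points for the simulated Xp region; piecewise
#: linear between anchors, averaging ~1.5 cM/Mb.
DEFAULT_MAP_POINTS = (
    (12_000_000, 0.00),
    (15_000_000, 4.10),
    (17_499_443, 7.55),
    (20_000_000, 11.40),
    (22_849_591, 15.62),
    (26_000_000, 20.70),
    (33_000_000, 31.50),
)

ALLELES = ("A", "B")


@dataclass(frozen=True)
class GenotypePanelConfig:
    n_markers: int = 60
    chrom_span_bp: tuple[int, int] = (12_000_000, 33_000_000)
    shared_interval_bp: tuple[int, int] = (17_499_443, 22_849_591)
    carrier_ids: tuple[str, ...] = ("F1_II1", "F2_II2")
    n_noncarriers: int = 6
    allele_freq: float = 0.35
    map_points: tuple[tuple[float, float], ...] = DEFAULT_MAP_POINTS
    chrom: str = "chrX"
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.chrom_span_bp
        slo, shi = self.shared_interval_bp
        if not (lo < slo < shi < hi):
            raise ValueError("shared_interval_bp must lie strictly within chrom_span_bp")
        if len(self.carrier_ids) < 2:
            raise ValueError("need at least 2 carriers")
        if not 0 < self.allele_freq < 1:
            raise ValueError("allele_freq must be in (0, 1)")
        bps = [p for p, _ in self.map_points]
        cms = [c for _, c in self.map_points]
        if not (np.all(np.diff(bps) > 0) and np.all(np.diff(cms) > 0)):
            raise ValueError("map_points must be strictly increasing in bp and cM")
        if self.n_markers < 5:
            raise ValueError("need at least 5 markers (interval + flanks)")


def simulate_genotype_panel(config: GenotypePanelConfig):
    """Return ``(panel, truth)``.

    ``panel`` has one row per marker (marker_id, pos_bp, cM, then one
    allele column per individual); ``truth`` records the planted interval
    and carrier ids.  Raises if the sampled markers fail to cover the
    shared interval with at least one marker inside and one flanking
    marker on each side.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    lo, hi = config.chrom_span_bp
    slo, shi = config.shared_interval_bp

    n_random = config.n_markers - 2
    pos = rng.choice(np.arange(lo, hi + 1), size=n_random, replace=False)
    pos = np.unique(np.concatenate([pos, [slo, shi]]))
    inside = (pos >= slo) & (pos <= shi)
    if inside.sum() < 1 or (pos < slo).sum() < 1 or (pos > shi).sum() < 1:
        raise ValueError(
            "marker coverage violated: need >=1 marker inside the shared "
            "interval and >=1 flanking marker on each side"
        )

    n_markers = len(pos)
    carriers = list(config.carrier_ids)
    noncarriers = [f"CTRL_{i+1}" for i in range(config.n_noncarriers)]
    freq = np.full(n_markers, config.allele_freq)

    def draw(n):
        return np.where(rng.random((n_markers, n)) < freq[:, None],
                        ALLELES[1], ALLELES[0])

    geno = {}
    carrier_mat = draw(len(carriers)).astype(object)
    shared_hap = draw(1)[:, 0]
    carrier_mat[inside, :] = shared_hap[inside, None]

    # force discordance at the first marker outside each end
    for idx in (np.where(pos < slo)[0].max(), np.where(pos > shi)[0].min()):
        row = carrier_mat[idx, :]
        if len(set(row)) == 1:
            flip = ALLELES[1] if row[0] == ALLELES[0] else ALLELES[0]
            carrier_mat[idx, 0] = flip
    for j, cid in enumerate(carriers):
        geno[cid] = carrier_mat[:, j]
    nc = draw(len(noncarriers))
    for j, cid in enumerate(noncarriers):
        geno[cid] = nc[:, j]

    bps = np.array([p for p, _ in config.map_points], dtype=float)
    cms = np.array([c for _, c in config.map_points], dtype=float)
    panel = pd.DataFrame(
        {
            "marker_id": [f"rsX{i:05d}" for i in range(n_markers)],
            "pos_bp": pos.astype(int),
            "cM": np.interp(pos, bps, cms),
            **geno,
        }
    )
    truth = {
        "chrom": config.chrom,
        "start_bp": int(slo),
        "end_bp": int(shi),
        "carriers": carriers,
        "noncarriers": noncarriers,
    }
    return panel, truth


def genetic_map_frame(config: GenotypePanelConfig) -> pd.DataFrame:
    """The config's genetic map as a (pos_bp, cM) table."""
    return pd.DataFrame(config.map_points, columns=["pos_bp", "cM"])
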