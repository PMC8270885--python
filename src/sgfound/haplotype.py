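"""Shared-haplotype detection on chromosome X and founder-mutation dating.

Affected males are hemizygous, so each individual carries a single allele
per marker and identity-by-descent sharing reduces to allele concordance:
the founder haplotype is the maximal run of consecutive markers around the
mutation at which all carriers are identical.  The segment's genetic length
(in cM) then dates the founder event: recombination erodes an ancestral
segment at ~1% per cM per meiosis, so a shared length of L cM among
descendants corresponds to on the order of ``200 / L`` generations, with a
generation time of 25 years.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "HaplotypeInterval",
    "FounderAgeEstimate",
    "find_shared_segment",
    "physical_span_mb",
    "genetic_length_cm",
    "estimate_founder_age",
]

#: Calibration constant of the length-based age rule g = AGE_CONSTANT_CM / L.
AGE_CONSTANT_CM = 200.0

DEFAULT_GENERATION_TIME_YEARS = 25.0


@dataclass(frozen=True)
class HaplotypeInterval:
    """A physical interval on chromosome X shared by all carriers.

    Coordinates are 1-based inclusive positions of the outermost concordant
    markers; ``span_mb`` is ``(end_bp - start_bp) / 1e6`` rounded to two
    decimals, the convention that reproduces published haplotype sizes.
    """

    chrom: str
    start_bp: int
    end_bp: int
    n_markers_inside: int
    length_cm: float | None = None

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError("start_bp must be <= end_bp")

    @property
    def span_mb(self) -> float:
        return physical_span_mb(self)


@dataclass(frozen=True)
class FounderAgeEstimate:
    """Point estimate of founder-mutation age from shared segment length."""

    length_cm_input: float
    generations_raw: float
    generations: int
    generation_time_years: float
    years: float

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"~{self.generations} generations (~{self.years:.0f} years) "
            f"from a {self.length_cm_input:g} cM shared segment"
        )


def find_shared_segment(
    panel: pd.DataFrame,
    carriers: list[str],
    mutation_pos_bp: int,
    *,
    chrom: str = "chrX",
    pos_col: str = "pos_bp",
    max_mismatch: int = 0,
) -> HaplotypeInterval:
    """Maximal run of consecutive markers, containing the mutation, at which
    all carriers share the same allele.

    Parameters
    ----------
    panel
        One row per marker with a physical-position column and one allele
        column per individual (hemizygous single-allele calls).
    carriers
        Column names of the affected individuals; at least two.
    mutation_pos_bp
        Physical position of the mutation; must lie within the marker span.
    max_mismatch
        Number of discordant markers tolerated inside the run (default 0:
        hemizygous array calls are high confidence).

    Returns the interval whose endpoints are the outermost concordant
    markers of the run.
    """
    if len(carriers) < 2:
        raise ValueError("sharing is undefined for fewer than two carriers")
    missing = [c for c in carriers if c not in panel.columns]
    if missing:
        raise KeyError(f"carrier columns not in panel: {missing}")
    panel = panel.sort_values(pos_col).reset_index(drop=True)
    pos = panel[pos_col].to_numpy()
    if not (pos[0] <= mutation_pos_bp <= pos[-1]):
        raise ValueError(
            f"mutation position {mutation_pos_bp} outside marker span "
            f"[{pos[0]}, {pos[-1]}]"
        )

    alleles = panel[list(carriers)].to_numpy()
    concordant = (alleles == alleles[:, [0]]).all(axis=1)

    # anchor: markers flanking (or at) the mutation position must share
    core = int(np.searchsorted(pos, mutation_pos_bp))
    anchors = {min(core, len(pos) - 1)}
    if pos[min(core, len(pos) - 1)] != mutation_pos_bp and core > 0:
        anchors.add(core - 1)
    nearest = min(anchors, key=lambda i: abs(int(pos[i]) - mutation_pos_bp))
    if not concordant[nearest]:
        raise ValueError(
            "no shared core: carriers are discordant at the marker nearest "
            f"the mutation (pos {pos[nearest]})"
        )

    lo = hi = nearest
    budget = max_mismatch
    while lo > 0:
        if concordant[lo - 1]:
            lo -= 1
        elif budget > 0 and lo - 2 >= 0 and concordant[lo - 2]:
            budget -= 1
            lo -= 2
        else:
            break
    while hi < len(pos) - 1:
        if concordant[hi + 1]:
            hi += 1
        elif budget > 0 and hi + 2 < len(pos) and concordant[hi + 2]:
            budget -= 1
            hi += 2
        else:
            break
    # endpoints must themselves be concordant markers
    while not concordant[lo]:
        lo += 1
    while not concordant[hi]:
        hi -= 1
    n_inside = int(concordant[lo : hi + 1].sum())
    return HaplotypeInterval(
        chrom=chrom,
        start_bp=int(pos[lo]),
        end_bp=int(pos[hi]),
        n_markers_inside=n_inside,
    )


def physical_span_mb(interval: HaplotypeInterval) -> float:
    """Physical span in Mb: ``(end - start) / 1e6`` rounded to 2 decimals."""
    return round((interval.end_bp - interval.start_bp) / 1e6, 2)


def genetic_length_cm(
    interval: HaplotypeInterval,
    genetic_map: pd.DataFrame,
    *,
    pos_col: str = "pos_bp",
    cm_col: str = "cM",
) -> float:
    """Genetic length ``cM(end) - cM(start)`` by piecewise-linear
    interpolation of a (bp, cM) map, strictly increasing in both columns.

    Positions outside the map range are linearly extrapolated from the
    terminal map segments, with a warning.
    """
    gmap = genetic_map.sort_values(pos_col)
    bp = gmap[pos_col].to_numpy(dtype=float)
    cm = gmap[cm_col].to_numpy(dtype=float)
    if len(bp) < 2:
        raise ValueError("genetic map needs at least two points")
    if not (np.all(np.diff(bp) > 0) and np.all(np.diff(cm) > 0)):
        raise ValueError("genetic map must be strictly increasing in bp and cM")

    def interp(x: float) -> float:
        if x < bp[0]:
            warnings.warn("position below map range; extrapolating", stacklevel=3)
            return cm[0] + (x - bp[0]) * (cm[1] - cm[0]) / (bp[1] - bp[0])
        if x > bp[-1]:
            warnings.warn("position above map range; extrapolating", stacklevel=3)
            return cm[-1] + (x - bp[-1]) * (cm[-1] - cm[-2]) / (bp[-1] - bp[-2])
        return float(np.interp(x, bp, cm))

    return interp(interval.end_bp) - interp(interval.start_bp)


def estimate_founder_age(
    length_cm: float,
    generation_time_years: float = DEFAULT_GENERATION_TIME_YEARS,
) -> FounderAgeEstimate:
    """Date a founder mutation from the shared genetic length.

    The rule is ``generations = 200 / length_cm``, rounded to the nearest
    integer for reporting, and ``years = generations * generation_time``.
    This is a calibration of the classic length-of-sharing decay argument
    (an ancestral segment shrinks by recombination at ~1%/cM/meiosis): an
    8.07 cM segment dates to ~25 generations (625 years), a 25.5 cM
    segment to ~8 generations (200 years).
    """
    if length_cm <= 0:
        raise ValueError("length_cm must be positive")
    g_raw = AGE_CONSTANT_CM / length_cm
    g = int(round(g_raw))
    g = max(g, 1)
    return FounderAgeEstimate(
        length_cm_input=float(length_cm),
        generations_raw=g_raw,
        generations=g,
        generation_time_years=float(generation_time_years),
        years=g * float(generation_time_years),
    )
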