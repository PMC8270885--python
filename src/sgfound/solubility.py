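"""Supernatant/pellet fractionation statistics.

RIPA fractionation splits cell lysate into a soluble supernatant and an
insoluble pellet; reduced supernatant share of a tagged protein indicates
aggregation.  Band densitometry is normalized to total protein loading and
to the mean of the wild-type construct within each experiment and fraction,
so WT maps to 1 by construction.  Mutants are compared to WT per fraction
with a two-tailed Mann-Whitney U test, Bonferroni-corrected across the
mutant constructs (replicates pooled across experiments, e.g. three
triplicate experiments giving n = 9 per group).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["normalize_fractions", "SolubilityAnalysis", "SolubilityResults",
           "mann_whitney_exact_or_asymptotic"]

FRACTIONS = ("supernatant", "pellet")
EXACT_N_MAX = 12  # per-group size up to which the exact null is enumerated


def normalize_fractions(
    table: pd.DataFrame,
    *,
    control: str = "WT",
    value_col: str = "band_intensity",
    total_col: str = "total_protein",
) -> pd.DataFrame:
    """Normalize densitometry to loading and to the per-experiment WT mean.

    ``normalized = (band/total) / mean_over_WT_replicates(band/total)``
    within each (experiment, fraction); the WT per-experiment mean is 1.
    """
    df = table.copy()
    required = {"construct", "experiment", "replicate", "fraction", value_col, total_col}
    missing = required - set(df.columns)
    if missing:
        raise KeyError(f"densitometry table missing columns: {sorted(missing)}")
    if (df[total_col] <= 0).any():
        raise ValueError("total_protein must be positive")
    df["loading_norm"] = df[value_col] / df[total_col]

    wt = df[df["construct"] == control]
    if wt.empty:
        raise ValueError(f"control construct {control!r} absent from table")
    wt_means = (
        wt.groupby(["experiment", "fraction"])["loading_norm"].mean().rename("wt_mean")
    )
    missing_exp = set(df["experiment"].unique()) - {e for e, _ in wt_means.index}
    if missing_exp:
        raise ValueError(f"control {control!r} missing from experiments {sorted(missing_exp)}")
    if (wt_means == 0).any():
        raise ValueError("wild-type mean intensity is zero in some experiment/fraction")
    df = df.join(wt_means, on=["experiment", "fraction"])
    df["normalized"] = df["loading_norm"] / df["wt_mean"]
    return df.drop(columns=["wt_mean"])


def _exact_mann_whitney_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact two-tailed Mann-Whitney p over the permutation null.

    Conditions on the pooled observed values, so ties are handled
    naturally; U uses the midrank (0.5 per tie) convention.  Two-tailed p
    is ``min(1, 2 * min(P(U <= u), P(U >= u)))``.
    """
    from itertools import combinations

    nx, ny = len(x), len(y)
    pooled = np.concatenate([x, y])
    # U for group x against group y: wins + half-ties
    def u_stat(ix: np.ndarray) -> float:
        xs = pooled[ix]
        mask = np.ones(nx + ny, dtype=bool)
        mask[ix] = False
        ys = pooled[mask]
        diff = xs[:, None] - ys[None, :]
        return float((diff > 0).sum() + 0.5 * (diff == 0).sum())

    u_obs = u_stat(np.arange(nx))
    us = np.array([u_stat(np.array(c)) for c in combinations(range(nx + ny), nx)])
    eps = 1e-9
    p_le = np.mean(us <= u_obs + eps)
    p_ge = np.mean(us >= u_obs - eps)
    return u_obs, min(1.0, 2.0 * min(p_le, p_ge))


def mann_whitney_exact_or_asymptotic(x, y) -> tuple[float, float, str]:
    """Two-tailed Mann-Whitney U: exact permutation null for groups up to
    12+12, normal approximation with tie correction otherwise.

    Returns (U, p, method).  All-tied samples give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("both groups must be nonempty")
    if np.all(np.concatenate([x, y]) == x[0]):
        # degenerate: no ordering information at all
        return len(x) * len(y) / 2.0, 1.0, "degenerate"
    if len(x) <= EXACT_N_MAX and len(y) <= EXACT_N_MAX:
        ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
        if not ties:
            res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            return float(res.statistic), float(res.pvalue), "exact"
        u, p = _exact_mann_whitney_p(x, y)
        return u, p, "exact"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue), "asymptotic"


def _stars(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


class SolubilityAnalysis:
    """Model object for a fractionation experiment.

    Parameters
    ----------
    table
        Densitometry rows (construct, experiment, replicate, fraction,
        band_intensity, total_protein).
    control
        Reference construct (default ``"WT"``).
    n_comparisons
        Bonferroni family size; default is the number of mutant constructs
        (supernatant and pellet treated as separate families).
    """

    def __init__(self, table: pd.DataFrame, *, control: str = "WT",
                 n_comparisons: int | None = None):
        self.table = table
        self.control = control
        self.n_comparisons = n_comparisons

    def fit(self) -> "SolubilityResults":
        norm = normalize_fractions(self.table, control=self.control)
        constructs = [c for c in norm["construct"].unique() if c != self.control]
        m = self.n_comparisons if self.n_comparisons is not None else max(len(constructs), 1)

        summary_rows = []
        for (construct, fraction), grp in norm.groupby(["construct", "fraction"], sort=False):
            vals = grp["normalized"].to_numpy()
            summary_rows.append(
                dict(construct=construct, fraction=fraction,
                     mean=vals.mean(), sd=vals.std(ddof=1) if len(vals) > 1 else 0.0,
                     n=len(vals))
            )
        summary = pd.DataFrame(summary_rows)

        comp_rows = []
        for fraction in norm["fraction"].unique():
            wt_vals = norm.query("construct == @self.control and fraction == @fraction")[
                "normalized"].to_numpy()
            for construct in constructs:
                mut = norm.query("construct == @construct and fraction == @fraction")[
                    "normalized"].to_numpy()
                if len(mut) == 0:
                    continue
                u, p, method = mann_whitney_exact_or_asymptotic(mut, wt_vals)
                p_adj = min(1.0, m * p)
                comp_rows.append(
                    dict(construct=construct, fraction=fraction,
                         mean_diff=mut.mean() - wt_vals.mean(),
                         U=u, p=p, p_bonferroni=p_adj, method=method,
                         stars=_stars(p_adj))
                )
        comparisons = pd.DataFrame(comp_rows)
        return SolubilityResults(norm, summary, comparisons, self.control, m)


@dataclass
class SolubilityResults:
    normalized: pd.DataFrame
    group_summary: pd.DataFrame
    comparisons: pd.DataFrame
    control: str
    n_comparisons: int

    def summary(self) -> str:
        lines = [
            "Solubility fractionation vs "
            f"{self.control} (two-tailed Mann-Whitney U, Bonferroni m={self.n_comparisons})",
            "", self.group_summary.to_string(index=False), "",
            self.comparisons.to_string(index=False) if not self.comparisons.empty
            else "(no mutant constructs)",
        ]
        return "\n".join(lines)
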