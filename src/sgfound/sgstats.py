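"""Replicate-level aggregation and repeated-measures inference for
stress-granule quantification experiments.

The experimental unit is the independent experiment (replicate): every
construct x treatment condition is measured in each experiment, so both
factors are within-subject.  Group means per condition are compared with a
two-way repeated-measures ANOVA using the Greenhouse-Geisser (GG)
sphericity correction, and constructs are compared against wild type with
Dunnett's many-to-one procedure on the paired per-replicate contrasts.

The two model classes follow the fit()-returns-results convention:

>>> res = RepeatedMeasuresAnova(wells, dv="prop_sg_cells",
...                             within=("construct", "treatment"),
...                             subject="replicate").fit()
>>> print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "aggregate_wells",
    "RepeatedMeasuresAnova",
    "RMAnovaResults",
    "DunnettComparison",
    "DunnettResults",
]

#: Seed and size of the Monte-Carlo reference sample for Dunnett critical
#: points; at 1e5 draws the p-value tolerance is about +/-0.002.
DUNNETT_MC_DRAWS = 100_000
DUNNETT_MC_SEED = 20231107

RESPONSE_COLUMNS = (
    "prop_sg_cells",
    "mean_sg_per_cell",
    "mean_enriched_sg_per_cell",
    "mean_nonenriched_sg_per_cell",
)


def aggregate_wells(
    image_summaries: pd.DataFrame,
    *,
    by=("construct", "treatment", "replicate"),
    weight_col: str = "n_cells_analyzed",
) -> pd.DataFrame:
    """Collapse per-image summaries to per-replicate group means.

    Means are cell-weighted across the images of a condition: an image
    contributing 150 analyzed cells counts three times as much as one
    contributing 50.  Returns one row per (construct, treatment, replicate)
    with the pooled cell count and each response's weighted mean.
    """
    df = image_summaries.copy()
    by = list(by)
    missing = set(by + [weight_col]) - set(df.columns)
    if missing:
        raise KeyError(f"image summaries missing columns: {sorted(missing)}")
    responses = [c for c in RESPONSE_COLUMNS if c in df.columns]
    if not responses:
        raise KeyError("no response columns found in image summaries")

    def _collapse(grp: pd.DataFrame) -> pd.Series:
        w = grp[weight_col].to_numpy(dtype=float)
        out = {"n_cells": w.sum(), "n_images": len(grp)}
        for col in responses:
            vals = grp[col].to_numpy(dtype=float)
            ok = ~np.isnan(vals)
            out[col] = np.average(vals[ok], weights=w[ok]) if w[ok].sum() > 0 else np.nan
        return pd.Series(out)

    wells = df.groupby(by, sort=False).apply(_collapse, include_groups=False).reset_index()
    return wells


def _check_complete(table: pd.DataFrame) -> None:
    if table.isna().any().any():
        bad = table.index[table.isna().any(axis=1)].tolist()
        raise ValueError(
            "incomplete repeated-measures design: subjects "
            f"{bad} lack some within-subject cells; drop them or supply a "
            "complete design"
        )


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal contrast matrix (rows orthonormal, each
    orthogonal to the unit vector)."""
    h = np.zeros((k - 1, k))
    for i in range(1, k):
        h[i - 1, :i] = 1.0
        h[i - 1, i] = -i
        h[i - 1] /= np.sqrt(i * (i + 1))
    return h


def _gg_epsilon(scores: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from per-subject contrast scores
    (n_subjects x q).  eps = tr(S)^2 / (q * tr(S^2)), clamped to
    [1/q, 1]."""
    q = scores.shape[1]
    s = np.cov(scores, rowvar=False)
    s = np.atleast_2d(s)
    eps = np.trace(s) ** 2 / (q * np.sum(s * s))
    return float(np.clip(eps, 1.0 / q, 1.0))


class RepeatedMeasuresAnova:
    """Two-way (or one-way) fully within-subject ANOVA with GG correction.

    Parameters
    ----------
    data
        Long-format table, one row per subject x cell.
    dv
        Response column.
    within
        One or two within-subject factor columns.
    subject
        Subject identifier column (the independent experiment).

    The design must be complete and balanced: every subject must have
    exactly one value in every factor-level combination (replicate rows
    for the same cell are averaged first).
    """

    def __init__(self, data: pd.DataFrame, dv: str, within, subject: str):
        self.data = data
        self.dv = dv
        self.within = [within] if isinstance(within, str) else list(within)
        if len(self.within) not in (1, 2):
            raise ValueError("within must name one or two factors")
        self.subject = subject

    def fit(self) -> "RMAnovaResults":
        df = self.data
        cell = df.groupby([self.subject] + self.within, sort=False)[self.dv].mean()
        wide = cell.unstack(self.within)
        _check_complete(wide)
        n = wide.shape[0]
        if n < 2:
            raise ValueError("repeated-measures ANOVA needs at least 2 subjects")
        levels = [df[f].nunique() for f in self.within]
        if any(k < 2 for k in levels):
            bad = [f for f, k in zip(self.within, levels) if k < 2]
            raise ValueError(f"within factor(s) {bad} have a single level")

        if len(self.within) == 1:
            table = self._fit_oneway(wide.to_numpy(), levels[0], n)
        else:
            a, b = levels
            y = wide.to_numpy().reshape(n, a, b)
            table = self._fit_twoway(y, n, a, b)
        return RMAnovaResults(anova_table=table, n_subjects=n,
                              within=self.within, dv=self.dv)

    @staticmethod
    def _effect_row(name, ss_eff, ss_err, df1, df2, scores):
        ms_eff = ss_eff / df1
        ms_err = ss_err / df2
        f = ms_eff / ms_err if ms_err > 0 else np.inf
        eps = _gg_epsilon(scores)
        p_unc = float(stats.f.sf(f, df1, df2))
        p_gg = float(stats.f.sf(f, eps * df1, eps * df2))
        return dict(effect=name, SS=ss_eff, df1=df1, df2=df2, SS_error=ss_err,
                    F=f, eps_GG=eps, p_unc=p_unc, p_GG=p_gg)

    def _fit_oneway(self, y: np.ndarray, a: int, n: int) -> pd.DataFrame:
        m = y.mean()
        m_s = y.mean(axis=1)
        m_a = y.mean(axis=0)
        ss_a = n * np.sum((m_a - m) ** 2)
        ss_err = np.sum((y - m_s[:, None] - m_a[None, :] + m) ** 2)
        c = _orthonormal_contrasts(a)
        row = self._effect_row(self.within[0], ss_a, ss_err,
                               a - 1, (a - 1) * (n - 1), y @ c.T)
        return pd.DataFrame([row]).set_index("effect")

    def _fit_twoway(self, y: np.ndarray, n: int, a: int, b: int) -> pd.DataFrame:
        m = y.mean()
        m_s = y.mean(axis=(1, 2))                      # subject
        m_a = y.mean(axis=(0, 2))                      # factor A
        m_b = y.mean(axis=(0, 1))                      # factor B
        m_sa = y.mean(axis=2)                          # n x a
        m_sb = y.mean(axis=1)                          # n x b
        m_ab = y.mean(axis=0)                          # a x b

        ss_a = n * b * np.sum((m_a - m) ** 2)
        ss_b = n * a * np.sum((m_b - m) ** 2)
        ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + m) ** 2)
        ss_as = b * np.sum((m_sa - m_s[:, None] - m_a[None, :] + m) ** 2)
        ss_bs = a * np.sum((m_sb - m_s[:, None] - m_b[None, :] + m) ** 2)
        resid = (
            y
            - m_sa[:, :, None] - m_sb[:, None, :] - m_ab[None, :, :]
            + m_s[:, None, None] + m_a[None, :, None] + m_b[None, None, :]
            - m
        )
        ss_abs = np.sum(resid ** 2)

        ca = _orthonormal_contrasts(a)
        cb = _orthonormal_contrasts(b)
        cab = np.kron(ca, cb)
        flat = y.reshape(n, a * b)

        rows = [
            self._effect_row(self.within[0], ss_a, ss_as,
                             a - 1, (a - 1) * (n - 1), m_sa @ ca.T),
            self._effect_row(self.within[1], ss_b, ss_bs,
                             b - 1, (b - 1) * (n - 1), m_sb @ cb.T),
            self._effect_row(f"{self.within[0]}:{self.within[1]}", ss_ab, ss_abs,
                             (a - 1) * (b - 1), (a - 1) * (b - 1) * (n - 1),
                             flat @ cab.T),
        ]
        return pd.DataFrame(rows).set_index("effect")


@dataclass
class RMAnovaResults:
    anova_table: pd.DataFrame
    n_subjects: int
    within: list[str]
    dv: str

    def summary(self) -> str:
        head = (
            f"Repeated-measures ANOVA on {self.dv!r} "
            f"({self.n_subjects} subjects; within: {', '.join(self.within)}; "
            "Greenhouse-Geisser corrected)"
        )
        with pd.option_context("display.float_format", "{:.6g}".format):
            body = self.anova_table.to_string()
        return head + "\n\n" + body


# ---------------------------------------------------------------------------
# Dunnett many-to-one comparisons on paired per-replicate contrasts
# ---------------------------------------------------------------------------

_MAXT_CACHE: dict[tuple, np.ndarray] = {}


def _max_abs_t_sample(m: int, df: int, draws: int, seed: int) -> np.ndarray:
    """Sorted Monte-Carlo sample of max_k |T_k| where (T_1..T_m) follow the
    equicorrelated (rho = 0.5) multivariate t with ``df`` degrees of
    freedom and a shared denominator — the null distribution of the
    studentized many-to-one contrasts sharing the control group."""
    key = (m, df, draws, seed)
    if key not in _MAXT_CACHE:
        rng = np.random.default_rng(seed)
        x = rng.standard_normal((draws, m + 1))
        z = (x[:, 1:] - x[:, [0]]) / np.sqrt(2.0)       # corr 0.5 construction
        w = rng.chisquare(df, size=draws) / df
        t = np.abs(z) / np.sqrt(w)[:, None]
        _MAXT_CACHE[key] = np.sort(t.max(axis=1))
    return _MAXT_CACHE[key]


class DunnettComparison:
    """Dunnett's test of each construct against a control, with the
    replicate (independent experiment) as the pairing unit.

    The error term is the construct x subject interaction mean square, with
    (k-1)(n-1) degrees of freedom; contrasts sharing the control are
    equicorrelated at 0.5, and the reference distribution of max |T| is
    evaluated by seeded Monte-Carlo (a single comparison reduces exactly to
    the paired two-sided t-test).
    """

    def __init__(self, data: pd.DataFrame, dv: str, group: str, subject: str,
                 *, control: str = "WT", conf_level: float = 0.95,
                 mc_draws: int = DUNNETT_MC_DRAWS, mc_seed: int = DUNNETT_MC_SEED):
        self.data = data
        self.dv = dv
        self.group = group
        self.subject = subject
        self.control = control
        self.conf_level = conf_level
        self.mc_draws = mc_draws
        self.mc_seed = mc_seed

    def fit(self) -> "DunnettResults":
        wide = (
            self.data.groupby([self.subject, self.group], sort=False)[self.dv]
            .mean().unstack(self.group)
        )
        if self.control not in wide.columns:
            raise ValueError(f"control group {self.control!r} absent")
        _check_complete(wide)
        groups = [g for g in wide.columns if g != self.control]
        if not groups:
            raise ValueError("need at least one non-control group")
        n, k = wide.shape
        if n < 2:
            raise ValueError("need at least 2 replicates")

        y = wide.to_numpy()
        m_s = y.mean(axis=1)
        m_g = y.mean(axis=0)
        ss_int = np.sum((y - m_s[:, None] - m_g[None, :] + y.mean()) ** 2)
        df_err = (k - 1) * (n - 1)
        ms_err = ss_int / df_err
        se = np.sqrt(2.0 * ms_err / n)

        diffs = wide[groups].to_numpy() - wide[[self.control]].to_numpy()
        dbar = diffs.mean(axis=0)
        m = len(groups)

        with np.errstate(divide="ignore", invalid="ignore"):
            tstats = np.where(se > 0, dbar / se, np.where(dbar == 0, 0.0, np.inf))

        alpha = 1.0 - self.conf_level
        if m == 1:
            p_adj = 2.0 * stats.t.sf(np.abs(tstats), df_err)
            crit = float(stats.t.ppf(1.0 - alpha / 2.0, df_err))
        else:
            sample = _max_abs_t_sample(m, df_err, self.mc_draws, self.mc_seed)
            idx = np.searchsorted(sample, np.abs(tstats), side="left")
            # MC tail estimate; floored at one draw so p stays in (0, 1]
            p_adj = np.maximum(1.0 - idx / len(sample), 1.0 / len(sample))
            crit = float(np.quantile(sample, self.conf_level))
        p_adj = np.where(np.isinf(tstats), 0.0, p_adj)
        p_adj = np.where((se == 0) & (dbar == 0), 1.0, np.minimum(p_adj, 1.0))

        table = pd.DataFrame(
            dict(
                comparison=[f"{g} vs {self.control}" for g in groups],
                mean_diff=dbar,
                ci_low=dbar - crit * se,
                ci_high=dbar + crit * se,
                t=tstats,
                p_adjusted=p_adj,
            )
        )
        return DunnettResults(table=table, df_error=df_err, ms_error=ms_err,
                              critical_value=crit, conf_level=self.conf_level,
                              control=self.control, dv=self.dv)


@dataclass
class DunnettResults:
    table: pd.DataFrame
    df_error: int
    ms_error: float
    critical_value: float
    conf_level: float
    control: str
    dv: str

    def summary(self) -> str:
        pct = int(round(self.conf_level * 100))
        lines = [
            f"Dunnett's multiple comparisons vs {self.control} on {self.dv!r} "
            f"(df_err={self.df_error}, |T|crit={self.critical_value:.4g})"
        ]
        for _, r in self.table.iterrows():
            lines.append(
                f"  {r.comparison}: p = {r.p_adjusted:.4g}; "
                f"mean diff. {r.mean_diff:.4g}; "
                f"{pct}% CI {r.ci_low:.4g} to {r.ci_high:.4g}"
            )
        return "\n".join(lines)


def plot_well_summaries(wells: pd.DataFrame, response: str = "prop_sg_cells", ax=None):
    """Bar plot of mean +/- SD of per-replicate group means, grouped by
    treatment with one bar per construct (the usual presentation of SG
    quantification panels)."""
    import matplotlib.pyplot as plt

    stats_df = (
        wells.groupby(["treatment", "construct"], sort=False)[response]
        .agg(["mean", "std"]).reset_index()
    )
    treatments = list(dict.fromkeys(stats_df["treatment"]))
    constructs = list(dict.fromkeys(stats_df["construct"]))
    if ax is None:
        _, ax = plt.subplots()
    width = 0.8 / len(constructs)
    for ci, construct in enumerate(constructs):
        sub = stats_df[stats_df["construct"] == construct].set_index("treatment")
        xs = [treatments.index(t) + ci * width for t in sub.index]
        ax.bar(xs, sub["mean"], width=width, yerr=sub["std"].fillna(0),
               capsize=2, label=str(construct))
    ax.set_xticks([i + 0.4 - width / 2 for i in range(len(treatments))])
    ax.set_xticklabels(treatments)
    ax.set_ylabel(response)
    ax.legend()
    return ax
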