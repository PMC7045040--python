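"""Descriptive layer: weekday means/SDs, variance-homogeneity tests, ICC.

Covers the questions asked of the raw panel before any modelling: how
consumption varies over the week, whether dispersion is comparable
across weekdays and across subjects (Levene), and how much of the total
variance lies between subjects (one-way random-effects intraclass
correlation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .panel import WEEKDAYS, PanelDataset

__all__ = [
    "LeveneResult",
    "DescriptivesReport",
    "weekday_stats",
    "levene_homogeneity",
    "icc_oneway",
    "describe",
]


@dataclass(frozen=True)
class LeveneResult:
    statistic: float
    df1: int
    df2: int
    pvalue: float
    center: str

    def as_dict(self) -> dict:
        return {
            "F": self.statistic,
            "df1": self.df1,
            "df2": self.df2,
            "p": self.pvalue,
            "center": self.center,
        }


def weekday_stats(dataset: PanelDataset) -> pd.DataFrame:
    """Per-weekday mean and sample SD (ddof=1) of the non-missing counts,
    plus a 'Grand' row over all days.

    A weekday with no data yields NaN entries (flagged absent, not zero).
    """
    df = dataset.data
    rows = []
    for w in WEEKDAYS:
        vals = df.loc[df["weekday"] == w, "count"].dropna().to_numpy(float)
        if len(vals) == 0:
            rows.append((w, np.nan, np.nan, 0))
        else:
            sd = np.std(vals, ddof=1) if len(vals) > 1 else 0.0
            rows.append((w, vals.mean(), sd, len(vals)))
    allv = df["count"].dropna().to_numpy(float)
    rows.append(("Grand", allv.mean(), np.std(allv, ddof=1), len(allv)))
    return pd.DataFrame(rows, columns=["weekday", "mean", "sd", "n"]).set_index("weekday")


def levene_homogeneity(
    values, groups, center: str = "mean"
) -> LeveneResult:
    """Levene's homogeneity-of-variance test.

    ``center='mean'`` is the classic Levene test (one-way ANOVA on
    absolute deviations from group means); ``center='median'`` is the
    Brown–Forsythe variant.  df1 = n_groups - 1, df2 = N - n_groups.
    """
    if center not in ("mean", "median"):
        raise ValueError("center must be 'mean' or 'median'")
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    keep = ~np.isnan(values)
    values, groups = values[keep], groups[keep]
    samples = [values[groups == g] for g in pd.unique(groups)]
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(s) < 2 for s in samples):
        raise ValueError("every group needs at least 2 values")
    stat, p = stats.levene(*samples, center=center)
    df1 = len(samples) - 1
    df2 = len(values) - len(samples)
    return LeveneResult(float(stat), df1, df2, float(p), center)


def icc_oneway(dataset: PanelDataset, transformed: bool = False) -> float:
    """One-way random-effects intraclass correlation of daily counts
    within subjects.

    Variance components come from the one-way ANOVA mean squares with
    the unbalanced-group correction
    k0 = (N - sum n_j^2 / N) / (J - 1); ICC = sigma2_b / (sigma2_b +
    MSW), clipped to [0, 1].  ``transformed`` is a hook for computing the
    ICC after per-subject scaling instead of on raw counts.
    """
    df = dataset.data.dropna(subset=["count"])
    groups = [g["count"].to_numpy(float) for _, g in df.groupby("subject_id", sort=False)]
    if len(groups) < 2:
        raise ValueError("ICC requires at least 2 subjects")
    if any(len(g) < 2 for g in groups):
        raise ValueError("ICC requires at least 2 observations per subject")
    if transformed:
        groups = [g / np.std(g, ddof=1) for g in groups]
    N = sum(len(g) for g in groups)
    J = len(groups)
    grand = np.concatenate(groups).mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    msb = ssb / (J - 1)
    msw = ssw / (N - J)
    k0 = (N - sum(len(g) ** 2 for g in groups) / N) / (J - 1)
    sigma2_b = (msb - msw) / k0
    icc = sigma2_b / (sigma2_b + msw)
    return float(np.clip(icc, 0.0, 1.0))


@dataclass
class DescriptivesReport:
    weekday_table: pd.DataFrame
    grand_mean: float
    grand_sd: float
    subject_table: pd.DataFrame  # per-subject mean / sd, sorted by mean
    levene_weekday: LeveneResult
    levene_subject: LeveneResult
    icc: float

    def as_dict(self) -> dict:
        return {
            "weekday": {
                w: {"mean": r["mean"], "sd": r["sd"], "n": int(r["n"])}
                for w, r in self.weekday_table.iterrows()
            },
            "grand_mean": self.grand_mean,
            "grand_sd": self.grand_sd,
            "subjects": self.subject_table.reset_index().to_dict(orient="records"),
            "levene_weekday": self.levene_weekday.as_dict(),
            "levene_subject": self.levene_subject.as_dict(),
            "icc": self.icc,
        }

    def render_text(self) -> str:
        lines = ["Day-of-week descriptives (raw counts)"]
        lines.append(self.weekday_table.to_string(float_format=lambda v: f"{v:.3f}"))
        lines.append("")
        lines.append(
            f"Grand mean {self.grand_mean:.3f} (SD {self.grand_sd:.3f}); ICC {self.icc:.3f}"
        )
        lw, ls = self.levene_weekday, self.levene_subject
        lines.append(
            f"Levene by weekday: F({lw.df1}, {lw.df2}) = {lw.statistic:.3f}, p = {lw.pvalue:.3g}"
        )
        lines.append(
            f"Levene by subject: F({ls.df1}, {ls.df2}) = {ls.statistic:.3f}, p = {ls.pvalue:.3g}"
        )
        return "\n".join(lines)


def describe(dataset: PanelDataset, center: str = "mean") -> DescriptivesReport:
    """Full descriptive report: weekday table, subject table, Levene
    tests for weekday and subject grouping, and the one-way ICC."""
    wtab = weekday_stats(dataset)
    grand = wtab.loc["Grand"]
    weekday_table = wtab.drop(index="Grand")
    df = dataset.data.dropna(subset=["count"])
    subject_table = (
        df.groupby("subject_id")["count"]
        .agg(mean="mean", sd=lambda v: np.std(v, ddof=1), n="size")
        .sort_values("mean")
    )
    lev_w = levene_homogeneity(df["count"], df["weekday"], center=center)
    lev_s = levene_homogeneity(df["count"], df["subject_id"], center=center)
    return DescriptivesReport(
        weekday_table=weekday_table,
        grand_mean=float(grand["mean"]),
        grand_sd=float(grand["sd"]),
        subject_table=subject_table,
        levene_weekday=lev_w,
        levene_subject=lev_s,
        icc=icc_oneway(dataset),
    )
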