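"""Residual diagnostics: normality and white noise.

A fully specified time-series model must leave residuals that are
(approximately) normal and serially uncorrelated.  Normality is checked
with a Kolmogorov–Smirnov test against a normal with the residuals' own
mean and SD — the honest p-value for that comparison is the
Lilliefors-corrected one; the naive fully-specified-parameter p is also
reported.  Whiteness is checked with a pooled Ljung–Box portmanteau
statistic over ``seasons x period`` lags (default three weekly seasons,
21 lags).

Pooling convention: residual autocorrelations use within-subject
products only (cross-products across subject boundaries would
manufacture spurious lags) with a single global centring — the
residuals of a fitted model are already centred, and re-demeaning each
short subject series separately would bias every pooled autocorrelation
downward by about J/N and break the null calibration of the test.  The
statistic

    Q = N (N + 2) sum_k r_k^2 / N_eff,k,   N_eff,k = pairs at lag k,

reduces exactly to the classical single-series Ljung–Box formula when
the panel holds one subject, and matches the sampling variance of the
pooled autocorrelations under the null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .correlogram import pooled_acf

__all__ = [
    "KSNormalityResult",
    "LjungBoxResult",
    "DiagnosticsReport",
    "ks_normality",
    "ljung_box",
    "diagnose",
]


@dataclass(frozen=True)
class KSNormalityResult:
    statistic: float
    pvalue: float  # Lilliefors-style (estimated parameters)
    pvalue_naive: float  # fully-specified normal, biased optimistic
    n: int

    def as_dict(self) -> dict:
        return {"D": self.statistic, "p": self.pvalue, "p_naive": self.pvalue_naive, "n": self.n}


def ks_normality(residuals) -> KSNormalityResult:
    """Kolmogorov–Smirnov normality check of a residual vector.

    The primary p-value accounts for the mean and SD being estimated
    from the same data (Lilliefors); the naive variant treats them as
    known.
    """
    from statsmodels.stats.diagnostic import lilliefors

    r = np.asarray(residuals, float)
    r = r[~np.isnan(r)]
    if len(r) < 8:
        raise ValueError("need at least 8 residuals")
    sd = r.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance residuals")
    d, p_lf = lilliefors(r, dist="norm", pvalmethod="table")
    _, p_naive = stats.kstest(r, "norm", args=(r.mean(), sd))
    return KSNormalityResult(float(d), float(p_lf), float(p_naive), len(r))


@dataclass(frozen=True)
class LjungBoxResult:
    q: float
    df: int
    pvalue: float
    n_lags: int
    acf: tuple[float, ...]

    def as_dict(self) -> dict:
        return {"Q": self.q, "df": self.df, "p": self.pvalue, "n_lags": self.n_lags}


def ljung_box(
    residual_panel,
    n_lags: int | None = None,
    seasons: int = 3,
    period: int = 7,
    df_correction: int = 0,
    demean: str = "global",
) -> LjungBoxResult:
    """Pooled Ljung–Box white-noise test on a residual panel.

    ``residual_panel`` is a long DataFrame (subject_id, t, value) or a
    PanelDataset.  ``n_lags`` defaults to ``seasons * period`` (three
    weekly seasons = 21 lags).  df = n_lags by default, mirroring a
    reported-df convention without a fitted-parameter correction; pass
    ``df_correction`` (e.g. the number of AR terms) to subtract it.
    """
    if n_lags is None:
        n_lags = seasons * period
    cg = pooled_acf(residual_panel, n_lags, demean=demean)
    N = float(cg.n_eff[0])
    if np.any(cg.n_eff[1:] <= 0):
        raise ValueError(f"n_lags {n_lags} is not shorter than the usable series")
    r = cg.acf[1:]
    q = float(N * (N + 2.0) * np.sum(r**2 / cg.n_eff[1:]))
    df = int(n_lags - df_correction)
    if df <= 0:
        raise ValueError("non-positive Ljung-Box df after correction")
    return LjungBoxResult(q, df, float(stats.chi2.sf(q, df)), n_lags, tuple(r.tolist()))


@dataclass
class DiagnosticsReport:
    ks: KSNormalityResult
    ljung_box: LjungBoxResult
    residual_acf: tuple[float, ...]
    normal: bool
    white_noise: bool
    alpha: float = 0.05

    def as_dict(self) -> dict:
        return {
            "ks": self.ks.as_dict(),
            "ljung_box": self.ljung_box.as_dict(),
            "residual_acf": list(self.residual_acf),
            "normal": self.normal,
            "white_noise": self.white_noise,
            "alpha": self.alpha,
        }


def diagnose(
    residual_panel, seasons: int = 3, period: int = 7, alpha: float = 0.05
) -> DiagnosticsReport:
    """Run both residual checks and return verdict flags at ``alpha``."""
    if isinstance(residual_panel, pd.DataFrame):
        values = residual_panel["value"].to_numpy(float)
    else:
        values = residual_panel.data["count"].to_numpy(float)
    ks = ks_normality(values)
    lb = ljung_box(residual_panel, seasons=seasons, period=period)
    return DiagnosticsReport(
        ks=ks,
        ljung_box=lb,
        residual_acf=lb.acf,
        normal=ks.pvalue > alpha,
        white_noise=lb.pvalue > alpha,
        alpha=alpha,
    )
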