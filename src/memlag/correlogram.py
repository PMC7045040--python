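"""Pooled autocorrelation and partial autocorrelation for panel data.

Cross-products are formed strictly within subjects (a concatenated-
series ACF would manufacture spurious correlation at subject
boundaries), summed across subjects, and normalised by the pooled lag-0
sum of squares.  By default each subject is demeaned by its own sample
mean first, so between-subject level differences do not inflate the
correlations; ``demean='global'`` (one pooled mean) and
``demean='none'`` are available for sensitivity and for residual
series that are already centred.

The partial autocorrelation is obtained from the pooled ACF by the
Durbin–Levinson recursion.  The significance band is the large-sample
white-noise approximation ±z_{.975}/sqrt(N_eff,k), with N_eff,k the
number of within-subject pairs actually available at lag k.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .panel import PanelDataset
from .transform import HomoscedasticPanel

__all__ = [
    "PooledCorrelogram",
    "LagSpan",
    "pooled_acf",
    "pooled_pacf",
    "significant_lag_span",
    "durbin_levinson",
]


@dataclass
class PooledCorrelogram:
    """Pooled correlogram to ``max_lag``; index 0 of ``acf`` is lag 0 (=1)."""

    acf: np.ndarray  # length max_lag + 1, acf[0] == 1
    pacf: np.ndarray | None  # length max_lag + 1, pacf[0] == 1 by convention
    n_eff: np.ndarray  # length max_lag + 1, pairs available per lag
    band: np.ndarray  # length max_lag + 1, +- band per lag
    demean: str

    @property
    def max_lag(self) -> int:
        return len(self.acf) - 1

    def as_dict(self) -> dict:
        return {
            "lags": list(range(self.max_lag + 1)),
            "acf": self.acf.tolist(),
            "pacf": None if self.pacf is None else self.pacf.tolist(),
            "n_eff": self.n_eff.tolist(),
            "band": self.band.tolist(),
            "demean": self.demean,
        }


def _series_list(panel) -> list[np.ndarray]:
    if isinstance(panel, HomoscedasticPanel):
        panel = panel.panel
    if isinstance(panel, PanelDataset):
        df = panel.data
        value_col = "count"
    else:  # a long DataFrame, e.g. a residual panel
        df = panel
        value_col = "value" if "value" in df.columns else "count"
    return [
        g.sort_values("t")[value_col].to_numpy(float)
        for _, g in df.groupby("subject_id", sort=False)
    ]


def pooled_acf(panel, max_lag: int, demean: str = "subject") -> PooledCorrelogram:
    """Pooled panel autocorrelation function up to ``max_lag``.

    Missing values simply drop the pairs (and lag-0 squares) they touch.
    Raises ValueError when no subject supplies a pair at ``max_lag``.
    """
    if demean not in ("subject", "global", "none"):
        raise ValueError("demean must be 'subject', 'global' or 'none'")
    series = _series_list(panel)
    if demean == "global":
        allv = np.concatenate([s[~np.isnan(s)] for s in series])
        gmean = allv.mean()
        series = [s - gmean for s in series]
    elif demean == "subject":
        series = [s - np.nanmean(s) for s in series]
    num = np.zeros(max_lag + 1)
    n_eff = np.zeros(max_lag + 1)
    denom = 0.0
    n0 = 0
    for s in series:
        valid = ~np.isnan(s)
        denom += np.nansum(s[valid] ** 2)
        n0 += int(valid.sum())
        n = len(s)
        for k in range(1, min(max_lag, n - 1) + 1):
            a, b = s[k:], s[:-k]
            ok = ~np.isnan(a) & ~np.isnan(b)
            num[k] += float(np.sum(a[ok] * b[ok]))
            n_eff[k] += int(ok.sum())
    if n_eff[max_lag] <= 0:
        raise ValueError(f"max_lag {max_lag} exceeds every subject's usable length")
    if denom <= 0:
        raise ValueError("zero pooled variance")
    acf = np.empty(max_lag + 1)
    acf[0] = 1.0
    acf[1:] = num[1:] / denom
    n_eff[0] = n0
    z = stats.norm.ppf(0.975)
    with np.errstate(divide="ignore"):
        band = np.where(n_eff > 0, z / np.sqrt(np.maximum(n_eff, 1)), np.inf)
    band[0] = 0.0
    return PooledCorrelogram(acf=acf, pacf=None, n_eff=n_eff, band=band, demean=demean)


def durbin_levinson(acf: np.ndarray) -> np.ndarray:
    """Partial autocorrelations phi_kk from an ACF sequence (acf[0]=1)."""
    m = len(acf) - 1
    pacf = np.zeros(m + 1)
    pacf[0] = 1.0
    if m == 0:
        return pacf
    phi_prev = np.array([acf[1]])
    pacf[1] = acf[1]
    for k in range(2, m + 1):
        num = acf[k] - float(phi_prev @ acf[k - 1 : 0 : -1])
        den = 1.0 - float(phi_prev @ acf[1:k])
        phi_kk = num / den if den != 0 else 0.0
        phi = np.empty(k)
        phi[:-1] = phi_prev - phi_kk * phi_prev[::-1]
        phi[-1] = phi_kk
        pacf[k] = phi_kk
        phi_prev = phi
    return pacf


def pooled_pacf(panel, max_lag: int, demean: str = "subject") -> PooledCorrelogram:
    """Pooled PACF: Durbin–Levinson applied to the pooled ACF sequence."""
    cg = pooled_acf(panel, max_lag, demean=demean)
    cg.pacf = durbin_levinson(cg.acf)
    return cg


@dataclass(frozen=True)
class LagSpan:
    """Largest lag whose correlation exceeds the significance band."""

    acf_span: int
    pacf_span: int | None
    significant_acf_lags: tuple[int, ...]
    significant_pacf_lags: tuple[int, ...] | None

    def as_dict(self) -> dict:
        return {
            "acf_span": self.acf_span,
            "pacf_span": self.pacf_span,
            "significant_acf_lags": list(self.significant_acf_lags),
            "significant_pacf_lags": None
            if self.significant_pacf_lags is None
            else list(self.significant_pacf_lags),
        }


def significant_lag_span(cg: PooledCorrelogram, side: str = "positive") -> LagSpan:
    """Scan the correlogram for the memory span: the largest lag whose
    correlation exceeds the white-noise band, reported for the ACF and,
    when present, the PACF.

    The PACF span is the autoregressive-order reading (the ACF of a
    persistent AR process does not cut off at the model order).  With
    ``side='positive'`` (default) only positive exceedances count: the
    habit-memory hypothesis is one-sided — past consumption raises,
    never lowers, present consumption — and the fitted model constrains
    every lag coefficient to be non-negative.  ``side='two-sided'``
    flags exceedances of either sign.
    """
    if side not in ("positive", "two-sided"):
        raise ValueError("side must be 'positive' or 'two-sided'")
    lags = np.arange(1, cg.max_lag + 1)

    def _sig(values):
        v = values[1:]
        hit = (v > cg.band[1:]) if side == "positive" else (np.abs(v) > cg.band[1:])
        return tuple(int(k) for k in lags[hit])

    sig_acf = _sig(cg.acf)
    acf_span = max(sig_acf) if sig_acf else 0
    if cg.pacf is None:
        return LagSpan(acf_span, None, sig_acf, None)
    sig_pacf = _sig(cg.pacf)
    pacf_span = max(sig_pacf) if sig_pacf else 0
    return LagSpan(acf_span, pacf_span, sig_acf, sig_pacf)
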