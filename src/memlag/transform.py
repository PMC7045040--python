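"""Per-subject homoscedastic rescaling and the seasonal lag design matrix.

Subjects differ strongly in the dispersion of their daily counts, which
violates the homogeneity assumptions of Gaussian ML estimation.  The
remedy is to divide every value of subject j by that subject's own
sample SD s_j, so each transformed series has sample variance exactly 1.
Subjects are deliberately *not* mean-centred: between-subject level
differences persist and are absorbed by the lag terms.

The lag design turns the transformed panel into regression rows: for
each usable day, the response, one column per lag (non-seasonal lags 1
and 2 plus seasonal multiples of 7 up to 56 by default), and six weekday
dummies with Sunday as the reference.  A row exists only if the response
and every required lag are observed for the same subject at exact index
arithmetic — no cross-subject leakage, no imputation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import WEEKDAYS, PanelDataset

__all__ = [
    "SubjectScaleError",
    "EmptyDesignError",
    "LagSpec",
    "HomoscedasticPanel",
    "LagDesign",
    "homoscedastic_transform",
    "build_lag_design",
    "encode_weekday",
]

DUMMY_COLUMNS = ("d_mon", "d_tue", "d_wed", "d_thu", "d_fri", "d_sat")


class SubjectScaleError(ValueError):
    """A subject's series is constant (or too short), so s_j = 0."""


class EmptyDesignError(ValueError):
    """No subject is long enough to contribute a single design row."""


@dataclass(frozen=True)
class LagSpec:
    """Which lags enter the model: non-seasonal lags plus multiples of
    the seasonal period (default 1, 2, 7, 14, ..., 56)."""

    nonseasonal: tuple[int, ...] = (1, 2)
    period: int = 7
    multiples: int = 8

    def __post_init__(self) -> None:
        if len(set(self.nonseasonal)) != len(self.nonseasonal):
            raise ValueError("duplicate non-seasonal lags")
        if any(k <= 0 for k in self.lags) or self.period <= 0 or self.multiples < 0:
            raise ValueError("lags must be distinct and positive")

    @property
    def seasonal(self) -> tuple[int, ...]:
        return tuple(self.period * m for m in range(1, self.multiples + 1))

    @property
    def lags(self) -> tuple[int, ...]:
        return tuple(sorted(set(self.nonseasonal) | set(self.seasonal)))

    @property
    def max_lag(self) -> int:
        return max(self.lags)


@dataclass
class HomoscedasticPanel:
    """Panel on the transformed scale together with each subject's s_j."""

    panel: PanelDataset
    scales: pd.Series  # index subject_id, values s_j > 0

    @property
    def data(self) -> pd.DataFrame:
        return self.panel.data


def homoscedastic_transform(dataset: PanelDataset, ddof: int = 1) -> HomoscedasticPanel:
    """Divide every subject's counts by that subject's sample SD.

    Missing values are preserved.  After the transform each subject's
    non-missing sample variance is exactly 1 (to numerical tolerance).

    Raises
    ------
    SubjectScaleError
        If any subject has fewer than 2 non-missing values or a constant
        series (s_j = 0); the error names the offending subjects.
    """
    df = dataset.data
    scales = {}
    bad = []
    for sid, g in df.groupby("subject_id", sort=False):
        vals = g["count"].dropna().to_numpy(float)
        s = float(np.std(vals, ddof=ddof)) if len(vals) >= 2 else 0.0
        if not s > 0.0:
            bad.append(sid)
        scales[sid] = s
    if bad:
        raise SubjectScaleError(f"constant or degenerate series for subjects: {bad}")
    out = df.copy()
    out["count"] = out["count"] / out["subject_id"].map(scales)
    return HomoscedasticPanel(
        panel=dataset.copy_with(out),
        scales=pd.Series(scales, name="s_j").rename_axis("subject_id"),
    )


def encode_weekday(weekday: str) -> np.ndarray:
    """Six-dummy encoding of a weekday with Sunday as the reference:
    Monday -> (1,0,0,0,0,0), ..., Saturday -> (0,...,1), Sunday -> zeros."""
    if weekday not in WEEKDAYS:
        raise ValueError(f"invalid weekday {weekday!r}")
    v = np.zeros(6)
    i = WEEKDAYS.index(weekday)
    if i < 6:  # Sunday is index 6
        v[i] = 1.0
    return v


@dataclass
class LagDesign:
    """Regression-ready rows plus a ledger of why rows were dropped."""

    frame: pd.DataFrame  # subject_id, t, weekday, y, lag_*, d_mon..d_sat
    lag_spec: LagSpec
    dropped: dict = field(default_factory=dict)

    @property
    def lag_columns(self) -> list[str]:
        return [f"lag_{k}" for k in self.lag_spec.lags]

    @property
    def dummy_columns(self) -> list[str]:
        return list(DUMMY_COLUMNS)

    def __len__(self) -> int:
        return len(self.frame)

    def response(self) -> np.ndarray:
        return self.frame["y"].to_numpy(float)

    def lag_matrix(self) -> np.ndarray:
        return self.frame[self.lag_columns].to_numpy(float)

    def dummy_matrix(self) -> np.ndarray:
        return self.frame[self.dummy_columns].to_numpy(float)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def build_lag_design(
    hpanel: HomoscedasticPanel | PanelDataset, lag_spec: LagSpec | None = None
) -> LagDesign:
    """Build the pooled lag + weekday-dummy design from a transformed panel.

    For each subject with n_j days, candidate rows are t in
    {max_lag+1, ..., n_j}; a candidate survives only if the response and
    all lag values are non-missing (listwise deletion).  The ``dropped``
    ledger reports, per cause: subjects shorter than the maximum lag
    (``short_subject``), rows consumed as lag burn-in (``burn_in``), and
    rows lost to missing values in the response or a lag (``missing``).
    """
    if lag_spec is None:
        lag_spec = LagSpec()
    panel = hpanel.panel if isinstance(hpanel, HomoscedasticPanel) else hpanel
    lags = lag_spec.lags
    maxlag = lag_spec.max_lag
    parts = []
    dropped = {"short_subject": 0, "burn_in": 0, "missing": 0, "short_subject_ids": []}
    for sid, g in panel.data.groupby("subject_id", sort=False):
        g = g.sort_values("t")
        n_j = len(g)
        if n_j <= maxlag:
            dropped["short_subject"] += n_j
            dropped["short_subject_ids"].append(sid)
            continue
        dropped["burn_in"] += maxlag
        y = g["count"].to_numpy(float)
        sub = pd.DataFrame(
            {
                "subject_id": sid,
                "t": g["t"].to_numpy()[maxlag:],
                "weekday": g["weekday"].to_numpy()[maxlag:],
                "y": y[maxlag:],
            }
        )
        for k in lags:
            sub[f"lag_{k}"] = y[maxlag - k : n_j - k]
        ok = sub[["y"] + [f"lag_{k}" for k in lags]].notna().all(axis=1)
        dropped["missing"] += int((~ok).sum())
        parts.append(sub[ok])
    if not parts or sum(len(p) for p in parts) == 0:
        raise EmptyDesignError(
            f"no subject long enough for max lag {maxlag} (or all rows missing)"
        )
    frame = pd.concat(parts, ignore_index=True)
    dummies = np.vstack([encode_weekday(w) for w in frame["weekday"]])
    for i, c in enumerate(DUMMY_COLUMNS):
        frame[c] = dummies[:, i]
    return LagDesign(frame=frame, lag_spec=lag_spec, dropped=dropped)
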