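"""Long-format daily-count panels: container, validation and CSV I/O.

A panel holds one short daily time series per subject (here: cigarettes
smoked per day), on a gapless 1-based day grid.  Days with no recorded
count keep their row and are flagged missing (NaN); nothing is ever
imputed at ingest, so downstream lag construction can apply listwise
deletion consistently.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WEEKDAYS",
    "PanelValidationError",
    "PanelDataset",
    "PanelSummary",
    "read_panel_csv",
    "write_panel_csv",
    "to_longitudinal",
    "summarize_panel",
]

#: Weekday labels in cyclic order; index 0 = Monday ... 6 = Sunday.
WEEKDAYS: tuple[str, ...] = ("Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun")
_WD_INDEX = {w: i for i, w in enumerate(WEEKDAYS)}


class PanelValidationError(ValueError):
    """Raised when panel data violate the day-grid or count invariants."""


def _normalize_weekday(value) -> str:
    """Accept 'Mon', 'monday', 0..6 (Mon=0) and return the canonical label."""
    if isinstance(value, (int, np.integer)):
        if 0 <= int(value) <= 6:
            return WEEKDAYS[int(value)]
        raise PanelValidationError(f"weekday index out of range: {value}")
    s = str(value).strip()
    key = s[:3].capitalize()
    if key in _WD_INDEX:
        return key
    raise PanelValidationError(f"unrecognised weekday: {value!r}")


@dataclass
class PanelDataset:
    """A validated long-format panel of daily counts.

    Attributes
    ----------
    data : pandas.DataFrame
        Columns ``subject_id``, ``t`` (1-based, gapless per subject),
        ``weekday`` (labels from :data:`WEEKDAYS`) and ``count``
        (float; NaN marks a missing record).
    subjects : pandas.DataFrame
        One row per subject (index ``subject_id``); may carry
        subject-constant covariates such as ``gender`` and ``age``.
    """

    data: pd.DataFrame
    subjects: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = self.data.reset_index(drop=True)
        if self.subjects is None:
            ids = pd.unique(self.data["subject_id"]) if len(self.data) else []
            self.subjects = pd.DataFrame(index=pd.Index(ids, name="subject_id"))
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        df = self.data
        required = {"subject_id", "t", "weekday", "count"}
        missing_cols = required - set(df.columns)
        if missing_cols:
            raise PanelValidationError(f"missing columns: {sorted(missing_cols)}")
        if len(df) == 0:
            return
        dup = df.duplicated(subset=["subject_id", "t"])
        if dup.any():
            raise PanelValidationError(
                f"duplicate (subject, t) at rows {df.index[dup].tolist()[:5]}"
            )
        for sid, g in df.groupby("subject_id", sort=False):
            t = g["t"].to_numpy()
            order = np.argsort(t)
            t = t[order]
            if t[0] != 1 or (np.diff(t) != 1).any():
                raise PanelValidationError(
                    f"subject {sid!r}: day index must be 1-based and gapless"
                )
            wd = [_WD_INDEX[w] for w in g["weekday"].to_numpy()[order]]
            if (np.diff(wd) % 7 != 1).any():
                where = int(np.nonzero(np.diff(wd) % 7 != 1)[0][0])
                raise PanelValidationError(
                    f"subject {sid!r}: weekday sequence breaks at t={t[where + 1]}"
                )
        level2 = [c for c in ("gender", "age") if c in self.subjects.columns]
        if level2 and self.subjects.index.has_duplicates:
            raise PanelValidationError("duplicate subject ids in level-2 table")

    # -- convenience ----------------------------------------------------
    @property
    def subject_ids(self) -> list:
        return list(self.subjects.index)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects.index)

    def subject_lengths(self) -> pd.Series:
        return self.data.groupby("subject_id", sort=False).size()

    def missing_fraction(self) -> float:
        if len(self.data) == 0:
            return 0.0
        return float(self.data["count"].isna().mean())

    def series(self, subject_id) -> pd.DataFrame:
        """One subject's rows ordered by t."""
        g = self.data[self.data["subject_id"] == subject_id]
        if len(g) == 0:
            raise KeyError(subject_id)
        return g.sort_values("t").reset_index(drop=True)

    def copy_with(self, data: pd.DataFrame) -> "PanelDataset":
        return PanelDataset(data=data.copy(), subjects=self.subjects.copy())


@dataclass(frozen=True)
class PanelSummary:
    n_subjects: int
    n_observations: int
    n_missing: int
    missing_fraction: float
    length_min: int
    length_max: int
    length_mode: int
    gender_counts: dict
    age_mean: float | None

    def as_dict(self) -> dict:
        return {
            "n_subjects": self.n_subjects,
            "n_observations": self.n_observations,
            "n_missing": self.n_missing,
            "missing_fraction": self.missing_fraction,
            "length_min": self.length_min,
            "length_max": self.length_max,
            "length_mode": self.length_mode,
            "gender_counts": dict(self.gender_counts),
            "age_mean": self.age_mean,
        }


def summarize_panel(dataset: PanelDataset) -> PanelSummary:
    """Panel-level descriptives: size, record-length distribution, missingness.

    The record-length mode uses a smallest-value tie-break.
    """
    if len(dataset.data) == 0:
        raise PanelValidationError("cannot summarize an empty panel")
    lengths = dataset.subject_lengths()
    counts = Counter(lengths.tolist())
    top = max(counts.values())
    mode = min(k for k, v in counts.items() if v == top)
    gender_counts: dict = {}
    age_mean = None
    if "gender" in dataset.subjects.columns:
        gender_counts = dataset.subjects["gender"].value_counts().to_dict()
    if "age" in dataset.subjects.columns:
        age_mean = float(dataset.subjects["age"].mean())
    n_missing = int(dataset.data["count"].isna().sum())
    return PanelSummary(
        n_subjects=dataset.n_subjects,
        n_observations=len(dataset.data),
        n_missing=n_missing,
        missing_fraction=dataset.missing_fraction(),
        length_min=int(lengths.min()),
        length_max=int(lengths.max()),
        length_mode=int(mode),
        gender_counts=gender_counts,
        age_mean=age_mean,
    )


# ---------------------------------------------------------------------------
# CSV input/output
# ---------------------------------------------------------------------------

_DEFAULT_COLUMNS = {"subject_id": "subject_id", "t": "t", "weekday": "weekday", "count": "count"}


def read_panel_csv(
    path,
    columns: Mapping[str, str] | None = None,
    start_weekday: str | Mapping | None = None,
    subjects: pd.DataFrame | None = None,
    allow_negative: bool = False,
) -> PanelDataset:
    """Read a long-format panel CSV into a validated :class:`PanelDataset`.

    Parameters
    ----------
    path : str or Path
        CSV with a header row; comma-separated, UTF-8.
    columns : mapping, optional
        Maps the canonical names ``subject_id``/``t``/``weekday``/``count``
        to the file's actual headers, absorbing arbitrary layouts.
    start_weekday : str or mapping, optional
        When the file carries no weekday column, the weekday of day 1 —
        a single label applied to every subject, or a per-subject mapping.
    subjects : DataFrame, optional
        Level-2 covariate table (index = subject id).

    Empty count cells become missing (NaN); they are never imputed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cmap = dict(_DEFAULT_COLUMNS)
    if columns:
        cmap.update(columns)
    raw = pd.read_csv(path)
    for canon in ("subject_id", "t", "count"):
        if cmap[canon] not in raw.columns:
            raise PanelValidationError(
                f"column {cmap[canon]!r} (for {canon}) not found in {path.name}"
            )
    df = pd.DataFrame(
        {
            "subject_id": raw[cmap["subject_id"]],
            "t": pd.to_numeric(raw[cmap["t"]], errors="raise").astype(int),
            "count": pd.to_numeric(raw[cmap["count"]], errors="coerce").astype(float),
        }
    )
    # a non-empty cell that fails numeric conversion is a data error, not MISSING
    source_blank = raw[cmap["count"]].isna() | (raw[cmap["count"]].astype(str).str.strip() == "")
    bad = df["count"].isna() & ~source_blank.to_numpy()
    if bad.any():
        raise PanelValidationError(f"non-numeric count at rows {df.index[bad].tolist()[:5]}")
    if not allow_negative and (df["count"].dropna() < 0).any():
        neg = df.index[df["count"] < 0].tolist()
        raise PanelValidationError(f"negative counts at rows {neg[:5]}")
    if cmap["weekday"] in raw.columns:
        df["weekday"] = [_normalize_weekday(w) for w in raw[cmap["weekday"]]]
    else:
        if start_weekday is None:
            raise PanelValidationError(
                "no weekday column: a start_weekday configuration is required"
            )
        df["weekday"] = _derive_weekdays(df, start_weekday)
    return PanelDataset(data=df[["subject_id", "t", "weekday", "count"]], subjects=subjects)


def _derive_weekdays(df: pd.DataFrame, start_weekday) -> list[str]:
    out = np.empty(len(df), dtype=object)
    for sid, g in df.groupby("subject_id", sort=False):
        if isinstance(start_weekday, Mapping):
            w0 = _WD_INDEX[_normalize_weekday(start_weekday[sid])]
        else:
            w0 = _WD_INDEX[_normalize_weekday(start_weekday)]
        out[g.index] = [WEEKDAYS[(w0 + int(t) - 1) % 7] for t in g["t"]]
    return list(out)


def write_panel_csv(dataset: PanelDataset, path) -> Path:
    """Write the long CSV that :func:`read_panel_csv` reads back identically.

    Counts are written via :func:`repr` of floats (integers stay integral),
    missing cells are left empty.
    """
    path = Path(path)
    df = dataset.data.copy()
    df = df.sort_values(["subject_id", "t"], kind="stable")

    def _fmt(v: float) -> str:
        if np.isnan(v):
            return ""
        if float(v).is_integer():
            return str(int(v))
        return repr(float(v))

    df["count"] = [_fmt(v) for v in df["count"]]
    df.to_csv(path, index=False)
    return path


def to_longitudinal(
    wide: pd.DataFrame,
    id_column: str | None = None,
    start_weekday: str | Mapping = "Mon",
    subjects: pd.DataFrame | None = None,
) -> PanelDataset:
    """Convert a person-level wide table (one row per subject, one column
    per day) to a longitudinal panel.

    Day columns are taken in their given order as t = 1, 2, ...; ragged
    rows (trailing absent cells) are allowed and simply end the record.
    Interior blank cells stay on the grid as missing days.
    """
    if id_column is None:
        id_column = wide.columns[0] if len(wide.columns) else "subject_id"
    day_cols = [c for c in wide.columns if c != id_column]
    # if the day columns carry numeric labels (day_1, d3, ...), they must be monotone
    import re

    labels = [re.search(r"(\d+)\s*$", str(c)) for c in day_cols]
    if day_cols and all(m is not None for m in labels):
        nums = [int(m.group(1)) for m in labels]  # type: ignore[union-attr]
        if any(b <= a for a, b in zip(nums, nums[1:])):
            raise PanelValidationError(f"non-monotone day labels: {day_cols}")
    rows = []
    for _, r in wide.iterrows():
        sid = r[id_column]
        values = [r[c] for c in day_cols]
        # drop trailing absent cells (ragged record); interior blanks = MISSING
        last = -1
        for i, v in enumerate(values):
            if not (v is None or (isinstance(v, float) and np.isnan(v)) or str(v).strip() == ""):
                last = i
        for i in range(last + 1):
            v = values[i]
            blank = v is None or (isinstance(v, float) and np.isnan(v)) or str(v).strip() == ""
            rows.append((sid, i + 1, np.nan if blank else float(v)))
    if not rows:
        return PanelDataset(
            data=pd.DataFrame(columns=["subject_id", "t", "weekday", "count"]),
            subjects=subjects,
        )
    df = pd.DataFrame(rows, columns=["subject_id", "t", "count"])
    df["weekday"] = _derive_weekdays(df, start_weekday)
    return PanelDataset(data=df[["subject_id", "t", "weekday", "count"]], subjects=subjects)
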