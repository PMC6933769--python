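"""Data containers for mixed-frequency indicator panels.

A :class:`RawPanel` holds heterogeneous-frequency raw series (one growth
series, several health indicators, a high-dimensional macro block), each
tagged with a role and a log-transform flag.  A :class:`StandardizedPanel`
is the stationary, standardized observation matrix ``X`` (T x n) plus the
growth series ``Y`` that the filter consumes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

Role = Literal["growth", "health", "macro"]
Frequency = Literal["annual", "quarterly"]


@dataclass
class RawSeries:
    """A single raw indicator series.

    ``values`` is a pandas Series indexed by a PeriodIndex whose frequency
    matches ``frequency`` ('A' for annual, 'Q' for quarterly).
    """

    series_id: str
    role: Role
    frequency: Frequency
    values: pd.Series
    log_flag: bool = False

    def __post_init__(self) -> None:
        idx = self.values.index
        if not isinstance(idx, pd.PeriodIndex):
            raise TypeError(f"{self.series_id}: values must use a PeriodIndex")
        if not idx.is_monotonic_increasing or idx.has_duplicates:
            raise ValueError(f"{self.series_id}: timestamps must be strictly increasing")
        freqstr = idx.freqstr or ""
        expected = "Q" if self.frequency == "quarterly" else "Y"
        if not freqstr.upper().startswith(expected) and not (
            expected == "Y" and freqstr.upper().startswith("A")
        ):
            raise ValueError(
                f"{self.series_id}: frequency '{self.frequency}' inconsistent with "
                f"PeriodIndex freq '{freqstr}'"
            )


@dataclass
class RawPanel:
    """Collection of raw series; exactly one must have the growth role."""

    series: list[RawSeries]

    def __post_init__(self) -> None:
        n_growth = sum(1 for s in self.series if s.role == "growth")
        if n_growth != 1:
            raise ValueError(f"panel must contain exactly one growth series, got {n_growth}")

    @property
    def growth(self) -> RawSeries:
        return next(s for s in self.series if s.role == "growth")

    def __len__(self) -> int:
        return len(self.series)

    # ------------------------------------------------------------------ I/O
    def to_csv(self, panel_path: str | Path, meta_path: str | Path) -> None:
        """Write the wide panel CSV and the per-series metadata CSV.

        Rows are labelled by quarter.  Annual series store each year's value
        in that year's Q1 row and are NaN elsewhere; ``meta.csv`` carries the
        frequency needed to reconstruct them.
        """
        frames = {}
        for s in self.series:
            if s.frequency == "quarterly":
                frames[s.series_id] = s.values.rename(s.series_id)
            else:
                qidx = pd.PeriodIndex([pd.Period(f"{p.year}Q1") for p in s.values.index], freq="Q")
                frames[s.series_id] = pd.Series(s.values.to_numpy(), index=qidx, name=s.series_id)
        wide = pd.concat(frames.values(), axis=1).sort_index()
        wide.index.name = "period"
        wide.to_csv(panel_path)
        meta = pd.DataFrame(
            {
                "series_id": [s.series_id for s in self.series],
                "role": [s.role for s in self.series],
                "frequency": [s.frequency for s in self.series],
                "log_transform": [s.log_flag for s in self.series],
            }
        )
        meta.to_csv(meta_path, index=False)

    @classmethod
    def from_csv(cls, panel_path: str | Path, meta_path: str | Path) -> "RawPanel":
        panel_path, meta_path = Path(panel_path), Path(meta_path)
        for p in (panel_path, meta_path):
            if not p.exists():
                raise FileNotFoundError(f"required input file missing: {p}")
        wide = pd.read_csv(panel_path, index_col="period")
        wide.index = pd.PeriodIndex(wide.index, freq="Q")
        meta = pd.read_csv(meta_path)
        required = {"series_id", "role", "frequency", "log_transform"}
        if not required.issubset(meta.columns):
            raise ValueError(f"{meta_path} missing columns {sorted(required - set(meta.columns))}")
        series = []
        for _, row in meta.iterrows():
            sid = row["series_id"]
            col = wide[sid].dropna()
            if row["frequency"] == "annual":
                col = pd.Series(
                    col.to_numpy(),
                    index=pd.PeriodIndex([pd.Period(p.year, freq="Y") for p in col.index], freq="Y"),
                    name=sid,
                )
            series.append(
                RawSeries(
                    series_id=sid,
                    role=row["role"],
                    frequency=row["frequency"],
                    values=col,
                    log_flag=bool(row["log_transform"]),
                )
            )
        return cls(series=series)


@dataclass
class StandardizedPanel:
    """Stationary standardized observation matrix plus the growth series.

    ``X`` is a T x n DataFrame (health + macro indicators) and ``Y`` a
    length-T Series, both on a common quarterly PeriodIndex.
    ``transform_log`` records, per series, the preprocessing steps applied.
    """

    quarters: pd.PeriodIndex
    X: pd.DataFrame
    Y: pd.Series
    transform_log: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.X) != len(self.quarters) or len(self.Y) != len(self.quarters):
            raise ValueError("X, Y and quarters must have equal length")

    @property
    def T(self) -> int:
        return len(self.quarters)

    @property
    def n_series(self) -> int:
        return self.X.shape[1]

    def validate(self, atol: float = 1e-8) -> None:
        """Check the standardization contract: columns mean 0, sd 1, no NaN."""
        mat = np.column_stack([self.X.to_numpy(), self.Y.to_numpy()])
        if not np.all(np.isfinite(mat)):
            raise ValueError("panel contains missing or non-finite values")
        mu = mat.mean(axis=0)
        sd = mat.std(axis=0, ddof=1)
        if np.any(np.abs(mu) > atol) or np.any(np.abs(sd - 1.0) > atol):
            raise ValueError("panel columns are not standardized to mean 0 / sd 1")

    def to_csv(self, path: str | Path, log_path: str | Path | None = None) -> None:
        out = self.X.copy()
        out.insert(0, self.Y.name or "growth", self.Y)
        out.index = self.quarters
        out.index.name = "period"
        out.to_csv(path)
        if log_path is not None:
            Path(log_path).write_text(json.dumps(self.transform_log, indent=1, sort_keys=True))

    @classmethod
    def from_csv(cls, path: str | Path, growth_col: str = "growth") -> "StandardizedPanel":
        df = pd.read_csv(path, index_col="period")
        df.index = pd.PeriodIndex(df.index, freq="Q")
        if growth_col not in df.columns:
            growth_col = df.columns[0]
        y = df[growth_col]
        x = df.drop(columns=[growth_col])
        return cls(quarters=df.index, X=x, Y=y)
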