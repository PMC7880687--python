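"""Core containers for single-cell CDK-activity traces.

A trace is one cell's cytoplasmic:nuclear DHB-ratio time series, with time
expressed in minutes relative to the anaphase of the mother cell (anaphase
= 0; pre-anaphase samples carry negative times).  A :class:`TraceSet` is a
collection of traces, optionally labeled with the cell's known fate
(proliferative = cycling G1 daughter, quiescent = G0 daughter).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import InputError

PROLIFERATIVE = "proliferative"
QUIESCENT = "quiescent"
UNKNOWN = "unknown"
FATES = (PROLIFERATIVE, QUIESCENT, UNKNOWN)

#: column order of the long ("tidy") trace-table schema
TRACE_TABLE_COLUMNS = ("cell_id", "lineage", "fate", "time_min", "dhb_ratio")


@dataclass
class CdkTrace:
    """One cell's anaphase-aligned DHB-ratio time series.

    Parameters
    ----------
    cell_id
        Unique identifier of the cell.
    times
        Sample times in minutes relative to anaphase, strictly increasing.
    ratios
        Cytoplasmic:nuclear DHB ratio at each time; finite and >= 0.
    lineage
        Lineage label (e.g. VPC, SM, VU); free-form.
    fate
        ``"proliferative"``, ``"quiescent"`` or ``"unknown"``.
    """

    cell_id: str
    times: np.ndarray
    ratios: np.ndarray
    lineage: str = UNKNOWN
    fate: str = UNKNOWN

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.ratios = np.asarray(self.ratios, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.ratios.shape:
            raise ValueError("times and ratios must be 1-D arrays of equal length")
        if self.times.size == 0:
            raise ValueError(f"trace {self.cell_id!r} is empty")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError(f"trace {self.cell_id!r}: times must be strictly increasing")
        if not np.all(np.isfinite(self.ratios)) or np.any(self.ratios < 0):
            raise ValueError(f"trace {self.cell_id!r}: ratios must be finite and >= 0")
        if self.fate not in FATES:
            raise ValueError(f"trace {self.cell_id!r}: unknown fate {self.fate!r}")

    def __len__(self) -> int:
        return self.times.size

    @property
    def has_anaphase_sample(self) -> bool:
        """True when a sample exists at t = 0 (the anaphase frame)."""
        return bool(np.any(self.times == 0.0))

    @property
    def sampling_interval(self) -> float:
        """Median spacing between consecutive samples, in minutes."""
        if self.times.size < 2:
            raise InputError(f"trace {self.cell_id!r} has a single sample")
        return float(np.median(np.diff(self.times)))

    def post_anaphase(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (times, ratios) of the samples at t >= 0."""
        sel = self.times >= 0.0
        return self.times[sel], self.ratios[sel]

    @property
    def duration_post_anaphase(self) -> float:
        """Minutes covered after anaphase (0 if no post-anaphase sample)."""
        t, _ = self.post_anaphase()
        return float(t.max()) if t.size else 0.0

    def ratio_at(self, time_min: float) -> float:
        """Ratio at the exact sample time ``time_min`` (KeyError if absent)."""
        idx = np.flatnonzero(self.times == time_min)
        if idx.size == 0:
            raise KeyError(f"trace {self.cell_id!r} has no sample at t={time_min}")
        return float(self.ratios[idx[0]])

    def with_fate(self, fate: str) -> "CdkTrace":
        return replace(self, fate=fate)


@dataclass
class TraceSet:
    """An ordered collection of :class:`CdkTrace`."""

    traces: list[CdkTrace] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.traces)

    def __iter__(self) -> Iterator[CdkTrace]:
        return iter(self.traces)

    def __getitem__(self, i: int) -> CdkTrace:
        return self.traces[i]

    @property
    def fates(self) -> list[str]:
        return [t.fate for t in self.traces]

    def subset(self, fate: str) -> "TraceSet":
        return TraceSet([t for t in self.traces if t.fate == fate])

    def sampling_interval(self) -> float:
        """Median sampling interval across all member traces, in minutes."""
        if not self.traces:
            raise InputError("empty TraceSet")
        return float(np.median([t.sampling_interval for t in self.traces if len(t) > 1]))

    def time_grid(self, post_anaphase_only: bool = False) -> np.ndarray:
        """Sorted union of all sample times across traces."""
        times = np.unique(np.concatenate([t.times for t in self.traces]))
        if post_anaphase_only:
            times = times[times >= 0.0]
        return times

    def ratios_at(self, time_min: float) -> tuple[np.ndarray, list[CdkTrace]]:
        """All ratios observed at exactly ``time_min``, with their traces."""
        vals, who = [], []
        for t in self.traces:
            idx = np.flatnonzero(t.times == time_min)
            if idx.size:
                vals.append(t.ratios[idx[0]])
                who.append(t)
        return np.asarray(vals, dtype=float), who

    def mean_trend_line(self, grid: Sequence[float] | None = None
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-timepoint mean ratio over the set.

        Returns ``(times, means, counts)`` on the given grid (default: the
        union of all observed times).  Timepoints with no observation carry
        NaN mean and count 0.
        """
        if not self.traces:
            raise InputError("empty TraceSet")
        grid = np.asarray(grid, dtype=float) if grid is not None else self.time_grid()
        sums = np.zeros(grid.size)
        counts = np.zeros(grid.size)
        for t in self.traces:
            idx = np.searchsorted(grid, t.times)
            ok = (idx < grid.size) & (grid[np.minimum(idx, grid.size - 1)] == t.times)
            sums[idx[ok]] += t.ratios[ok]
            counts[idx[ok]] += 1
        with np.errstate(invalid="ignore"):
            means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        return grid, means, counts

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table with columns cell_id, lineage, fate, time_min, dhb_ratio."""
        rows = []
        for t in self.traces:
            for tm, r in zip(t.times, t.ratios):
                rows.append((t.cell_id, t.lineage, t.fate, tm, r))
        return pd.DataFrame(rows, columns=list(TRACE_TABLE_COLUMNS))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "TraceSet":
        """Build a TraceSet from a long-format table (samples sorted by time)."""
        traces = []
        for cell_id, grp in df.groupby("cell_id", sort=False):
            grp = grp.sort_values("time_min")
            lineage = str(grp["lineage"].iloc[0]) if "lineage" in grp else UNKNOWN
            fate = str(grp["fate"].iloc[0]) if "fate" in grp else UNKNOWN
            traces.append(CdkTrace(
                cell_id=str(cell_id),
                times=grp["time_min"].to_numpy(dtype=float),
                ratios=grp["dhb_ratio"].to_numpy(dtype=float),
                lineage=lineage,
                fate=fate,
            ))
        return cls(traces)
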