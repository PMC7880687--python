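"""Permutation tests for DHB-ratio group and time-course comparisons.

Two statistics are supported:

* single-timepoint comparisons use the absolute difference of group means,
  ``|x̄1 − x̄2|``;
* time-course comparisons use the area between the per-timepoint mean
  trend lines of the two groups, computed as the L1 norm
  ``Σ_t |x̄1(t) − x̄2(t)|`` over the shared time grid.

The null distribution is built by randomly re-partitioning the data,
without replacement, into two groups of the original sizes; for
time courses the unit of permutation is the whole trace, never an
individual timepoint.  The empirical p-value is the proportion of
replicates whose statistic strictly exceeds the observed one.  When no
replicate exceeds it, the p-value is reported as a floor, p < 1/n_reps
(the convention behind "p < 1e-7" at 1e8 replicates — the true value is
below what the replicate count can resolve).

An exhaustive enumeration oracle over all partitions is provided for
small inputs, both as a user-facing exact test and as an independent
check of the sampled test.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np

from .errors import GridError, InputError, SizeError
from .traces import TraceSet

logger = logging.getLogger(__name__)

DEFAULT_N_REPS = 100_000
_BATCH = 2_000  # replicates per vectorized batch

STAT_MEAN_DIFF = "mean_diff"
STAT_TIMECOURSE_L1 = "timecourse_l1"


@dataclass(frozen=True)
class PermutationResult:
    """Outcome of a permutation test.

    ``p_value`` equals ``n_exceed / n_reps`` when at least one replicate
    exceeds the observed statistic.  When none does, ``p_is_floor`` is
    True and ``p_value`` holds the floor ``1 / n_reps``, to be read as
    "p < 1/n_reps".
    """

    observed_stat: float
    n_reps: int
    n_exceed: int
    p_value: float
    p_is_floor: bool
    seed: int | None

    @property
    def p_report(self) -> str:
        """Human-readable p-value, honoring the floor convention."""
        if self.p_is_floor:
            return f"p < {1.0 / self.n_reps:.3g}"
        return f"p = {self.p_value:.3g}"

    @classmethod
    def from_counts(cls, observed: float, n_reps: int, n_exceed: int,
                    seed: int | None) -> "PermutationResult":
        if n_exceed > 0:
            return cls(observed, n_reps, n_exceed, n_exceed / n_reps, False, seed)
        return cls(observed, n_reps, 0, 1.0 / n_reps, True, seed)

    def to_dict(self) -> dict:
        return {
            "observed_stat": self.observed_stat,
            "n_reps": self.n_reps,
            "n_exceed": self.n_exceed,
            "p_value": self.p_value,
            "p_is_floor": self.p_is_floor,
            "seed": self.seed,
        }


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------


def mean_diff_stat(group_1, group_2) -> float:
    """Absolute difference of group means, ``|x̄1 − x̄2|``."""
    g1 = np.asarray(group_1, dtype=float)
    g2 = np.asarray(group_2, dtype=float)
    if g1.size == 0 or g2.size == 0:
        raise InputError("both groups must be nonempty")
    return float(abs(g1.mean() - g2.mean()))


@dataclass(frozen=True)
class TrendLinePair:
    """Per-timepoint mean trend lines of two groups on a common grid."""

    times: np.ndarray
    mean_1: np.ndarray
    mean_2: np.ndarray
    n_1: np.ndarray
    n_2: np.ndarray

    def __post_init__(self) -> None:
        lens = {len(self.times), len(self.mean_1), len(self.mean_2),
                len(self.n_1), len(self.n_2)}
        if len(lens) != 1:
            raise GridError("trend-line vectors must share one grid length")
        if np.any(np.asarray(self.n_1) < 1) or np.any(np.asarray(self.n_2) < 1):
            raise GridError("every grid time needs >= 1 observation per group")


def trend_line_pair(group_1: TraceSet, group_2: TraceSet) -> TrendLinePair:
    """Mean trend lines of two trace sets on their shared time grid.

    Timepoints observed in only one group are dropped (and logged), so the
    L1 statistic is always computed over a common grid.
    """
    if len(group_1) == 0 or len(group_2) == 0:
        raise InputError("both groups must contain traces")
    grid = np.union1d(group_1.time_grid(), group_2.time_grid())
    _, m1, c1 = group_1.mean_trend_line(grid)
    _, m2, c2 = group_2.mean_trend_line(grid)
    shared = (c1 > 0) & (c2 > 0)
    dropped = grid[~shared]
    if dropped.size:
        logger.info("dropping %d timepoint(s) missing from one group: %s",
                    dropped.size, dropped.tolist())
    return TrendLinePair(times=grid[shared], mean_1=m1[shared], mean_2=m2[shared],
                         n_1=c1[shared].astype(int), n_2=c2[shared].astype(int))


def timecourse_l1_stat(pair: TrendLinePair) -> float:
    """Area between the mean trend lines: ``Σ_t |x̄1(t) − x̄2(t)|``."""
    return float(np.abs(np.asarray(pair.mean_1) - np.asarray(pair.mean_2)).sum())


# ---------------------------------------------------------------------------
# sampled permutation test
# ---------------------------------------------------------------------------


def _trace_matrix(traces: list) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack traces on the union grid: values (NaN-free), indicator, grid."""
    grid = np.unique(np.concatenate([t.times for t in traces]))
    vals = np.zeros((len(traces), grid.size))
    obs = np.zeros((len(traces), grid.size))
    for i, t in enumerate(traces):
        idx = np.searchsorted(grid, t.times)
        vals[i, idx] = t.ratios
        obs[i, idx] = 1.0
    return vals, obs, grid


def _l1_stats_for_selections(sel: np.ndarray, vals: np.ndarray,
                             obs: np.ndarray) -> np.ndarray:
    """L1 trend-line statistic for each row of the 0/1 selection matrix.

    ``sel`` is (batch, n_traces); a 1 assigns the trace to group 1.
    Timepoints that end up unobserved in either group of a replicate are
    dropped from that replicate's sum, mirroring the shared-grid rule.
    """
    sum1 = sel @ vals
    cnt1 = sel @ obs
    sum2 = vals.sum(axis=0) - sum1
    cnt2 = obs.sum(axis=0) - cnt1
    valid = (cnt1 > 0) & (cnt2 > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        diff = np.abs(sum1 / cnt1 - sum2 / cnt2)
    return np.where(valid, diff, 0.0).sum(axis=1)


def _exceed_threshold(observed: float) -> float:
    # replicate statistics mathematically equal to the observed one can land
    # an ulp above it along the vectorized path; "strictly greater" must not
    # count such ties
    return observed + 1e-9 * max(1.0, abs(observed))


def _as_groups(group_1, group_2, stat: str):
    if stat == STAT_MEAN_DIFF:
        g1 = np.asarray(group_1, dtype=float).ravel()
        g2 = np.asarray(group_2, dtype=float).ravel()
        if g1.size == 0 or g2.size == 0:
            raise InputError("both groups must be nonempty")
        return g1, g2
    if stat == STAT_TIMECOURSE_L1:
        t1 = list(group_1)
        t2 = list(group_2)
        if not t1 or not t2:
            raise InputError("both groups must contain traces")
        return t1, t2
    raise InputError(f"unknown statistic {stat!r}")


def permutation_test(group_1, group_2, stat: str = STAT_MEAN_DIFF,
                     n_reps: int = DEFAULT_N_REPS,
                     seed: int | None = None) -> PermutationResult:
    """Seeded random-partition permutation test.

    Parameters
    ----------
    group_1, group_2
        For ``stat="mean_diff"``: 1-D arrays of single-timepoint ratios.
        For ``stat="timecourse_l1"``: trace sets (or lists of traces);
        whole traces are re-assigned between groups.
    stat
        ``"mean_diff"`` or ``"timecourse_l1"``.
    n_reps
        Number of random re-partitions (>= 1).  Each preserves the
        original group sizes.
    seed
        Seed for the replicate generator; recorded in the result.
    """
    if n_reps < 1:
        raise InputError("n_reps must be >= 1")
    g1, g2 = _as_groups(group_1, group_2, stat)
    rng = np.random.default_rng(seed)

    if stat == STAT_MEAN_DIFF:
        observed = mean_diff_stat(g1, g2)
        cutoff = _exceed_threshold(observed)
        pooled = np.concatenate([g1, g2])
        n1, n = g1.size, pooled.size
        base = np.zeros(n)
        base[:n1] = 1.0
        total = pooled.sum()
        n_exceed = 0
        done = 0
        while done < n_reps:
            b = min(_BATCH, n_reps - done)
            sel = rng.permuted(np.broadcast_to(base, (b, n)).copy(), axis=1)
            s1 = sel @ pooled
            stats = np.abs(s1 / n1 - (total - s1) / (n - n1))
            n_exceed += int((stats > cutoff).sum())
            done += b
        return PermutationResult.from_counts(observed, n_reps, n_exceed, seed)

    observed = timecourse_l1_stat(trend_line_pair(TraceSet(g1), TraceSet(g2)))
    cutoff = _exceed_threshold(observed)
    vals, obs, _ = _trace_matrix(g1 + g2)
    m1, m = len(g1), len(g1) + len(g2)
    base = np.zeros(m)
    base[:m1] = 1.0
    n_exceed = 0
    done = 0
    while done < n_reps:
        b = min(_BATCH, n_reps - done)
        sel = rng.permuted(np.broadcast_to(base, (b, m)).copy(), axis=1)
        stats = _l1_stats_for_selections(sel, vals, obs)
        n_exceed += int((stats > cutoff).sum())
        done += b
    return PermutationResult.from_counts(observed, n_reps, n_exceed, seed)


# ---------------------------------------------------------------------------
# exhaustive oracle
# ---------------------------------------------------------------------------

MAX_EXHAUSTIVE = 12


def exhaustive_permutation_oracle(group_1, group_2,
                                  stat: str = STAT_MEAN_DIFF) -> PermutationResult:
    """Exact permutation test by enumerating every partition.

    Enumerates all C(n, n1) ways of splitting the pooled observations (or
    pooled traces, for the time-course statistic) into groups of the
    original sizes; the p-value is the exact proportion of partitions
    whose statistic strictly exceeds the observed one.  Limited to 12
    observations (traces) total.
    """
    g1, g2 = _as_groups(group_1, group_2, stat)
    n1, n = len(g1), len(g1) + len(g2)
    if n > MAX_EXHAUSTIVE:
        raise SizeError(f"{n} observations exceed the exhaustive bound "
                        f"of {MAX_EXHAUSTIVE}")
    if stat == STAT_MEAN_DIFF:
        pooled = list(np.concatenate([g1, g2]))
        def stat_fn(sel: set) -> float:
            a = [pooled[i] for i in sel]
            b = [pooled[i] for i in range(n) if i not in sel]
            return mean_diff_stat(a, b)
        observed = mean_diff_stat(g1, g2)
    else:
        pooled = list(g1) + list(g2)
        def stat_fn(sel: set) -> float:
            a = TraceSet([pooled[i] for i in sel])
            b = TraceSet([pooled[i] for i in range(n) if i not in sel])
            return timecourse_l1_stat(trend_line_pair(a, b))
        observed = timecourse_l1_stat(trend_line_pair(TraceSet(g1), TraceSet(g2)))

    n_parts = math.comb(n, n1)
    n_exceed = sum(1 for combo in itertools.combinations(range(n), n1)
                   if stat_fn(set(combo)) > observed)
    return PermutationResult.from_counts(observed, n_parts, n_exceed, None)
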