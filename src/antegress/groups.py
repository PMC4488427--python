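"""Burst segmentation of escape sequences and the group flow rate.

Consecutive escapers belong to one *group* when the interval between them
is strictly below the width-specific threshold — the mathematical
expectation (mean) of the pooled intervals for that exit width. A group of
N ants spanning evacuation time t_S = t_N - t_1 has group flow rate

    Q_S = (N - 1) / t_S        [ants/s]

A two-ant group exiting simultaneously has t_S = 0 and an infinite Q_S;
such groups are excluded from statistics and counted separately. For
statistics the minimum group size is 2 at the single-ant-wide 0.5 cm exit
and 3 at wider exits (where simultaneous pairs occur), both configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Tuple, Union

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError, SingularityError
from .intervals import compute_intervals, mean_interval, pool_intervals
from .types import EgressSeries, ExperimentDataset

GROUP_TABLE_COLUMNS = (
    "width_cm", "trial_id", "group_index", "S", "t1_s", "tN_s", "tS_s", "QS",
)


@dataclass(frozen=True)
class EscapeGroup:
    """A maximal run of consecutive escapers."""

    times_s: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        object.__setattr__(self, "times_s", t)
        t.setflags(write=False)
        if t.size == 0:
            raise DomainError("a group must contain at least one escaper")

    @property
    def S(self) -> int:
        return int(self.times_s.size)

    @property
    def t1_s(self) -> float:
        return float(self.times_s[0])

    @property
    def tN_s(self) -> float:
        return float(self.times_s[-1])

    @property
    def tS_s(self) -> float:
        return self.tN_s - self.t1_s


@dataclass(frozen=True)
class GroupingResult:
    """Partition of one trial's events into groups (singletons included)."""

    threshold_s: float
    groups: tuple
    exit_width_cm: float
    trial_id: str

    @property
    def sizes(self) -> tuple:
        return tuple(g.S for g in self.groups)


def segment_groups(series: EgressSeries, threshold_s: float) -> GroupingResult:
    """Split a trial into maximal runs with consecutive intervals < threshold.

    "Below" is strict: an interval exactly equal to the threshold starts a
    new group. Every event belongs to exactly one group; singletons are
    retained.
    """
    if threshold_s <= 0:
        raise DomainError(f"threshold must be positive, got {threshold_s}")
    times = series.times_s
    groups = []
    start = 0
    for i in range(1, times.size):
        if times[i] - times[i - 1] >= threshold_s:
            groups.append(EscapeGroup(times_s=times[start:i]))
            start = i
    if times.size:
        groups.append(EscapeGroup(times_s=times[start:]))
    return GroupingResult(
        threshold_s=float(threshold_s),
        groups=tuple(groups),
        exit_width_cm=series.exit_width_cm,
        trial_id=series.trial_id,
    )


def group_flow_rate(group: EscapeGroup) -> float:
    """Q_S = (S - 1) / t_S for a group of at least two ants."""
    if group.S < 2:
        raise DomainError("group flow rate requires a group of at least 2 ants")
    if group.tS_s == 0:
        raise SingularityError(
            "group evacuation time t_S is zero (simultaneous escapes); Q_S is infinite"
        )
    return (group.S - 1) / group.tS_s


def expectation_thresholds(
    dataset: ExperimentDataset, condition: str = "repellent"
) -> Dict[float, float]:
    """Pooled mean interval per width — the group-segmentation criterion."""
    out: Dict[float, float] = {}
    for width in dataset.widths:
        trials = dataset.select(condition=condition, width=width)
        sets = [compute_intervals(s) for s in trials if s.n_escaped >= 2]
        if not sets:
            continue
        out[width] = mean_interval(pool_intervals(sets, width))
    return out


def default_min_size(width: float, small_exit_cm: float = 0.5) -> int:
    """2 at the single-ant-wide exit, 3 elsewhere (simultaneous-pair guard)."""
    return 2 if width <= small_exit_cm + 1e-9 else 3


MinSize = Union[int, Mapping[float, int]]


def _min_size_for(min_size: MinSize, width: float) -> int:
    if isinstance(min_size, Mapping):
        if width not in min_size:
            raise ConfigurationError(f"no min_size configured for width {width}")
        m = int(min_size[width])
    else:
        m = int(min_size)
    if m < 2:
        raise ConfigurationError(f"min_size must be >= 2, got {m}")
    return m


@dataclass(frozen=True)
class GroupTable:
    """Tidy table of qualifying groups plus the singularity-exclusion count."""

    table: pd.DataFrame
    n_singular_excluded: int


def collect_group_stats(
    dataset: ExperimentDataset,
    thresholds: Mapping[float, float],
    min_size: MinSize = 3,
    condition: str = "repellent",
) -> GroupTable:
    """One row per qualifying group (S >= min_size, t_S > 0) with its Q_S.

    Groups meeting the size cut whose evacuation time is zero are excluded
    and tallied in ``n_singular_excluded``.
    """
    rows = []
    n_singular = 0
    for width in dataset.widths:
        trials = dataset.select(condition=condition, width=width)
        if not trials:
            continue
        if width not in thresholds:
            raise ConfigurationError(f"no grouping threshold configured for width {width}")
        m = _min_size_for(min_size, width)
        for series in trials:
            result = segment_groups(series, thresholds[width])
            for idx, group in enumerate(result.groups):
                if group.S < m:
                    continue
                if group.tS_s == 0:
                    n_singular += 1
                    continue
                rows.append(
                    (width, series.trial_id, idx, group.S,
                     group.t1_s, group.tN_s, group.tS_s, group_flow_rate(group))
                )
    table = pd.DataFrame(rows, columns=list(GROUP_TABLE_COLUMNS))
    return GroupTable(table=table, n_singular_excluded=n_singular)


def mean_group_flow_rate(rows: pd.DataFrame, min_size: int = 3) -> float:
    """Arithmetic mean Q_S over groups with S >= min_size."""
    qualifying = rows.loc[rows["S"] >= min_size, "QS"]
    if qualifying.empty:
        raise DomainError(f"no qualifying groups with S >= {min_size}")
    return float(qualifying.mean())
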