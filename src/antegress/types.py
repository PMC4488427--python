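"""Core containers for egress event data.

An *egress event* is one ant completely passing through the exit, recorded
as a timestamp. A trial is an ordered sequence of such timestamps together
with its condition (repellent vs. water control), exit width, and the number
of ants initially placed in the chamber. Times are stored in seconds
relative to the trial's first escape (the time-zero convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

from .errors import ValidationError

CONDITIONS = ("repellent", "control")

#: Standard exit widths in cm; 1w = 0.5 cm passes a single ant at a time.
STANDARD_WIDTHS_CM = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0)

_TIME_TOL = 1e-9


def normalize_condition(label: str) -> str:
    """Map a condition label to the canonical lowercase form.

    Labels are case-insensitive; anything other than ``repellent`` or
    ``control`` (after stripping and lowercasing) is rejected.
    """
    norm = str(label).strip().lower()
    if norm not in CONDITIONS:
        raise ValidationError(
            f"unknown condition label {label!r}; expected one of {CONDITIONS}"
        )
    return norm


@dataclass(frozen=True)
class EgressSeries:
    """One trial's ordered escape times.

    Parameters
    ----------
    trial_id
        Opaque unique label for the trial.
    condition
        ``"repellent"`` or ``"control"`` (case-insensitive on input).
    exit_width_cm
        Exit width in cm; must be positive.
    n_initial
        Number of ants placed in the chamber (30 +/- 2 in the original
        design; under control conditions only a fraction escape).
    times_s
        Non-decreasing escape times in seconds; the first entry must be 0
        (time of the first escape) when the series is non-empty.
    """

    trial_id: str
    condition: str
    exit_width_cm: float
    n_initial: int
    times_s: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "condition", normalize_condition(self.condition))
        times = np.asarray(self.times_s, dtype=float)
        object.__setattr__(self, "times_s", times)
        times.setflags(write=False)
        if self.exit_width_cm <= 0:
            raise ValidationError(f"exit_width_cm must be > 0, got {self.exit_width_cm}")
        if int(self.n_initial) < 1:
            raise ValidationError(f"n_initial must be >= 1, got {self.n_initial}")
        object.__setattr__(self, "n_initial", int(self.n_initial))
        if times.ndim != 1:
            raise ValidationError("times_s must be one-dimensional")
        if times.size:
            if np.any(np.diff(times) < 0):
                raise ValidationError(f"times_s must be non-decreasing ({self.trial_id})")
            if abs(times[0]) > _TIME_TOL:
                raise ValidationError(
                    f"times_s[0] must be 0 (time-zero convention), got {times[0]}"
                )
        if times.size > self.n_initial:
            raise ValidationError(
                f"{times.size} escapes exceed n_initial={self.n_initial} ({self.trial_id})"
            )

    @property
    def n_escaped(self) -> int:
        return int(self.times_s.size)

    def equals(self, other: "EgressSeries", time_tol: float = _TIME_TOL) -> bool:
        return (
            self.trial_id == other.trial_id
            and self.condition == other.condition
            and abs(self.exit_width_cm - other.exit_width_cm) < 1e-12
            and self.n_initial == other.n_initial
            and self.times_s.size == other.times_s.size
            and bool(np.all(np.abs(self.times_s - other.times_s) <= time_tol))
        )

    def __eq__(self, other: object) -> bool:  # times compared to 1 ns
        if not isinstance(other, EgressSeries):
            return NotImplemented
        return self.equals(other)

    def __hash__(self) -> int:
        return hash((self.trial_id, self.condition, self.exit_width_cm))


@dataclass(frozen=True)
class ExperimentDataset:
    """A collection of trials, typically one full width x condition design."""

    series: tuple
    provenance: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "series", tuple(self.series))
        ids = [s.trial_id for s in self.series]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate trial_id values: {dupes}")

    @property
    def widths(self) -> tuple:
        return tuple(sorted({s.exit_width_cm for s in self.series}))

    @property
    def conditions(self) -> tuple:
        return tuple(sorted({s.condition for s in self.series}))

    def select(
        self,
        condition: Optional[str] = None,
        width: Optional[float] = None,
    ) -> tuple:
        """Trials matching the given condition and/or exit width."""
        out = self.series
        if condition is not None:
            cond = normalize_condition(condition)
            out = tuple(s for s in out if s.condition == cond)
        if width is not None:
            out = tuple(s for s in out if abs(s.exit_width_cm - width) < 1e-9)
        return out

    def __iter__(self) -> Iterator[EgressSeries]:
        return iter(self.series)

    def __len__(self) -> int:
        return len(self.series)

    def equals(self, other: "ExperimentDataset", time_tol: float = _TIME_TOL) -> bool:
        """Content equality ignoring provenance and trial order."""
        if len(self) != len(other):
            return False
        mine = {s.trial_id: s for s in self.series}
        theirs = {s.trial_id: s for s in other.series}
        if mine.keys() != theirs.keys():
            return False
        return all(mine[k].equals(theirs[k], time_tol) for k in mine)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExperimentDataset):
            return NotImplemented
        return self.equals(other)

    def __hash__(self) -> int:
        return hash(tuple(sorted(s.trial_id for s in self.series)))
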