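"""Seeded synthetic egress experiments.

The generator emulates the statistical structure the downstream analysis
assumes: a full design of 6 exit widths (0.5-3.0 cm) x 6 repellent
repetitions (3 for the water control), 30 +/- 2 ants per trial, escape
times on a 25 fps video grid (0.04 s), and inter-escape intervals drawn
i.i.d. from an exponential distribution whose scale beta depends on the
exit width. Under the control condition only a small fraction of ants
exits (each independently with probability ``control_escape_prob``).

The default ``beta_by_width`` values are the decay scales characteristic of
the original experiments, so a default synthetic experiment qualitatively
reproduces the observed width dependence (beta shrinking as the exit
widens). Simultaneous escapes arise naturally when an interval rounds to
zero frames; no extra tie mechanism exists.

Randomness contract: a single root seed; each series draws from a stream
derived deterministically from (seed, width, condition, repetition), so any
subset of the design is reproducible in isolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional, Sequence

import numpy as np
import yaml

from .errors import ConfigurationError
from .types import CONDITIONS, STANDARD_WIDTHS_CM, EgressSeries, ExperimentDataset

#: Width-specific exponential decay scales (seconds) used by default.
DEFAULT_BETA_BY_WIDTH = {0.5: 3.17, 1.0: 2.95, 1.5: 2.79, 2.0: 1.81, 2.5: 1.47, 3.0: 1.50}


def _width_key(width: float) -> int:
    # stable integer identifier for seeding streams per width
    return int(round(width * 1000))


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a synthetic egress experiment.

    Attributes
    ----------
    widths_cm
        Exit widths to simulate.
    beta_by_width
        Exponential interval scale beta (s) per width; every width in
        ``widths_cm`` must have an entry.
    reps_repellent, reps_control
        Repetitions per width under each condition.
    n_agents_mean, n_agents_jitter
        Ants per trial: mean +/- uniform integer jitter.
    frame_dt_s
        Video time grid (0.04 s = 25 fps); all times are multiples of it.
    control_escape_prob
        Per-ant escape probability under the water control.
    seed
        Root seed for the whole experiment.
    """

    widths_cm: Sequence[float] = STANDARD_WIDTHS_CM
    beta_by_width: Mapping[float, float] = field(
        default_factory=lambda: dict(DEFAULT_BETA_BY_WIDTH)
    )
    reps_repellent: int = 6
    reps_control: int = 3
    n_agents_mean: int = 30
    n_agents_jitter: int = 2
    frame_dt_s: float = 0.04
    control_escape_prob: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "widths_cm", tuple(float(w) for w in self.widths_cm))
        object.__setattr__(
            self, "beta_by_width", {float(w): float(b) for w, b in self.beta_by_width.items()}
        )
        if any(b <= 0 for b in self.beta_by_width.values()):
            raise ConfigurationError("all beta values must be > 0")
        if self.frame_dt_s <= 0:
            raise ConfigurationError("frame_dt_s must be > 0")
        if not 0.0 <= self.control_escape_prob <= 1.0:
            raise ConfigurationError("control_escape_prob must be in [0, 1]")
        if self.reps_repellent < 1 or self.reps_control < 0:
            raise ConfigurationError("repetition counts out of range")
        if self.n_agents_mean - self.n_agents_jitter < 1:
            raise ConfigurationError("n_agents_mean - n_agents_jitter must be >= 1")

    def beta_for(self, width: float) -> float:
        w = float(width)
        if w not in self.beta_by_width:
            raise ConfigurationError(f"no beta configured for width {width} cm")
        return self.beta_by_width[w]

    def stream(self, width: float, condition: str, rep: int) -> np.random.Generator:
        """Deterministic per-series random stream."""
        cond_idx = CONDITIONS.index(condition)
        return np.random.default_rng(
            [int(self.seed), _width_key(width), cond_idx, int(rep)]
        )

    def to_mapping(self) -> dict:
        d = asdict(self)
        d["widths_cm"] = list(self.widths_cm)
        d["beta_by_width"] = {str(w): b for w, b in self.beta_by_width.items()}
        return d

    @classmethod
    def from_mapping(cls, data: Mapping) -> "SimulationConfig":
        data = dict(data)
        if "beta_by_width" in data:
            data["beta_by_width"] = {float(w): float(b) for w, b in data["beta_by_width"].items()}
        return cls(**data)

    @classmethod
    def from_file(cls, path) -> "SimulationConfig":
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
        data = yaml.safe_load(text)  # YAML is a superset of JSON
        if not isinstance(data, Mapping):
            raise ConfigurationError(f"config file {path!r} must contain a mapping")
        return cls.from_mapping(data)


def simulate_series(
    config: SimulationConfig,
    width: float,
    condition: str,
    stream: np.random.Generator,
    trial_id: Optional[str] = None,
) -> EgressSeries:
    """Draw one trial.

    The agent count is ``n_agents_mean`` plus uniform integer jitter. Under
    the repellent every agent escapes; under control each escapes
    independently with ``control_escape_prob``. Inter-escape intervals are
    i.i.d. exponential with the width's beta, rounded to the frame grid, and
    accumulated from time zero.
    """
    beta = config.beta_for(width)
    jitter = config.n_agents_jitter
    n = int(config.n_agents_mean + stream.integers(-jitter, jitter + 1))
    if condition == "repellent":
        escapers = n
    elif condition == "control":
        escapers = int(stream.binomial(n, config.control_escape_prob))
    else:
        raise ConfigurationError(f"unknown condition {condition!r}")

    dt = config.frame_dt_s
    if escapers == 0:
        times = np.empty(0)
    else:
        intervals = stream.exponential(beta, size=escapers - 1)
        intervals = np.round(intervals / dt) * dt
        times = np.concatenate([[0.0], np.cumsum(intervals)])
        times = np.round(times / dt) * dt  # keep exact grid multiples after summation
    if trial_id is None:
        trial_id = f"{condition}-w{width:g}"
    return EgressSeries(
        trial_id=trial_id,
        condition=condition,
        exit_width_cm=float(width),
        n_initial=n,
        times_s=times,
    )


def simulate_experiment(config: SimulationConfig) -> ExperimentDataset:
    """Simulate the full design: every width under both conditions."""
    series = []
    for width in config.widths_cm:
        config.beta_for(width)  # fail fast on missing beta
        for condition, reps in (
            ("repellent", config.reps_repellent),
            ("control", config.reps_control),
        ):
            for rep in range(reps):
                stream = config.stream(width, condition, rep)
                series.append(
                    simulate_series(
                        config,
                        width,
                        condition,
                        stream,
                        trial_id=f"{condition}-w{width:g}-r{rep:02d}",
                    )
                )
    return ExperimentDataset(
        series=tuple(series), provenance=f"synthetic(seed={config.seed})"
    )
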