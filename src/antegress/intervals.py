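"""Inter-escape interval statistics and the two nonlinear fits.

The central quantity is the *time interval* (headway): the elapsed time
between one ant completely passing through the exit and the next. Pooled
over repetitions of one exit width, the relative-frequency histogram of
these intervals decays exponentially and is modelled as

    p_f(dt) = alpha * exp(-dt / beta) + epsilon

with one (alpha, beta, epsilon) triple per exit width. beta (seconds) is
the decay scale: a larger beta means a heavier long-interval tail. The
cumulative number of escaped ants over time is modelled by the saturating
exponential y(x) = A1 * exp(-x / t1) + y0 (A1 < 0 for a rising count).

The mean interval is the reciprocal of the mean flow rate Q (ants/s).
Means are computed from the raw pooled intervals, not from the histogram,
so they do not depend on the binning rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

from .errors import ConfigurationError, DomainError, ValidationError
from .types import EgressSeries

BIN_RULES = ("sturges", "scott", "fixed_width")


@dataclass(frozen=True)
class IntervalSet:
    """Inter-escape intervals for one exit width (one trial or pooled)."""

    exit_width_cm: float
    condition: str
    intervals_s: np.ndarray
    source: str = "per_trial"  # "per_trial" | "pooled"

    def __post_init__(self) -> None:
        iv = np.asarray(self.intervals_s, dtype=float)
        object.__setattr__(self, "intervals_s", iv)
        iv.setflags(write=False)
        if iv.size and iv.min() < 0:
            raise ValidationError("intervals must be non-negative")

    @property
    def n(self) -> int:
        return int(self.intervals_s.size)


@dataclass(frozen=True)
class IntervalHistogram:
    """Binned interval counts; the fit target is counts / n_total."""

    bin_edges_s: np.ndarray
    counts: np.ndarray
    rule: str
    n_total: int

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges_s, dtype=float)
        counts = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "bin_edges_s", edges)
        object.__setattr__(self, "counts", counts)
        if counts.size != edges.size - 1:
            raise ValidationError("need len(counts) == len(bin_edges) - 1")
        if int(counts.sum()) != self.n_total:
            raise ValidationError("histogram counts do not sum to n_total")

    @property
    def midpoints_s(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_s[:-1] + self.bin_edges_s[1:])

    @property
    def frequencies(self) -> np.ndarray:
        return self.counts / self.n_total


@dataclass(frozen=True)
class ExpDecayFit:
    """alpha*exp(-t/beta)+epsilon least-squares fit of an interval histogram."""

    alpha: float
    beta: float
    epsilon: float
    sse: float
    converged: bool


@dataclass(frozen=True)
class EscapeCurveFit:
    """y0 + A1*exp(-x/t1) fit of the cumulative escape count."""

    y0: float
    A1: float
    t1: float
    sse: float
    converged: bool


@dataclass(frozen=True)
class TrendFit:
    """Ordinary least-squares line of beta on exit width."""

    slope: float
    intercept: float
    r_squared: float


def compute_intervals(series: EgressSeries) -> IntervalSet:
    """Successive differences of the escape times; k events give k-1 intervals."""
    return IntervalSet(
        exit_width_cm=series.exit_width_cm,
        condition=series.condition,
        intervals_s=np.diff(series.times_s),
        source="per_trial",
    )


def pool_intervals(sets: Iterable[IntervalSet], width: Optional[float] = None) -> IntervalSet:
    """Concatenate interval sets sharing one width and condition."""
    sets = list(sets)
    if not sets:
        raise DomainError("no interval sets to pool")
    widths = {s.exit_width_cm for s in sets}
    conditions = {s.condition for s in sets}
    if len(widths) > 1:
        raise ValidationError(f"cannot pool mixed exit widths: {sorted(widths)}")
    if len(conditions) > 1:
        raise ValidationError(f"cannot pool mixed conditions: {sorted(conditions)}")
    (w,) = widths
    if width is not None and abs(w - width) > 1e-9:
        raise ValidationError(f"interval sets have width {w}, expected {width}")
    return IntervalSet(
        exit_width_cm=w,
        condition=next(iter(conditions)),
        intervals_s=np.concatenate([s.intervals_s for s in sets]),
        source="pooled",
    )


def mean_interval(iset: IntervalSet) -> float:
    """Arithmetic mean interval in seconds (the 'mathematical expectation')."""
    if iset.n == 0:
        raise DomainError("mean interval of an empty interval set is undefined")
    return float(iset.intervals_s.mean())


def mean_flow_rate(iset: IntervalSet) -> float:
    """Q = 1 / mean interval, in ants per second."""
    m = mean_interval(iset)
    if m <= 0:
        raise DomainError("mean interval is zero (all escapes simultaneous); Q undefined")
    return 1.0 / m


def build_histogram(
    iset: IntervalSet,
    rule: str = "sturges",
    fixed_width_s: Optional[float] = None,
) -> IntervalHistogram:
    """Bin the intervals on [0, max interval].

    Sturges (the default): ceil(1 + log2 n) equal-width bins. Scott: the
    variance-based bin width, clipped to at least one bin. The last bin is
    right-closed, so every value lands in exactly one bin.
    """
    if rule not in BIN_RULES:
        raise ConfigurationError(f"unknown binning rule {rule!r}; expected one of {BIN_RULES}")
    if iset.n == 0:
        raise DomainError("cannot bin an empty interval set")
    data = iset.intervals_s
    hi = float(data.max())
    if hi <= 0:
        hi = 1.0  # all-zero intervals: one unit bin holding everything
    if rule == "sturges":
        k = math.ceil(1 + math.log2(iset.n))
        edges = np.linspace(0.0, hi, k + 1)
    elif rule == "scott":
        sd = float(data.std(ddof=1)) if iset.n > 1 else 0.0
        h = 3.49 * sd * iset.n ** (-1.0 / 3.0)
        k = max(1, math.ceil(hi / h)) if h > 0 else 1
        edges = np.linspace(0.0, hi, k + 1)
    else:  # fixed_width
        if fixed_width_s is None or fixed_width_s <= 0:
            raise ConfigurationError("fixed_width rule requires a positive fixed_width_s")
        k = max(1, math.ceil(hi / fixed_width_s))
        edges = np.arange(k + 1) * fixed_width_s
        if edges[-1] < hi:  # guard against float shortfall
            edges = np.append(edges, edges[-1] + fixed_width_s)
    counts, edges = np.histogram(data, bins=edges)
    return IntervalHistogram(bin_edges_s=edges, counts=counts, rule=rule, n_total=iset.n)


def _exp_decay(t, alpha, beta, epsilon):
    return alpha * np.exp(-t / beta) + epsilon


def fit_exp_decay(
    x: Sequence[float],
    y: Sequence[float],
    p0: Optional[Tuple[float, float, float]] = None,
) -> ExpDecayFit:
    """Least-squares fit of alpha*exp(-x/beta)+epsilon to (x, y) points.

    The default start is moment-matched: epsilon0 = min(y),
    alpha0 = max(y) - epsilon0, beta0 = the y-weighted mean of x (the
    histogram analogue of the sample mean interval). Non-convergence is
    reported via ``converged=False`` with the start values retained.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise DomainError("need at least 3 points to fit the three-parameter decay")
    if p0 is None:
        eps0 = float(y.min())
        alpha0 = max(float(y.max()) - eps0, 1e-12)
        wsum = float(y.sum())
        beta0 = float(np.average(x, weights=y)) if wsum > 0 else float(x.mean())
        beta0 = max(beta0, 1e-6)
        p0 = (alpha0, beta0, eps0)
    try:
        popt, _ = optimize.curve_fit(
            _exp_decay,
            x,
            y,
            p0=p0,
            bounds=([-np.inf, 1e-12, -np.inf], [np.inf, np.inf, np.inf]),
            max_nfev=10000,
        )
        converged = True
    except (RuntimeError, optimize.OptimizeWarning):
        popt, converged = p0, False
    resid = y - _exp_decay(x, *popt)
    return ExpDecayFit(
        alpha=float(popt[0]),
        beta=float(popt[1]),
        epsilon=float(popt[2]),
        sse=float(np.sum(resid**2)),
        converged=converged,
    )


def fit_interval_frequency(hist: IntervalHistogram) -> ExpDecayFit:
    """Fit the decay model to (bin midpoint, relative frequency) pairs."""
    if hist.counts.size < 3:
        raise DomainError("need at least 3 bins to fit the interval-frequency model")
    return fit_exp_decay(hist.midpoints_s, hist.frequencies)


def _sat_exp(x, y0, a1, t1):
    return y0 + a1 * np.exp(-x / t1)


def fit_sat_exp(
    x: Sequence[float],
    y: Sequence[float],
    p0: Optional[Tuple[float, float, float]] = None,
) -> EscapeCurveFit:
    """Least-squares fit of y0 + A1*exp(-x/t1) to (x, y) points."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4:
        raise DomainError("need at least 4 points to fit the escape curve")
    if p0 is None:
        y0_0 = float(y.max())
        a1_0 = float(y.min()) - y0_0  # y(0) ~ smallest count
        t1_0 = float(x.max()) / 3 if x.max() > 0 else 1.0
        p0 = (y0_0, a1_0 if a1_0 != 0 else -1.0, max(t1_0, 1e-6))
    try:
        popt, _ = optimize.curve_fit(
            _sat_exp,
            x,
            y,
            p0=p0,
            bounds=([-np.inf, -np.inf, 1e-12], [np.inf, np.inf, np.inf]),
            max_nfev=10000,
        )
        converged = True
    except (RuntimeError, optimize.OptimizeWarning):
        popt, converged = p0, False
    resid = y - _sat_exp(x, *popt)
    return EscapeCurveFit(
        y0=float(popt[0]),
        A1=float(popt[1]),
        t1=float(popt[2]),
        sse=float(np.sum(resid**2)),
        converged=converged,
    )


def fit_escape_curve(series: EgressSeries) -> EscapeCurveFit:
    """Fit the cumulative escape count sampled at the event times.

    The cumulative count is a right-continuous step function; its value at
    the i-th event time is i, and those (time, count) pairs are the fit
    data. The fitted y0 estimates the total number of escapers.
    """
    k = series.n_escaped
    if k < 4:
        raise DomainError(f"need at least 4 events to fit the escape curve, got {k}")
    return fit_sat_exp(series.times_s, np.arange(1, k + 1, dtype=float))


def beta_trend(points: Iterable[Tuple[float, float]]) -> TrendFit:
    """OLS line of the decay scale beta against exit width."""
    pts = list(points)
    widths = np.array([p[0] for p in pts], dtype=float)
    betas = np.array([p[1] for p in pts], dtype=float)
    if np.unique(widths).size < 2:
        raise DomainError("need at least 2 distinct widths for a trend line")
    res = stats.linregress(widths, betas)
    return TrendFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )
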