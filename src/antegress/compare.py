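"""Two-sample comparisons, star annotation, and correlation.

Three analyses: pairwise t-tests of the pooled intervals between every two
exit widths; the Pearson correlation between group size S and group flow
rate Q_S; and the treatment-vs-control comparison of per-trial escaped
counts. Significance is annotated with stars using strict thresholds:
three stars for p < 0.001, two for p < 0.01, one for p < 0.05, none
otherwise. Welch's t-test (unequal variances) is the default; the
pooled-variance variant is available by flag. p-values are kept at full
precision and stars derive from the unrounded value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DomainError
from .intervals import compute_intervals, pool_intervals
from .types import ExperimentDataset

T_TEST_VARIANTS = ("welch", "pooled")
STAR_THRESHOLDS = (0.001, 0.01, 0.05)


def stars_from_p(p: float) -> int:
    """3/2/1/0 stars for p strictly below 0.001/0.01/0.05."""
    if p < 0.001:
        return 3
    if p < 0.01:
        return 2
    if p < 0.05:
        return 1
    return 0


@dataclass(frozen=True)
class ComparisonResult:
    statistic: float
    p_two_tailed: float
    stars: int
    group_labels: Tuple[str, str]
    n_a: int
    n_b: int


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_two_tailed: float
    n: int


def two_sample_t_test(
    a: Sequence[float],
    b: Sequence[float],
    variant: str = "welch",
    labels: Tuple[str, str] = ("a", "b"),
) -> ComparisonResult:
    """Two-tailed t-test of two independent samples.

    Each sample needs at least two values, and the two samples must not
    both be constant (the statistic is undefined with zero variance on
    both sides; a single constant sample is fine under Welch).
    """
    if variant not in T_TEST_VARIANTS:
        raise ConfigurationError(f"unknown t-test variant {variant!r}")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DomainError("each sample needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise DomainError("both samples are constant; the t statistic is undefined")
    with warnings.catch_warnings():
        # scipy warns about precision loss when one sample is near-constant;
        # expected for escaped-count data and handled by the variance guard above
        warnings.filterwarnings("ignore", category=RuntimeWarning,
                                message="Precision loss occurred")
        t, p = stats.ttest_ind(a, b, equal_var=(variant == "pooled"))
    return ComparisonResult(
        statistic=float(t),
        p_two_tailed=float(p),
        stars=stars_from_p(float(p)),
        group_labels=labels,
        n_a=int(a.size),
        n_b=int(b.size),
    )


@dataclass(frozen=True)
class PairwiseTests:
    """Symmetric matrix of comparisons over unordered width pairs."""

    results: Dict[Tuple[float, float], ComparisonResult]

    def get(self, width_a: float, width_b: float) -> ComparisonResult:
        key = (min(width_a, width_b), max(width_a, width_b))
        return self.results[key]

    def __len__(self) -> int:
        return len(self.results)

    def __iter__(self):
        return iter(self.results.items())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (wa, wb, r.statistic, r.p_two_tailed, r.stars, r.n_a, r.n_b)
            for (wa, wb), r in sorted(self.results.items())
        ]
        return pd.DataFrame(
            rows,
            columns=["width_a", "width_b", "statistic", "p", "stars", "n_a", "n_b"],
        )


def pairwise_interval_tests(
    dataset: ExperimentDataset,
    variant: str = "welch",
    condition: str = "repellent",
    correction: Optional[str] = None,
) -> PairwiseTests:
    """t-tests of pooled intervals between every pair of exit widths.

    Intervals are pooled across all repetitions per width. No
    multiple-testing correction is applied by default; pass
    ``correction="bonferroni"`` or ``"holm"`` to adjust the p-values
    (stars then derive from the adjusted values).
    """
    pooled: Dict[float, np.ndarray] = {}
    for width in dataset.widths:
        trials = dataset.select(condition=condition, width=width)
        sets = [compute_intervals(s) for s in trials if s.n_escaped >= 2]
        if sets:
            pooled[width] = pool_intervals(sets, width).intervals_s
    widths = sorted(pooled)
    if len(widths) < 2:
        raise DomainError("need interval samples for at least 2 widths")
    pairs = [(wa, wb) for i, wa in enumerate(widths) for wb in widths[i + 1 :]]
    results = {
        (wa, wb): two_sample_t_test(
            pooled[wa], pooled[wb], variant=variant, labels=(f"{wa:g}cm", f"{wb:g}cm")
        )
        for wa, wb in pairs
    }
    if correction is not None:
        from statsmodels.stats.multitest import multipletests

        method = {"bonferroni": "bonferroni", "holm": "holm"}.get(correction)
        if method is None:
            raise ConfigurationError(f"unknown correction {correction!r}")
        keys = list(results)
        raw = [results[k].p_two_tailed for k in keys]
        _, adj, _, _ = multipletests(raw, method=method)
        for k, p_adj in zip(keys, adj):
            r = results[k]
            results[k] = ComparisonResult(
                statistic=r.statistic,
                p_two_tailed=float(p_adj),
                stars=stars_from_p(float(p_adj)),
                group_labels=r.group_labels,
                n_a=r.n_a,
                n_b=r.n_b,
            )
    return PairwiseTests(results=results)


def pearson_correlation(
    s_values: Sequence[float], qs_values: Sequence[float]
) -> CorrelationResult:
    """Product-moment correlation with a two-tailed p (t transform, n-2 df)."""
    s = np.asarray(s_values, dtype=float)
    q = np.asarray(qs_values, dtype=float)
    if s.size != q.size:
        raise DomainError("paired samples must have equal length")
    if s.size < 3:
        raise DomainError("need at least 3 pairs for a correlation")
    if s.var() == 0 or q.var() == 0:
        raise DomainError("correlation is undefined for a constant input")
    res = stats.pearsonr(s, q)
    return CorrelationResult(
        r=float(res.statistic), p_two_tailed=float(res.pvalue), n=int(s.size)
    )


def treatment_vs_control_counts(
    dataset: ExperimentDataset, width: float, variant: str = "welch"
) -> ComparisonResult:
    """t-test on per-trial escaped counts, repellent vs. water control."""
    rep = [s.n_escaped for s in dataset.select(condition="repellent", width=width)]
    ctl = [s.n_escaped for s in dataset.select(condition="control", width=width)]
    if len(rep) < 2 or len(ctl) < 2:
        raise DomainError(
            f"need >=2 trials per condition at width {width} cm "
            f"(got {len(rep)} repellent, {len(ctl)} control)"
        )
    return two_sample_t_test(rep, ctl, variant=variant, labels=("repellent", "control"))
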