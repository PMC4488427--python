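"""End-to-end analysis: intervals -> fits -> grouping -> comparisons.

``run_analysis`` executes every stage on an :class:`ExperimentDataset` and
returns a JSON-serializable report. Partial failures (a non-converged fit,
a width without enough data for some statistic) are recorded in the report
rather than aborting the run. The report structure is versioned and
validated against the schema shipped with the package.
"""

from __future__ import annotations

import hashlib
import importlib.resources
import json
import logging
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .compare import pairwise_interval_tests, pearson_correlation, treatment_vs_control_counts
from .errors import ConfigurationError, DomainError, EgressError, ValidationError
from .groups import (
    collect_group_stats,
    default_min_size,
    expectation_thresholds,
    mean_group_flow_rate,
)
from .intervals import (
    beta_trend,
    build_histogram,
    compute_intervals,
    fit_interval_frequency,
    mean_flow_rate,
    mean_interval,
    pool_intervals,
)
from .types import ExperimentDataset

logger = logging.getLogger("antegress")

SCHEMA_VERSION = "1"


@dataclass(frozen=True)
class AnalysisOptions:
    """Tunable knobs of the pipeline.

    bin_rule / fixed_width_s control interval histograms; ttest_variant is
    ``welch`` or ``pooled``; threshold_overrides pins the group-segmentation
    threshold per width instead of the data-derived pooled mean;
    min_size_overrides pins the minimum group size per width (default: 2 at
    <= small_exit_cm, 3 elsewhere); correction optionally adjusts the
    pairwise p-values; seed is provenance only.
    """

    bin_rule: str = "sturges"
    fixed_width_s: Optional[float] = None
    ttest_variant: str = "welch"
    threshold_overrides: Optional[Mapping[float, float]] = None
    min_size_overrides: Optional[Mapping[float, int]] = None
    small_exit_cm: float = 0.5
    correction: Optional[str] = None
    seed: Optional[int] = None

    def to_mapping(self) -> dict:
        d = asdict(self)
        if self.threshold_overrides is not None:
            d["threshold_overrides"] = {str(k): v for k, v in self.threshold_overrides.items()}
        if self.min_size_overrides is not None:
            d["min_size_overrides"] = {str(k): v for k, v in self.min_size_overrides.items()}
        return d

    @classmethod
    def from_mapping(cls, data: Mapping) -> "AnalysisOptions":
        data = dict(data)
        for key in ("threshold_overrides", "min_size_overrides"):
            if data.get(key) is not None:
                cast = float if key == "threshold_overrides" else int
                data[key] = {float(k): cast(v) for k, v in data[key].items()}
        return cls(**data)

    @classmethod
    def from_file(cls, path) -> "AnalysisOptions":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh.read())
        if data is None:
            data = {}
        if not isinstance(data, Mapping):
            raise ConfigurationError(f"config file {path!r} must contain a mapping")
        data = {k: v for k, v in data.items() if k != "xlsx_column_map"}
        return cls.from_mapping(data)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_mapping(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _jsonable(value):
    if isinstance(value, (np.floating, np.integer)):
        return value.item()
    if isinstance(value, np.ndarray):
        return value.tolist()
    return value


def run_analysis(
    dataset: ExperimentDataset,
    options: Optional[AnalysisOptions] = None,
    source: Optional[str] = None,
) -> dict:
    """Run the full pipeline and return the report dictionary.

    Stages, in order: per-trial intervals; pooled per-width histograms and
    decay fits; mean intervals and flow rates Q; group segmentation at the
    expectation threshold and group flow rates Q_S; the beta-vs-width
    trend; pairwise interval t-tests; S-Q_S correlations; and, when
    control trials are present, treatment-vs-control escaped-count tests.
    Deterministic given (dataset, options) apart from the timestamp.
    """
    if options is None:
        options = AnalysisOptions()
    if len(dataset) == 0:
        raise DomainError("empty dataset: nothing to analyze")
    if not dataset.select(condition="repellent"):
        raise DomainError("dataset has no repellent trials")

    notes: list = []
    thresholds = dict(expectation_thresholds(dataset, condition="repellent"))
    if options.threshold_overrides:
        thresholds.update({float(k): float(v) for k, v in options.threshold_overrides.items()})

    min_sizes = {
        w: default_min_size(w, options.small_exit_cm) for w in dataset.widths
    }
    if options.min_size_overrides:
        min_sizes.update({float(k): int(v) for k, v in options.min_size_overrides.items()})

    group_result = collect_group_stats(
        dataset, thresholds, min_size=min_sizes, condition="repellent"
    )
    gt = group_result.table

    per_width = []
    beta_points = []
    correlations = []
    for width in dataset.widths:
        trials = dataset.select(condition="repellent", width=width)
        sets = [compute_intervals(s) for s in trials if s.n_escaped >= 2]
        block = {
            "width_cm": width,
            "n_trials": len(trials),
            "n_intervals": 0,
            "mean_interval_s": None,
            "Q": None,
            "alpha": None,
            "beta": None,
            "epsilon": None,
            "sse": None,
            "converged": False,
            "threshold_s": thresholds.get(width),
            "min_size": min_sizes[width],
            "n_groups": 0,
            "mean_QS": None,
        }
        if sets:
            pooled = pool_intervals(sets, width)
            block["n_intervals"] = pooled.n
            block["mean_interval_s"] = mean_interval(pooled)
            try:
                block["Q"] = mean_flow_rate(pooled)
            except DomainError as exc:
                notes.append(f"width {width}: {exc}")
            try:
                hist = build_histogram(pooled, rule=options.bin_rule,
                                       fixed_width_s=options.fixed_width_s)
                fit = fit_interval_frequency(hist)
                block.update(
                    alpha=fit.alpha, beta=fit.beta, epsilon=fit.epsilon,
                    sse=fit.sse, converged=fit.converged,
                )
                if fit.converged:
                    beta_points.append((width, fit.beta))
            except (DomainError, EgressError) as exc:
                notes.append(f"width {width}: interval-frequency fit skipped ({exc})")
        else:
            notes.append(f"width {width}: no trials with >=2 events")

        rows = gt[gt["width_cm"] == width]
        block["n_groups"] = int(len(rows))
        if len(rows):
            block["mean_QS"] = mean_group_flow_rate(rows, min_size=min_sizes[width])
            if rows["S"].nunique() > 1 and len(rows) >= 3:
                corr = pearson_correlation(rows["S"].to_numpy(), rows["QS"].to_numpy())
                correlations.append(
                    {"width_cm": width, "r": corr.r, "p": corr.p_two_tailed, "n": corr.n}
                )
            else:
                notes.append(f"width {width}: S-QS correlation skipped (too few/constant groups)")
        else:
            notes.append(f"width {width}: no qualifying groups")
        logger.info(
            "width %.1f cm: %d trials, %d intervals, %d groups, fit converged=%s",
            width, block["n_trials"], block["n_intervals"], block["n_groups"],
            block["converged"],
        )
        per_width.append(block)

    trend = None
    if len({w for w, _ in beta_points}) >= 2:
        t = beta_trend(beta_points)
        trend = {"slope": t.slope, "intercept": t.intercept, "r_squared": t.r_squared}
    else:
        notes.append("beta trend skipped: fewer than 2 widths with converged fits")

    interval_tests = []
    try:
        matrix = pairwise_interval_tests(
            dataset, variant=options.ttest_variant, correction=options.correction
        )
        interval_tests = [
            {
                "width_a": wa, "width_b": wb,
                "statistic": r.statistic, "p": r.p_two_tailed, "stars": r.stars,
                "n_a": r.n_a, "n_b": r.n_b,
            }
            for (wa, wb), r in sorted(matrix.results.items())
        ]
    except (DomainError, EgressError) as exc:
        notes.append(f"pairwise interval tests skipped ({exc})")

    escaped_tests = []
    for width in dataset.widths:
        if len(dataset.select(condition="control", width=width)) >= 2:
            try:
                r = treatment_vs_control_counts(dataset, width, variant=options.ttest_variant)
                escaped_tests.append(
                    {
                        "width_cm": width, "statistic": r.statistic,
                        "p": r.p_two_tailed, "stars": r.stars,
                        "n_repellent": r.n_a, "n_control": r.n_b,
                    }
                )
            except DomainError as exc:
                notes.append(f"width {width}: escaped-count test skipped ({exc})")

    report = {
        "schema_version": SCHEMA_VERSION,
        "provenance": {
            "package_version": __version__,
            "source": source if source is not None else dataset.provenance,
            "seed": options.seed,
            "bin_rule": options.bin_rule,
            "ttest_variant": options.ttest_variant,
            "config_hash": options.config_hash(),
            "timestamp": datetime.now(timezone.utc).isoformat(),
        },
        "per_width": per_width,
        "beta_trend": trend,
        "interval_tests": interval_tests,
        "correlations": correlations,
        "escaped_count_tests": escaped_tests,
        "group_summary": {
            "n_groups_total": int(len(gt)),
            "n_singular_excluded": int(group_result.n_singular_excluded),
        },
        "notes": notes,
    }
    return json.loads(json.dumps(report, default=_jsonable))


def report_to_json(report: dict) -> str:
    """Canonical JSON serialization (sorted keys, 2-space indent)."""
    return json.dumps(report, sort_keys=True, indent=2, default=_jsonable)


def load_schema() -> dict:
    text = importlib.resources.files("antegress").joinpath("report_schema.json").read_text()
    return json.loads(text)


def _check(instance, schema, path="$") -> list:
    """Minimal structural validator for the subset of JSON Schema we use
    (type, required, properties, items; 'number' accepts int)."""
    errors = []
    types = schema.get("type")
    if types is not None:
        if isinstance(types, str):
            types = [types]
        pytypes = {
            "object": dict, "array": list, "string": str,
            "number": (int, float), "integer": int, "boolean": bool,
            "null": type(None),
        }
        ok = any(
            isinstance(instance, pytypes[t]) and not (t in ("number", "integer")
                                                      and isinstance(instance, bool))
            for t in types
        )
        if not ok:
            errors.append(f"{path}: expected {types}, got {type(instance).__name__}")
            return errors
    if isinstance(instance, dict):
        for key in schema.get("required", []):
            if key not in instance:
                errors.append(f"{path}: missing required key {key!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in instance:
                errors.extend(_check(instance[key], sub, f"{path}.{key}"))
    if isinstance(instance, list) and "items" in schema:
        for i, item in enumerate(instance):
            errors.extend(_check(item, schema["items"], f"{path}[{i}]"))
    return errors


def validate_report(report: dict) -> None:
    """Raise :class:`ValidationError` if the report violates the schema."""
    errors = _check(report, load_schema())
    if errors:
        raise ValidationError("invalid report: " + "; ".join(errors[:10]))


def per_width_frame(report: dict) -> pd.DataFrame:
    """Per-width summary block as a tidy DataFrame."""
    return pd.DataFrame(report["per_width"])
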