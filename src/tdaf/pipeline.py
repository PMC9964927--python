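"""TDAF orchestration: slice → extract features → pool into time bins.

Time Dispersion Analysis of Features cuts every series of a class into the
same overlapping sub-minute windows, computes per-window features, and
pools each feature across series by window index ("bin").  The resulting
per-bin dispersion (min, quartiles, median, max) reconstructs the feature's
trajectory through time, revealing transient behaviour that whole-series
statistics average away.  Before/after-stimulus classes are then compared
bin by bin on their medians.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import (
    BinSummary,
    DEFAULT_DELAY_FRACTION,
    DEFAULT_WINDOW_SECONDS,
    FeatureVector,
    VoltageSeries,
    slice_windows,
    summarize_bins,
)
from .errors import ConfigurationError, EmptyInputError, TdafError
from .features import FeatureConfig, extract_features

logger = logging.getLogger(__name__)

__all__ = ["TdafConfig", "TdafReport", "run_tdaf", "compare_phases", "plot_tdaf", "PhaseComparison"]

DEFAULT_EFFECT_WINDOW_S = 600.0  # the "first minutes" comparison span


@dataclass(frozen=True)
class TdafConfig:
    window_seconds: float = DEFAULT_WINDOW_SECONDS
    delay_fraction: float = DEFAULT_DELAY_FRACTION
    feature_config: FeatureConfig = FeatureConfig()
    effect_window_s: float = DEFAULT_EFFECT_WINDOW_S

    @property
    def feature_names(self) -> tuple[str, ...]:
        names: list[str] = []
        for f in self.feature_config.features:
            if f == "abp":
                names.extend(f"abp_{b.name}" for b in self.feature_config.bands)
            else:
                names.append(f)
        return tuple(names)


@dataclass
class TdafReport:
    """Per-class, per-feature dispersion summaries ordered by time bin."""

    class_code: str
    feature_name: str
    summaries: list[BinSummary]
    window_seconds: float = DEFAULT_WINDOW_SECONDS
    delay_fraction: float = DEFAULT_DELAY_FRACTION

    def __post_init__(self) -> None:
        idx = [s.bin_index for s in self.summaries]
        if idx != list(range(len(idx))):
            raise TdafError("bin summaries must be consecutive from 0 with no gaps")

    @property
    def step_seconds(self) -> float:
        return (1 - self.delay_fraction) * self.window_seconds

    @property
    def medians(self) -> np.ndarray:
        return np.array([s.median for s in self.summaries])

    @property
    def low_coverage_bins(self) -> list[int]:
        """Bins where fewer than half the pooled windows were valid."""
        if not self.summaries:
            return []
        n_max = max(s.n_values for s in self.summaries)
        return [s.bin_index for s in self.summaries if s.n_values < 0.5 * n_max]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "class": self.class_code,
                "feature": self.feature_name,
                "bin_index": [s.bin_index for s in self.summaries],
                "n": [s.n_values for s in self.summaries],
                "min": [s.minimum for s in self.summaries],
                "q1": [s.q1 for s in self.summaries],
                "median": [s.median for s in self.summaries],
                "q3": [s.q3 for s in self.summaries],
                "max": [s.maximum for s in self.summaries],
            }
        )


def run_tdaf(
    series: Iterable[VoltageSeries] | str | os.PathLike,
    config: TdafConfig = TdafConfig(),
) -> dict[tuple[str, str], TdafReport]:
    """Run the full TDAF pipeline; returns reports keyed by (class, feature).

    ``series`` is an iterable of :class:`VoltageSeries` or the path to an
    experiment manifest.  Within a class all series must share sampling
    rate and length.  A window where an extractor is degenerate contributes
    a missing value to its bin only (logged); the bin's order statistics
    are computed over the remaining values.  Deterministic and invariant
    to the ordering of the input series.
    """
    if isinstance(series, (str, os.PathLike)):
        from .simulate import load_manifest

        series = load_manifest(series)
    groups: dict[str, list[VoltageSeries]] = {}
    for s in series:
        groups.setdefault(s.label, []).append(s)
    if not groups:
        raise EmptyInputError("no input series")

    reports: dict[tuple[str, str], TdafReport] = {}
    for code in sorted(groups):
        members = sorted(groups[code], key=lambda s: s.series_id)
        fs_set = {s.fs for s in members}
        if len(fs_set) != 1:
            raise ConfigurationError(f"heterogeneous sampling rates in class {code}: {fs_set}")
        n_set = {len(s) for s in members}
        if len(n_set) != 1:
            raise ConfigurationError(f"heterogeneous series lengths in class {code}: {n_set}")
        vectors: list[FeatureVector] = []
        for s in members:
            for w in slice_windows(s, config.window_seconds, config.delay_fraction):
                vectors.append(extract_features(w, config.feature_config))
        for feature in config.feature_names:
            summaries = summarize_bins(vectors, feature)
            n_missing = sum(
                max(s2.n_values for s2 in summaries) - s2.n_values for s2 in summaries
            )
            if n_missing:
                logger.info(
                    "class %s feature %s: %d missing window values", code, feature, n_missing
                )
            reports[(code, feature)] = TdafReport(
                class_code=code,
                feature_name=feature,
                summaries=summaries,
                window_seconds=config.window_seconds,
                delay_fraction=config.delay_fraction,
            )
    return reports


def extract_feature_table(
    series: Iterable[VoltageSeries],
    config: TdafConfig = TdafConfig(),
) -> pd.DataFrame:
    """Per-window feature table: one row per (series, bin).

    Columns: series_id, class, bin_index, then one column per feature
    (``apen``, ``dfa_alpha``, ``abp_<band>``).
    """
    rows = []
    for s in series:
        for w in slice_windows(s, config.window_seconds, config.delay_fraction):
            fv = extract_features(w, config.feature_config)
            row = {"series_id": s.series_id, "class": s.label, "bin_index": fv.bin_index}
            for name in config.feature_names:
                row[name] = fv.value(name)
            rows.append(row)
    if not rows:
        raise EmptyInputError("no input series")
    return pd.DataFrame(rows)


@dataclass
class PhaseComparison:
    """Bin-wise before/after medians with the first-minutes effect summary."""

    table: pd.DataFrame
    effect_window_s: float
    effect_bins: list[int]
    effect_mean_difference: float


def compare_phases(
    report_before: TdafReport,
    report_after: TdafReport,
    effect_window_s: float = DEFAULT_EFFECT_WINDOW_S,
    fs: float = 62.5,
) -> PhaseComparison:
    """Median difference (after − before) per bin, plus the headline
    summary: the mean median-difference over the first minutes.

    Only windows lying *entirely* inside ``[0, effect_window_s]`` enter the
    summary — a window straddling the boundary mixes the response with the
    unperturbed regime and would dilute the recovered effect size.
    """
    if report_before.feature_name != report_after.feature_name:
        raise ConfigurationError("reports compare different features")
    if report_before.class_code[:2] != report_after.class_code[:2]:
        raise ConfigurationError(
            f"reports compare different class bases: "
            f"{report_before.class_code} vs {report_after.class_code}"
        )
    nb, na = len(report_before.summaries), len(report_after.summaries)
    if nb != na:
        raise ConfigurationError(f"mismatched bin counts: {nb} vs {na}")

    w = math.floor(report_before.window_seconds * fs)
    step = math.floor((1 - report_before.delay_fraction) * w)
    start_times = np.arange(nb) * step / fs
    end_times = start_times + w / fs

    med_b = report_before.medians
    med_a = report_after.medians
    table = pd.DataFrame(
        {
            "bin_index": np.arange(nb),
            "start_time_s": start_times,
            "median_before": med_b,
            "median_after": med_a,
            "difference": med_a - med_b,
        }
    )
    effect = end_times <= effect_window_s
    effect_bins = list(np.flatnonzero(effect))
    diffs = (med_a - med_b)[effect]
    mean_diff = float(np.nanmean(diffs)) if effect_bins else math.nan
    return PhaseComparison(
        table=table,
        effect_window_s=effect_window_s,
        effect_bins=effect_bins,
        effect_mean_difference=mean_diff,
    )


def plot_tdaf(report: TdafReport, path: str | os.PathLike) -> None:
    """Render a report as median line + quartile ribbon + min/max whiskers."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if not report.summaries:
        raise EmptyInputError("cannot plot an empty report")
    t = np.array(
        [s.bin_index for s in report.summaries], dtype=float
    ) * (1 - report.delay_fraction) * report.window_seconds / 60.0
    q1 = np.array([s.q1 for s in report.summaries])
    q3 = np.array([s.q3 for s in report.summaries])
    lo = np.array([s.minimum for s in report.summaries])
    hi = np.array([s.maximum for s in report.summaries])
    fig, ax = plt.subplots(figsize=(8, 3.5))
    ax.fill_between(t, lo, hi, alpha=0.15, label="min–max")
    ax.fill_between(t, q1, q3, alpha=0.35, label="Q1–Q3")
    ax.plot(t, report.medians, lw=1.5, label="median")
    ax.set_xlabel("time (min)")
    ax.set_ylabel(report.feature_name)
    ax.set_title(f"{report.class_code} — {report.feature_name}")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(os.fspath(path), dpi=120)
    plt.close(fig)


def reports_to_frame(reports: dict[tuple[str, str], TdafReport]) -> pd.DataFrame:
    """Concatenate reports into one tidy table (class, feature, bin stats)."""
    return pd.concat([r.to_frame() for _, r in sorted(reports.items())], ignore_index=True)


def write_reports(reports: dict[tuple[str, str], TdafReport], path: str | os.PathLike) -> None:
    """Write all reports as one delimited text table with fixed formatting."""
    frame = reports_to_frame(reports)
    frame.to_csv(os.fspath(path), index=False, float_format="%.10g")
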