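"""Domain types, file I/O and window slicing for electrome time series.

An *electrome* recording is a single-channel voltage-variation series (µV)
sampled at a fixed rate (62.5 Hz by default, one hour per series).  Each
series carries class metadata — treatment, tissue (stimulated/local vs.
distant/systemic leaf) and phase (before vs. after the stimulus) — which
collapses into one of eight class codes (``tlb``, ``tla``, ``tsb``, ``tsa``,
``clb``, ``cla``, ``csb``, ``csa``).

The TDAF procedure cuts every series into sub-minute windows with a fixed
overlap, so that window *k* of every series covers the same time span; the
window index ("bin") is the key used later to pool per-window features
across series and summarise their dispersion through time.
"""

from __future__ import annotations

import enum
import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    ConfigurationError,
    EmptyInputError,
    InsufficientLengthError,
    ParseError,
)

__all__ = [
    "Treatment",
    "Tissue",
    "Phase",
    "VoltageSeries",
    "WindowSlice",
    "FeatureVector",
    "BinSummary",
    "class_code",
    "read_series",
    "write_series",
    "slice_windows",
    "summarize_bins",
]

DEFAULT_FS = 62.5  # Hz
DEFAULT_WINDOW_SECONDS = 48.0
DEFAULT_DELAY_FRACTION = 0.2


class Treatment(str, enum.Enum):
    W = "W"  # wounding (leaf cut)
    HS = "HS"  # heat shock
    W_HS = "W_HS"  # combined wounding + heat shock
    CONTROL = "CONTROL"


class Tissue(str, enum.Enum):
    LOCAL = "LOCAL"  # the stimulated leaf
    SYSTEMIC = "SYSTEMIC"  # a distant, non-stimulated leaf


class Phase(str, enum.Enum):
    BEFORE = "BEFORE"
    AFTER = "AFTER"


def class_code(treatment: Treatment, tissue: Tissue, phase: Phase) -> str:
    """Derive the class code, e.g. (W, LOCAL, BEFORE) -> ``tlb``.

    The first letter distinguishes treated (``t``) from control (``c``)
    plants, the second local/systemic tissue, the third before/after phase.
    """
    t = "c" if treatment == Treatment.CONTROL else "t"
    l = "l" if tissue == Tissue.LOCAL else "s"
    p = "b" if phase == Phase.BEFORE else "a"
    return t + l + p


@dataclass(eq=False)
class VoltageSeries:
    """One channel of voltage variation in µV with class metadata."""

    samples: np.ndarray
    fs: float = DEFAULT_FS
    treatment: Treatment = Treatment.CONTROL
    tissue: Tissue = Tissue.LOCAL
    phase: Phase = Phase.BEFORE
    series_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise EmptyInputError("VoltageSeries requires a non-empty 1-D sample array")
        if not self.fs > 0:
            raise ConfigurationError(f"sampling frequency must be positive, got {self.fs}")
        self.treatment = Treatment(self.treatment)
        self.tissue = Tissue(self.tissue)
        self.phase = Phase(self.phase)

    @property
    def label(self) -> str:
        return class_code(self.treatment, self.tissue, self.phase)

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    def __len__(self) -> int:
        return self.samples.size


@dataclass(eq=False)
class WindowSlice:
    """A contiguous sub-minute segment of a parent series.

    ``bin_index`` is the window's position in time, shared by all series
    sliced with the same configuration; ``start_time`` is in seconds from
    the series start (sample 0 maps to t = 0).
    """

    parent_id: str
    bin_index: int
    start_time: float
    samples: np.ndarray
    fs: float = DEFAULT_FS

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.bin_index < 0:
            raise ConfigurationError("bin_index must be nonnegative")


@dataclass
class FeatureVector:
    """Per-window features: ApEn, DFA scaling exponent, band powers (µV²).

    ``dfa_alpha`` may be NaN when the window was degenerate for DFA (e.g.
    constant); band names are a subset of low/delta/theta/alpha/beta.
    """

    bin_index: int
    apen: float = math.nan
    dfa_alpha: float = math.nan
    abp: dict[str, float] = field(default_factory=dict)
    series_id: str = ""

    def value(self, feature_name: str) -> float:
        """Look up a feature by flat name: ``apen``, ``dfa_alpha`` or ``abp_<band>``."""
        if feature_name == "apen":
            return self.apen
        if feature_name == "dfa_alpha":
            return self.dfa_alpha
        if feature_name.startswith("abp_"):
            band = feature_name[4:]
            if band in self.abp:
                return self.abp[band]
        raise KeyError(f"unknown feature name: {feature_name!r}")


@dataclass
class BinSummary:
    """Dispersion of one feature pooled across series at one time bin."""

    bin_index: int
    n_values: int
    minimum: float
    q1: float
    median: float
    q3: float
    maximum: float

    def __post_init__(self) -> None:
        if self.n_values >= 1 and not (
            self.minimum <= self.q1 <= self.median <= self.q3 <= self.maximum
        ):
            raise ValueError("order statistics must be nondecreasing")


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _delimiter_for(path: str | os.PathLike) -> str:
    return "\t" if str(path).lower().endswith((".tsv", ".tab")) else ","


def read_series(
    path: str | os.PathLike,
    fs: float = DEFAULT_FS,
    treatment: Treatment = Treatment.CONTROL,
    tissue: Tissue = Tissue.LOCAL,
    phase: Phase = Phase.BEFORE,
    series_id: str | None = None,
) -> VoltageSeries:
    """Read a delimited text signal file into a :class:`VoltageSeries`.

    The file is either two columns (``time_s``, ``voltage_uV``) or a single
    voltage column; an optional header line is recognised and skipped.
    Samples are returned in file order with no resampling.
    """
    delim = _delimiter_for(path)
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    values: list[float] = []
    for i, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        parts = line.split(delim)
        try:
            values.append(float(parts[-1]))
        except ValueError as exc:
            if i == 1:  # optional header line
                continue
            raise ParseError(
                f"non-numeric value {parts[-1]!r} at line {i} of {path}", line_number=i
            ) from exc
    if not values:
        raise EmptyInputError(f"no data rows in {path}")
    sid = series_id if series_id is not None else os.path.splitext(os.path.basename(path))[0]
    return VoltageSeries(
        samples=np.asarray(values),
        fs=fs,
        treatment=treatment,
        tissue=tissue,
        phase=phase,
        series_id=sid,
    )


def write_series(series: VoltageSeries, path: str | os.PathLike) -> None:
    """Write a series as delimited text (``time_s,voltage_uV`` header).

    Voltages are formatted with 17 significant digits so that
    :func:`read_series` inverts the write exactly on the voltage column.
    """
    if series.samples.size == 0:  # pragma: no cover - blocked by VoltageSeries
        raise EmptyInputError("refusing to write an empty series")
    delim = _delimiter_for(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"time_s{delim}voltage_uV\n")
        for i, v in enumerate(series.samples):
            fh.write(f"{i / series.fs:.6f}{delim}{v:.17g}\n")


# ---------------------------------------------------------------------------
# Window slicing
# ---------------------------------------------------------------------------

def slice_windows(
    series: VoltageSeries,
    window_seconds: float = DEFAULT_WINDOW_SECONDS,
    delay_fraction: float = DEFAULT_DELAY_FRACTION,
) -> list[WindowSlice]:
    """Cut a series into overlapping sub-minute windows.

    Window length is ``w = floor(window_seconds * fs)`` samples and the hop
    is ``s = floor((1 - delay_fraction) * w)`` samples, i.e. consecutive
    windows share a ``delay_fraction`` overlap so that features are not
    biased by behaviour exactly at a cut point.  Windows start at offsets
    0, s, 2s, … while a full window fits; a trailing partial window is
    discarded (padding would bias entropy and spectral estimates).
    """
    if not window_seconds < 60:
        raise ConfigurationError(
            f"window_seconds must be < 60 (sub-minute windows), got {window_seconds}"
        )
    if not 0 < delay_fraction < 1:
        raise ConfigurationError(f"delay_fraction must be in (0, 1), got {delay_fraction}")
    w = math.floor(window_seconds * series.fs)
    if w < 1:
        raise ConfigurationError("window shorter than one sample")
    s = math.floor((1 - delay_fraction) * w)
    n = series.samples.size
    if n < w:
        raise InsufficientLengthError(
            f"series of {n} samples is shorter than one {w}-sample window"
        )
    count = (n - w) // s + 1
    step_seconds = s / series.fs
    return [
        WindowSlice(
            parent_id=series.series_id or series.label,
            bin_index=k,
            start_time=k * step_seconds,
            samples=series.samples[k * s : k * s + w],
            fs=series.fs,
        )
        for k in range(count)
    ]


# ---------------------------------------------------------------------------
# Bin pooling
# ---------------------------------------------------------------------------

def summarize_bins(
    features: Iterable[FeatureVector] | Sequence[Sequence[FeatureVector]],
    feature_name: str,
) -> list[BinSummary]:
    """Pool one named feature across series and summarise per time bin.

    ``features`` is a flat iterable of :class:`FeatureVector` (or a
    sequence of per-series sequences, which is flattened); for each
    ``bin_index`` the min, Q1, median, Q3 and max of the pooled values are
    returned, bins ordered by index.  NaN feature values (windows where an
    extractor was degenerate) are excluded from the order statistics; a bin
    with no valid value reports ``n_values = 0`` and NaN statistics.

    Quartiles use linear interpolation between order statistics.
    """
    flat: list[FeatureVector] = []
    for item in features:
        if isinstance(item, FeatureVector):
            flat.append(item)
        else:
            flat.extend(item)
    if not flat:
        raise EmptyInputError("no feature vectors to summarize")
    bins: dict[int, list[float]] = {}
    for fv in flat:
        bins.setdefault(fv.bin_index, []).append(fv.value(feature_name))
    out: list[BinSummary] = []
    for idx in sorted(bins):
        vals = np.asarray(bins[idx], dtype=float)
        valid = vals[~np.isnan(vals)]
        if valid.size == 0:
            out.append(
                BinSummary(idx, 0, math.nan, math.nan, math.nan, math.nan, math.nan)
            )
            continue
        q1, med, q3 = np.percentile(valid, [25, 50, 75])
        out.append(
            BinSummary(
                bin_index=idx,
                n_values=int(valid.size),
                minimum=float(valid.min()),
                q1=float(q1),
                median=float(med),
                q3=float(q3),
                maximum=float(valid.max()),
            )
        )
    return out
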