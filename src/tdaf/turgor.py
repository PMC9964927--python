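"""Turgor (patch-pressure) series: normalization and variability analysis.

A magnetic leaf-clamp probe reports *patch pressure* — the pressure between
two magnets clamped on a leaf — which tracks relative leaf turgor.  Series
are sampled every 10 s for one hour before and one hour after a stimulus.
Analysis is descriptive: pressure is expressed as a percentage of its
initial value and the irregularity of each half is quantified by the
coefficient of variation CV% = 100 · sd / mean.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .core import Treatment
from .errors import DegenerateInputError, EmptyInputError, InsufficientLengthError

__all__ = [
    "TurgorSeries",
    "normalize_percent",
    "coefficient_of_variation",
    "before_after_cv",
]


@dataclass(eq=False)
class TurgorSeries:
    """Patch-pressure samples at fixed interval with a stimulus timestamp."""

    samples: np.ndarray
    sample_interval_s: float = 10.0
    stimulus_time_s: float = 3600.0
    treatment: Treatment = Treatment.CONTROL
    series_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size == 0:
            raise EmptyInputError("TurgorSeries requires non-empty samples")
        span = (self.samples.size - 1) * self.sample_interval_s
        if not 0 <= self.stimulus_time_s <= span:
            raise ValueError(
                f"stimulus_time_s={self.stimulus_time_s} outside series span [0, {span}]"
            )

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) * self.sample_interval_s


def normalize_percent(series: TurgorSeries) -> TurgorSeries:
    """Express pressure as percent of the initial (t = 0) value.

    The first normalized value is exactly 100; negative excursions are
    allowed (the probe reports relative pressure).  Idempotent up to scale:
    normalizing an already-normalized series returns it unchanged.
    """
    first = series.samples[0]
    if first == 0:
        raise DegenerateInputError("cannot normalize: first sample is zero")
    return replace(series, samples=100.0 * series.samples / first)


def coefficient_of_variation(values: Sequence[float] | np.ndarray) -> float:
    """CV% = 100 · sample standard deviation (n−1) / mean.

    Scale-invariant under positive rescaling; sensitive to mean shifts.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise InsufficientLengthError("CV requires at least 2 values")
    mean = x.mean()
    if mean == 0:
        raise DegenerateInputError("CV undefined for zero-mean values")
    return float(100.0 * x.std(ddof=1) / mean)


def before_after_cv(series: TurgorSeries) -> tuple[float, float]:
    """CV% of the percent-normalized series before vs. at/after the stimulus.

    The sample at exactly ``stimulus_time_s`` belongs to the *after* side
    (stimulus effects begin at application).
    """
    norm = normalize_percent(series)
    split = int(np.ceil(series.stimulus_time_s / series.sample_interval_s))
    before = norm.samples[:split]
    after = norm.samples[split:]
    if before.size < 2 or after.size < 2:
        raise InsufficientLengthError("need at least 2 samples on each side of the stimulus")
    return coefficient_of_variation(before), coefficient_of_variation(after)
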