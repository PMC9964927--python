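"""Seeded generators for synthetic electrome and turgor series.

The study design these generators emulate: common-bean plants stimulated by
wounding (W, a leaf cut), heat shock (HS, a flame at distance), or both at
once on different leaves (W+HS), with unstimulated controls; voltage
recorded for one hour before and one hour after the stimulus on the
stimulated (local) leaf and on a distant (systemic) leaf, and leaf turgor
(patch pressure) sampled every 10 s on the systemic leaf.

Baseline electrome
    1/f^β colored Gaussian noise (β = 1.5 by default: plant extracellular
    recordings are strongly red) scaled to ``baseline_sigma`` µV, with a
    superposed Poisson train of biexponential spikes whose peak amplitudes
    are ≥ 50 µV (drawn uniformly from ``spike_amp_range``); systemic-leaf
    spikes are scaled down by ``systemic_amplitude_scale``.

Post-stimulus regime (non-control)
    Within the response window the electrome becomes dominated by a large
    coherent slow wave — a variation-potential-like depolarization with
    0.2 Hz and 1.2 Hz components, several times the baseline σ — and spike
    amplitudes grow.  This one mechanism jointly produces the three
    reported signatures: a drop in approximate entropy (the signal becomes
    regular at the scale of the r = 0.02 σ tolerance), a rise in the DFA
    exponent (stronger temporal correlation) and a rise in low/delta band
    power.  The wave amplitude is looked up from a calibration table
    (measured once with the full analysis pipeline at default parameters)
    so that a scenario's ``apen_drop_target`` is what the pipeline actually
    recovers.  Combined stimulation is biphasic: two response lobes
    separated by a trough near +10 min.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

from .core import (
    DEFAULT_FS,
    Phase,
    Tissue,
    Treatment,
    VoltageSeries,
    class_code,
    write_series,
)
from .errors import ConfigurationError, TdafError
from .turgor import TurgorSeries

__all__ = [
    "StimulusScenario",
    "ElectromeGenParams",
    "TurgorGenParams",
    "colored_noise",
    "spike_train",
    "generate_electrome",
    "generate_turgor",
    "generate_experiment",
    "load_manifest",
]


# ---------------------------------------------------------------------------
# Scenarios
# ---------------------------------------------------------------------------

# Per-treatment ApEn drop targets reported for local and systemic leaves.
# Local leaves: "a decrease of 0.3 ... in all treatments"; systemic leaves
# were quantified per treatment (W 0.1, HS 0.3, W+HS 0.2).
_APEN_DROP_DEFAULTS: dict[tuple[Treatment, Tissue], float] = {
    (Treatment.W, Tissue.LOCAL): 0.3,
    (Treatment.HS, Tissue.LOCAL): 0.3,
    (Treatment.W_HS, Tissue.LOCAL): 0.3,
    (Treatment.W, Tissue.SYSTEMIC): 0.1,
    (Treatment.HS, Tissue.SYSTEMIC): 0.3,
    (Treatment.W_HS, Tissue.SYSTEMIC): 0.2,
    (Treatment.CONTROL, Tissue.LOCAL): 0.0,
    (Treatment.CONTROL, Tissue.SYSTEMIC): 0.0,
}


@dataclass(frozen=True)
class StimulusScenario:
    """What a treatment does to the electrome after the stimulus."""

    treatment: Treatment
    tissue: Tissue = Tissue.LOCAL
    response_onset_s: float = 0.0
    response_duration_s: float = 600.0
    biphasic: bool = False
    apen_drop_target: float = 0.3
    systemic_amplitude_scale: float = 0.5
    # slow-wave amplitude in units of baseline sigma; None -> calibrated
    # from apen_drop_target via the frozen lookup table
    wave_amplitude_factor: float | None = None
    background_attenuation: float = 1.0  # stochastic background scale inside the response
    spike_amp_gain: float = 1.5  # spike amplitude multiplier inside the response

    def __post_init__(self) -> None:
        if not self.response_duration_s > 0:
            raise ConfigurationError("response_duration_s must be positive")
        if not 0 < self.systemic_amplitude_scale <= 1:
            raise ConfigurationError("systemic_amplitude_scale must be in (0, 1]")

    @classmethod
    def default(cls, treatment: Treatment, tissue: Tissue = Tissue.LOCAL) -> "StimulusScenario":
        treatment = Treatment(treatment)
        tissue = Tissue(tissue)
        return cls(
            treatment=treatment,
            tissue=tissue,
            biphasic=(treatment == Treatment.W_HS),
            apen_drop_target=_APEN_DROP_DEFAULTS[(treatment, tissue)],
        )


@dataclass(frozen=True)
class ElectromeGenParams:
    fs: float = DEFAULT_FS
    duration_s: float = 3600.0
    baseline_sigma: float = 20.0  # µV
    spectral_exponent: float = 1.5  # 1/f^beta baseline
    spike_rate: float = 1.0  # events per minute
    spike_amp_range: tuple[float, float] = (50.0, 300.0)  # µV, peaks >= 50 µV
    seed: int = 0

    def __post_init__(self) -> None:
        n = self.duration_s * self.fs
        if abs(n - round(n)) > 1e-9:
            raise ConfigurationError(
                f"duration_s * fs = {n} is not an integer sample count"
            )
        if self.spike_amp_range[0] < 50.0:
            raise ConfigurationError("spike amplitudes must be >= 50 µV")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))


# ---------------------------------------------------------------------------
# Signal building blocks
# ---------------------------------------------------------------------------

def colored_noise(
    rng: np.random.Generator, n: int, beta: float, sigma: float = 1.0
) -> np.ndarray:
    """1/f^beta Gaussian noise by spectral synthesis, normalized to sd sigma.

    beta = 0 is white noise, 1 pink, 2 Brownian-like; beta = 2H − 1 yields
    fractional-Gaussian-noise-like series with Hurst exponent H.
    """
    white = rng.standard_normal(n)
    if beta == 0:
        x = white
    else:
        spectrum = np.fft.rfft(white)
        f = np.fft.rfftfreq(n)
        scale = np.empty_like(f)
        scale[0] = 0.0
        scale[1:] = f[1:] ** (-beta / 2.0)
        x = np.fft.irfft(spectrum * scale, n)
    sd = x.std()
    if sd == 0:  # pragma: no cover - requires n == 1
        return np.zeros(n)
    return x * (sigma / sd)


def _spike_kernel(fs: float, rise_s: float = 0.2, decay_s: float = 1.0) -> np.ndarray:
    """Biexponential transient normalized to unit peak, ~5 decay constants long."""
    t = np.arange(0.0, rise_s + 5 * decay_s, 1.0 / fs)
    k = np.exp(-t / decay_s) - np.exp(-t / rise_s)
    return k / k.max()


def spike_train(
    rng: np.random.Generator,
    n: int,
    fs: float,
    rate_per_min: float,
    amp_range: tuple[float, float],
    amp_scale: float = 1.0,
    amp_gain_envelope: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Poisson train of biexponential spikes.

    Returns ``(signal, peak_amplitudes)``; peak amplitudes are drawn from
    ``amp_range`` (before ``amp_scale``), each spike's sign is random, and
    an optional envelope multiplies the amplitude at the spike onset (used
    to enlarge post-stimulus spikes).
    """
    duration_min = n / fs / 60.0
    count = rng.poisson(rate_per_min * duration_min)
    signal = np.zeros(n)
    kernel = _spike_kernel(fs)
    onsets = np.sort(rng.integers(0, max(n - kernel.size, 1), size=count))
    amps = rng.uniform(amp_range[0], amp_range[1], size=count)
    signs = rng.choice([-1.0, 1.0], size=count)
    for onset, amp, sign in zip(onsets, amps, signs):
        gain = 1.0 if amp_gain_envelope is None else 1.0 + amp_gain_envelope[onset]
        seg = kernel * (amp * gain * amp_scale * sign)
        end = min(onset + kernel.size, n)
        signal[onset:end] += seg[: end - onset]
    return signal, amps


def _response_envelope(t: np.ndarray, scenario: StimulusScenario) -> np.ndarray:
    """0→1 envelope of the post-stimulus response with 5 s cosine ramps.

    Monophasic: one lobe over [onset, onset + duration].  Biphasic: a first
    lobe over ~95 % of the duration, a trough near +10 min, then a second
    lobe of equal length starting at onset + 1.2 × duration.
    """
    if scenario.biphasic:
        d = scenario.response_duration_s
        lobes = [
            (scenario.response_onset_s, scenario.response_onset_s + 0.95 * d),
            (scenario.response_onset_s + 1.2 * d, scenario.response_onset_s + 2.2 * d),
        ]
    else:
        lobes = [
            (
                scenario.response_onset_s,
                scenario.response_onset_s + scenario.response_duration_s,
            )
        ]
    env = np.zeros_like(t)
    ramp = 5.0
    for lo, hi in lobes:
        rising = np.clip((t - lo) / ramp, 0.0, 1.0)
        falling = np.clip((hi - t) / ramp, 0.0, 1.0)
        env = np.maximum(env, np.minimum(rising, falling))
    return env


# Calibration table: pipeline-recovered first-10-min median ApEn drop
# (default window/ApEn parameters, mean over 10 generator seeds) as a
# function of the slow-wave amplitude in units of baseline sigma, at the
# generator defaults above.  Built once with the full pipeline and frozen.
_DROP_TO_WAVE_AMPLITUDE: tuple[tuple[float, float], ...] = (
    # (recovered ApEn drop, wave amplitude factor)
    (0.000, 3.0),
    (0.025, 3.5),
    (0.051, 4.0),
    (0.080, 4.5),
    (0.107, 5.0),
    (0.133, 5.5),
    (0.159, 6.0),
    (0.183, 6.5),
    (0.207, 7.0),
    (0.229, 7.5),
    (0.250, 8.0),
    (0.270, 8.5),
    (0.289, 9.0),
    (0.308, 9.5),
    (0.325, 10.0),
    (0.355, 11.0),
    (0.383, 12.0),
)


def _wave_amplitude_for_drop(drop: float) -> float:
    drops = np.array([d for d, _ in _DROP_TO_WAVE_AMPLITUDE])
    amps = np.array([a for _, a in _DROP_TO_WAVE_AMPLITUDE])
    return float(np.interp(drop, drops, amps))  # clipped at the table ends


# ---------------------------------------------------------------------------
# Electrome generator
# ---------------------------------------------------------------------------

def generate_electrome(
    params: ElectromeGenParams,
    scenario: StimulusScenario,
    phase: Phase,
    series_id: str = "",
) -> VoltageSeries:
    """Generate one 1-h electrome series for a scenario and phase.

    Deterministic: the same (params, scenario, phase) always yields the
    same series; the before/after phases use distinct substreams derived
    from ``params.seed``.
    """
    phase = Phase(phase)
    scenario = replace(scenario, treatment=Treatment(scenario.treatment))
    n = params.n_samples
    fs = params.fs
    rng = np.random.default_rng([params.seed, 0 if phase == Phase.BEFORE else 1])

    baseline = colored_noise(rng, n, params.spectral_exponent, params.baseline_sigma)
    spike_scale = (
        scenario.systemic_amplitude_scale if scenario.tissue == Tissue.SYSTEMIC else 1.0
    )
    t = np.arange(n) / fs

    stimulated = phase == Phase.AFTER and scenario.treatment != Treatment.CONTROL
    if scenario.wave_amplitude_factor is not None:
        amp_factor = scenario.wave_amplitude_factor
    elif scenario.apen_drop_target > 0:
        amp_factor = _wave_amplitude_for_drop(scenario.apen_drop_target)
    else:
        amp_factor = 0.0
    responding = stimulated and amp_factor > 0
    if responding:
        env = _response_envelope(t, scenario)
        noise_scale = 1.0 - env * (1.0 - scenario.background_attenuation)
        phases = rng.uniform(0, 2 * np.pi, size=2)
        amp = amp_factor * params.baseline_sigma
        wave = (
            amp
            * env
            * (
                0.6 * np.sin(2 * np.pi * 0.2 * t + phases[0])
                + 0.4 * np.sin(2 * np.pi * 1.2 * t + phases[1])
            )
        )
        gain_env = env * (scenario.spike_amp_gain - 1.0)
        spikes, _ = spike_train(
            rng, n, fs, params.spike_rate, params.spike_amp_range, spike_scale, gain_env
        )
        samples = baseline * noise_scale + wave + spikes
    else:
        # unstimulated regime: baseline + spikes only
        spikes, _ = spike_train(
            rng, n, fs, params.spike_rate, params.spike_amp_range, spike_scale
        )
        samples = baseline + spikes

    return VoltageSeries(
        samples=samples,
        fs=fs,
        treatment=scenario.treatment,
        tissue=scenario.tissue,
        phase=phase,
        series_id=series_id or f"{class_code(scenario.treatment, scenario.tissue, phase)}_{params.seed}",
    )


# ---------------------------------------------------------------------------
# Turgor generator
# ---------------------------------------------------------------------------

# Scenario CV% defaults (before, after): HS and W+HS are the reported
# averages; W (oscillation damping) and CONTROL (mild decrease) are not
# quantified in print and are package choices.
_TURGOR_CV_DEFAULTS: dict[Treatment, tuple[float, float]] = {
    Treatment.HS: (18.84, 27.06),
    Treatment.W_HS: (9.89, 28.27),
    Treatment.W: (15.0, 12.0),
    Treatment.CONTROL: (12.0, 10.0),
}


@dataclass(frozen=True)
class TurgorGenParams:
    sample_interval_s: float = 10.0
    duration_s: float = 7200.0
    baseline_pressure: float = 100.0  # relative probe units
    oscillation_period_s: float = 1800.0
    oscillation_amplitude: float = 3.0
    noise_sd: float = 1.5
    cv_before_pct: float | None = None  # None -> scenario default
    cv_after_pct: float | None = None
    calibrate_cv: bool = True  # False -> emit the raw shape, no CV rescaling
    stimulus_time_s: float = 3600.0
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(2 * self.stimulus_time_s - self.duration_s) > 1e-9:
            raise ConfigurationError("stimulus_time_s must split the series into equal halves")


def generate_turgor(
    params: TurgorGenParams,
    scenario: StimulusScenario,
    series_id: str = "",
) -> TurgorSeries:
    """Generate a 2-h patch-pressure series around a stimulus at mid-series.

    The base signal is a slow sinusoid (stomatal-oscillation-like) plus
    Gaussian noise; the post-stimulus half is reshaped per treatment —
    HS: sharper, faster oscillation; W: exponential damping of the
    oscillation from +15 min; W+HS: a quick sustained pressure ramp from
    +4 min; CONTROL: unchanged.  When CV% targets are given (or defaulted
    per treatment) the deviations of each half about its mean are rescaled
    so the realized CV% of that half matches the target exactly.
    """
    treatment = Treatment(scenario.treatment)
    if params.calibrate_cv:
        default_b, default_a = _TURGOR_CV_DEFAULTS[treatment]
        cv_b = params.cv_before_pct if params.cv_before_pct is not None else default_b
        cv_a = params.cv_after_pct if params.cv_after_pct is not None else default_a
        if cv_b <= 0 or cv_a <= 0:
            raise ConfigurationError("CV targets must be positive")
    else:
        cv_b = cv_a = None

    rng = np.random.default_rng([params.seed, 2])
    n = int(round(params.duration_s / params.sample_interval_s))
    t = np.arange(n) * params.sample_interval_s
    ts = params.stimulus_time_s
    phase0 = rng.uniform(0, 2 * np.pi)

    osc = params.oscillation_amplitude * np.sin(2 * np.pi * t / params.oscillation_period_s + phase0)
    noise = params.noise_sd * rng.standard_normal(n) if params.noise_sd > 0 else np.zeros(n)
    after = t >= ts

    if treatment == Treatment.HS:
        # sharper, faster oscillation after the stimulus
        osc_after = 1.5 * params.oscillation_amplitude * np.sin(
            2 * np.pi * t / (params.oscillation_period_s / 2) + phase0
        )
        osc = np.where(after, osc_after, osc)
    elif treatment == Treatment.W:
        # damping of the oscillation starting 15 min after the stimulus
        damp = np.ones(n)
        tail = t >= ts + 900.0
        damp[tail] = np.exp(-(t[tail] - ts - 900.0) / 1200.0)
        osc = np.where(after, osc * damp, osc)
    elif treatment == Treatment.W_HS:
        # quick, sharp sustained pressure increase from ~+4 min
        ramp = np.clip((t - ts - 240.0) / 300.0, 0.0, 1.0)
        osc = osc + 0.25 * params.baseline_pressure * ramp

    x = params.baseline_pressure + osc + noise

    split = int(np.ceil(ts / params.sample_interval_s))
    for sl, target in ((slice(0, split), cv_b), (slice(split, n), cv_a)):
        if target is None:
            continue
        half = x[sl]
        mean = half.mean()
        dev = half - mean
        sd = dev.std(ddof=1)
        if sd == 0:  # pragma: no cover
            raise TdafError("cannot calibrate CV of a constant half")
        x[sl] = mean + dev * (target / 100.0 * mean / sd)

    return TurgorSeries(
        samples=x,
        sample_interval_s=params.sample_interval_s,
        stimulus_time_s=ts,
        treatment=treatment,
        series_id=series_id or f"turgor_{treatment.value}_{params.seed}",
    )


# ---------------------------------------------------------------------------
# Experiment-level generation
# ---------------------------------------------------------------------------

def generate_experiment(
    n_replicates: int,
    out_dir: str | os.PathLike,
    master_seed: int = 0,
    electrome_params: ElectromeGenParams = ElectromeGenParams(),
    turgor_params: TurgorGenParams = TurgorGenParams(),
    treatments: Iterable[Treatment] = tuple(Treatment),
    tissues: Iterable[Tissue] = (Tissue.LOCAL, Tissue.SYSTEMIC),
    include_turgor: bool = True,
) -> pd.DataFrame:
    """Emit a full treatment × tissue × phase × replicate set of files.

    Per-series seeds derive from ``master_seed`` by a fixed counter scheme
    (treatment index, tissue index, replicate), so a manifest is exactly
    reproducible.  Voltage files use the signal_core text format; the
    returned manifest (also written as ``manifest.csv``) lists
    file, kind, class, treatment, tissue, phase, seed.
    """
    if n_replicates < 1:
        raise ConfigurationError("n_replicates must be >= 1")
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    seen: set[str] = set()
    treatments = [Treatment(tr) for tr in treatments]
    tissues = [Tissue(ti) for ti in tissues]
    for t_idx, treatment in enumerate(treatments):
        for s_idx, tissue in enumerate(tissues):
            scenario = StimulusScenario.default(treatment, tissue)
            for rep in range(n_replicates):
                seed = _derive_seed(master_seed, t_idx, s_idx, rep)
                for phase in (Phase.BEFORE, Phase.AFTER):
                    code = class_code(treatment, tissue, phase)
                    fname = f"{treatment.value}_{tissue.value.lower()}_{phase.value.lower()}_r{rep}.csv"
                    path = os.path.join(out_dir, fname)
                    if fname in seen or os.path.exists(path):
                        raise TdafError(f"output path collision: {path}")
                    seen.add(fname)
                    series = generate_electrome(
                        replace(electrome_params, seed=seed),
                        scenario,
                        phase,
                        series_id=os.path.splitext(fname)[0],
                    )
                    write_series(series, path)
                    rows.append(
                        dict(
                            file=fname,
                            kind="voltage",
                            **{"class": code},
                            treatment=treatment.value,
                            tissue=tissue.value,
                            phase=phase.value,
                            seed=seed,
                        )
                    )
        if include_turgor:
            for rep in range(n_replicates):
                seed = _derive_seed(master_seed, t_idx, 7, rep)
                scenario = StimulusScenario.default(treatment, Tissue.SYSTEMIC)
                series = generate_turgor(replace(turgor_params, seed=seed), scenario)
                fname = f"turgor_{treatment.value}_r{rep}.csv"
                path = os.path.join(out_dir, fname)
                if fname in seen or os.path.exists(path):
                    raise TdafError(f"output path collision: {path}")
                seen.add(fname)
                _write_turgor(series, path)
                rows.append(
                    dict(
                        file=fname,
                        kind="turgor",
                        **{"class": "turgor"},
                        treatment=treatment.value,
                        tissue=Tissue.SYSTEMIC.value,
                        phase="",
                        seed=seed,
                    )
                )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return manifest


def _derive_seed(master_seed: int, t_idx: int, s_idx: int, rep: int) -> int:
    # counter-based scheme, kept below 2**31
    return (master_seed * 1_000_003 + t_idx * 10_007 + s_idx * 1_009 + rep) % (2**31 - 1)


def _write_turgor(series: TurgorSeries, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("time_s,pressure\n")
        for time, v in zip(series.times, series.samples):
            fh.write(f"{time:.1f},{v:.17g}\n")


def load_manifest(
    manifest_path: str | os.PathLike,
) -> list[VoltageSeries]:
    """Load every voltage series listed in an experiment manifest."""
    from .core import read_series  # local import to keep module load light

    manifest = pd.read_csv(manifest_path)
    base = os.path.dirname(os.fspath(manifest_path))
    out = []
    for _, row in manifest.iterrows():
        if row.get("kind", "voltage") != "voltage":
            continue
        out.append(
            read_series(
                os.path.join(base, row["file"]),
                treatment=Treatment(row["treatment"]),
                tissue=Tissue(row["tissue"]),
                phase=Phase(row["phase"]),
                series_id=os.path.splitext(row["file"])[0],
            )
        )
    return out
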