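# Methods

## The problem

Plants produce continuous low-voltage electrical activity — the *electrome* —
measurable as µV-scale potential differences between electrodes inserted in
leaf tissue. Stimuli such as wounding (W), heat shock (HS) or both combined
(W+HS) perturb this activity both at the stimulated (local) leaf and at
distant (systemic) leaves, and the perturbation is transient: it concentrates
in roughly the first ten minutes after the stimulus. Whole-series statistics
average such transients away. The package implements **Time Dispersion
Analysis of Features (TDAF)**: every series is cut into identical overlapping
sub-minute windows, features are computed per window, and each feature is
pooled across series by window index ("bin") so its dispersion — min,
quartiles, median, max — can be followed through time and compared between
the hour before and the hour after a stimulus.

## Windowing

Series are one hour at fs = 62.5 Hz (225,000 samples). The default window is
48 s (3000 samples) with a 20 % overlap between consecutive windows
(hop = 0.8·w = 2400 samples), giving 93 windows per series. Overlap avoids
biasing features by behaviour that happens to fall exactly at a cut point.
The window must be sub-minute (a configuration error otherwise); a trailing
partial window is discarded rather than padded, because padding biases both
entropy and spectral estimates. Window length and overlap are configurable.

## Features

**Approximate entropy.** ApEn = Φ_m(r) − Φ_{m+1}(r), where Φ_m(r) is the
mean over the M = N−(m−1)τ embedding vectors of ln(count/M), count being the
number of vectors within Chebyshev distance r (the self-match included — the
standard convention, which keeps counts positive and the estimate defined).
Defaults m = 2, τ = 1, r = 0.02·σ with σ the standard deviation (ddof 0) of
the *analysed window*, so ApEn is invariant to the voltage unit. The 0.02
coefficient is an unusually tight tolerance (the ApEn literature commonly
uses 0.1–0.25); it is kept as the default because it is the analysis this
package reproduces, but `r_coef` is a first-class parameter. At r = 0.02·σ
the statistic is dominated by how many embedding neighbours exist at all:
counts for white noise are near 1 (ApEn ≈ 0.23 on 3000-sample windows) and
*any* added temporal structure initially raises ApEn; only signals that are
nearly deterministic at the window scale drive it down. This shapes the
synthetic stimulus-response mechanism below.

**DFA.** The window is mean-centred and cumulatively summed into a profile;
for each box size n (default: 16 log-spaced integers from 4 to N/4) the
profile is split into non-overlapping boxes, a least-squares line is removed
per box, and F(n) is the RMS of the pooled residuals. α is the slope of
log2 F vs log2 n. α ≈ 0.5 means no memory; 0.5 < α < 1 persistent
stationary correlations; α < 0.5 anti-persistence; α > 1 non-stationary,
fractional-Brownian-like (H = α − 1). On 20 series of white noise
(N = 10,000) the estimator's mean α is ≈ 0.51, on integrated noise ≈ 1.49.
A zero-variance window raises a degenerate-input error, which the pipeline
records as a missing value for that bin only.

**Average band power.** Welch PSD (Hann window, 512-sample segments, 50 %
overlap, per-segment mean removal, density scaling) followed by composite
Simpson integration over low (0–0.5 Hz), delta (0.5–4), theta (4–8), alpha
(8–12) and beta (12–30 Hz). The 512-sample segment gives ≈ 0.122 Hz
resolution — five grid points inside the low band — while still averaging
~10 segments per 3000-sample window. Gamma (30–100 Hz) is excluded: Nyquist
is 31.25 Hz at fs = 62.5. Bands with fewer than three grid points fall back
to the trapezoid rule with a warning. Band powers scale with the square of
the voltage unit (µV² units).

## Pooling and phase comparison

Per class (treatment × tissue × phase) and feature, windows from all series
are pooled by bin index; quartiles use linear interpolation. Missing values
(degenerate windows) are excluded from a bin's order statistics, not
imputed; bins with under 50 % valid values are flagged. `compare_phases`
reports per-bin median differences (after − before) and summarises the
first minutes as the mean median-difference over the bins whose windows lie
*entirely* inside the effect window (600 s by default — at the default
geometry, bins 0–14). Windows straddling the boundary mix the response with
the unperturbed regime and would dilute the recovered effect size, so they
are excluded from the summary (they still appear in the per-bin table). No
inferential statistics are attached to the curves; the output is
descriptive, as dispersion plots and difference tables.

## The synthetic experiment

No raw recordings are available, so a seeded generator defines the study
conditions end to end.

**Baseline electrome** = 1/f^β colored Gaussian noise, spectrally
synthesised and normalised to `baseline_sigma` (20 µV), plus a Poisson
train (1/min) of biexponential spikes (0.2 s rise, 1 s decay, random sign)
with peak amplitudes uniform in 50–300 µV — spikes are by definition the
>50 µV transients. Systemic-leaf spike amplitudes are halved. The default
spectral exponent is β = 1.5: plant extracellular recordings are strongly
red, and this choice gives baseline window ApEn ≈ 0.8–1.1 at r = 0.02·σ,
leaving headroom for the reported post-stimulus decreases of up to 0.3
(with β = 1.0 the baseline window ApEn is ≈ 0.37 while even a pure
sinusoid retains ≈ 0.10, so a 0.3 decrease could not exist).

**Post-stimulus response.** Inside the response window (onset at the
stimulus, 600 s duration) the electrome acquires a large coherent slow
wave — a variation-potential-like depolarisation with 0.2 Hz and 1.2 Hz
components and random phases — and spike amplitudes grow by ×1.5. A single
mechanism produces all three reported signatures at once: the window
becomes dominated by a predictable waveform (ApEn falls), temporal
correlation strengthens (DFA α rises from ≈ 1.1 toward ≈ 1.4), and low/delta
band power rises by one to two orders of magnitude. An AR(1) "regularity"
component was evaluated first and rejected: at r = 0.02·σ any AR(1)
admixture *raises* ApEn (more embedding neighbours, imperfectly
predictable), so it cannot reproduce the reported decrease.

The wave amplitude is the effect-size dial. A frozen calibration table maps
a scenario's `apen_drop_target` to the wave amplitude (in units of baseline
σ): the table was built by running the full default pipeline over a grid of
amplitudes (10 generator seeds each) and recording the first-10-min mean
median-ApEn difference. Default targets follow the reported values: 0.3 for
all local treatments; 0.1 (W), 0.3 (HS) and 0.2 (W+HS) for systemic leaves;
0 for controls (whose after-phase is statistically identical to before).
Combined stimulation is biphasic: the envelope has two lobes separated by a
quiet trough near +10 min. Envelope edges use 5 s cosine ramps.

**Turgor series** are 2 h at one sample per 10 s (720 points), a slow
sinusoid (default period 1800 s, stomatal-oscillation-like) around
100 pressure units plus Gaussian noise, with treatment-specific morphology
after the mid-series stimulus: HS — sharper, faster oscillation; W —
exponential damping from +15 min; W+HS — a quick sustained pressure ramp
from +4 min; control — unchanged. Each half's deviations about its mean are
then rescaled so the realised CV% matches the scenario targets exactly.
Targets for HS (18.84 → 27.06 %) and W+HS (9.89 → 28.27 %) are the reported
averages; W (15 → 12 %) and control (12 → 10 %) are not quantified in print
and are package choices consistent with the described damping/mild-decrease
behaviour. Setting `calibrate_cv=False` emits the raw shape (used to verify
the closed-form CV of a pure sampled sinusoid).

**Seeding.** Every generator consumes a `numpy` `Generator` seeded from
`(seed, substream)` pairs; experiment-level per-series seeds derive from the
master seed by a fixed counter scheme, so a manifest is exactly reproducible
and replicates are independent.

## What the generator does and does not emulate

It reproduces the *dimensions* of the study (series length, rate, class
structure), the spike phenomenology (rate, amplitude floor, local/systemic
asymmetry), and the direction and calibrated magnitude of the post-stimulus
changes in ApEn, DFA α and low/delta power, including the biphasic combined
response. It does not model membrane or ion-channel biophysics, real spike
waveform diversity, circadian or irrigation-driven drifts, electrode
artefacts, or any plant-to-plant communication. Passing tests therefore
demonstrate that the analysis pipeline measures what it claims on signals
with the assumed statistical structure — not that real bean electromes have
that structure.

## Numerical choices and limitations

- ApEn inner loop is an O(M²) pairwise count (numba-compiled) with early
  exit on the first embedding coordinate; results match a brute-force
  distance-matrix oracle to 1e-12.
- A perfectly periodic finite series has ApEn of order 1e-5, not exactly 0
  (the last template has one fewer continuation); the constant-input case
  returns exactly 0 by definition.
- DFA boxes are non-overlapping, first-order detrended, fitted in log2;
  fewer than 4 usable box sizes is an error.
- Quartiles use linear interpolation; report files are written with fixed
  numeric formatting so identical runs are byte-identical.
- Test and example problem sizes (replicate counts, shortened series where
  only structure matters) are chosen to keep the default suite quick while
  preserving each check's power; the effect-size recovery check uses the
  full one-hour geometry with 10 replicates per arm.
- The CV defaults for W and control turgor scenarios, and the exact biphasic
  lobe timing, are interpretations of qualitative descriptions; both are
  configurable.
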