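"""Synthetic electrome and turgor generators: determinism, dimensions,
spike constraints and stimulus-response structure."""

import dataclasses

import numpy as np
import pytest

from tdaf.core import Phase, Tissue, Treatment, slice_windows
from tdaf.errors import ConfigurationError, TdafError
from tdaf.features import FeatureConfig, approximate_entropy, band_powers
from tdaf.simulate import (
    ElectromeGenParams,
    StimulusScenario,
    TurgorGenParams,
    colored_noise,
    generate_electrome,
    generate_experiment,
    generate_turgor,
    load_manifest,
    spike_train,
)
from tdaf.turgor import before_after_cv

W_LOCAL = StimulusScenario.default(Treatment.W, Tissue.LOCAL)
CONTROL_LOCAL = StimulusScenario.default(Treatment.CONTROL, Tissue.LOCAL)


class TestElectromeGenerator:
    def test_one_hour_sample_count(self):
        """One hour at 62.5 Hz is exactly 225,000 points."""
        s = generate_electrome(ElectromeGenParams(seed=1), W_LOCAL, Phase.BEFORE)
        assert len(s) == 225_000

    def test_determinism(self):
        p = ElectromeGenParams(seed=42)
        a = generate_electrome(p, W_LOCAL, Phase.AFTER)
        b = generate_electrome(p, W_LOCAL, Phase.AFTER)
        assert np.array_equal(a.samples, b.samples)

    def test_phases_differ(self):
        p = ElectromeGenParams(seed=42)
        before = generate_electrome(p, CONTROL_LOCAL, Phase.BEFORE)
        after = generate_electrome(p, CONTROL_LOCAL, Phase.AFTER)
        assert not np.array_equal(before.samples, after.samples)

    def test_white_noise_variance(self):
        """With spikes off and a flat spectrum the output is unit-variance
        white noise (up to the exact normalization)."""
        p = ElectromeGenParams(
            duration_s=600, baseline_sigma=1.0, spectral_exponent=0.0, spike_rate=0.0, seed=3
        )
        s = generate_electrome(p, CONTROL_LOCAL, Phase.BEFORE)
        assert s.samples.var() == pytest.approx(1.0, rel=0.05)

    def test_non_integer_sample_count_rejected(self):
        with pytest.raises(ConfigurationError):
            ElectromeGenParams(duration_s=0.01, fs=62.5)

    def test_spike_amplitude_floor_enforced(self):
        with pytest.raises(ConfigurationError):
            ElectromeGenParams(spike_amp_range=(10.0, 100.0))

    def test_spike_peaks_at_least_50uv(self):
        rng = np.random.default_rng(8)
        _, amps = spike_train(rng, 200_000, 62.5, rate_per_min=5.0, amp_range=(50.0, 300.0))
        assert amps.size > 0
        assert np.all(amps >= 50.0)

    def test_systemic_spikes_smaller(self):
        rng1, rng2 = np.random.default_rng(9), np.random.default_rng(9)
        local, _ = spike_train(rng1, 100_000, 62.5, 5.0, (50.0, 300.0), amp_scale=1.0)
        systemic, _ = spike_train(rng2, 100_000, 62.5, 5.0, (50.0, 300.0), amp_scale=0.5)
        assert np.abs(systemic).max() == pytest.approx(0.5 * np.abs(local).max())

    def test_colored_noise_beta_controls_spectrum(self):
        """Steeper beta concentrates variance at low frequencies."""
        rng = np.random.default_rng(0)
        flat = band_powers(colored_noise(rng, 50_000, 0.0), 62.5)
        red = band_powers(colored_noise(rng, 50_000, 2.0), 62.5)
        assert red["low"] / sum(red.values()) > flat["low"] / sum(flat.values())


class TestStimulusResponse:
    @pytest.fixture
    def short_params(self):
        # 20-min series keeps the response window plus margin
        return ElectromeGenParams(duration_s=1200, seed=0)

    def test_response_lowers_apen_and_raises_delta_power(self, short_params):
        """Across seeds, post-stimulus windows inside the response lobe
        have lower median ApEn and higher median delta power than the
        matched pre-stimulus windows; controls show no such shift."""
        d_apen, d_delta, d_apen_ctrl = [], [], []
        for seed in range(10):
            p = dataclasses.replace(short_params, seed=seed)
            for scenario, apen_sink in ((W_LOCAL, d_apen), (CONTROL_LOCAL, d_apen_ctrl)):
                before = generate_electrome(p, scenario, Phase.BEFORE)
                after = generate_electrome(p, scenario, Phase.AFTER)
                def effect_median(series, fn):
                    vals = [
                        fn(w.samples)
                        for w in slice_windows(series)
                        if w.start_time + 48.0 <= 600.0
                    ]
                    return float(np.median(vals))
                apen_sink.append(
                    effect_median(after, approximate_entropy)
                    - effect_median(before, approximate_entropy)
                )
                if scenario is W_LOCAL:
                    d_delta.append(
                        effect_median(after, lambda x: band_powers(x, 62.5)["delta"])
                        - effect_median(before, lambda x: band_powers(x, 62.5)["delta"])
                    )
        assert np.median(d_apen) < 0
        assert np.median(d_delta) > 0
        # paired control differences centred on zero
        from scipy import stats

        assert stats.wilcoxon(d_apen_ctrl).pvalue > 0.01

    def test_biphasic_envelope_has_trough(self):
        """The combined stimulus applies the slow wave in two lobes with a
        quiet trough near +10 min."""
        scenario = StimulusScenario.default(Treatment.W_HS, Tissue.LOCAL)
        assert scenario.biphasic
        p = ElectromeGenParams(duration_s=1800, seed=2, spike_rate=0.0)
        after = generate_electrome(p, scenario, Phase.AFTER)
        t = np.arange(len(after)) / after.fs
        def seg_sd(lo, hi):
            return after.samples[(t >= lo) & (t < hi)].std()
        trough = seg_sd(600, 700)
        lobe1 = seg_sd(100, 500)
        lobe2 = seg_sd(800, 1200)
        assert lobe1 > 2 * trough and lobe2 > 2 * trough


class TestTurgorGenerator:
    def test_sample_count(self):
        s = generate_turgor(TurgorGenParams(seed=0), CONTROL_LOCAL)
        assert len(s.samples) == 720

    def test_whs_cv_ratio_matches_report(self):
        """Combined stimulus: CV rises from 9.89 % to 28.27 % (ratio > 2)."""
        s = generate_turgor(
            TurgorGenParams(seed=1), StimulusScenario.default(Treatment.W_HS, Tissue.SYSTEMIC)
        )
        cv_b, cv_a = before_after_cv(s)
        assert cv_b == pytest.approx(9.89, abs=0.5)
        assert cv_a == pytest.approx(28.27, abs=0.5)
        assert cv_a / cv_b > 2

    def test_hs_cv_targets(self):
        s = generate_turgor(
            TurgorGenParams(seed=1), StimulusScenario.default(Treatment.HS, Tissue.SYSTEMIC)
        )
        cv_b, cv_a = before_after_cv(s)
        assert cv_b == pytest.approx(18.84, abs=0.5)
        assert cv_a == pytest.approx(27.06, abs=0.5)

    def test_pure_sinusoid_closed_form_cv(self):
        """Noise off, calibration off: CV equals the closed form of a
        sampled sinusoid, 100 * (a/sqrt(2)) / mean."""
        params = TurgorGenParams(
            noise_sd=0.0, calibrate_cv=False, oscillation_amplitude=5.0,
            oscillation_period_s=1800.0, seed=7,
        )
        s = generate_turgor(params, CONTROL_LOCAL)
        cv = 100 * s.samples.std(ddof=1) / s.samples.mean()
        expected = 100 * (5.0 / np.sqrt(2)) / 100.0
        assert cv == pytest.approx(expected, rel=0.02)

    def test_cv_targets_must_be_positive(self):
        with pytest.raises(ConfigurationError):
            generate_turgor(TurgorGenParams(cv_before_pct=-1.0, seed=0), CONTROL_LOCAL)

    def test_stimulus_must_split_halves(self):
        with pytest.raises(ConfigurationError):
            TurgorGenParams(duration_s=7200, stimulus_time_s=1000)


class TestExperimentGeneration:
    def test_file_counts_and_manifest_round_trip(self, tmp_path):
        params = ElectromeGenParams(duration_s=60, seed=0)
        manifest = generate_experiment(
            2, tmp_path / "exp", master_seed=5, electrome_params=params
        )
        voltage = manifest[manifest["kind"] == "voltage"]
        assert len(voltage) == 2 * 4 * 2 * 2  # replicates x treatments x tissues x phases
        assert len(manifest[manifest["kind"] == "turgor"]) == 2 * 4
        loaded = load_manifest(tmp_path / "exp" / "manifest.csv")
        assert len(loaded) == len(voltage)
        by_id = {s.series_id: s for s in loaded}
        for _, row in voltage.iterrows():
            sid = row["file"].rsplit(".", 1)[0]
            assert by_id[sid].label == row["class"]

    def test_distinct_replicates_distinct_series(self, tmp_path):
        params = ElectromeGenParams(duration_s=60, seed=0)
        manifest = generate_experiment(
            2, tmp_path / "exp2", master_seed=1, electrome_params=params
        )
        loaded = load_manifest(tmp_path / "exp2" / "manifest.csv")
        r0 = next(s for s in loaded if s.series_id == "W_local_before_r0")
        r1 = next(s for s in loaded if s.series_id == "W_local_before_r1")
        assert not np.array_equal(r0.samples, r1.samples)

    def test_path_collision_rejected(self, tmp_path):
        params = ElectromeGenParams(duration_s=60, seed=0)
        generate_experiment(1, tmp_path / "exp3", electrome_params=params)
        with pytest.raises(TdafError):
            generate_experiment(1, tmp_path / "exp3", electrome_params=params)
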