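"""Spectral pipeline: segmentation, periodograms, bands, normalization."""

import numpy as np
import pytest

from bulbwave import (
    AttenuationModel,
    Band,
    CohortDesign,
    ConditionTimeline,
    DEFAULT_BANDS,
    FULL_BAND,
    PowerSpectrum,
    Recording,
    SegmentSchedule,
    SimulationParams,
    analyze_cohort,
    band_power,
    build_gain_envelope,
    condition_spectrum,
    extract_segments,
    normalize_power,
    peak_frequency,
    periodogram_hamming,
    power_time_course,
    simulate_cohort,
    simulate_recording,
)
from bulbwave.lfpsim import constant_envelope


def _flat_recording(duration_min, fs=200.0, timeline=None, seed=0):
    rng = np.random.default_rng(seed)
    n = int(round(duration_min * 60 * fs))
    tl = timeline or ConditionTimeline([("control", 0, duration_min)])
    return Recording(rng.standard_normal(n), fs, tl)


class TestExtractSegments:
    def test_hour_long_recording_yields_twelve_segments(self, schedule):
        rec = _flat_recording(60)
        segs = extract_segments(rec, schedule)
        assert [s.start_min for s in segs] == [5.0 * k for k in range(12)]
        assert all(s.samples.size == 20 * 200 for s in segs)

    def test_exactly_one_segment_from_twenty_seconds(self, schedule):
        rec = _flat_recording(20.0 / 60.0)
        segs = extract_segments(rec, schedule)
        assert len(segs) == 1 and segs[0].start_s == 0.0

    def test_too_short_recording_rejected(self, schedule):
        rec = _flat_recording(10.0 / 60.0)
        with pytest.raises(ValueError, match="shorter than one segment"):
            extract_segments(rec, schedule)

    def test_epoch_boundary_assignment(self, schedule):
        """Each segment belongs to the epoch that wholly contains it."""
        tl = ConditionTimeline([("control", 0, 17), ("abeta_30nM", 17, 60)])
        rec = _flat_recording(60, timeline=tl)
        segs = extract_segments(rec, schedule)
        # independent enumeration of interval containment
        for s in segs:
            t0, t1 = s.start_min, s.start_min + 20.0 / 60.0
            expected = None
            for e in tl.epochs:
                if e.start_min <= t0 and t1 <= e.end_min:
                    expected = e.label
            assert s.condition == expected
        assert segs[3].start_min == 15.0 and segs[3].condition == "control"
        assert all(s.condition is not None for s in segs)


class TestPeriodogram:
    def test_sinusoid_parseval(self):
        """10-Hz unit sinusoid: band mass at 10 Hz, integral ~ 0.5 uV^2."""
        fs, dur = 1000.0, 20.0
        t = np.arange(int(fs * dur)) / fs
        x = np.sin(2 * np.pi * 10.0 * t)
        spec = periodogram_hamming(x, fs)
        total = band_power(spec, FULL_BAND)
        assert total == pytest.approx(0.5, rel=0.01)
        near_peak = band_power(spec, Band("peak", 9.0, 11.0))
        assert near_peak / total > 0.999
        assert spec.freqs[1] - spec.freqs[0] == pytest.approx(1.0 / dur)

    def test_parseval_on_random_segments(self, rng):
        """Full-range PSD integral equals segment variance within 1%."""
        fs, n = 3000.0, 600000  # long segments keep the taper-vs-variance
        for _ in range(3):      # statistical wiggle well below the 1% band
            x = rng.standard_normal(n)
            spec = periodogram_hamming(x, fs, f_min=0.0, f_max=fs / 2)
            assert band_power(spec, Band("all", 0.0, fs / 2)) == pytest.approx(
                np.var(x), rel=0.01
            )

    def test_window_power_correction_identity(self, rng):
        """The PSD integrates exactly to the taper-weighted mean square."""
        fs, n = 250.0, 5000
        x = rng.standard_normal(n).cumsum()  # strongly autocorrelated
        spec = periodogram_hamming(x, fs, f_min=0.0, f_max=fs / 2)
        w = np.hamming(n)
        xd = x - x.mean()
        weighted_ms = np.sum((w * xd) ** 2) / np.sum(w**2)
        # trapezoid loses only half the (tiny) DC and Nyquist end bins
        assert band_power(spec, Band("all", 0.0, fs / 2)) == pytest.approx(
            weighted_ms, rel=1e-3
        )

    def test_zero_segment_gives_zero_spectrum(self):
        spec = periodogram_hamming(np.zeros(4000), 200.0)
        assert np.all(spec.power == 0.0)

    def test_constant_segment_gives_zero_spectrum(self):
        spec = periodogram_hamming(np.full(4000, 7.3), 200.0)
        assert np.allclose(spec.power, 0.0, atol=1e-20)

    def test_quadratic_scaling_exact(self, rng):
        x = rng.standard_normal(4000)
        a = periodogram_hamming(x, 200.0)
        b = periodogram_hamming(3.0 * x, 200.0)
        np.testing.assert_allclose(b.power, 9.0 * a.power, rtol=1e-9)

    def test_fmax_above_nyquist_rejected(self, rng):
        with pytest.raises(ValueError, match="Nyquist"):
            periodogram_hamming(rng.standard_normal(1000), 80.0, f_max=50.0)


class TestConditionSpectrum:
    def test_average_of_last_two_segments(self, schedule):
        """Only the last n segments of the epoch contribute, bin-averaged."""
        rec = _flat_recording(22)  # 5 whole segments at 0, 5, 10, 15, 20 min
        segs = extract_segments(rec, schedule)
        assert len(segs) == 5
        spec = condition_spectrum(rec, "control", schedule)
        p3 = periodogram_hamming(segs[3].samples, rec.sampling_rate)
        p4 = periodogram_hamming(segs[4].samples, rec.sampling_rate)
        np.testing.assert_allclose(spec.power, (p3.power + p4.power) / 2, rtol=1e-12)
        assert spec.provenance["segment_start_s"] == [15 * 60.0, 20 * 60.0]

    def test_identical_segments_idempotent(self, schedule):
        one = np.random.default_rng(0).standard_normal(20 * 200)
        period = int(5 * 60 * 200)
        samples = np.zeros(2 * period)
        samples[:one.size] = one
        samples[period : period + one.size] = one
        rec = Recording(samples, 200.0, ConditionTimeline([("control", 0, 10)]))
        spec = condition_spectrum(rec, "control", schedule)
        np.testing.assert_allclose(
            spec.power, periodogram_hamming(one, 200.0).power, rtol=1e-12
        )

    def test_too_few_segments_named_error(self, schedule):
        tl = ConditionTimeline([("control", 0, 4), ("abeta_3nM", 4, 6)])
        rec = _flat_recording(6, timeline=tl)
        with pytest.raises(ValueError, match="abeta_3nM"):
            condition_spectrum(rec, "abeta_3nM", schedule)

    def test_missing_condition_rejected(self, schedule):
        rec = _flat_recording(20)
        with pytest.raises(ValueError, match="washout"):
            condition_spectrum(rec, "washout", schedule)


class TestBandPower:
    def test_flat_psd_rectangle(self):
        freqs = np.arange(1.0, 50.0001, 0.05)
        spec = PowerSpectrum(freqs, np.full(freqs.size, 2.0))
        assert band_power(spec, Band("theta", 2, 12)) == pytest.approx(20.0)

    def test_zero_spectrum_zero_bands(self):
        freqs = np.arange(1.0, 50.0001, 0.05)
        spec = PowerSpectrum(freqs, np.zeros(freqs.size))
        for band in DEFAULT_BANDS:
            assert band_power(spec, band) == 0.0

    def test_band_additivity(self, rng):
        freqs = np.arange(1.0, 50.0001, 0.05)
        spec = PowerSpectrum(freqs, rng.exponential(1.0, freqs.size))
        parts = [Band("theta", 2, 12), Band("gap", 12, 13), Band("beta", 13, 35),
                 Band("gamma", 35, 50)]
        total = sum(band_power(spec, b) for b in parts)
        assert total == pytest.approx(band_power(spec, Band("broad", 2, 50)), rel=1e-9)

    def test_band_outside_range_rejected(self):
        freqs = np.arange(1.0, 50.0001, 0.05)
        spec = PowerSpectrum(freqs, np.ones(freqs.size))
        with pytest.raises(ValueError, match="outside"):
            band_power(spec, Band("hf", 40, 80))


class TestNormalizeAndPeak:
    def test_normalization_examples(self):
        assert normalize_power(50.0, 100.0) == 50.0
        assert normalize_power(123.4, 123.4) == 100.0
        assert normalize_power(0.0, 5.0) == 0.0
        with pytest.raises(ValueError, match="control power"):
            normalize_power(1.0, 0.0)

    def test_peak_argmax_and_ties(self):
        freqs = np.arange(1.0, 50.0001, 0.05)
        power = np.ones(freqs.size)
        power[np.argmin(np.abs(freqs - 13.0))] = 5.0
        assert peak_frequency(PowerSpectrum(freqs, power)) == pytest.approx(13.0)
        # uniform spectrum: ties break toward the lowest frequency
        assert peak_frequency(PowerSpectrum(freqs, np.ones(freqs.size))) == 1.0
        assert np.isnan(peak_frequency(PowerSpectrum(freqs, np.zeros(freqs.size))))

    def test_simulated_control_peak_near_resonance(self, fast_params, schedule):
        """Cohort-mean estimated peak frequency tracks the generative 13.3 Hz."""
        tl = ConditionTimeline([("control", 0, 15)])
        design = CohortDesign(7, fast_params, tl, AttenuationModel({}), 8)
        peaks = [
            peak_frequency(condition_spectrum(r, "control", schedule))
            for r in simulate_cohort([design], seed=21)
        ]
        assert np.mean(peaks) == pytest.approx(13.3, abs=2.0)


class TestTimeCourse:
    def test_null_time_course_near_hundred(self, quiet_params, schedule):
        tl = ConditionTimeline([("control", 0, 15), ("control", 15, 45)])
        env = build_gain_envelope(tl, AttenuationModel({}), 8)
        rec = simulate_recording(quiet_params, env, 45, timeline=tl)
        tc = power_time_course(rec, schedule)
        assert tc.times_min[0] == 0.0
        # single 20-s periodograms of a resonance-dominated signal carry
        # ~10% sampling noise; the mean over segments is much tighter
        assert np.abs(tc.normalized_power - 100.0).max() < 40.0
        assert np.mean(tc.normalized_power) == pytest.approx(100.0, abs=12.0)

    def test_step_gain_drops_to_quarter(self, quiet_params, schedule):
        tl = ConditionTimeline([("control", 0, 15), ("abeta_30nM", 15, 45)])
        model = AttenuationModel({"abeta_30nM": 0.25}, onset_halftime_min=0.0)
        env = build_gain_envelope(tl, model, 8)
        rec = simulate_recording(quiet_params, env, 45, timeline=tl)
        tc = power_time_course(rec, schedule)
        assert np.mean(tc.normalized_power[2:]) == pytest.approx(25.0, abs=5.0)

    def test_missing_reference_rejected(self, schedule):
        rec = _flat_recording(30)
        with pytest.raises(ValueError, match="washout"):
            power_time_course(rec, schedule, reference_condition="washout")

    def test_onset_tracks_printed_kinetics(self, fast_params, schedule):
        """30 nM preset: cohort-mean power ~76% at 15 min, ~59% at 25 min."""
        tl = ConditionTimeline([("control", 0, 20), ("abeta_30nM", 20, 80)])
        model = AttenuationModel({"abeta_30nM": 0.401}, 10.8, 15.0, 6.9)
        design = CohortDesign(7, fast_params, tl, model, 8)
        recs = simulate_cohort([design], seed=3)
        tcs = [power_time_course(r, schedule) for r in recs]
        at15 = np.mean([tc.at(15.0) for tc in tcs])
        at25 = np.mean([tc.at(25.0) for tc in tcs])
        assert at15 == pytest.approx(75.7, abs=10.0)
        assert at25 == pytest.approx(58.8, abs=10.0)


class TestAnalyzeCohort:
    def test_null_cohort_near_hundred_and_control_exact(self, fast_params, schedule):
        tl = ConditionTimeline([("control", 0, 15), ("inverse_abeta", 15, 45)])
        model = AttenuationModel({"inverse_abeta": 1.0})
        design = CohortDesign(7, fast_params, tl, model, 8)
        result = analyze_cohort(simulate_cohort([design], seed=9), schedule)
        ctrl = result.per_slice.query("condition == 'control'")
        assert np.allclose(ctrl["normalized_power_pct"], 100.0)
        inv = result.summary.query("condition == 'inverse_abeta' and band == 'full'")
        assert inv["mean_normalized_pct"].iloc[0] == pytest.approx(100.0, abs=10.0)

    def test_single_recording_sem_is_nan(self, fast_params, schedule):
        tl = ConditionTimeline([("control", 0, 15)])
        design = CohortDesign(1, fast_params, tl, AttenuationModel({}), 8)
        result = analyze_cohort(simulate_cohort([design], seed=2), schedule)
        assert result.summary["sem_normalized_pct"].isna().all()
        assert (result.summary["n"] == 1).all()

    def test_heterogeneous_timelines_rejected(self, fast_params, schedule):
        tl1 = ConditionTimeline([("control", 0, 15)])
        tl2 = ConditionTimeline([("control", 0, 15), ("washout", 15, 30)])
        d1 = CohortDesign(1, fast_params, tl1, AttenuationModel({}), 8)
        d2 = CohortDesign(1, fast_params, tl2, AttenuationModel({}), 8)
        recs = simulate_cohort([d1], 1) + simulate_cohort([d2], 2)
        with pytest.raises(ValueError, match="heterogeneous"):
            analyze_cohort(recs, schedule)

    def test_attenuated_cohort_recovers_plateau(self, fast_params, schedule):
        tl = ConditionTimeline([("control", 0, 15), ("abeta_30nM", 15, 45)])
        model = AttenuationModel({"abeta_30nM": 0.40}, onset_halftime_min=0.0)
        design = CohortDesign(7, fast_params, tl, model, 8)
        result = analyze_cohort(simulate_cohort([design], seed=4), schedule)
        row = result.summary.query("condition == 'abeta_30nM' and band == 'full'")
        assert row["mean_normalized_pct"].iloc[0] == pytest.approx(40.0, abs=10.0)
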