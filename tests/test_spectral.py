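"""Weighted spectrogram, band powers, peak-frequency tracks, SG smoothing."""

import numpy as np
import pytest
from scipy import signal as sps

from gaeeg.records import EEGRecord
from gaeeg.spectral import (ALPHA_BAND, DELTA_BAND, FULL_BAND,
                            PeakFrequencyTrack, Spectrogram, band_power,
                            mean_band_power, peak_frequency,
                            relative_band_power, sg_smooth, spectrogram)
from tests.conftest import tone_record


def _flat_spectrogram(value=1.0, df=0.05, dt=5.0, n_t=20):
    freqs = np.round(np.arange(0.0, 45.0 + df / 2, df), 6)
    power = np.full((freqs.size, n_t), float(value))
    return Spectrogram(times=np.arange(n_t) * dt, freqs=freqs, power=power)


def test_pure_tone_peaks_at_tone_frequency_every_frame():
    spec = spectrogram(tone_record(freq=10.0, duration=120.0))
    track = peak_frequency(spec, ALPHA_BAND)
    np.testing.assert_allclose(track.values, 10.0, atol=0.05)


def test_identical_channels_reduce_to_single_channel_psd():
    rec = tone_record(freq=10.0, duration=100.0)
    spec = spectrogram(rec)
    f, t, p = sps.spectrogram(rec.samples[0], fs=rec.fs, window="hann",
                              nperseg=int(20 * rec.fs),
                              noverlap=int(15 * rec.fs),
                              scaling="density", mode="psd")
    keep = f <= 45.0
    np.testing.assert_allclose(spec.power, p[keep], rtol=1e-10)


def test_record_shorter_than_window_raises():
    with pytest.raises(ValueError):
        spectrogram(tone_record(duration=10.0))


@pytest.mark.parametrize("band,expected", [
    ((0.1, 4.0), 3.9),     # interval width on a flat unit spectrum
    ((8.0, 12.0), 4.0),
])
def test_flat_spectrum_band_power_equals_band_width(band, expected):
    series = band_power(_flat_spectrogram(), band)
    np.testing.assert_allclose(series.values, expected, rtol=1e-12)


def test_band_power_locality_single_bin_spike():
    spec = _flat_spectrogram(value=0.0)
    i10 = int(np.argmin(np.abs(spec.freqs - 10.0)))
    spec.power[i10, :] = 7.0          # mass m in the 10 Hz bin
    m = 7.0 * 0.05                    # trapezoid mass of a one-bin spike
    np.testing.assert_allclose(band_power(spec, ALPHA_BAND).values, m,
                               rtol=1e-12)
    np.testing.assert_allclose(band_power(spec, DELTA_BAND).values, 0.0,
                               atol=1e-15)


def test_relative_power_flat_spectrum_is_ratio_of_widths():
    series = relative_band_power(_flat_spectrogram(), ALPHA_BAND)
    np.testing.assert_allclose(series.values, 100.0 * 4.0 / 44.9, rtol=1e-9)


def test_relative_power_is_100_when_all_energy_in_band():
    spec = _flat_spectrogram(value=0.0)
    # strictly interior rows so the trapezoid edge triangles also fall
    # inside the band
    rows = (spec.freqs > 8.05) & (spec.freqs < 11.95)
    spec.power[rows, :] = 3.0
    np.testing.assert_allclose(relative_band_power(spec, ALPHA_BAND).values,
                               100.0, rtol=1e-12)


def test_band_power_additive_over_partition():
    rng = np.random.default_rng(1)
    spec = _flat_spectrogram()
    spec.power = rng.uniform(0.1, 2.0, spec.power.shape)
    total = band_power(spec, FULL_BAND).values
    parts = sum(band_power(spec, b).values
                for b in [(0.1, 4.0), (4.0, 8.0), (8.0, 45.0)])
    np.testing.assert_allclose(parts, total, rtol=1e-10)


def test_relative_power_over_full_band_is_100():
    rng = np.random.default_rng(2)
    spec = _flat_spectrogram()
    spec.power = rng.uniform(0.1, 2.0, spec.power.shape)
    np.testing.assert_allclose(relative_band_power(spec, FULL_BAND).values,
                               100.0, rtol=1e-10)


def test_peak_frequency_invariant_to_positive_scaling():
    rng = np.random.default_rng(3)
    spec = _flat_spectrogram()
    spec.power = rng.uniform(0.1, 2.0, spec.power.shape)
    t1 = peak_frequency(spec, ALPHA_BAND).values
    spec.power *= 37.5
    t2 = peak_frequency(spec, ALPHA_BAND).values
    np.testing.assert_array_equal(t1, t2)


def test_peak_frequency_tie_breaks_to_lowest_bin():
    spec = _flat_spectrogram(value=0.0)
    for f in (9.0, 11.0):
        spec.power[np.argmin(np.abs(spec.freqs - f)), :] = 5.0
    assert np.all(peak_frequency(spec, ALPHA_BAND).values == 9.0)


def test_peak_frequency_undefined_inside_exclusions():
    spec = _flat_spectrogram(n_t=40)
    track = peak_frequency(spec, ALPHA_BAND, exclusions=[(50.0, 100.0)])
    inside = (spec.times >= 50.0) & (spec.times < 100.0)
    assert np.all(np.isnan(track.values[inside]))
    assert not np.any(np.isnan(track.values[~inside]))


def test_ramping_peak_is_tracked():
    spec = _flat_spectrogram(value=0.0, n_t=41)
    ramp = np.linspace(10.0, 12.0, 41)
    for j, f in enumerate(ramp):
        spec.power[np.argmin(np.abs(spec.freqs - f)), j] = 1.0
    track = peak_frequency(spec, ALPHA_BAND)
    np.testing.assert_allclose(track.values, ramp, atol=0.05)


def test_sg_smooth_preserves_linear_and_constant_tracks():
    t = np.arange(0.0, 600.0, 5.0)
    for values in (np.full(t.size, 9.5), 8.0 + 0.004 * t):
        track = PeakFrequencyTrack(times=t, values=values.copy(),
                                   band=(8.0, 12.0))
        out = sg_smooth(track)
        ref = np.interp(out.times, t, values)
        np.testing.assert_allclose(out.values, ref, atol=1e-9)


def test_sg_smooth_suppresses_fast_oscillation_keeps_slow():
    t = np.arange(0.0, 1800.0, 5.0)
    slow = 0.8 * np.sin(2 * np.pi * t / 900.0)
    fast = 0.5 * np.sin(2 * np.pi * t / 25.0)
    track = PeakFrequencyTrack(times=t, values=10.0 + slow + fast,
                               band=(8.0, 14.0))
    out = sg_smooth(track)
    spec_in = np.abs(np.fft.rfft(track.values - track.values.mean()))
    spec_out = np.abs(np.fft.rfft(out.values - out.values.mean()))
    f = np.fft.rfftfreq(t.size, 5.0)
    i_fast = np.argmin(np.abs(f - 1.0 / 25.0))
    i_slow = np.argmin(np.abs(f - 1.0 / 900.0))
    assert spec_out[i_fast] < spec_in[i_fast] / 10.0
    assert abs(spec_out[i_slow] / spec_in[i_slow] - 1.0) < 0.1


def test_sg_smooth_windows_without_two_samples_stay_undefined():
    t = np.arange(0.0, 600.0, 5.0)
    v = np.full(t.size, 10.0)
    v[20:100] = np.nan          # a 400 s gap
    out = sg_smooth(PeakFrequencyTrack(times=t, values=v, band=(8, 12)))
    mid = (out.times > 200.0) & (out.times < 400.0)
    assert np.all(np.isnan(out.values[mid]))


def test_spectrogram_energy_matches_welch_oracle():
    rng = np.random.default_rng(8)
    rec = EEGRecord(fs=250.0, samples=np.tile(rng.standard_normal(250 * 120),
                                              (4, 1)))
    spec = spectrogram(rec, f_hi=125.0)
    f_w, p_w = sps.welch(rec.samples[0], fs=rec.fs, window="hann",
                         nperseg=int(20 * rec.fs), noverlap=int(15 * rec.fs))
    energy_spec = np.trapezoid(spec.power.mean(axis=1), spec.freqs)
    energy_welch = np.trapezoid(p_w, f_w)
    assert abs(energy_spec / energy_welch - 1.0) < 0.05


def test_relative_power_matches_generator_energy_accounting():
    """Maintenance-epoch relative powers vs the generator's analytic budget.

    Amplitude modulation and frequency wander are disabled so the planted
    band energies are deterministic; the measured means must then match
    the analytic relative powers closely.
    """
    from gaeeg.synthetic import PatientSpec, _relative_powers, \
        synthesize_record
    spec = PatientSpec(induction_min=3.0, maintenance_min=5.0,
                       am_depth=0.0, freq_wander_hz=0.0)
    rec = synthesize_record(spec, seed=2)
    sp = spectrogram(rec)
    maint = rec.phase_plan.maintenance_span
    exp_delta, exp_alpha = _relative_powers(spec)
    meas_alpha = mean_band_power(relative_band_power(sp, ALPHA_BAND), maint)
    meas_delta = mean_band_power(relative_band_power(sp, DELTA_BAND), maint)
    assert meas_alpha == pytest.approx(exp_alpha, abs=1.0)
    assert meas_delta == pytest.approx(exp_delta, abs=2.0)


def test_mean_band_power_skips_undefined_frames():
    spec = _flat_spectrogram(n_t=10)
    series = relative_band_power(spec, ALPHA_BAND)
    series.values[3] = np.nan
    assert mean_band_power(series) == pytest.approx(100.0 * 4.0 / 44.9,
                                                    rel=1e-9)
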