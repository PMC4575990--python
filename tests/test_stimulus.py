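"""Stimulus synthesis: pulse trains, sine song, noise and protocols."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst
from scipy.signal import find_peaks, hilbert

from songtune.stimulus import (NoiseSpec, PulseTrainSpec, SineSpec,
                               StimulusProtocol, db_to_amplitude,
                               make_intermittent_protocol, make_noise,
                               make_pulse, make_pulse_train,
                               make_ramp_protocol, make_sine)


class TestPulse:
    def test_carrier_frequency_dominates_spectrum(self):
        wf = make_pulse(PulseTrainSpec())
        # zero-padding to 1 s gives 1-Hz FFT bins
        assert wf.spectral_argmax(min_duration_s=1.0) == pytest.approx(220.0, abs=1.0)

    def test_envelope_peak_amplitude_and_zero_mean(self):
        spec = PulseTrainSpec(level_db=80.0)
        wf = make_pulse(spec)
        a = db_to_amplitude(80.0)
        # envelope maximum is A (the raw waveform peaks a little lower
        # because the carrier quarter-period is comparable to sigma)
        env = np.abs(hilbert(wf.samples))
        assert env.max() == pytest.approx(a, rel=0.05)
        assert np.abs(wf.samples).max() <= a + 1e-12
        # odd carrier x even envelope integrates to ~0
        assert abs(wf.samples.sum()) / np.abs(wf.samples).sum() < 1e-10

    def test_db_level_sets_energy(self):
        e = {db: np.sum(make_pulse(PulseTrainSpec(level_db=db)).samples ** 2)
             for db in (80.0, 86.0)}
        assert e[86.0] / e[80.0] == pytest.approx(10 ** 0.6, rel=1e-9)

    def test_low_sample_rate_rejected(self):
        with pytest.raises(ValueError, match="sample_rate"):
            PulseTrainSpec(carrier_freq=220.0, sample_rate=500.0)


class TestPulseTrain:
    def test_peak_to_peak_span_40_pulses_35ms(self):
        wf = make_pulse_train(PulseTrainSpec(ipi_ms=35.0, n_pulses=40))
        env = np.abs(hilbert(wf.samples))
        min_dist = int(0.8 * 0.035 * wf.sample_rate)
        peaks, _ = find_peaks(env, distance=min_dist, height=0.5 * env.max())
        assert len(peaks) == 40
        span = (peaks[-1] - peaks[0]) / wf.sample_rate
        assert span == pytest.approx(39 * 0.035, abs=1e-3)

    def test_single_pulse_train_is_pulse(self):
        spec = PulseTrainSpec(n_pulses=1)
        np.testing.assert_array_equal(make_pulse_train(spec).samples,
                                      make_pulse(spec).samples)

    def test_autocorrelation_peak_at_ipi(self):
        wf = make_pulse_train(PulseTrainSpec(ipi_ms=35.0, n_pulses=40))
        x = wf.samples
        ac = np.correlate(x, x, mode="full")[len(x) - 1:]
        lo = int(0.020 * wf.sample_rate)
        hi = int(0.050 * wf.sample_rate)
        lag = (lo + np.argmax(ac[lo:hi])) / wf.sample_rate
        assert lag == pytest.approx(0.035, abs=1e-3)

    def test_spectral_comb_at_pulse_rate_harmonics(self):
        ipi_s = 0.035
        wf = make_pulse_train(PulseTrainSpec(ipi_ms=35.0, n_pulses=40))
        n = 16 * len(wf.samples)
        spec = np.abs(np.fft.rfft(wf.samples, n=n))
        freqs = np.fft.rfftfreq(n, 1 / wf.sample_rate)
        # comb lines near the carrier sit at multiples of 1/IPI
        peak_f = freqs[np.argmax(spec)]
        assert peak_f % (1 / ipi_s) == pytest.approx(0.0, abs=2.0) or \
            (1 / ipi_s) - peak_f % (1 / ipi_s) < 2.0

    def test_overlapping_pulses_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            make_pulse_train(PulseTrainSpec(ipi_ms=10.0, envelope_sigma_ms=2.0))


class TestSineAndNoise:
    def test_sine_duration_and_frequency(self):
        wf = make_sine(SineSpec(freq=140.0, duration=1.4, sample_rate=10_000.0))
        assert len(wf.samples) == 14000
        assert wf.spectral_argmax(min_duration_s=1.4) == pytest.approx(140.0, abs=1.0)

    def test_noise_seed_determinism(self):
        a = make_noise(NoiseSpec(seed=7))
        b = make_noise(NoiseSpec(seed=7))
        np.testing.assert_array_equal(a.samples, b.samples)
        c = make_noise(NoiseSpec(seed=8))
        assert not np.array_equal(a.samples, c.samples)

    def test_noise_spectrum_flat_across_octaves(self):
        wf = make_noise(NoiseSpec(duration=10.0, seed=1))
        spec = np.abs(np.fft.rfft(wf.samples)) ** 2
        freqs = np.fft.rfftfreq(len(wf.samples), 1 / wf.sample_rate)
        powers = []
        f = 40.0
        while 2 * f <= wf.sample_rate / 2:
            band = (freqs >= f) & (freqs < 2 * f)
            powers.append(spec[band].mean())
            f *= 2
        assert max(powers) / min(powers) < 2.0

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            SineSpec(duration=0.0)
        with pytest.raises(ValueError):
            NoiseSpec(duration=-1.0)


@given(level=hst.floats(min_value=50.0, max_value=100.0))
@settings(max_examples=20, deadline=None)
def test_db_scaling_is_20log10(level):
    """Amplitude ratio between two levels follows the 20 log10 rule for
    every stimulus type."""
    for build, ref in [
        (lambda db: make_pulse(PulseTrainSpec(level_db=db)),
         make_pulse(PulseTrainSpec(level_db=80.0))),
        (lambda db: make_sine(SineSpec(level_db=db)),
         make_sine(SineSpec(level_db=80.0))),
        (lambda db: make_noise(NoiseSpec(level_db=db, seed=3)),
         make_noise(NoiseSpec(level_db=80.0, seed=3))),
    ]:
        wf = build(level)
        ratio = np.abs(wf.samples).max() / np.abs(ref.samples).max()
        assert ratio == pytest.approx(10 ** ((level - 80.0) / 20.0), rel=1e-9)


class TestProtocols:
    def test_ramp_default_duration(self):
        proto = make_ramp_protocol(PulseTrainSpec(), levels_db=None,
                                   block_s=30.0, lead_silence_s=60.0)
        assert len(proto.segments) == 13
        assert proto.total_s == pytest.approx(60 + 13 * 30)
        # blocks sit on the shared 30-s grid
        starts = [s.start_s for s in proto.segments]
        assert starts == [60.0 + 30.0 * i for i in range(13)]
        levels = [s.level_db for s in proto.segments]
        np.testing.assert_allclose(levels, np.arange(60, 90.1, 2.5))

    def test_single_level_ramp(self):
        proto = make_ramp_protocol(PulseTrainSpec(), levels_db=[80.0])
        assert len(proto.segments) == 1

    def test_empty_levels_rejected(self):
        with pytest.raises(ValueError):
            make_ramp_protocol(PulseTrainSpec(), levels_db=[])
        with pytest.raises(ValueError, match="non-decreasing"):
            make_ramp_protocol(PulseTrainSpec(), levels_db=[80.0, 70.0])

    def test_intermittent_train_count(self):
        proto = make_intermittent_protocol(PulseTrainSpec(), period_s=5.0,
                                           total_song_s=120.0)
        assert len(proto.segments) == 24

    def test_intermittent_pulse_count_ipi_independent(self):
        protos = {ipi: make_intermittent_protocol(PulseTrainSpec(ipi_ms=ipi))
                  for ipi in (15.0, 95.0)}
        counts = {ipi: sum(s.spec.n_pulses for s in p.segments)
                  for ipi, p in protos.items()}
        assert counts[15.0] == counts[95.0]

    def test_long_train_rejected(self):
        # 40 pulses at 95 ms span 3.705 s < 5 s and are fine ...
        make_intermittent_protocol(PulseTrainSpec(ipi_ms=95.0), period_s=5.0)
        # ... but a 200-ms IPI train (7.8 s) exceeds the 5-s period
        with pytest.raises(ValueError, match="span"):
            make_intermittent_protocol(PulseTrainSpec(ipi_ms=200.0),
                                       period_s=5.0)

    def test_zero_song_window_is_silence(self):
        proto = make_intermittent_protocol(PulseTrainSpec(), total_song_s=0.0)
        assert len(proto.segments) == 0
        assert np.all(proto.render().samples == 0)

    def test_json_round_trip_preserves_samples(self, tmp_path):
        proto = make_intermittent_protocol(PulseTrainSpec(), total_song_s=20.0,
                                           lead_s=2.0, tail_s=2.0)
        path = tmp_path / "proto.json"
        proto.to_json(path)
        back = StimulusProtocol.from_json(path)
        np.testing.assert_array_equal(proto.render().samples,
                                      back.render().samples)

    def test_wav_round_trip(self, tmp_path):
        wf = make_sine(SineSpec())
        path = tmp_path / "sine.wav"
        wf.to_wav(path)
        from songtune.stimulus import Waveform
        back = Waveform.from_wav(path)
        np.testing.assert_allclose(back.samples, wf.samples, atol=1e-7)
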