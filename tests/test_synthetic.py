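"""Synthetic-scene generator: spectral content, timing and determinism."""

import numpy as np
import pytest
from scipy.signal import find_peaks, stft

from dolphinet import (
    EventSpec,
    PulseParams,
    SceneConfig,
    VocalizationClass,
    WhistleContour,
    default_event,
    render_scene,
    synthesize_pulse_train,
    synthesize_whistle,
)
from dolphinet.synthetic import _band_rms

FS = 192_000


def spectral_peak_hz(wave, fs):
    spectrum = np.abs(np.fft.rfft(wave))
    return np.fft.rfftfreq(wave.size, 1.0 / fs)[np.argmax(spectrum)]


def spectral_centroid_hz(wave, fs):
    power = np.abs(np.fft.rfft(wave)) ** 2
    freqs = np.fft.rfftfreq(wave.size, 1.0 / fs)
    return float((power * freqs).sum() / power.sum())


class TestWhistle:
    def test_constant_contour_peaks_at_tone(self):
        spec = EventSpec(1, 0.0, 0.5, contour=WhistleContour(10_000, 10_000))
        wave = synthesize_whistle(spec, FS)
        assert wave.size == int(0.5 * FS)
        bin_hz = FS / wave.size
        assert abs(spectral_peak_hz(wave, FS) - 10_000) <= bin_hz

    def test_zero_duration_is_empty(self):
        spec = EventSpec(1, 0.0, 0.0, contour=WhistleContour(10_000, 10_000))
        assert synthesize_whistle(spec, FS).size == 0

    def test_linear_sweep_ridge_is_monotonic(self):
        spec = EventSpec(1, 0.0, 0.5, contour=WhistleContour(5_000, 15_000))
        wave = synthesize_whistle(spec, FS)
        freqs, _, Z = stft(wave, fs=FS, nperseg=2048)
        ridge = freqs[np.argmax(np.abs(Z), axis=0)]
        interior = ridge[2:-2]  # taper regions excluded
        assert np.all(np.diff(interior) >= 0)
        assert interior[-1] > interior[0]

    def test_contour_above_nyquist_rejected(self):
        spec = EventSpec(1, 0.0, 0.1, contour=WhistleContour(40_000, 90_000))
        with pytest.raises(ValueError, match="[Nn]yquist"):
            synthesize_whistle(spec, 96_000)

    def test_out_of_band_contour_rejected_at_spec(self):
        with pytest.raises(ValueError, match="band"):
            EventSpec(1, 0.0, 0.1, contour=WhistleContour(1_000, 2_000))


class TestPulseTrain:
    def test_zero_jitter_pulse_count(self):
        spec = EventSpec(2, 0.0, 0.1, pulse=PulseParams(ici_s=0.01))
        wave = synthesize_pulse_train(spec, FS)
        peaks, _ = find_peaks(np.abs(wave), height=0.3, distance=int(0.005 * FS))
        assert len(peaks) == 10

    def test_feeding_buzz_centroid_below_30khz(self):
        spec = default_event(VocalizationClass.FEEDING_BUZZ, 0.0, 0.1)
        wave = synthesize_pulse_train(spec, FS)
        assert spectral_centroid_hz(wave, FS) < 30_000

    def test_click_train_centroid_above_40khz(self):
        for klass in (VocalizationClass.ECHOLOCATION_CLICK, VocalizationClass.BURST_PULSE):
            spec = default_event(klass, 0.0, 0.2)
            wave = synthesize_pulse_train(spec, FS)
            assert spectral_centroid_hz(wave, FS) > 40_000

    def test_buzz_default_ici_below_10ms(self):
        spec = default_event(VocalizationClass.FEEDING_BUZZ, 0.0, 0.1)
        assert spec.pulse.ici_s < 0.010

    def test_nonpositive_ici_rejected(self):
        with pytest.raises(ValueError, match="interval"):
            PulseParams(ici_s=0.0)

    @pytest.mark.parametrize("ici", [0.005, 0.02, 0.1])
    def test_ici_recovered_within_ten_percent(self, ici, rng):
        spec = EventSpec(
            2, 0.0, max(20 * ici, 0.1),
            pulse=PulseParams(ici_s=ici, ici_jitter=0.1, center_hz=60_000),
        )
        wave = synthesize_pulse_train(spec, FS, rng=rng)
        peaks, _ = find_peaks(np.abs(wave), height=0.3, distance=int(0.4 * ici * FS))
        measured = np.mean(np.diff(peaks)) / FS
        assert measured == pytest.approx(ici, rel=0.10)

    def test_centroid_tracks_center_frequency_within_ten_percent(self):
        for center in (20_000, 50_000, 70_000):
            spec = EventSpec(2, 0.0, 0.1, pulse=PulseParams(ici_s=0.01, center_hz=center))
            wave = synthesize_pulse_train(spec, FS)
            assert spectral_centroid_hz(wave, FS) == pytest.approx(center, rel=0.10)


class TestRenderScene:
    def test_empty_scene_is_pure_noise(self):
        waveform, labels = render_scene(SceneConfig(duration=1.0, seed=0))
        assert waveform.shape == (FS,)
        assert labels == []
        assert np.std(waveform) > 0

    def test_same_seed_identical_output(self):
        config = SceneConfig(duration=0.5, seed=7, events=[default_event(2, 0.1, 0.3)])
        w1, l1 = render_scene(config)
        w2, l2 = render_scene(config)
        assert np.array_equal(w1, w2)
        assert l1 == l2

    def test_snr_lifts_in_band_rms(self, whistle_scene):
        config, waveform, labels = whistle_scene
        event = config.events[0]
        band = event.frequency_band()
        i0, i1 = int(0.3 * FS), int(0.7 * FS)
        noise_only, _ = render_scene(SceneConfig(duration=1.0, seed=config.seed))
        signal_rms = _band_rms(waveform[i0:i1], FS, band)
        noise_rms = _band_rms(noise_only[i0:i1], FS, band)
        assert signal_rms > 3 * noise_rms  # +20 dB nominal

    def test_label_fidelity_energy_in_class_band(self):
        for klass in (1, 2, 3, 4):
            config = SceneConfig(
                duration=1.0, seed=31 + klass, events=[default_event(klass, 0.2, 0.5, snr_db=15)]
            )
            waveform, labels = render_scene(config)
            assert len(labels) == 1
            event = config.events[0]
            band = event.frequency_band()
            i0, i1 = int(0.2 * FS), int(0.7 * FS)
            noise_only, _ = render_scene(SceneConfig(duration=1.0, seed=config.seed))
            assert _band_rms(waveform[i0:i1], FS, band) > 1.5 * _band_rms(
                noise_only[i0:i1], FS, band
            )

    def test_event_beyond_scene_rejected(self):
        config = SceneConfig(duration=0.5, events=[default_event(2, 0.4, 0.3)])
        with pytest.raises(ValueError, match="beyond"):
            render_scene(config)

    def test_annotations_match_event_intervals(self):
        config = SceneConfig(
            duration=1.0, seed=9,
            events=[default_event(2, 0.1, 0.2), default_event(1, 0.5, 0.4)],
        )
        _, labels = render_scene(config)
        assert [int(l.klass) for l in labels] == [2, 1]
        assert [l.start for l in labels] == pytest.approx([0.1, 0.5])
        assert [l.end for l in labels] == pytest.approx([0.3, 0.9])

    def test_yaml_round_trip(self, tmp_path):
        config = SceneConfig(
            duration=1.0, seed=5,
            events=[default_event(1, 0.1, 0.5), default_event(4, 0.7, 0.2)],
        )
        path = tmp_path / "scene.yaml"
        config.to_yaml(path)
        restored = SceneConfig.from_file(path)
        assert restored == config
        w1, _ = render_scene(config)
        w2, _ = render_scene(restored)
        assert np.array_equal(w1, w2)
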