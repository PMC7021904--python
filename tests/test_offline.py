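"""Offline TFR, burst characterization, averaging and session statistics."""

import numpy as np
import pytest

from betaburst.offline import (
    TFR,
    beta_power_change,
    morlet_tfr,
    offline_burst_detect,
    time_locked_average,
    training_effect,
)
from betaburst.realtime import SampleStream
from betaburst.surrogate import Burst, SurrogateSpec, make_burst, synthesize

from .conftest import tone

FS = 1000.0


class TestMorlet:
    def test_tone_peaks_at_tone_frequency(self):
        tfr = morlet_tfr(tone(20.0, duration=3.0, fs=FS), cycles=7.0)
        mid = tfr.power[:, 1000:2000]
        assert np.all(tfr.freqs[np.argmax(mid, axis=0)] == 20.0)

    def test_power_quadratic_in_amplitude(self):
        t1 = morlet_tfr(tone(20.0, duration=3.0, fs=FS, amplitude=1.0))
        t2 = morlet_tfr(tone(20.0, duration=3.0, fs=FS, amplitude=2.0))
        np.testing.assert_allclose(t2.power[:, 500:2500],
                                   4.0 * t1.power[:, 500:2500], rtol=1e-9)

    def test_matches_direct_convolution_oracle(self):
        """fftconvolve path equals a literal per-sample wavelet dot product."""
        rng = np.random.default_rng(0)
        x = rng.standard_normal(900)
        tfr = morlet_tfr(SampleStream(x, FS), cycles=7.0, freqs=[20.0])
        sigma = 7.0 / (2 * np.pi * 20.0)
        half = int(np.ceil(4 * sigma * FS))
        tk = np.arange(-half, half + 1) / FS
        kern = np.exp(-tk**2 / (2 * sigma**2)) * np.exp(2j * np.pi * 20.0 * tk)
        kern *= 2.0 / np.exp(-tk**2 / (2 * sigma**2)).sum()
        for i in (300, 420):
            seg = x[i - half : i + half + 1]
            expected = np.abs(np.dot(seg, kern[::-1])) ** 2
            assert tfr.power[0, i] == pytest.approx(expected, rel=1e-9)

    def test_wavelet_smears_burst_duration(self):
        burst = make_burst(20.0, 1.5, 0.04, 1.0, FS, 3.0)
        tfr = morlet_tfr(SampleStream(burst, FS), freqs=[20.0])
        row = tfr.power[0]
        half_max = row.max() / 2.0
        width_ms = np.sum(row > half_max)  # 1 sample = 1 ms at 1 kHz
        envelope_fwhm_ms = 2.355 * 0.04 * 1000.0
        assert width_ms >= envelope_fwhm_ms

    def test_rejections(self):
        with pytest.raises(ValueError):
            morlet_tfr(tone(20.0, fs=FS), freqs=[600.0])
        with pytest.raises(ValueError):
            morlet_tfr(tone(20.0, fs=FS), cycles=0.5)


class TestOfflineBurstDetect:
    def test_planted_burst_recovered(self):
        spec = SurrogateSpec(
            sampling_rate=FS, duration=10.0,
            bursts=(Burst(21.0, 5.0, 0.1, 2.0),),
            pink_amplitude=0.3, white_amplitude=0.1, seed=4,
        )
        stream, _ = synthesize(spec)
        tfr = morlet_tfr(stream)
        bursts = offline_burst_detect(tfr)
        strongest = bursts.loc[bursts["peak_power"].idxmax()]
        assert abs(strongest["peak_frequency"] - 21.0) <= 1.0
        assert abs(strongest["peak_time"] - 5.0) <= 0.1

    def test_zero_tfr_yields_nothing(self):
        tfr = TFR(np.zeros((5, 100)), np.arange(5.0), np.arange(100) / FS,
                  "morlet-7")
        assert offline_burst_detect(tfr).empty

    def test_strong_burst_duration_exceeds_gate(self):
        spec = SurrogateSpec(
            sampling_rate=FS, duration=10.0,
            bursts=(Burst(20.0, 5.0, 0.04, 5.0),),
            pink_amplitude=0.1, white_amplitude=0.05, seed=5,
        )
        stream, _ = synthesize(spec)
        bursts = offline_burst_detect(morlet_tfr(stream))
        strongest = bursts.loc[bursts["peak_power"].idxmax()]
        assert strongest["duration_ms"] >= 70.0

    def test_power_fom_above_unity(self):
        rng = np.random.default_rng(6)
        stream = SampleStream(rng.standard_normal(8000), FS)
        bursts = offline_burst_detect(morlet_tfr(stream))
        assert (bursts["power_fom"] > 1.0).all()

    def test_normalised_tfr_rejected(self):
        tfr = TFR(np.ones((2, 10)), np.arange(2.0), np.arange(10) / FS,
                  "morlet-7", normalization="per-frequency-98th-percentile")
        with pytest.raises(ValueError):
            offline_burst_detect(tfr)


class TestTimeLockedAverage:
    @staticmethod
    def _burst_train(phases, n=20, fs=FS):
        dur = 2.0 * n
        x = np.zeros(int(dur * fs))
        times = 1.0 + 2.0 * np.arange(n)
        for te, ph in zip(times, phases):
            t = np.arange(len(x)) / fs - te
            x += np.sin(2 * np.pi * 20.0 * t + ph) * np.exp(
                -(t**2) / (2 * 0.05**2)
            )
        return SampleStream(x, fs), times + 0.1

    def test_identical_bursts_average_to_one_burst(self):
        stream, events = self._burst_train(np.zeros(20))
        out = time_locked_average(stream, events, window=0.2)
        assert out["n_used"] == 20
        assert np.max(np.abs(out["mean"])) == pytest.approx(1.0, abs=0.1)

    def test_incoherent_average_shrinks(self):
        rng = np.random.default_rng(8)
        phases = rng.uniform(0, 2 * np.pi, 20)
        stream, events = self._burst_train(phases)
        out = time_locked_average(stream, events, window=0.2,
                                  align_to_trough=False)
        assert np.max(np.abs(out["mean"])) < 0.5  # ~1/sqrt(n) suppression

    def test_trough_alignment_creates_sustained_oscillation(self):
        """Aligning phase-random bursts makes the mean oscillate at 20 Hz,
        the deceptive sustained-rhythm appearance."""
        rng = np.random.default_rng(9)
        phases = rng.uniform(0, 2 * np.pi, 20)
        stream, events = self._burst_train(phases)
        aligned = time_locked_average(stream, events, window=0.2)
        spec = np.abs(np.fft.rfft(aligned["mean"]))
        freqs = np.fft.rfftfreq(len(aligned["mean"]), 1 / FS)
        peak_f = freqs[np.argmax(spec[1:]) + 1]
        assert abs(peak_f - 20.0) <= 3.0
        assert np.max(np.abs(aligned["mean"])) > 2 * 1.0 / np.sqrt(20)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            time_locked_average(tone(20.0, fs=FS), [])


class TestBetaPowerChange:
    def test_identical_sessions_zero(self):
        s = np.ones((6, 100))
        np.testing.assert_allclose(beta_power_change([s, s, s]), 0.0)

    def test_doubling_gives_plus_hundred(self):
        s1 = np.full((6, 50), 2.0)
        out = beta_power_change([s1, 2.0 * s1])
        assert out[0] == 0.0
        assert out[1] == pytest.approx(100.0)

    def test_matches_literal_double_loop(self):
        rng = np.random.default_rng(10)
        sessions = [rng.random((6, rng.integers(50, 80))) + 0.1
                    for _ in range(4)]

        def oracle(sessions):
            out = []
            ref = sessions[0]
            for P in sessions:
                acc = 0.0
                for f in range(P.shape[0]):
                    num = sum(P[f, t] for t in range(P.shape[1])) / P.shape[1]
                    den = sum(ref[f, t] for t in range(ref.shape[1])) / ref.shape[1]
                    acc += num / den
                out.append(acc / P.shape[0] * 100.0 - 100.0)
            return np.array(out)

        np.testing.assert_allclose(beta_power_change(sessions), oracle(sessions),
                                   rtol=1e-10)

    def test_invariant_to_global_rescaling(self):
        rng = np.random.default_rng(11)
        sessions = [rng.random((6, 60)) + 0.1 for _ in range(3)]
        a = beta_power_change(sessions)
        b = beta_power_change([7.3 * s for s in sessions])
        np.testing.assert_allclose(a, b, rtol=1e-10)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            beta_power_change([np.zeros((6, 10)), np.ones((6, 10))])


class TestTrainingEffect:
    def test_all_equal_is_zero(self):
        x = np.ones(30)
        np.testing.assert_array_equal(training_effect(x, x, x, x), 0.0)

    def test_substitution(self):
        x = np.ones(30)
        out = training_effect(x, x, x + 2.0, x)
        np.testing.assert_allclose(out, 2.0)

    def test_mismatched_axes_rejected(self):
        with pytest.raises(ValueError):
            training_effect(np.ones(30), np.ones(30), np.ones(31), np.ones(31))

    def test_band_specific_effect_from_surrogate_epochs(self):
        """Planting 22 Hz bursts only in late-session pre-reward epochs
        yields a positive effect in the beta band, none at high gamma."""
        freqs = np.arange(5.0, 101.0, 5.0)

        def mean_power(with_burst, seed):
            rng_spec = SurrogateSpec(
                sampling_rate=FS, duration=1.0,
                bursts=(Burst(22.0, 0.5, 0.05, 2.0),) if with_burst else (),
                pink_amplitude=0.3, white_amplitude=0.1, seed=seed,
            )
            acc = []
            for k in range(8):
                stream, _ = synthesize(
                    SurrogateSpec(
                        sampling_rate=FS, duration=1.0, bursts=rng_spec.bursts,
                        pink_amplitude=0.3, white_amplitude=0.1,
                        seed=seed * 100 + k,
                    )
                )
                tfr = morlet_tfr(stream, freqs=freqs)
                acc.append(tfr.power[:, 400:600].mean(axis=1))
            return np.mean(acc, axis=0)

        p1_pre, p1_post = mean_power(False, 1), mean_power(False, 2)
        p9_pre, p9_post = mean_power(True, 3), mean_power(False, 4)
        eff = training_effect(p1_pre, p1_post, p9_pre, p9_post)
        beta = (freqs >= 20.0) & (freqs <= 25.0)
        gamma = freqs >= 40.0
        assert eff[beta].max() > 0.1
        assert np.abs(eff[gamma]).max() < 0.5 * eff[beta].max()
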