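"""Perturbation measures (jitter, shimmer, PSD), the spectral noise
measures, and the exact arithmetic of the printed breathiness-index
equation."""

import numpy as np
import pytest

from breathvoice.acoustic import (ABI_COEFFS, ABI_INTERCEPT, ABI_SCALE,
                                  AcousticMeasures, abi, gne_max, h1_h2,
                                  hf_noise, hnr_d, jitter_local,
                                  period_sequence, psd, shimmer_local)
from breathvoice.core import MonoSignal, SignalError

from conftest import sine


def pulse_train(f0, duration, fs):
    n = int(duration * fs)
    x = np.zeros(n)
    x[::int(round(fs / f0))] = 1.0
    return MonoSignal(x, fs)


class TestPeriodSequence:
    def test_pure_tone_periods_exact(self):
        periods, _ = period_sequence(sine(100.0, 2.0, 48000.0), 100.0)
        assert np.allclose(periods, 0.01, atol=1e-5)

    def test_jittered_construction_recovered(self):
        """Glottal-like pulse cycles built with 1% random period
        perturbation measure back at the constructed local jitter."""
        from scipy import signal as sps_
        fs = 48000.0
        rng = np.random.default_rng(0)
        periods_true = 0.005 * (1 + 0.01 * rng.standard_normal(300))
        edges = np.cumsum(periods_true)
        n = int(edges[-1] * fs) + 100
        pulses = np.zeros(n)
        idx = np.round(edges * fs).astype(int)
        pulses[idx[idx < n]] = 1.0
        t = np.arange(int(0.005 * fs)) / fs
        kernel = np.exp(-t / 0.002) * np.cos(2 * np.pi * 660 * t)
        sig = MonoSignal(np.convolve(pulses, kernel)[:n], fs)
        periods, _ = period_sequence(sig, 200.0)
        measured = jitter_local(periods)
        expected = jitter_local(periods_true)
        assert measured == pytest.approx(expected, abs=0.2)

    def test_too_few_cycles_rejected(self):
        with pytest.raises(SignalError):
            period_sequence(sine(100.0, 0.02, 48000.0), 100.0)


class TestPerturbation:
    def test_constant_periods_zero(self):
        p = np.full(100, 0.01)
        assert jitter_local(p) == 0.0
        assert psd(p) == pytest.approx(0.0, abs=1e-12)

    def test_alternating_periods_hand_value(self):
        """Alternating 10.0/10.2 ms: mean |dT| = 0.2 ms over mean 10.1 ms
        gives 1.98% by the local-jitter formula."""
        p = np.array([0.010, 0.0102] * 50)
        assert jitter_local(p) == pytest.approx(0.0002 / 0.0101 * 100, abs=1e-9)
        assert jitter_local(p) == pytest.approx(1.9802, abs=1e-3)

    def test_constant_amplitudes_zero_shimmer(self):
        pct, db = shimmer_local(np.full(50, 0.3))
        assert pct == 0.0 and db == 0.0

    def test_shimmer_db_hand_value(self):
        a = np.array([1.0, 2.0, 1.0, 2.0])
        _, db = shimmer_local(a)
        assert db == pytest.approx(20 * np.log10(2.0), abs=1e-9)


class TestSpectralMeasures:
    def test_hnr_matches_energy_ratio_oracle(self):
        """A tone plus -20 dB in-band noise measures 20 dB, matching the
        closed-form energy ratio (noise confined to the analysis band so
        the oracle is exact)."""
        from scipy import signal as sps
        fs = 16000.0
        tone = sine(220.0, 2.0, fs).samples
        rng = np.random.default_rng(1)
        sos = sps.butter(8, 4000.0, fs=fs, output="sos")
        noise = sps.sosfilt(sos, rng.standard_normal(tone.size))
        noise *= np.sqrt(np.mean(tone ** 2)) / 10 / np.sqrt(np.mean(noise ** 2))
        sig = MonoSignal(tone + noise, fs)
        assert hnr_d(sig, 220.0) == pytest.approx(20.0, abs=1.0)

    def test_equal_harmonics_give_zero_h1h2(self):
        fs = 16000.0
        t = np.arange(int(2 * fs)) / fs
        sig = MonoSignal(np.sin(2 * np.pi * 200 * t)
                         + np.sin(2 * np.pi * 400 * t), fs)
        assert h1_h2(sig, 200.0) == pytest.approx(0.0, abs=0.1)

    def test_gne_limits(self):
        fs = 16000.0
        train = pulse_train(220.0, 2.0, fs)
        noise = MonoSignal(np.random.default_rng(0).standard_normal(int(2 * fs)), fs)
        assert gne_max(train) > 0.7
        assert gne_max(noise) < 0.3

    def test_hf_noise_energy_split(self):
        fs = 16000.0
        lo = sine(1000.0, 2.0, fs).samples
        hi = sine(7000.0, 2.0, fs).samples
        sig = MonoSignal(lo + hi, fs)
        # equal-power split above/below the cutoff: ratio to total is -3 dB
        assert hf_noise(sig, cutoff=6000.0) == pytest.approx(-3.01, abs=0.2)


class TestAbiEquation:
    def test_all_zero_inputs_give_scaled_intercept(self):
        m = AcousticMeasures(**{k: 0.0 for k in ABI_COEFFS})
        assert abi(m) == pytest.approx(ABI_INTERCEPT * ABI_SCALE, abs=1e-9)
        assert abi(m) == pytest.approx(14.7597, abs=1e-4)

    def test_cpps_root_of_linear_form(self):
        root = ABI_INTERCEPT / 0.172
        m = AcousticMeasures(**{k: 0.0 for k in ABI_COEFFS})
        m.cpps = root
        assert abi(m) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("name", list(ABI_COEFFS))
    def test_finite_difference_equals_coefficient(self, name):
        """The index is affine: a unit bump in any input moves the output
        by exactly coefficient x scale."""
        base = AcousticMeasures(**{k: 1.0 for k in ABI_COEFFS})
        bumped = AcousticMeasures(**{k: 1.0 for k in ABI_COEFFS})
        setattr(bumped, name, 2.0)
        assert (abi(bumped) - abi(base)
                == pytest.approx(ABI_COEFFS[name] * ABI_SCALE, abs=1e-9))

    def test_missing_measure_named_in_error(self):
        m = AcousticMeasures(**{k: 0.0 for k in ABI_COEFFS})
        m.gne_max_4500 = float("nan")
        with pytest.raises(SignalError, match="gne_max_4500"):
            abi(m)

    def test_breathiness_grid_abi_trends_upward(self, make_voice):
        """Across the aspiration grid the full nine-measure index trends
        upward from the non-breathy baseline, matching the reported
        class-mean ordering.  At the extreme end the index saturates
        (cycle-parameter estimates degrade in the noise), so the check is
        on the trend, not strict per-step monotonicity."""
        from breathvoice.acoustic import measure_all
        from breathvoice.cepstral import cpps
        means = []
        for b in (0.0, 0.5, 1.0):
            vals = []
            for seed in (3, 13, 23, 33):
                v = make_voice(breathiness=b, seed=seed)
                c, _ = cpps(v)
                vals.append(abi(measure_all(v, c, 220.0)))
            means.append(np.mean(vals))
        assert means[1] > means[0] + 1.0
        assert means[2] > means[0] + 1.0


class TestGainInvariance:
    def test_dimensionless_measures_unchanged_by_gain(self, make_voice):
        from breathvoice.cepstral import cpps
        v = make_voice(breathiness=0.5, seed=6)
        loud = MonoSignal(8.0 * v.samples, v.sample_rate)
        p1, a1 = period_sequence(v, 220.0)
        p2, a2 = period_sequence(loud, 220.0)
        assert jitter_local(p1) == pytest.approx(jitter_local(p2), abs=1e-6)
        assert shimmer_local(a1)[0] == pytest.approx(shimmer_local(a2)[0], abs=1e-6)
        assert gne_max(v) == pytest.approx(gne_max(loud), abs=1e-6)
        assert h1_h2(v, 220.0) == pytest.approx(h1_h2(loud, 220.0), abs=1e-6)
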