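import numpy as np
import pytest

import fcqual as fq
from fcqual import pemo
from fcqual.pemo import (
    Audiogram,
    ChannelLoss,
    adaptation_stage,
    decompose_hearing_loss,
    design_filterbank,
    erb_number,
    hi_stage,
    modulation_stage,
    peripheral_and_envelope,
)

from conftest import tone

FS = fq.WORKING_RATE_HZ


class TestFilterbankDesign:
    def test_psm_bank_top_channel_below_upper_edge(self):
        fb = design_filterbank(FS, 235.0, 15300.0)
        assert fb.center_freqs_hz[-1] <= 15300.0
        assert fb.center_freqs_hz[0] == pytest.approx(235.0)

    def test_degenerate_edges_give_single_filter(self):
        fb = design_filterbank(FS, 1000.0, 1000.0)
        assert fb.n_channels == 1

    def test_channel_count_matches_erb_number_difference(self):
        fb = design_filterbank(FS, 235.0, 4000.0)
        expected = erb_number(4000.0) - erb_number(235.0)
        assert abs((fb.n_channels - 1) - expected) <= 1

    def test_edge_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            design_filterbank(FS, 235.0, 17000.0)


class TestPeripheralEnvelope:
    def test_silence_gives_zero_envelopes(self):
        fb = design_filterbank(FS, 235.0, 4000.0)
        sig = fq.AudioSignal(np.zeros(FS // 4), FS)
        env = peripheral_and_envelope(sig, fb)
        assert np.all(env == 0)
        assert env.shape == (FS // 4, fb.n_channels)

    def test_on_center_tone_dominates_distant_channels(self):
        fb = design_filterbank(FS, 235.0, 8000.0)
        fc = fb.center_freqs_hz[10]
        env = peripheral_and_envelope(tone(fc, 0.5), fb)
        steady = env[env.shape[0] // 2 :].mean(axis=0)
        near = steady[10]
        far = np.concatenate([steady[:8], steady[13:]])  # >= ~2 ERB away
        assert near / far.max() > 10

    def test_am_depth_preserved(self):
        fb = design_filterbank(FS, 900.0, 1100.0)
        c = int(np.argmin(np.abs(fb.center_freqs_hz - 1000.0)))
        n = 2 * FS
        t = np.arange(n) / FS
        m = 0.5
        x = 0.3 * (1 + m * np.sin(2 * np.pi * 4.0 * t)) * np.sin(2 * np.pi * 1000.0 * t)
        env = peripheral_and_envelope(fq.AudioSignal(x, FS), fb)[:, c]
        spec = np.abs(np.fft.rfft(env[FS // 2 :]))  # skip onset
        df = FS / (n - FS // 2)
        k4 = int(round(4.0 / df))
        depth = 2 * spec[k4] / spec[0]
        assert depth == pytest.approx(m, abs=0.1 * m)


class TestHearingLossDecomposition:
    def test_zero_audiogram_gives_zero_losses(self):
        fb = design_filterbank(FS, 235.0, 4000.0)
        losses = decompose_hearing_loss(Audiogram.flat(0.0), fb)
        assert all(l.ihcl_db == 0 and l.ohcl_db == 0 for l in losses)

    @pytest.mark.parametrize(
        "total, ohcl, ihcl", [(50.0, 40.0, 10.0), (80.0, 55.0, 25.0)]
    )
    def test_split_rule_with_cap(self, total, ohcl, ihcl):
        fb = design_filterbank(FS, 235.0, 4000.0)
        losses = decompose_hearing_loss(
            Audiogram.flat(total), fb, ohc_fraction=0.8, ohcl_cap_db=55.0
        )
        for l in losses:
            assert l.ohcl_db == pytest.approx(ohcl)
            assert l.ihcl_db == pytest.approx(ihcl)
            assert l.ihcl_db + l.ohcl_db == pytest.approx(l.total_hl_db)

    def test_interpolation_is_log_frequency_linear(self):
        fb = design_filterbank(FS, 1000.0, 1000.0)  # single channel at 1 kHz
        ag = Audiogram(np.array([500.0, 2000.0]), np.array([20.0, 60.0]))
        (loss,) = decompose_hearing_loss(ag, fb)
        assert loss.total_hl_db == pytest.approx(40.0)  # geometric midpoint

    def test_invalid_audiogram_rejected(self):
        with pytest.raises(ValueError):
            Audiogram(np.array([1000.0]), np.array([20.0]))
        with pytest.raises(ValueError):
            Audiogram(np.array([500.0, 250.0]), np.array([10.0, 10.0]))
        with pytest.raises(ValueError):
            Audiogram(np.array([500.0, 1000.0]), np.array([10.0, 150.0]))


class TestHIStage:
    def _loss(self, ihcl, ohcl):
        return ChannelLoss(1000.0, ihcl + ohcl, ihcl, ohcl)

    def test_zero_loss_identity_bitwise(self):
        env = np.abs(np.random.default_rng(0).standard_normal((100, 3)))
        out = hi_stage(env, [self._loss(0, 0)] * 3)
        np.testing.assert_array_equal(out, env)

    def test_pure_ihcl_is_linear_attenuation(self):
        env = np.abs(np.random.default_rng(1).standard_normal((50, 1)))
        out = hi_stage(env, [self._loss(20.0, 0.0)])
        np.testing.assert_allclose(out, env * 0.1, rtol=1e-12)

    def test_expansion_slope_decreases_toward_one(self):
        levels_in = np.linspace(20.0, 95.0, 16)
        amps = 10 ** ((levels_in - 100.0) / 20.0)
        out = hi_stage(amps[:, None], [self._loss(0.0, 40.0)])[:, 0]
        levels_out = 100.0 + 20 * np.log10(out)
        slopes = np.diff(levels_out) / np.diff(levels_in)
        assert np.all(slopes > 1.0)
        assert np.all(np.diff(slopes) < 1e-9)  # decreasing with level
        assert slopes[0] > 1.3 and slopes[-1] < 1.1

    def test_threshold_shift_equals_ohcl_at_zero_db(self):
        amp = 10 ** ((0.0 - 100.0) / 20.0)  # 0 dB SPL input
        out = hi_stage(np.array([[amp]]), [self._loss(0.0, 40.0)])[0, 0]
        assert 100.0 + 20 * np.log10(out) == pytest.approx(-40.0, abs=1e-9)

    def test_identity_at_and_above_convergence_level(self):
        amps = 10 ** ((np.array([100.0, 110.0]) - 100.0) / 20.0)
        out = hi_stage(amps[:, None], [self._loss(0.0, 55.0)])[:, 0]
        np.testing.assert_allclose(out, amps, rtol=1e-12)

    def test_output_monotone_nonincreasing_in_ihcl(self):
        env = np.abs(np.random.default_rng(2).standard_normal((50, 1)))
        outs = [hi_stage(env, [self._loss(i, 0.0)])[:, 0] for i in (0.0, 10.0, 30.0)]
        assert np.all(outs[1] <= outs[0]) and np.all(outs[2] <= outs[1])

    def test_increasing_ohcl_suppresses_soft_components(self):
        amps = 10 ** ((np.linspace(10, 90, 9) - 100.0) / 20.0)[:, None]
        o0 = hi_stage(amps, [self._loss(0.0, 0.0)])
        o40 = hi_stage(amps, [self._loss(0.0, 40.0)])
        o55 = hi_stage(amps, [self._loss(0.0, 55.0)])
        assert np.all(o40 <= o0) and np.all(o55 <= o40)

    def test_channel_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            hi_stage(np.zeros((10, 2)), [self._loss(0, 0)])


class TestAdaptation:
    FS_ENV = 4000.0

    def _steady(self, amp, dur_s=3.0):
        x = np.full((int(self.FS_ENV * dur_s), 1), amp)
        return adaptation_stage(x, self.FS_ENV)[-1, 0]

    def test_log_like_compression_of_stationary_levels(self):
        y0, y20, y40 = (self._steady(a) for a in (1e-4, 1e-3, 1e-2))
        ratio = (y20 - y0) / (y40 - y0)
        assert ratio == pytest.approx(0.5, abs=0.1)

    def test_zero_input_zero_steady_output(self):
        assert abs(self._steady(0.0)) < 1e-6

    def test_onset_overshoot(self):
        n = int(self.FS_ENV * 3)
        x = np.zeros((n, 1))
        x[n // 3 :] = 0.05
        out = adaptation_stage(x, self.FS_ENV)[:, 0]
        assert out[n // 3 :].max() / out[-1] > 2

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            adaptation_stage(np.array([[-0.1]]), self.FS_ENV)


class TestModulationStage:
    FS_ENV = 4000.0

    def _fb(self):
        return design_filterbank(FS, 1000.0, 1000.0)

    def test_dc_input_only_in_lowest_band(self):
        x = np.full((8000, 1), 5.0)
        ir = modulation_stage(x, self.FS_ENV, "fb", self._fb())
        steady = np.abs(ir.values[6000:, 0, :]).mean(axis=0)
        assert steady[0] > 100 * max(steady[1:].max(), 1e-12)

    def test_4hz_modulation_passes_lowpass_mode(self):
        n = 8000
        t = np.arange(n) / self.FS_ENV
        x = (5.0 + np.sin(2 * np.pi * 4.0 * t))[:, None]
        ir = modulation_stage(x, self.FS_ENV, "lp", self._fb())
        out_amp = np.abs(
            np.fft.rfft(ir.values[n // 2 :, 0])[int(round(4.0 / (self.FS_ENV / (n / 2))))]
        )
        in_amp = np.abs(
            np.fft.rfft(x[n // 2 :, 0])[int(round(4.0 / (self.FS_ENV / (n / 2))))]
        )
        assert 20 * np.log10(out_amp / in_amp) > -3.0

    def test_40hz_modulation_maximal_in_nearest_band(self):
        n = 16000
        t = np.arange(n) / self.FS_ENV
        x = (5.0 + np.sin(2 * np.pi * 40.0 * t))[:, None]
        ir = modulation_stage(x, self.FS_ENV, "fb", self._fb())
        rms = np.sqrt(np.mean(ir.values[n // 2 :, 0, 1:] ** 2, axis=0))
        centers = np.asarray(pemo.MODULATION_CENTERS_HZ)
        assert centers[int(np.argmax(rms))] == pytest.approx(46.3)

    def test_invalid_mode_rejected(self):
        with pytest.raises(ValueError):
            modulation_stage(np.zeros((10, 1)), self.FS_ENV, "xx", self._fb())


class TestFullFrontEnd:
    def test_zero_audiogram_reproduces_nh_bitwise(self, short_speechlike):
        fb = design_filterbank(FS, 235.0, 4000.0)
        ir_nh = fq.compute_internal_representation(short_speechlike, fb, None, "lp")
        ir_hi = fq.compute_internal_representation(
            short_speechlike, fb, Audiogram.flat(0.0), "lp"
        )
        np.testing.assert_array_equal(ir_nh.values, ir_hi.values)

    def test_deterministic(self, short_speechlike):
        fb = design_filterbank(FS, 235.0, 4000.0)
        a = fq.compute_internal_representation(short_speechlike, fb)
        b = fq.compute_internal_representation(short_speechlike, fb)
        np.testing.assert_array_equal(a.values, b.values)

    def test_band_occupancy_tracks_signal_spectrum(self):
        fb = design_filterbank(FS, 235.0, 8000.0)
        ir = fq.compute_internal_representation(tone(1000.0, 0.5).at_level(65.0), fb)
        activity = np.sqrt(np.mean(ir.values**2, axis=0))
        on = int(np.argmin(np.abs(fb.center_freqs_hz - 1000.0)))
        assert int(np.argmax(activity)) in (on - 1, on, on + 1)
        # adaptation compresses ~logarithmically, so off-band channels are
        # suppressed but not annihilated in model units
        far = np.abs(erb_number(fb.center_freqs_hz) - erb_number(1000.0)) > 5
        assert activity[on] > 3 * activity[far].max()
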