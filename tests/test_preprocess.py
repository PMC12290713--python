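import numpy as np
import pytest

import nirsync as ns
from nirsync import preprocess as pp
from nirsync.core_io import HOMER_EXTINCTION, ValidationError
from nirsync.synthetic_data import band_limited_noise

FS = 3.9063


def _recording_from_intensity(intensity, n_short=0):
    n_ch = intensity.shape[0] - n_short
    mon = ns.default_montage(n_ch, n_short)
    return ns.RawRecording(
        participant_id="P01", age=23.3,
        condition=ns.Condition("task", "Intact"),
        fs=FS, intensity=intensity, montage=mon,
    )


class TestOpticalDensity:
    def test_constant_intensity_gives_zero_od(self):
        I = np.full((2, 2, 50), 3.7)
        od = pp.intensity_to_od(_recording_from_intensity(I))
        np.testing.assert_allclose(od.od, 0.0, atol=1e-15)

    def test_half_mean_sample_gives_ln2(self):
        # choose the odd sample so that it equals exactly half the series mean
        n = 100
        b = (n - 1) / (2 * n - 1)
        x = np.ones(n)
        x[-1] = b
        assert b == pytest.approx(x.mean() / 2)
        I = np.tile(x, (1, 2, 1))
        od = pp.intensity_to_od(_recording_from_intensity(I))
        assert od.od[0, 0, -1] == pytest.approx(np.log(2.0), abs=1e-12)

    def test_forward_model_od_equals_beer_lambert_term(self, rng):
        # OD from forward-modelled intensities must equal eps*dc*DPF*rho
        # (up to the per-channel constant fixed by the mean reference)
        mon = ns.default_montage(1, 0)
        dpf = [pp.compute_dpf(23.3, wl) for wl in mon.wavelengths]
        E = HOMER_EXTINCTION.matrix(mon.wavelengths)
        dc = rng.normal(0, 1e-6, size=(2, 200))  # mol/L
        y = np.einsum("wj,jt->wt", E, dc) * np.array(dpf)[:, None] * 3.0
        I = np.exp(-y)[None]
        od = pp.intensity_to_od(_recording_from_intensity(I))
        got = od.od[0] - od.od[0].mean(axis=1, keepdims=True)
        want = y - y.mean(axis=1, keepdims=True)
        np.testing.assert_allclose(got, want, atol=1e-9)


class TestMotionCorrection:
    def _clean_od(self, rng, n=600):
        x = np.stack([band_limited_noise(n, FS, rng) for _ in range(4)])
        return pp.OpticalDensitySeries(od=x.reshape(2, 2, n) * 0.02, fs=FS)

    def test_clean_series_nearly_unchanged(self, rng):
        od = self._clean_od(rng)
        out = pp.correct_motion_hybrid(od)
        rms_in = np.sqrt(np.mean(od.od**2))
        rms_diff = np.sqrt(np.mean((out.od - od.od) ** 2))
        assert rms_diff <= 0.02 * rms_in

    def test_large_spike_suppressed(self, rng):
        od = self._clean_od(rng)
        spiked = od.od.copy()
        sd = spiked[0, 0].std()
        spiked[0, 0, 300] += 20 * sd
        out = pp.correct_motion_hybrid(
            pp.OpticalDensitySeries(od=spiked, fs=FS)
        )
        excursion_before = abs(spiked[0, 0, 300] - od.od[0, 0, 300])
        excursion_after = abs(out.od[0, 0, 300] - od.od[0, 0, 300])
        assert excursion_after <= 0.2 * excursion_before
        assert out.od.shape == od.od.shape

    def test_window_longer_than_series_is_error(self, rng):
        od = pp.OpticalDensitySeries(od=np.zeros((1, 2, 10)), fs=FS)
        with pytest.raises(ValueError):
            pp.correct_motion_hybrid(od, window_s=100.0)


class TestDPF:
    def test_cohort_mean_inside_printed_envelopes(self):
        # printed cohort means/sds at the five device wavelengths
        envelopes = {
            760: (6.060, 0.095), 785: (6.045, 0.073), 808: (5.849, 0.073),
            830: (5.521, 0.073), 850: (5.037, 0.091),
        }
        for wl, (mean, sd) in envelopes.items():
            dpf = pp.compute_dpf(23.3, wl)
            assert abs(dpf - mean) <= 3 * sd, wl

    def test_dpf_decreases_from_760_to_850(self):
        assert pp.compute_dpf(25.0, 850.0) < pp.compute_dpf(25.0, 760.0)

    def test_positive_over_age_wavelength_grid(self):
        for age in np.linspace(19, 31, 5):
            for wl in (760, 785, 808, 830, 850):
                assert pp.compute_dpf(age, wl) > 0

    @pytest.mark.parametrize("age,wl", [(0, 760), (150, 760), (25, 500), (25, 1100)])
    def test_out_of_range_inputs_rejected(self, age, wl):
        with pytest.raises(ValueError):
            pp.compute_dpf(age, wl)


class TestBeerLambertInversion:
    def test_zero_od_gives_zero_concentrations(self):
        mon = ns.default_montage(2, 0)
        od = pp.OpticalDensitySeries(od=np.zeros((2, 2, 30)), fs=FS)
        hb = pp.od_to_hemoglobin(od, mon, dpf_per_wavelength=[6.0, 5.0])
        np.testing.assert_allclose(hb.hbo, 0.0)
        np.testing.assert_allclose(hb.hbr, 0.0)

    def test_two_wavelength_hand_oracle(self, rng):
        # forward-compute OD from known concentrations with the 760/850
        # coefficients and invert with an explicit hand-built 2x2 solve
        mon = ns.default_montage(1, 0)  # wavelengths 760, 850; rho = 3 cm
        dpf = [6.06, 5.04]
        E = np.array([[645.0, 1669.0], [1097.0, 781.0]])
        dc_true = rng.normal(0, 1e-6, size=(2, 100))
        od_arr = (E @ dc_true) * np.array(dpf)[:, None] * 3.0
        hb = pp.od_to_hemoglobin(
            pp.OpticalDensitySeries(od=od_arr[None], fs=FS), mon,
            dpf_per_wavelength=dpf,
        )
        # independent oracle: solve the 2x2 system sample by sample
        oracle = np.linalg.solve(E, od_arr / (np.array(dpf)[:, None] * 3.0))
        np.testing.assert_allclose(hb.hbo[0], oracle[0] * 1e6, rtol=1e-9)
        np.testing.assert_allclose(hb.hbr[0], oracle[1] * 1e6, rtol=1e-9)
        np.testing.assert_allclose(hb.hbo[0], dc_true[0] * 1e6, rtol=1e-9)

    def test_four_wavelength_consistent_system_recovers(self, rng):
        mon = ns.default_montage(1, 0, wavelengths=(785.0, 808.0, 830.0, 850.0))
        dpf = [pp.compute_dpf(23.3, wl) for wl in mon.wavelengths]
        E = HOMER_EXTINCTION.matrix(mon.wavelengths)
        dc_true = rng.normal(0, 1e-6, size=(2, 80))
        od_arr = (E @ dc_true) * np.array(dpf)[:, None] * 3.0
        hb = pp.od_to_hemoglobin(
            pp.OpticalDensitySeries(od=od_arr[None], fs=FS), mon,
            dpf_per_wavelength=dpf,
        )
        np.testing.assert_allclose(hb.hbo[0], dc_true[0] * 1e6, rtol=1e-8)
        np.testing.assert_allclose(hb.hbr[0], dc_true[1] * 1e6, rtol=1e-8)

    def test_ill_conditioned_extinction_rejected(self):
        bad = ns.ExtinctionTable({760.0: (1000.0, 500.0), 850.0: (1000.0001, 500.00005)})
        mon = ns.default_montage(1, 0)
        od = pp.OpticalDensitySeries(od=np.ones((1, 2, 10)), fs=FS)
        with pytest.raises(np.linalg.LinAlgError, match="760"):
            pp.od_to_hemoglobin(od, mon, extinction=bad, dpf_per_wavelength=[6, 5])


class TestBandpass:
    def _tone(self, freq, n=4000):
        t = np.arange(n) / FS
        return np.sin(2 * np.pi * freq * t)

    def test_passband_tone_preserved(self):
        hb = ns.HemoglobinSeries(
            hbo=self._tone(0.05)[None], hbr=self._tone(0.05)[None],
            fs=FS, channel_ids=["c"],
        )
        out = ns.bandpass_filter(hb)
        mid = slice(1000, 3000)
        ratio = out.hbo[0, mid].std() / hb.hbo[0, mid].std()
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_stopband_attenuation_of_designed_response(self):
        # evaluate the designed zero-phase response directly: |H|^2 at 1 Hz
        from scipy import signal as sps

        sos = sps.butter(3, [0.005, 0.20], btype="bandpass", fs=FS, output="sos")
        _, h = sps.sosfreqz(sos, worN=[1.0], fs=FS)
        assert np.abs(h[0]) ** 2 <= 0.05  # forward-backward gain

    def test_constant_offset_removed(self):
        hb = ns.HemoglobinSeries(
            hbo=np.full((1, 500), 4.2), hbr=np.full((1, 500), -1.0),
            fs=FS, channel_ids=["c"],
        )
        out = ns.bandpass_filter(hb)
        assert abs(out.hbo.mean()) < 1e-8

    def test_band_outside_nyquist_rejected(self):
        hb = ns.HemoglobinSeries(
            hbo=np.zeros((1, 100)), hbr=np.zeros((1, 100)), fs=FS, channel_ids=["c"]
        )
        with pytest.raises(ValueError):
            ns.bandpass_filter(hb, low=0.01, high=2.5)


class TestShortChannelQuality:
    def _recording(self, short_signal, rng, n=1867):
        t = np.arange(n) / FS
        long_sig = 1.0 + 0.01 * band_limited_noise(n, FS, rng)
        I = np.empty((3, 2, n))
        I[:2] = long_sig  # two long channels
        I[2] = 1.0 + short_signal
        mon = ns.default_montage(2, 1)
        return ns.RawRecording("P", 23.0, ns.Condition("t", "Intact"), FS, I, mon)

    def test_cardiac_component_flags_good(self, rng):
        t = np.arange(1867) / FS
        cardiac = 0.02 * np.sin(2 * np.pi * 1.1 * t)
        rec = self._recording(cardiac + 0.001 * rng.standard_normal(1867), rng)
        q = ns.assess_short_channel_quality(rec)
        assert q == {"SS01-DS01": True}

    def test_white_noise_only_flags_bad(self, rng):
        rec = self._recording(0.01 * rng.standard_normal(1867), rng)
        q = ns.assess_short_channel_quality(rec)
        assert q == {"SS01-DS01": False}

    def test_no_short_channels_is_error(self, rng):
        mon = ns.default_montage(2, 0)
        rec = ns.RawRecording(
            "P", 23.0, ns.Condition("t", "Intact"), FS,
            np.ones((2, 2, 100)), mon,
        )
        with pytest.raises(ValidationError):
            ns.assess_short_channel_quality(rec)

    def test_all_bad_short_channels_excludes_participant(self, rng):
        rec = self._recording(0.01 * rng.standard_normal(1867), rng)
        with pytest.raises(pp.ParticipantExcluded):
            ns.run_preprocessing(rec)


class TestShortChannelRegression:
    def test_linear_combination_leaves_residual(self, rng):
        n = 500
        shorts = rng.standard_normal((2, n))
        resid = rng.standard_normal(n)
        # orthogonalize residual against shorts and the intercept
        X = np.column_stack([np.ones(n), shorts[0], shorts[1], -0.6 * shorts[0],
                             -0.6 * shorts[1]])
        resid -= X @ np.linalg.lstsq(X, resid, rcond=None)[0]
        y = 2.0 * shorts[0] - 1.5 * shorts[1] + resid
        hb_long = ns.HemoglobinSeries(y[None], (0.5 * y)[None], FS, ["L"])
        hb_short = ns.HemoglobinSeries(shorts, -0.6 * shorts, FS, ["s1", "s2"])
        out = ns.short_channel_regression(hb_long, hb_short)
        np.testing.assert_allclose(out.hbo[0], resid, atol=1e-8)

    def test_matches_ols_oracle(self, rng):
        import statsmodels.api as sm

        n = 300
        shorts = rng.standard_normal((2, n))
        y = rng.standard_normal(n)
        hb_long = ns.HemoglobinSeries(y[None], y[None], FS, ["L"])
        hb_short = ns.HemoglobinSeries(shorts, 0.5 * shorts, FS, ["s1", "s2"])
        out = ns.short_channel_regression(hb_long, hb_short)
        # oracle: OLS on the raw short series spans the same column space
        X = sm.add_constant(np.vstack([shorts, 0.5 * shorts]).T)
        oracle = sm.OLS(y, X).fit().resid
        np.testing.assert_allclose(out.hbo[0], oracle, atol=1e-8)

    def test_uncorrelated_shorts_leave_long_untouched(self, rng):
        n = 2000
        y = rng.standard_normal(n)
        shorts = rng.standard_normal((2, n))
        out = ns.short_channel_regression(
            ns.HemoglobinSeries(y[None], y[None], FS, ["L"]),
            ns.HemoglobinSeries(shorts, shorts * 0.5, FS, ["s1", "s2"]),
        )
        assert out.hbo.shape == (1, n)
        assert np.corrcoef(out.hbo[0], y)[0, 1] > 0.995

    def test_projection_never_increases_variance(self, rng):
        for _ in range(5):
            y = rng.standard_normal((3, 200))
            shorts = rng.standard_normal((2, 200))
            out = ns.short_channel_regression(
                ns.HemoglobinSeries(y, y, FS, ["a", "b", "c"]),
                ns.HemoglobinSeries(shorts, shorts, FS, ["s1", "s2"]),
            )
            assert np.all(out.hbo.var(axis=1) <= y.var(axis=1) + 1e-12)

    def test_zero_variance_shorts_rejected(self):
        with pytest.raises(np.linalg.LinAlgError):
            ns.short_channel_regression(
                ns.HemoglobinSeries(np.ones((1, 50)), np.ones((1, 50)), FS, ["L"]),
                ns.HemoglobinSeries(np.ones((1, 50)), np.ones((1, 50)), FS, ["s"]),
            )


class TestFullChain:
    def test_standardization_idempotent(self, rng):
        hb = ns.HemoglobinSeries(
            rng.standard_normal((3, 100)), rng.standard_normal((3, 100)),
            FS, ["a", "b", "c"],
        )
        once = ns.standardize(hb)
        twice = ns.standardize(once)
        np.testing.assert_allclose(once.hbo, twice.hbo, atol=1e-12)
        assert abs(once.hbo.mean(axis=1)).max() < 1e-10

    def test_noiseless_recording_recovers_ground_truth(self):
        params = ns.CohortParams(
            n_participants=2, n_long_channels=4, n_short_channels=0,
            duration_s=150, stimuli=("task",),
            signal_channels_intact=("S001-D001", "S002-D002"),
            signal_channels_scrambled=(),
            noise_sd=0.0, scalp_sd=0.0, cardiac_amp=0.0, measurement_noise=0.0,
        )
        cohort = ns.generate_cohort(params, seed=5)
        rec = cohort.recordings[0]
        hb = ns.run_preprocessing(rec)
        truth = cohort.truth.hb_noiseless[(rec.participant_id, rec.condition.label)]
        for i in range(2):  # signal channels only; others are identically zero
            r = np.corrcoef(hb.hbo[i], truth.hbo[i])[0, 1]
            assert r > 0.99

    def test_deterministic_and_standardized(self, small_cohort):
        rec = small_cohort.recordings[0]
        a = ns.run_preprocessing(rec)
        b = ns.run_preprocessing(rec)
        np.testing.assert_array_equal(a.hbo, b.hbo)
        assert a.standardized
        assert abs(a.hbo.mean(axis=1)).max() < 1e-8
        assert a.n_channels == len(rec.montage.long_channels)
        assert any("short_channel_regression" in s for s in a.provenance)
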