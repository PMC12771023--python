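"""Substitution-method estimator checks: spectra, reflection, impedance,
attenuation, and aggregation, against the generator's ground truth and
closed-form oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sonowindow as sw
from sonowindow import material as mat

REF = mat.ReferenceReflector()


def characterize(truth: sw.PlateMaterial, seed=1, **gen_kw):
    """Full estimator round trip on generated plate data."""
    kw = dict(n_locations=1, n_repetitions=1, location_jitter=0.0,
              noise_sigma=0.0, seed=seed)
    kw.update(gen_kw)
    sample, reference, info = sw.gen_plate_pulse_echo(truth, **kw)
    s_ff = mat.compute_spectrum(sample, info["t_front"], face="front")
    s_bf = mat.compute_spectrum(sample, info["t_back"], face="back")
    s_0 = mat.compute_spectrum(reference, info["t_ref"], face="reference")
    medium = mat.MediumConstants(sample_thickness_d=truth.thickness_cm)
    gammas = mat.estimate_reflection_coefficient(s_ff, s_0, REF)
    slopes, intercepts, _ = mat.estimate_attenuation(
        s_ff, s_bf, gammas, medium, REF,
        gamma_back=None if truth.gamma_back is None else truth.gamma_back,
    )
    return gammas, slopes, intercepts, (s_ff, s_bf, s_0)


class TestComputeSpectrum:
    def test_pure_tone_peaks_at_nearest_bin(self):
        fs = 250e6
        t = np.arange(1000) / fs
        wave = np.sin(2 * np.pi * 30e6 * t)[None, None, :]
        ds = mat.PulseEchoDataset(wave, fs)
        spec = mat.compute_spectrum(ds, 2.0e-6, window_duration=1.0e-6)
        peak_f = spec.frequencies[np.argmax(spec.magnitude[0])]
        df = spec.frequencies[1] - spec.frequencies[0]
        assert abs(peak_f - 30e6) <= df

    def test_identical_inputs_give_identical_spectra(self):
        truth = sw.PlateMaterial(gamma_front=0.37)
        sample, ref, info = sw.gen_plate_pulse_echo(
            truth, n_locations=2, n_repetitions=3, location_jitter=0.0,
            noise_sigma=0.0, seed=0)
        s1 = mat.compute_spectrum(sample, info["t_front"])
        s2 = mat.compute_spectrum(sample, info["t_front"])
        np.testing.assert_array_equal(s1.magnitude, s2.magnitude)

    def test_plate_echo_peak_matches_direct_dft_oracle(self):
        """Spectral peak equals the DFT of the analytic pulse expression."""
        truth = sw.PlateMaterial(gamma_front=0.25)
        sample, _, info = sw.gen_plate_pulse_echo(
            truth, n_locations=1, n_repetitions=1, location_jitter=0.0,
            noise_sigma=0.0, seed=1)
        spec = mat.compute_spectrum(sample, info["t_front"])
        # oracle: evaluate the generator's pulse model on the gate grid directly
        pulse = sw.PulseModel(center_frequency_mhz=30.0, fractional_bandwidth=0.8)
        fs = sample.sample_rate
        half = 0.115e-6 / 2
        i0 = int(round((info["t_front"] - half) * fs))
        i1 = int(round((info["t_front"] + half) * fs))
        tt = np.arange(i0, i1) / fs - info["t_front"]
        oracle_mag = np.abs(np.fft.rfft(pulse(tt), n=4096))
        freqs = np.fft.rfftfreq(4096, 1 / fs)
        df = freqs[1] - freqs[0]
        assert abs(
            spec.frequencies[np.argmax(spec.magnitude[0])]
            - freqs[np.argmax(oracle_mag)]
        ) <= df

    def test_window_outside_waveform_raises(self):
        ds = mat.PulseEchoDataset(np.zeros((1, 1, 100)), 250e6)
        with pytest.raises(ValueError):
            mat.compute_spectrum(ds, 10.0e-6)

    def test_all_zero_window_flagged(self):
        ds = mat.PulseEchoDataset(np.zeros((1, 1, 500)), 250e6)
        with pytest.warns(UserWarning, match="degenerate"):
            spec = mat.compute_spectrum(ds, 1.0e-6)
        assert spec.degenerate


class TestReflectionCoefficient:
    def test_identical_spectra_return_gamma0(self):
        f = np.linspace(0, 50e6, 100)
        mag = np.ones((1, 100))
        s = mat.SpectrumSet(f, mag, 0.115e-6, "front")
        r = mat.SpectrumSet(f, mag.copy(), 0.115e-6, "reference")
        assert mat.estimate_reflection_coefficient(s, r, REF)[0] == pytest.approx(0.37)

    @pytest.mark.parametrize("gamma,tol", [(0.25, 0.005), (0.797, 0.01)])
    def test_recovers_configured_gamma(self, gamma, tol):
        gammas, _, _, _ = characterize(sw.PlateMaterial(gamma_front=gamma))
        assert gammas[0] == pytest.approx(gamma, abs=tol)

    def test_zero_reference_raises(self):
        f = np.linspace(0, 50e6, 100)
        s = mat.SpectrumSet(f, np.ones((1, 100)), 0.115e-6, "front")
        r = mat.SpectrumSet(f, np.zeros((1, 100)), 0.115e-6, "reference")
        with pytest.raises(ZeroDivisionError):
            mat.estimate_reflection_coefficient(s, r, REF)


class TestImpedance:
    @pytest.mark.parametrize(
        "gamma,expected", [(0.797, 13.09), (0.2408, 2.417)]
    )
    def test_printed_worked_examples(self, gamma, expected):
        z = mat.estimate_impedance(gamma, mat.MediumConstants())
        assert z == pytest.approx(expected, rel=0.005)

    def test_matched_medium(self):
        med = mat.MediumConstants()
        assert mat.estimate_impedance(0.0, med) == med.z_w

    def test_domain_error(self):
        with pytest.raises(ValueError):
            mat.estimate_impedance(1.0, mat.MediumConstants())

    @settings(deadline=None, derandomize=True)
    @given(st.floats(min_value=0.0, max_value=0.999))
    def test_inverse_identity_and_monotonicity(self, gamma):
        med = mat.MediumConstants()
        z = mat.estimate_impedance(gamma, med)
        assert mat.impedance_to_reflection(z, med) == pytest.approx(gamma, abs=1e-12)
        if gamma < 0.99:
            assert mat.estimate_impedance(gamma + 0.005, med) > z


class TestAttenuation:
    def test_lossless_sample_gives_zero(self):
        f = np.linspace(0, 125e6, 2048)
        gamma = 0.3
        s_ff = mat.SpectrumSet(f, np.full((1, f.size), 2.0), 0.115e-6, "front")
        s_bf = mat.SpectrumSet(f, np.full((1, f.size), 2.0 * (1 - gamma**2)),
                               0.115e-6, "back")
        slopes, intercepts, _ = mat.estimate_attenuation(
            s_ff, s_bf, gamma, mat.MediumConstants(), REF)
        assert slopes[0] == pytest.approx(0.0, abs=1e-9)
        assert intercepts[0] == pytest.approx(0.0, abs=1e-9)

    def test_recovers_coc_truth_within_2pct(self):
        truth = sw.PlateMaterial(gamma_front=0.2408, alpha_slope=2.92,
                                 alpha_30=98.3, thickness_cm=0.024)
        _, slopes, intercepts, _ = characterize(truth)
        assert slopes[0] == pytest.approx(2.92, rel=0.02)
        assert intercepts[0] == pytest.approx(98.3, rel=0.02)

    def test_asymmetric_faces_need_two_face_variant(self):
        """Different front/back reflectivity: the two-face correction recovers
        the configured attenuation; the symmetric variant is biased."""
        truth = sw.PlateMaterial(gamma_front=0.0822, gamma_back=0.0664,
                                 alpha_slope=3.6, alpha_30=84.0,
                                 thickness_cm=0.025)
        gammas, slopes4, a30_4, (s_ff, s_bf, _) = characterize(truth)
        assert slopes4[0] == pytest.approx(3.6, rel=0.02)
        assert a30_4[0] == pytest.approx(84.0, rel=0.02)
        medium = mat.MediumConstants(sample_thickness_d=truth.thickness_cm)
        _, a30_3, _ = mat.estimate_attenuation(s_ff, s_bf, gammas, medium, REF)
        assert abs(a30_3[0] - 84.0) / 84.0 > 0.02   # symmetric form is biased


class TestAggregate:
    def test_identical_estimates(self):
        p = mat.aggregate_material({"gamma_s": [0.3] * 5, "z_s": [2.0] * 5})
        assert p.gamma_s == 0.3 and p.standard_errors["gamma_s"] == 0.0

    def test_closed_form_se(self):
        p = mat.aggregate_material({"gamma_s": [0.1] * 5,
                                    "alpha_30": [1, 2, 3, 4, 5]})
        assert p.alpha_30 == pytest.approx(3.0)
        assert p.standard_errors["alpha_30"] == pytest.approx(0.7071, abs=1e-4)

    def test_single_location_flagged(self):
        with pytest.warns(UserWarning, match="standard error undefined"):
            p = mat.aggregate_material({"gamma_s": [0.3]})
        assert np.isnan(p.standard_errors["gamma_s"])

    def test_location_jitter_propagates_to_se(self):
        """SE of the per-location reflection estimates tracks sigma/sqrt(5)."""
        truth = sw.PlateMaterial(gamma_front=0.37)
        rel_ses = []
        for seed in (7, 8, 9, 10):
            gammas, _, _, _ = characterize(
                truth, seed=seed, n_locations=5, location_jitter=0.01)
            p = mat.aggregate_material({"gamma_s": gammas})
            rel_ses.append(p.standard_errors["gamma_s"] / p.gamma_s)
        expected = 0.01 / np.sqrt(5)
        assert expected / 3 < np.mean(rel_ses) < expected * 3


def test_averaging_contract_under_noise():
    """SNR 40 dB with 500 repetitions: reflection estimates stable to <1 %."""
    truth = sw.PlateMaterial(gamma_front=0.2408)
    vals = []
    for seed in (0, 1, 2):
        gammas, _, _, _ = characterize(
            truth, seed=seed, n_locations=2, n_repetitions=500,
            noise_sigma=0.01)
        vals.append(gammas.mean())
    assert (max(vals) - min(vals)) / np.mean(vals) < 0.01


def test_find_echo_centers_locates_both_faces():
    truth = sw.PlateMaterial(gamma_front=0.3, thickness_cm=0.03)
    sample, _, info = sw.gen_plate_pulse_echo(
        truth, n_locations=1, n_repetitions=1, noise_sigma=0.0,
        location_jitter=0.0, seed=0)
    t1, t2 = mat.find_echo_centers(sample, n_echoes=2)
    assert t1 == pytest.approx(info["t_front"], abs=2e-8)
    assert t2 == pytest.approx(info["t_back"], abs=2e-8)
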