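"""Aperture arithmetic, analytic-signal handling, IRM->FRM synthesis,
noise floors, and delay-and-sum geometry."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.signal import gausspulse

import sonowindow as sw
from sonowindow import beamforming as bf

GEOM128 = sw.ArrayGeometry()


class TestTxAperture:
    def test_interior_aperture_matches_rayline_numbering(self):
        ap = bf.make_tx_aperture(10, 6.0, 8.0, GEOM128)
        assert list(ap.elements) == list(range(4, 17))

    def test_edge_aperture_is_truncated(self):
        ap = bf.make_tx_aperture(3, 6.0, 8.0, GEOM128)
        assert list(ap.elements) == list(range(1, 10))

    def test_infinite_fnum_has_zero_relative_delays(self):
        ap = bf.make_tx_aperture(64, np.inf, 8.0, GEOM128)
        np.testing.assert_allclose(ap.delays, 0.0)

    @settings(deadline=None, derandomize=True)
    @given(st.integers(min_value=7, max_value=122))
    def test_interior_apertures_odd_and_symmetric(self, center):
        ap = bf.make_tx_aperture(center, 6.0, 8.0, GEOM128)
        assert ap.elements.size == 13 and ap.elements.size % 2 == 1
        assert ap.elements[6] == center
        # focusing delays symmetric about the center, zero at the edges
        np.testing.assert_allclose(ap.delays, ap.delays[::-1], atol=1e-15)
        assert ap.delays.min() == 0.0

    def test_sample_count_arithmetic(self):
        assert bf.n_samples_for_duration(62.5e6, 28.656e-6) == 1792


class TestAnalytic:
    def test_tone_envelope_is_flat(self):
        geom = sw.ArrayGeometry(n_elements=2, n_samples=512)
        t = geom.times_s
        data = np.broadcast_to(np.cos(2 * np.pi * 20e6 * t), (2, 2, 512)).copy()
        em = bf.to_analytic(sw.EchoMatrix(data, "IRM", geom))
        env = np.abs(em.data[0, 0, 50:-50])
        np.testing.assert_allclose(env, 1.0, atol=0.02)

    def test_zero_trace_stays_zero(self):
        geom = sw.ArrayGeometry(n_elements=2, n_samples=64)
        em = bf.to_analytic(sw.EchoMatrix(np.zeros((2, 2, 64)), "IRM", geom))
        assert np.all(em.data == 0)

    def test_pulse_envelope_peaks_at_center(self):
        geom = sw.ArrayGeometry(n_elements=2, n_samples=512)
        t = geom.times_s - 256 / geom.sample_rate_hz
        data = np.broadcast_to(gausspulse(t, fc=18e6, bw=0.6), (2, 2, 512)).copy()
        em = bf.to_analytic(sw.EchoMatrix(data, "IRM", geom))
        assert abs(int(np.argmax(np.abs(em.data[0, 0]))) - 256) <= 1

    def test_double_hilbert_rejected(self):
        geom = sw.ArrayGeometry(n_elements=2, n_samples=64)
        em = bf.to_analytic(sw.EchoMatrix(np.zeros((2, 2, 64)), "IRM", geom))
        with pytest.raises(TypeError):
            bf.to_analytic(em)


class TestIrmToFrm:
    GEOM = sw.ArrayGeometry(n_elements=32, n_samples=448)

    def _irm(self, scale=1.0, seed=0):
        scene = sw.ScatteringScene(plate=None,
                                   point_scatterers=[(0.0, 2.0, 5.0 * scale)],
                                   noise_sigma=0.0, seed=seed)
        return sw.to_analytic(sw.gen_irm(scene, self.GEOM))

    def test_zero_irm_gives_zero_frm(self):
        em = sw.EchoMatrix(np.zeros((32, 32, 448), dtype=complex), "IRM", self.GEOM)
        frm = bf.irm_to_frm(em, 6.0, 2.0)
        assert np.allclose(frm.data, 0) and frm.kind == "FRM_synthetic"

    def test_linear_in_amplitude(self):
        f1 = bf.irm_to_frm(self._irm(1.0), 6.0, 2.0)
        f2 = bf.irm_to_frm(self._irm(2.0), 6.0, 2.0)
        np.testing.assert_allclose(f2.data, 2.0 * f1.data, atol=1e-9)

    def test_point_scatterer_matches_physical_frm(self):
        """Two independent forward routes (continuous-delay physical focusing
        vs discrete shift-and-sum of single-element records) agree."""
        scene = sw.ScatteringScene(plate=None, point_scatterers=[(0.0, 2.0, 5.0)],
                                   noise_sigma=0.0, seed=0)
        frm_s = bf.irm_to_frm(sw.to_analytic(sw.gen_irm(scene, self.GEOM)), 6.0, 2.0)
        frm_p = sw.to_analytic(sw.gen_frm_physical(scene, self.GEOM, 6.0, 2.0))
        central = slice(8, 24)
        ep, es = np.abs(frm_p.data[central]), np.abs(frm_s.data[central])
        nrms = np.sqrt(np.mean((ep - es) ** 2) / np.mean(ep**2))
        assert nrms < 0.05

    def test_rejects_non_irm(self):
        em = sw.EchoMatrix(np.zeros((32, 32, 448), dtype=complex),
                           "FRM_physical", self.GEOM)
        with pytest.raises(TypeError):
            bf.irm_to_frm(em)


class TestNoiseFloor:
    def test_zero_matrix_floor_is_zero(self):
        geom = sw.ArrayGeometry(n_elements=32, n_samples=448)
        em = sw.EchoMatrix(np.zeros((32, 32, 448), dtype=complex), "FRM_physical", geom)
        assert bf.estimate_noise_floor_frm(em, (1, 3), (8, 24)) == 0.0

    def test_constant_envelope_nine_gives_twenty_db(self):
        geom = sw.ArrayGeometry(n_elements=32, n_samples=448)
        data = np.full((32, 32, 448), 9.0 + 0j)
        em = sw.EchoMatrix(data, "FRM_physical", geom)
        assert bf.estimate_noise_floor_frm(em, (1, 3), (8, 24)) == pytest.approx(20.0)

    def test_gaussian_noise_floor_matches_envelope_expectation(self):
        """Floor within 1 dB of a direct Monte-Carlo expectation of the
        analytic-noise envelope level."""
        geom = sw.ArrayGeometry(n_elements=32, n_samples=448)
        rng = np.random.default_rng(3)
        em = bf.to_analytic(sw.EchoMatrix(
            rng.normal(0, 0.1, (32, 32, 448)), "FRM_physical", geom))
        floor = bf.estimate_noise_floor_frm(em, (1, 3), (8, 24))
        # oracle: envelope of analytic white noise is Rayleigh(sigma)
        r = np.random.default_rng(99).rayleigh(0.1, 200_000)
        expected = np.mean(20 * np.log10(r + 1))
        assert floor == pytest.approx(expected, abs=1.0)

    def test_empty_depth_range_raises(self):
        geom = sw.ArrayGeometry(n_elements=32, n_samples=448)
        em = sw.EchoMatrix(np.zeros((32, 32, 448), dtype=complex), "FRM_physical", geom)
        with pytest.raises(ValueError):
            bf.estimate_noise_floor_frm(em, (50, 60), (8, 24))


class TestDasReceive:
    def test_zero_frm_is_uniform_zero_db(self):
        geom = sw.ArrayGeometry(n_elements=32, n_samples=448)
        em = sw.EchoMatrix(np.zeros((32, 32, 448), dtype=complex), "FRM_physical", geom)
        bm = bf.das_receive(em, 2.0)
        assert np.allclose(bm.db_values, 0.0) and bm.noise_floor_db == 0.0

    def test_point_target_peak_at_true_position(self, point_frm):
        bm = bf.das_receive(point_frm, 2.0, floor_depth_range_mm=(1.0, 2.0))
        iz, il = np.unravel_index(np.argmax(bm.db_values), bm.db_values.shape)
        dz = point_frm.geometry.c_mps / 2 / point_frm.geometry.sample_rate_hz * 1e3
        assert abs(bm.axial_mm[iz] - 4.0) <= dz + 1e-9
        assert abs(bm.lateral_mm[il] - 0.0) <= point_frm.geometry.pitch_mm + 1e-9

    def test_lateral_width_non_increasing_with_smaller_fnum(self, point_frm):
        widths = []
        for fn in (6.0, 4.0, 3.0, 2.0, 1.0):
            bm = bf.das_receive(point_frm, fn, floor_depth_range_mm=(1.0, 2.0))
            env = bf.envelope_from_db(bm.db_values)
            iz = int(np.argmax(env.max(axis=1)))
            prof = env[iz]
            above = np.nonzero(prof > prof.max() * 10 ** (-6 / 20))[0]
            widths.append((above[-1] - above[0]) * point_frm.geometry.pitch_mm)
        assert all(w2 <= w1 + 1e-12 for w1, w2 in zip(widths, widths[1:]))

    def test_delay_perturbation_reduces_coherent_peak(self, point_frm):
        """The coherently summed peak is maximal at the geometric delays;
        shifting every receive delay by one sample strictly reduces it."""
        geom = point_frm.geometry
        i = 32
        x = geom.element_x_mm
        x0 = x[i]
        ap = bf.make_tx_aperture(i + 1, 6.0, 4.0, geom)
        z = 4.0
        sel = np.abs(x - x0) <= z / 4.0
        t_rt = ap.center_delay + (z + np.sqrt(z**2 + (x[sel] - x0) ** 2)) * 1e-3 / geom.c_mps

        def coherent(extra_samples):
            s = t_rt * geom.sample_rate_hz + extra_samples
            i0 = np.floor(s).astype(int)
            fr = s - i0
            tr = point_frm.data[i][sel]
            vals = (1 - fr) * tr[np.arange(sel.sum()), i0] + fr * tr[np.arange(sel.sum()), i0 + 1]
            return abs(vals.sum())

        assert coherent(0) > coherent(1)

    def test_window_echo_maps_to_true_depth(self, eq_bundle):
        """d = t c / 2 places the window front face at its scene depth."""
        bm = eq_bundle["bm_p"]
        line = bm.db_values[:, 32]
        band = (bm.axial_mm > 3.0) & (bm.axial_mm < 5.0)
        iz = np.nonzero(band)[0][np.argmax(line[band])]
        geom = eq_bundle["frm_p"].geometry
        dz = geom.c_mps / 2 / geom.sample_rate_hz * 1e3
        assert abs(bm.axial_mm[iz] - 4.0) <= dz + 1e-9

    def test_requires_focused_kind(self):
        geom = sw.ArrayGeometry(n_elements=32, n_samples=448)
        em = sw.EchoMatrix(np.zeros((32, 32, 448), dtype=complex), "IRM", geom)
        with pytest.raises(TypeError):
            bf.das_receive(em, 2.0)


class TestOptimalFnum:
    @pytest.mark.parametrize(
        "alpha,expected,tol",
        [(0.34, 1.41, 0.005), (np.pi / 4, 0.5, 1e-12), (0.1, 4.9833, 1e-4)],
    )
    def test_values(self, alpha, expected, tol):
        assert bf.optimal_receive_fnum(alpha) == pytest.approx(expected, abs=tol)

    def test_domain(self):
        with pytest.raises(ValueError):
            bf.optimal_receive_fnum(0.0)


def test_synthetic_physical_equivalency(eq_bundle):
    """Envelope B-modes from physically and synthetically focused data of the
    same noiseless scene agree to a few percent (normalized RMS) over the
    central transmissions."""
    central = eq_bundle["central"]
    ep = bf.envelope_from_db(eq_bundle["bm_p"].db_values[:, central])
    es = bf.envelope_from_db(eq_bundle["bm_s"].db_values[:, central])
    nrms = np.sqrt(np.mean((ep - es) ** 2) / np.mean(ep**2))
    assert nrms < 0.05
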