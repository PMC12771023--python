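"""Synthetic acoustic and optical data with the statistical structure the
analysis assumes.

Acoustic scenes contain a specular optical-window plate, discrete point
scatterers, optional diffuse speckle and electronic noise.  The plate both
reflects specularly (front and back face, the back face attenuated by the
film) and *rings*: when a transmit wavefront strikes it, every surface
point within a lateral extent of the beam axis re-emits a damped sinusoid
whose amplitude is proportional to the local incident pressure.  The
strike is treated as exciting the plate as a whole (drum-like; in-plate
wave speeds are much larger than in water), so off-axis re-emission starts
at the window-depth round-trip time rather than at each point's own water
path — which is what places ringing clutter at and above the window in the
reconstructed image.  Focused multi-element transmissions therefore ring
proportionally more than single-element ones, and a water-backed ("wet")
window rings less than an air-backed ("dry") one.

Element emission is an omnidirectional point source with 1/r spreading
(distances in mm); all generators are pure functions of their parameters
and seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import gausspulse

from .beamforming import ArrayGeometry, EchoMatrix, make_tx_aperture
from .material import PulseEchoDataset
from .optical import BeadStack

__all__ = [
    "PulseModel",
    "PlateMaterial",
    "PlateSpec",
    "SpeckleSpec",
    "ScatteringScene",
    "gen_plate_pulse_echo",
    "gen_speckle_scene",
    "gen_irm",
    "gen_frm_physical",
    "gen_bead_stack",
]


@dataclass(frozen=True)
class PulseModel:
    """Gaussian-modulated sinusoid transmit pulse.

    Defaults model the imaging array's mid-band: 18 MHz center, 60 %
    fractional bandwidth (-6 dB), unit amplitude.
    """

    center_frequency_mhz: float = 18.0
    fractional_bandwidth: float = 0.6
    amplitude: float = 1.0

    def __post_init__(self):
        if not 0 < self.fractional_bandwidth < 2:
            raise ValueError("fractional bandwidth must lie in (0, 2)")

    @property
    def fc_hz(self) -> float:
        return self.center_frequency_mhz * 1e6

    @property
    def half_support_s(self) -> float:
        """Time beyond which the envelope is below -80 dB."""
        ref = 10.0 ** (-6 / 20.0)
        a = -((np.pi * self.fc_hz * self.fractional_bandwidth) ** 2) / (4.0 * np.log(ref))
        return float(np.sqrt(np.log(1e4) / a))

    def __call__(self, t):
        """Evaluate the pulse at times ``t`` (seconds, peak envelope at 0)."""
        return self.amplitude * gausspulse(
            np.asarray(t, dtype=float), fc=self.fc_hz, bw=self.fractional_bandwidth
        )


# --------------------------------------------------------------------------
# Single-element substitution-method data
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PlateMaterial:
    """Ground-truth film for the pulse-echo generator.

    ``gamma_back`` defaults to the front value (symmetric faces); the
    attenuation law alpha(f) = alpha_slope (f - 30 MHz) + alpha_30 (dB/cm)
    is applied over the whole spectrum.  For steep slopes it extrapolates
    below zero outside the fit band; over a sub-millimeter film the
    resulting sub-band gain is a fraction of a dB and keeps the forward
    model an exact inverse of the linear-law estimator.
    """

    gamma_front: float
    alpha_slope: float = 0.0          # dB cm^-1 MHz^-1
    alpha_30: float = 0.0             # dB cm^-1
    thickness_cm: float = 0.024
    gamma_back: float | None = None
    c_plate_mps: float = 2400.0

    @property
    def gamma_bf(self) -> float:
        return self.gamma_front if self.gamma_back is None else self.gamma_back

    def alpha_db_per_cm(self, f_hz):
        f_mhz = np.asarray(f_hz, dtype=float) / 1e6
        return self.alpha_slope * (f_mhz - 30.0) + self.alpha_30


def gen_plate_pulse_echo(
    material: PlateMaterial,
    pulse: PulseModel | None = None,
    n_locations: int = 5,
    n_repetitions: int = 500,
    location_jitter: float = 0.003,
    noise_sigma: float = 0.01,
    gamma_0: float = 0.37,
    sample_rate_hz: float = 250e6,
    n_samples: int = 1000,
    echo_time_s: float = 2.0e-6,
    seed: int = 0,
) -> tuple[PulseEchoDataset, PulseEchoDataset, dict]:
    """Forward model for the substitution method.

    The reference reflector returns ``gamma_0 * pulse`` at ``echo_time_s``;
    the film returns a front-face echo ``gamma_front * pulse`` at the same
    delay plus a back-face echo ``(1 - gamma_front^2) * gamma_back * pulse``
    delayed by the round trip through the film and low-pass shaped by the
    linear attenuation law applied in the frequency domain
    (10^(-alpha(f) * 2d / 20)).  Per-location amplitude jitter is a shared
    multiplicative factor on a location's echoes; repetitions differ only by
    additive white Gaussian noise (``noise_sigma`` relative to the pulse
    amplitude).

    Returns ``(sample, reference, info)`` where ``info`` holds the echo gate
    centers ``t_front``, ``t_back`` and ``t_ref``.
    """
    if pulse is None:
        # Broadband 30 MHz single-element immersion transducer.
        pulse = PulseModel(center_frequency_mhz=30.0, fractional_bandwidth=0.8)
    rng = np.random.default_rng(seed)
    fs = sample_rate_hz
    t = np.arange(n_samples) / fs
    t_front = echo_time_s
    t_back = t_front + 2.0 * (material.thickness_cm * 1e-2) / material.c_plate_mps
    if t_back - t_front < 2 * pulse.half_support_s * 0.5:
        warnings.warn("front and back echoes overlap for this thickness/pulse",
                      stacklevel=2)
        overlapping = True
    else:
        overlapping = False

    front_clean = material.gamma_front * pulse(t - t_front)
    back_unatt = (1.0 - material.gamma_front**2) * material.gamma_bf * pulse(t - t_back)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    att = 10.0 ** (-material.alpha_db_per_cm(freqs) * 2.0 * material.thickness_cm / 20.0)
    back_clean = np.fft.irfft(np.fft.rfft(back_unatt) * att, n=n_samples)
    ref_clean = gamma_0 * pulse(t - t_front)

    jit_sample = 1.0 + location_jitter * rng.standard_normal(n_locations)
    jit_ref = 1.0 + location_jitter * rng.standard_normal(n_locations)
    sigma = noise_sigma * pulse.amplitude

    def build(clean_by_loc):
        w = np.repeat(clean_by_loc[:, None, :], n_repetitions, axis=1)
        if sigma > 0:
            w = w + rng.normal(0.0, sigma, w.shape)
        return w

    sample_w = build(jit_sample[:, None] * (front_clean + back_clean)[None, :])
    ref_w = build(jit_ref[:, None] * ref_clean[None, :])

    sample = PulseEchoDataset(sample_w, fs, role="sample",
                              overlapping_echoes=overlapping)
    reference = PulseEchoDataset(ref_w, fs, role="reference")
    info = {"t_front": t_front, "t_back": t_back, "t_ref": t_front,
            "gamma_0": gamma_0}
    return sample, reference, info


# --------------------------------------------------------------------------
# Array imaging scenes
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PlateSpec:
    """The optical window in an imaging scene."""

    depth_mm: float = 8.0
    gamma_front: float = 0.797
    gamma_back_dry: float = 0.95       # window/air back face, near-total
    thickness_um: float = 170.0
    alpha_slope: float = 0.0           # dB cm^-1 MHz^-1
    alpha_30: float = 0.0              # dB cm^-1
    c_plate_mps: float = 5570.0
    ring_amplitude: float = 100.0      # incident-pressure -> re-emission coupling
    ring_frequency_mhz: float | None = None   # None: pulse center frequency
    ring_decay_us: float = 1.0
    ring_lateral_extent_mm: float = 6.0

    def gamma_back(self, coupling: str) -> float:
        """Back-face reflectivity: water coupling drops it to the front value."""
        return self.gamma_front if coupling == "wet" else self.gamma_back_dry

    def alpha_db_per_cm(self, f_hz: float) -> float:
        f_mhz = f_hz / 1e6
        return max(self.alpha_slope * (f_mhz - 30.0) + self.alpha_30, 0.0)

    def ring_coupling(self, coupling: str, f_ring_hz: float) -> float:
        """Effective ring drive per unit incident pressure.

        Front-face radiation force scales with gamma_front; the back-face
        contribution with the twice-attenuated transmitted pulse times the
        back-face reflectivity.
        """
        d_cm = self.thickness_um * 1e-4
        att = 10.0 ** (-self.alpha_db_per_cm(f_ring_hz) * 2.0 * d_cm / 20.0)
        gf = self.gamma_front
        return self.ring_amplitude * (
            gf + (1.0 - gf**2) * self.gamma_back(coupling) * att
        )


@dataclass(frozen=True)
class SpeckleSpec:
    """Diffuse sub-resolution scatterers in a depth band."""

    density_per_mm2: float
    depth_band_mm: tuple[float, float]
    amplitude_sigma: float = 1.0
    lateral_extent_mm: float | None = None   # None: array span


@dataclass
class ScatteringScene:
    """Everything insonified in an imaging acquisition."""

    plate: PlateSpec | None = None
    point_scatterers: list = field(default_factory=list)   # (x_mm, z_mm, amplitude)
    speckle: SpeckleSpec | None = None
    noise_sigma: float = 1e-3
    coupling: str = "dry"
    seed: int = 0

    def __post_init__(self):
        if self.coupling not in ("dry", "wet"):
            raise ValueError("coupling must be 'dry' or 'wet'")


def gen_speckle_scene(
    density_per_mm2: float,
    depth_band_mm: tuple[float, float],
    lateral_extent_mm: float,
    seed_or_rng,
    amplitude_sigma: float = 1.0,
) -> np.ndarray:
    """Poisson-distributed scatterers with Gaussian amplitudes.

    Returns an (n, 3) array of (x_mm, z_mm, amplitude); the expected count
    is density x band area.
    """
    if density_per_mm2 < 0:
        raise ValueError("density must be non-negative")
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    z0, z1 = depth_band_mm
    area = (z1 - z0) * lateral_extent_mm
    n = rng.poisson(density_per_mm2 * area)
    if n == 0:
        return np.empty((0, 3))
    x = rng.uniform(-lateral_extent_mm / 2.0, lateral_extent_mm / 2.0, n)
    z = rng.uniform(z0, z1, n)
    a = rng.normal(0.0, amplitude_sigma, n)
    return np.column_stack([x, z, a])


def _scene_scatterers(scene: ScatteringScene, geometry: ArrayGeometry,
                      rng: np.random.Generator) -> np.ndarray:
    parts = []
    if scene.point_scatterers:
        parts.append(np.asarray(scene.point_scatterers, dtype=float).reshape(-1, 3))
    if scene.speckle is not None:
        extent = scene.speckle.lateral_extent_mm
        if extent is None:
            extent = geometry.n_elements * geometry.pitch_mm
        parts.append(
            gen_speckle_scene(
                scene.speckle.density_per_mm2,
                scene.speckle.depth_band_mm,
                extent,
                rng,
                scene.speckle.amplitude_sigma,
            )
        )
    if not parts:
        return np.empty((0, 3))
    return np.concatenate(parts, axis=0)


def _windowed_pulse_add(frame, t0, amps, pulse, fs):
    """Accumulate ``amps * pulse(t - t0)`` into each receive trace.

    ``t0`` and ``amps`` are (..., n_rx)-shaped with the last axis matching
    the frame's receive rows (leading axes enumerate sources).
    """
    n_rx, n_t = frame.shape
    half = pulse.half_support_s
    w = int(np.ceil(2 * half * fs)) + 2
    t0 = np.atleast_2d(t0)
    amps = np.atleast_2d(amps)
    k0 = np.floor((t0 - half) * fs).astype(int)             # (n_src, n_rx)
    cols = np.arange(w)
    kk = k0[..., None] + cols                               # (n_src, n_rx, w)
    tt = kk / fs - t0[..., None]
    vals = amps[..., None] * pulse(tt)
    mask = (kk >= 0) & (kk < n_t)
    rows = np.broadcast_to(np.arange(n_rx)[None, :, None], kk.shape)
    flat = rows[mask] * n_t + kk[mask]
    np.add.at(frame.ravel(), flat, vals[mask])


def _simulate_frame(
    firing_idx0: np.ndarray,
    firing_delays_s: np.ndarray,
    axis_x_mm: float,
    scene: ScatteringScene,
    geometry: ArrayGeometry,
    pulse: PulseModel,
    scatterers: np.ndarray,
    ring_source_spacing_mm: float | None,
) -> np.ndarray:
    """One RF frame (receive element x time) for a given firing set.

    Transmit delays are applied in continuous time, so this doubles as the
    physically focused oracle for the discrete-shift synthetic route.
    """
    g = geometry
    n_rx, n_t = g.n_elements, g.n_samples
    frame = np.zeros((n_rx, n_t))
    x = g.element_x_mm
    c = g.c_mps
    fs = g.sample_rate_hz

    # --- discrete scatterers (1/r spreading both ways, distances in mm)
    if scatterers.size:
        sx, sz, sa = scatterers.T
        r2 = np.sqrt((sx[:, None] - x[None, :]) ** 2 + sz[:, None] ** 2)  # (n_sc, n_rx)
        for e, tau in zip(firing_idx0, firing_delays_s):
            r1 = np.sqrt((sx - x[e]) ** 2 + sz**2)                        # (n_sc,)
            t0 = tau + (r1[:, None] + r2) * 1e-3 / c
            amps = sa[:, None] / (r1[:, None] * r2)
            _windowed_pulse_add(frame, t0, amps, pulse, fs)

    plate = scene.plate
    if plate is not None:
        zp = plate.depth_mm
        gf = plate.gamma_front
        gb = plate.gamma_back(scene.coupling)
        d_cm = plate.thickness_um * 1e-4
        att_fc = 10.0 ** (-plate.alpha_db_per_cm(pulse.fc_hz) * 2.0 * d_cm / 20.0)
        t_film = 2.0 * plate.thickness_um * 1e-6 / plate.c_plate_mps

        # --- specular front/back-face echoes via the image source
        for e, tau in zip(firing_idx0, firing_delays_s):
            r_spec = np.sqrt((x[e] - x) ** 2 + (2.0 * zp) ** 2)           # (n_rx,)
            t0 = tau + r_spec * 1e-3 / c
            _windowed_pulse_add(frame, t0, gf / r_spec, pulse, fs)
            _windowed_pulse_add(
                frame, t0 + t_film, (1.0 - gf**2) * gb * att_fc / r_spec, pulse, fs
            )

        # --- drum-like ringing re-emission
        f_ring = (plate.ring_frequency_mhz or pulse.center_frequency_mhz) * 1e6
        gamma_t = plate.ring_decay_us * 1e-6
        ring_eff = plate.ring_coupling(scene.coupling, f_ring) * pulse.amplitude
        if ring_eff > 0:
            spacing = ring_source_spacing_mm or g.pitch_mm
            ext = plate.ring_lateral_extent_mm
            xs = axis_x_mm + np.arange(-ext, ext + spacing / 2.0, spacing)
            s_c = -1.0 / gamma_t + 2j * np.pi * f_ring
            e_t = np.exp(s_c * g.times_s)                                 # (n_t,)
            w_r = int(np.ceil(6.0 * gamma_t * fs))
            for e, tau in zip(firing_idx0, firing_delays_s):
                onset = tau + zp * 1e-3 / c       # wavefront strikes the plate
                r_es = np.sqrt((xs - x[e]) ** 2 + zp**2)                  # (n_src,)
                for s in range(xs.size):
                    r_sr = np.sqrt((xs[s] - x) ** 2 + zp**2)              # (n_rx,)
                    t0 = onset + r_sr * 1e-3 / c
                    z_rx = (ring_eff / (r_es[s] * r_sr)) * np.exp(-s_c * t0)
                    k0 = np.ceil(t0 * fs).astype(int)
                    for r in range(n_rx):
                        a, b = k0[r], min(n_t, k0[r] + w_r)
                        if a < b:
                            frame[r, a:b] += (z_rx[r] * e_t[a:b]).imag
    return frame


def _gen_matrix(scene, geometry, pulse, kind, apertures, axes,
                ring_source_spacing_mm):
    rng = np.random.default_rng(scene.seed)
    scatterers = _scene_scatterers(scene, geometry, rng)
    n = geometry.n_elements
    data = np.empty((n, n, geometry.n_samples))
    for i, (ap, axis_x) in enumerate(zip(apertures, axes)):
        idx0, delays = ap
        data[i] = _simulate_frame(
            idx0, delays, axis_x, scene, geometry, pulse, scatterers,
            ring_source_spacing_mm,
        )
    if scene.noise_sigma > 0:
        data += rng.normal(0.0, scene.noise_sigma, data.shape)
    return data


def gen_irm(
    scene: ScatteringScene,
    geometry: ArrayGeometry,
    pulse: PulseModel | None = None,
    ring_source_spacing_mm: float | None = None,
) -> EchoMatrix:
    """Synthetic-aperture acquisition: one element pulsed at a time."""
    pulse = pulse or PulseModel()
    x = geometry.element_x_mm
    aps = [(np.array([e]), np.array([0.0])) for e in range(geometry.n_elements)]
    data = _gen_matrix(scene, geometry, pulse, "IRM", aps, x, ring_source_spacing_mm)
    return EchoMatrix(data, "IRM", geometry,
                      meta={"scene_seed": scene.seed, "coupling": scene.coupling})


def gen_frm_physical(
    scene: ScatteringScene,
    geometry: ArrayGeometry,
    tx_f_number: float = 6.0,
    focal_depth_mm: float = 8.0,
    pulse: PulseModel | None = None,
    ring_source_spacing_mm: float | None = None,
) -> EchoMatrix:
    """Rayline acquisition with physically focused transmissions.

    The transmit field of each aperture is the delayed coherent sum of its
    element emissions, evaluated in continuous time — the independent
    physical-focusing oracle for :func:`~sonowindow.beamforming.irm_to_frm`.
    """
    pulse = pulse or PulseModel()
    x = geometry.element_x_mm
    aps, axes = [], []
    for i in range(geometry.n_elements):
        ap = make_tx_aperture(i + 1, tx_f_number, focal_depth_mm, geometry)
        aps.append((ap.elements - 1, ap.delays))
        axes.append(x[i])
    data = _gen_matrix(scene, geometry, pulse, "FRM_physical", aps, axes,
                       ring_source_spacing_mm)
    return EchoMatrix(data, "FRM_physical", geometry, focal_depth_mm, tx_f_number,
                      meta={"scene_seed": scene.seed, "coupling": scene.coupling})


# --------------------------------------------------------------------------
# Optical bead stacks
# --------------------------------------------------------------------------

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def gen_bead_stack(
    true_fwhm_x_um: float,
    true_fwhm_y_um: float,
    true_fwhm_z_um: float = 1.6,
    pixel_um: float = 0.125,
    z_step_um: float = 0.2,
    shape: tuple[int, int, int] = (17, 64, 64),
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> BeadStack:
    """3D Gaussian bead image with configured lateral FWHMs.

    The bead center is offset from the stack center by a uniform sub-voxel
    amount; ``noise_sigma`` is additive Gaussian noise relative to the unit
    peak.  Requires ``pixel_um < fwhm/3`` so the profile is resolved.
    """
    if pixel_um >= min(true_fwhm_x_um, true_fwhm_y_um) / 3.0:
        raise ValueError("pixel size too coarse for the requested FWHM")
    rng = np.random.default_rng(seed)
    nz, ny, nx = shape
    cz, cy, cx = ((n - 1) / 2.0 + rng.uniform(-0.5, 0.5) for n in shape)
    sx = true_fwhm_x_um * _FWHM_TO_SIGMA / pixel_um
    sy = true_fwhm_y_um * _FWHM_TO_SIGMA / pixel_um
    sz = true_fwhm_z_um * _FWHM_TO_SIGMA / z_step_um
    z, y, x2 = np.ogrid[:nz, :ny, :nx]
    vox = np.exp(
        -((z - cz) ** 2) / (2 * sz**2)
        - ((y - cy) ** 2) / (2 * sy**2)
        - ((x2 - cx) ** 2) / (2 * sx**2)
    )
    if noise_sigma > 0:
        vox = vox + rng.normal(0.0, noise_sigma, vox.shape)
    return BeadStack(vox, pixel_size_um=pixel_um, z_step_um=z_step_um)
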