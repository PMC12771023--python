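"""Substitution-method acoustic characterization of thin-film optical windows.

A single-element transducer insonifies the film at normal incidence; echoes
from the front and back faces are compared against a planar reference
reflector of known reflectivity recorded in the same geometry.  From the
gated echo spectra the pipeline estimates

* the amplitude reflection coefficient  |Gamma_s| = |Gamma_0| S_ff(fc) / S0bar(fc),
* the characteristic impedance          Z_s = Z_w (1 + |Gamma_s|) / (1 - |Gamma_s|),
* the linear attenuation law            alpha(f) = alpha_s (f - 30 MHz) + alpha_30,
  fitted from alpha(f) = 8.686 ln[(S_bf^2/S_ff^2) K] / (-4 d)  over the
  reference's -3 dB band, with K = 1/(1-Gamma^2)^2 for symmetric faces and
  K = Gamma_ff^2 / ((1-Gamma_ff^2)^2 Gamma_bf^2) when the faces differ.

S denotes the magnitude (amplitude) spectrum of the gated echo throughout,
which makes the reflection ratio and the squared attenuation ratio
dimensionally consistent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert

__all__ = [
    "PulseEchoDataset",
    "SpectrumSet",
    "MaterialAcousticProperties",
    "ReferenceReflector",
    "MediumConstants",
    "compute_spectrum",
    "estimate_reflection_coefficient",
    "estimate_impedance",
    "impedance_to_reflection",
    "estimate_attenuation",
    "aggregate_material",
    "find_echo_centers",
]

PROPERTY_NAMES = ("gamma_s", "z_s", "alpha_slope", "alpha_30")


@dataclass
class PulseEchoDataset:
    """Repeated single-element RF pulse-echo waveforms.

    ``waveforms`` has shape [location, repetition, time sample]; the study
    design uses 5 lateral locations x 500 repetitions.
    ``role`` is ``"sample"`` or ``"reference"``.
    """

    waveforms: np.ndarray
    sample_rate: float
    role: str = "sample"
    overlapping_echoes: bool = False

    def __post_init__(self):
        self.waveforms = np.asarray(self.waveforms, dtype=float)
        if self.waveforms.ndim != 3:
            raise ValueError("waveforms must be [location, repetition, sample]")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.role not in ("sample", "reference"):
            raise ValueError("role must be 'sample' or 'reference'")

    @property
    def n_locations(self) -> int:
        return self.waveforms.shape[0]

    @property
    def n_repetitions(self) -> int:
        return self.waveforms.shape[1]

    @property
    def n_samples(self) -> int:
        return self.waveforms.shape[2]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate


@dataclass
class SpectrumSet:
    """Repetition-averaged magnitude spectra of a gated echo, per location."""

    frequencies: np.ndarray          # Hz, strictly increasing
    magnitude: np.ndarray            # [location, frequency], >= 0
    window_duration: float           # s
    face: str                        # "front" | "back" | "reference"
    degenerate: bool = False         # all-zero gate

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.magnitude = np.atleast_2d(np.asarray(self.magnitude, dtype=float))
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if np.any(self.magnitude < 0):
            raise ValueError("magnitude spectra must be non-negative")

    def bin_nearest(self, f_hz: float) -> int:
        return int(np.argmin(np.abs(self.frequencies - f_hz)))


@dataclass
class ReferenceReflector:
    """Known planar reflector (plexiglass) and the spectral band it defines."""

    gamma_0: float = 0.37
    fit_band: tuple[float, float] = (19e6, 34e6)
    center_frequency: float = 30e6

    def __post_init__(self):
        if not 0 < self.gamma_0 < 1:
            raise ValueError("gamma_0 must lie in (0, 1)")
        if self.fit_band[0] >= self.fit_band[1]:
            raise ValueError("fit_band must be an increasing interval")


@dataclass
class MediumConstants:
    """Water coupling path and sample thickness."""

    z_w: float = 1.48                # MRayl
    c_w: float = 1480.0              # m/s
    sample_thickness_d: float = 0.024  # cm

    def __post_init__(self):
        if min(self.z_w, self.c_w, self.sample_thickness_d) <= 0:
            raise ValueError("all medium constants must be positive")


@dataclass
class MaterialAcousticProperties:
    """Aggregated acoustic properties with per-location spread."""

    gamma_s: float
    z_s: float
    alpha_slope: float               # dB cm^-1 MHz^-1
    alpha_30: float                  # dB cm^-1
    per_location_values: dict = field(default_factory=dict)
    standard_errors: dict = field(default_factory=dict)
    material: str = ""

    def __post_init__(self):
        if not 0 <= self.gamma_s < 1:
            raise ValueError("gamma_s must lie in [0, 1)")
        if self.z_s <= 0:
            raise ValueError("z_s must be positive")


def compute_spectrum(
    dataset: PulseEchoDataset,
    echo_window_center: float,
    window_duration: float = 0.115e-6,
    face: str = "front",
    nfft: int = 4096,
) -> SpectrumSet:
    """Magnitude spectrum of a rectangularly gated echo, averaged over repetitions.

    The gate of ``window_duration`` seconds is centered on
    ``echo_window_center`` and must lie entirely within the waveform.  The
    gated segment is zero-padded to ``nfft`` before the rFFT so the grid
    resolves the attenuation fit band; a gate that contains the whole echo
    makes this exact.
    """
    fs = dataset.sample_rate
    half = window_duration / 2.0
    i0 = int(round((echo_window_center - half) * fs))
    i1 = int(round((echo_window_center + half) * fs))
    if i0 < 0 or i1 > dataset.n_samples or i1 <= i0:
        raise ValueError(
            f"echo window [{echo_window_center - half:.3e}, "
            f"{echo_window_center + half:.3e}] s lies outside the waveform"
        )
    seg = dataset.waveforms[:, :, i0:i1]
    mags = np.abs(np.fft.rfft(seg, n=nfft, axis=-1))    # [loc, rep, freq]
    magnitude = mags.mean(axis=1)
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    degenerate = bool(np.all(seg == 0))
    if degenerate:
        warnings.warn("all-zero echo window: degenerate spectrum", stacklevel=2)
    return SpectrumSet(freqs, magnitude, window_duration, face, degenerate)


def estimate_reflection_coefficient(
    front: SpectrumSet,
    reference: SpectrumSet,
    ref: ReferenceReflector,
) -> np.ndarray:
    """Per-location |Gamma_s| from the front-face / reference spectral ratio at fc.

    The reference magnitude is averaged across its locations before the
    ratio (the bar in S0bar); both spectra are evaluated at the grid
    frequency nearest fc.
    """
    if front.frequencies.shape != reference.frequencies.shape or not np.allclose(
        front.frequencies, reference.frequencies
    ):
        raise ValueError("front and reference spectra must share a frequency grid")
    k = front.bin_nearest(ref.center_frequency)
    s0 = reference.magnitude[:, k].mean()
    if s0 <= 0:
        raise ZeroDivisionError(
            f"reference magnitude at fc={ref.center_frequency:.3g} Hz is zero; "
            "check the reference gate placement"
        )
    return ref.gamma_0 * front.magnitude[:, k] / s0


def estimate_impedance(gamma_s, medium: MediumConstants):
    """Z_s = Z_w (1 + |Gamma_s|) / (1 - |Gamma_s|), in MRayl."""
    g = np.asarray(gamma_s, dtype=float)
    if np.any(g < 0) or np.any(g >= 1):
        raise ValueError("gamma_s must lie in [0, 1)")
    z = medium.z_w * (1.0 + g) / (1.0 - g)
    return float(z) if np.isscalar(gamma_s) or g.ndim == 0 else z


def impedance_to_reflection(z_s, medium: MediumConstants):
    """Algebraic inverse of :func:`estimate_impedance`."""
    z = np.asarray(z_s, dtype=float)
    g = (z - medium.z_w) / (z + medium.z_w)
    return float(g) if np.isscalar(z_s) or g.ndim == 0 else g


def estimate_attenuation(
    front: SpectrumSet,
    back: SpectrumSet,
    gamma_front,
    medium: MediumConstants,
    ref: ReferenceReflector,
    gamma_back=None,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Linear attenuation fit alpha(f) = alpha_s (f - 30) + alpha_30 per location.

    ``gamma_front`` (and optionally ``gamma_back`` for films whose two faces
    reflect differently) may be scalars or per-location arrays.  Points with
    non-positive spectral ratio (possible under noise) are dropped from the
    ordinary-least-squares fit; the dropped count is returned.

    Returns ``(alpha_slope, alpha_30, n_dropped)`` with slopes in
    dB cm^-1 MHz^-1 and intercepts in dB cm^-1.
    """
    if front.magnitude.shape[0] != back.magnitude.shape[0]:
        raise ValueError("front and back spectra must have matching locations")
    n_loc = front.magnitude.shape[0]
    g_ff = np.broadcast_to(np.asarray(gamma_front, dtype=float), (n_loc,))
    g_bf = None if gamma_back is None else np.broadcast_to(
        np.asarray(gamma_back, dtype=float), (n_loc,)
    )
    d = medium.sample_thickness_d
    if d <= 0:
        raise ValueError("sample thickness must be positive")
    band = (front.frequencies >= ref.fit_band[0]) & (front.frequencies <= ref.fit_band[1])
    if band.sum() < 2:
        raise ValueError("fewer than 2 frequency points in the fit band")
    f_mhz = front.frequencies[band] / 1e6
    fc_mhz = ref.center_frequency / 1e6

    slopes = np.empty(n_loc)
    intercepts = np.empty(n_loc)
    n_dropped = 0
    for l in range(n_loc):
        if g_bf is None:
            k_fac = 1.0 / (1.0 - g_ff[l] ** 2) ** 2
        else:
            k_fac = g_ff[l] ** 2 / ((1.0 - g_ff[l] ** 2) ** 2 * g_bf[l] ** 2)
        ratio = (back.magnitude[l, band] ** 2 / front.magnitude[l, band] ** 2) * k_fac
        valid = ratio > 0
        dropped = int(np.count_nonzero(~valid))
        if dropped:
            warnings.warn(
                f"location {l}: dropped {dropped} non-positive spectral-ratio points",
                stacklevel=2,
            )
            n_dropped += dropped
        if valid.sum() < 2:
            raise ValueError(f"location {l}: fewer than 2 valid band points for the fit")
        alpha_f = 8.686 * np.log(ratio[valid]) / (-4.0 * d)
        slope, intercept = np.polyfit(f_mhz[valid] - fc_mhz, alpha_f, 1)
        slopes[l] = slope
        intercepts[l] = intercept
    return slopes, intercepts, n_dropped


def aggregate_material(per_location: dict, material: str = "") -> MaterialAcousticProperties:
    """Mean and standard error (sample SD / sqrt(n)) across lateral locations.

    ``per_location`` maps property names (``gamma_s``, ``z_s``,
    ``alpha_slope``, ``alpha_30``) to per-location arrays.  A single
    location yields the mean with an undefined (NaN) standard error.
    """
    means, ses, values = {}, {}, {}
    for name, vals in per_location.items():
        v = np.asarray(vals, dtype=float)
        values[name] = v
        means[name] = float(v.mean())
        if v.size >= 2:
            ses[name] = float(v.std(ddof=1) / np.sqrt(v.size))
        else:
            warnings.warn(
                f"{name}: single location, standard error undefined", stacklevel=2
            )
            ses[name] = float("nan")
    return MaterialAcousticProperties(
        gamma_s=means.get("gamma_s", 0.0),
        z_s=means.get("z_s", 1.0),
        alpha_slope=means.get("alpha_slope", 0.0),
        alpha_30=means.get("alpha_30", 0.0),
        per_location_values=values,
        standard_errors=ses,
        material=material,
    )


def find_echo_centers(dataset: PulseEchoDataset, n_echoes: int = 2,
                      min_separation: float = 0.115e-6) -> list[float]:
    """Locate echo gate centers by peak-envelope detection on the mean waveform."""
    from scipy.signal import find_peaks

    mean_wave = dataset.waveforms.mean(axis=(0, 1))
    env = np.abs(hilbert(mean_wave))
    dist = max(1, int(round(min_separation * dataset.sample_rate)))
    peaks, props = find_peaks(env, distance=dist, height=env.max() * 1e-3)
    if len(peaks) < n_echoes:
        raise ValueError(f"found only {len(peaks)} echoes, expected {n_echoes}")
    order = np.argsort(props["peak_heights"])[::-1][:n_echoes]
    chosen = np.sort(peaks[order])
    return [float(p / dataset.sample_rate) for p in chosen]
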