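"""Echo-matrix data model and delay-and-sum beamforming for a linear array.

Two acquisition schemes share one container: the focused response matrix
(FRM) holds echoes from physically focused rayline transmissions indexed by
the aperture-center element, and the inter-element response matrix (IRM)
holds the response of every single-element transmit / receive pair.  An IRM
can be converted into a synthetically focused FRM by delaying and summing
its transmit slices with the same delays a physical aperture would use.
B-mode images are formed by dynamic-receive delay-and-sum with a
configurable receive f-number, log-compressed as 20 log10(envelope + 1) and
referenced to a noise floor measured in anechoic water.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import hilbert

__all__ = [
    "ArrayGeometry",
    "TxAperture",
    "EchoMatrix",
    "BModeImage",
    "n_samples_for_duration",
    "make_tx_aperture",
    "to_analytic",
    "irm_to_frm",
    "estimate_noise_floor_frm",
    "das_receive",
    "optimal_receive_fnum",
    "log_compress",
    "envelope_from_db",
]

KINDS = ("FRM_physical", "FRM_synthetic", "IRM")


def n_samples_for_duration(sample_rate_hz: float, duration_s: float) -> int:
    """Sample count for an acquisition window: round(fs * T) + 1."""
    return int(round(sample_rate_hz * duration_s)) + 1


@dataclass(frozen=True)
class ArrayGeometry:
    """Linear-array acquisition geometry (defaults: the 128-element, 0.1 mm
    pitch, 62.5 MHz / 1792-sample profile with c = 1480 m/s and a 0.34 rad
    element sensitivity half-angle)."""

    n_elements: int = 128
    pitch_mm: float = 0.1
    sample_rate_hz: float = 62.5e6
    n_samples: int = 1792
    c_mps: float = 1480.0
    sensitivity_half_angle_rad: float = 0.34

    def __post_init__(self):
        if self.n_elements <= 0 or self.pitch_mm <= 0 or self.n_samples <= 0:
            raise ValueError("geometry dimensions must be positive")

    @property
    def element_x_mm(self) -> np.ndarray:
        """Element centers, x = 0 at the array center."""
        return (np.arange(self.n_elements) - (self.n_elements - 1) / 2.0) * self.pitch_mm

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate_hz

    @property
    def depth_mm(self) -> np.ndarray:
        """Round-trip depth mapping d = t c / 2 of the sample grid."""
        return self.times_s * self.c_mps / 2.0 * 1e3

    @property
    def duration_s(self) -> float:
        return (self.n_samples - 1) / self.sample_rate_hz

    def depth_to_sample(self, depth_mm: float) -> float:
        return depth_mm * 1e-3 * 2.0 / self.c_mps * self.sample_rate_hz


@dataclass
class TxAperture:
    """A contiguous transmit aperture with focusing delays (min delay 0).

    Element indices are 1-based in user-facing fields, matching rayline
    transmission numbering (transmission #10 at f/6, 8 mm uses [4..16]).
    """

    center_index: int
    elements: np.ndarray
    delays: np.ndarray
    center_delay: float

    def __post_init__(self):
        self.elements = np.asarray(self.elements, dtype=int)
        self.delays = np.asarray(self.delays, dtype=float)
        if self.center_index not in self.elements:
            raise ValueError("aperture must contain its center element")
        if np.any(np.diff(self.elements) != 1):
            raise ValueError("aperture elements must be contiguous")
        if np.any(self.delays < 0) or not np.isclose(self.delays.min(), 0.0):
            raise ValueError("delays must be >= 0 with minimum 0")


@dataclass
class EchoMatrix:
    """3D echo matrix [transmit index, receive element, time sample].

    ``kind`` is ``"FRM_physical"``, ``"FRM_synthetic"`` or ``"IRM"``; the
    transmit index is an aperture-center element index for FRMs and a
    single-element index for IRMs.  ``data`` is real RF or the complex
    analytic signal (see :func:`to_analytic`).
    """

    data: np.ndarray
    kind: str
    geometry: ArrayGeometry
    tx_focal_depth_mm: float = 8.0
    tx_f_number: float = 6.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}")
        g = self.geometry
        if self.data.shape != (g.n_elements, g.n_elements, g.n_samples):
            raise ValueError(
                f"data shape {self.data.shape} does not match geometry "
                f"({g.n_elements}, {g.n_elements}, {g.n_samples})"
            )

    @property
    def is_analytic(self) -> bool:
        return np.iscomplexobj(self.data)


@dataclass
class BModeImage:
    """Log-compressed B-mode in dB, floor-referenced so noise sits at 0 dB."""

    db_values: np.ndarray            # [axial, lateral]
    axial_mm: np.ndarray
    lateral_mm: np.ndarray
    receive_f_number: float
    noise_floor_db: float

    def __post_init__(self):
        self.db_values = np.asarray(self.db_values, dtype=float)
        if not np.all(np.isfinite(self.db_values)):
            raise ValueError("db_values must be finite")
        for v in (self.axial_mm, self.lateral_mm):
            if np.any(np.diff(v) <= 0):
                raise ValueError("coordinate vectors must be strictly increasing")


def log_compress(envelope: np.ndarray) -> np.ndarray:
    """20 log10(envelope + 1); the +1 keeps zeros finite and defines the floor."""
    return 20.0 * np.log10(np.abs(envelope) + 1.0)


def envelope_from_db(db: np.ndarray) -> np.ndarray:
    """Inverse of :func:`log_compress`."""
    return 10.0 ** (np.asarray(db) / 20.0) - 1.0


def make_tx_aperture(
    center_index: int,
    f_number: float,
    focal_depth_mm: float,
    geometry: ArrayGeometry,
) -> TxAperture:
    """Transmit aperture for a rayline: nominal width focal_depth / f#,
    element count the largest odd integer <= width/pitch, clipped at the
    array edges, with geometric focusing delays offset to a minimum of 0.
    """
    if not 1 <= center_index <= geometry.n_elements:
        raise ValueError("center_index outside the array")
    if f_number <= 0:
        raise ValueError("f_number must be positive")
    if np.isinf(f_number):
        n_active = 1
    else:
        n_active = int(np.floor(focal_depth_mm / (f_number * geometry.pitch_mm)))
        if n_active % 2 == 0:
            n_active -= 1
        n_active = max(n_active, 1)
    half = (n_active - 1) // 2
    lo = max(1, center_index - half)
    hi = min(geometry.n_elements, center_index + half)
    elements = np.arange(lo, hi + 1)

    x = geometry.element_x_mm
    x0 = x[center_index - 1]
    if np.isinf(f_number):
        delays = np.zeros(elements.size)
    else:
        path_mm = np.sqrt((x[elements - 1] - x0) ** 2 + focal_depth_mm**2)
        delays = (path_mm.max() - path_mm) * 1e-3 / geometry.c_mps
    center_delay = float(delays[np.searchsorted(elements, center_index)])
    return TxAperture(center_index, elements, delays, center_delay)


def to_analytic(em: EchoMatrix) -> EchoMatrix:
    """Analytic signal along the time axis; the magnitude is the envelope."""
    if em.is_analytic:
        raise TypeError("EchoMatrix is already complex analytic")
    return replace(em, data=hilbert(em.data, axis=-1))


def _fft_delay(spectra: np.ndarray, freqs: np.ndarray, delay_s: float) -> np.ndarray:
    return spectra * np.exp(-2j * np.pi * freqs * delay_s)


def irm_to_frm(
    irm: EchoMatrix,
    f_number: float = 6.0,
    focal_depth_mm: float = 8.0,
    method: str = "fft",
) -> EchoMatrix:
    """Synthesize a focused FRM from single-element (IRM) data.

    For each aperture-center index i the transmit slices of the IRM are
    delayed by the physical aperture's focusing delays and summed:
    FRM(i, rx, t) = sum_e IRM(e, rx, t - tau_e).  Fractional delays use an
    exact FFT phase ramp by default (``method="fft"``); ``"linear"`` does
    two-point interpolation in time instead.
    """
    if irm.kind != "IRM":
        raise TypeError(f"irm_to_frm needs an IRM, got kind={irm.kind!r}")
    geom = irm.geometry
    n_el, _, n_t = irm.data.shape
    out = np.zeros_like(irm.data, dtype=complex if irm.is_analytic else float)

    if method == "fft":
        # Zero-pad to guard against circular wrap of late ringing tails.
        pad = n_t // 4
        n_fft = n_t + pad
        freqs = np.fft.fftfreq(n_fft, d=1.0 / geom.sample_rate_hz)
        slice_fft = np.fft.fft(irm.data, n=n_fft, axis=-1)
        for i in range(n_el):
            ap = make_tx_aperture(i + 1, f_number, focal_depth_mm, geom)
            acc = np.zeros((n_el, n_fft), dtype=complex)
            for e, tau in zip(ap.elements, ap.delays):
                acc += _fft_delay(slice_fft[e - 1], freqs, tau)
            shifted = np.fft.ifft(acc, axis=-1)[:, :n_t]
            out[i] = shifted if irm.is_analytic else shifted.real
    elif method == "linear":
        for i in range(n_el):
            ap = make_tx_aperture(i + 1, f_number, focal_depth_mm, geom)
            for e, tau in zip(ap.elements, ap.delays):
                s = tau * geom.sample_rate_hz
                m = int(np.floor(s))
                f = s - m
                sl = irm.data[e - 1]
                shifted = np.zeros_like(sl)
                if m < n_t:
                    shifted[:, m:] = (1.0 - f) * sl[:, : n_t - m]
                if m + 1 < n_t:
                    shifted[:, m + 1 :] += f * sl[:, : n_t - m - 1]
                out[i] += shifted
    else:
        raise ValueError("method must be 'fft' or 'linear'")

    return EchoMatrix(
        out, "FRM_synthetic", geom, focal_depth_mm, f_number, dict(irm.meta)
    )


def estimate_noise_floor_frm(
    frm: EchoMatrix,
    depth_range_mm: tuple[float, float] = (1.0, 6.0),
    tx_index_range: tuple[int, int] = (24, 104),
) -> float:
    """Noise floor from the matched transmit/receive traces in anechoic water.

    Mean over transmit indices i in ``tx_index_range`` (1-based, inclusive)
    of the mean of 20 log10(|M(i, i, depth band)| + 1).
    """
    if not frm.is_analytic:
        raise TypeError("noise floor needs the analytic signal (run to_analytic)")
    depth = frm.geometry.depth_mm
    sel = (depth >= depth_range_mm[0]) & (depth <= depth_range_mm[1])
    if not np.any(sel):
        raise ValueError("empty depth range for noise-floor estimation")
    lo, hi = tx_index_range
    idx = np.arange(lo - 1, hi)
    diag = frm.data[idx, idx][:, sel]
    return float(log_compress(diag).mean())


def das_receive(
    frm: EchoMatrix,
    receive_f_number: float,
    noise_floor_db: float | None = None,
    floor_depth_range_mm: tuple[float, float] = (1.0, 6.0),
    floor_line_range: tuple[int, int] | None = None,
) -> BModeImage:
    """Dynamic-receive delay-and-sum B-mode with one A-line per transmission.

    At each depth z the receive aperture spans z / f# centered on the
    rayline axis (clipped to the array; the center element is always kept).
    Element traces are delayed by the round-trip geometry
    tau(e, z) = t_tx + (z + sqrt(z^2 + (x_e - x0)^2)) / c, where t_tx is the
    transmit firing time of the aperture-center element, summed coherently
    with linearly interpolated fractional delays, envelope-detected and
    compressed as 20 log10(env + 1).  The noise floor (given, or measured
    from the image's own anechoic band) is subtracted so it sits at 0 dB.
    """
    if frm.kind not in ("FRM_physical", "FRM_synthetic"):
        raise TypeError("das_receive needs a focused response matrix")
    if not frm.is_analytic:
        raise TypeError("das_receive needs the analytic signal (run to_analytic)")
    if receive_f_number <= 0:
        raise ValueError("receive_f_number must be positive")

    geom = frm.geometry
    n_el, n_t = geom.n_elements, geom.n_samples
    x = geom.element_x_mm
    fs = geom.sample_rate_hz
    c = geom.c_mps
    z_mm = geom.depth_mm                       # one pixel per time sample
    half_w = z_mm / (2.0 * receive_f_number)   # (n_z,)
    clipped_warned = False

    db = np.empty((n_t, n_el))
    for i in range(n_el):
        x0 = x[i]
        ap = make_tx_aperture(i + 1, frm.tx_f_number, frm.tx_focal_depth_mm, geom)
        dx = np.abs(x - x0)                    # (n_el,)
        mask = dx[None, :] <= half_w[:, None]  # (n_z, n_el)
        mask[:, i] = True                      # always keep the axis element
        if not clipped_warned and np.all(mask[-1]):
            warnings.warn(
                f"receive f/{receive_f_number:g} aperture spans the whole array "
                "at depth; clipped to the array",
                stacklevel=2,
            )
            clipped_warned = True
        t_rt = ap.center_delay + (
            z_mm[:, None] + np.sqrt(z_mm[:, None] ** 2 + dx[None, :] ** 2)
        ) * 1e-3 / c                           # (n_z, n_el)
        s = t_rt * fs
        i0 = np.floor(s).astype(int)
        frac = s - i0
        valid = (i0 >= 0) & (i0 < n_t - 1)
        i0c = np.clip(i0, 0, n_t - 2)
        traces = frm.data[i]                   # (n_el, n_t)
        g0 = np.take_along_axis(traces, i0c.T, axis=1)      # (n_el, n_z)
        g1 = np.take_along_axis(traces, i0c.T + 1, axis=1)
        gathered = ((1.0 - frac.T) * g0 + frac.T * g1) * (valid & mask).T
        line = gathered.sum(axis=0)            # (n_z,)
        db[:, i] = log_compress(line)

    if noise_floor_db is None:
        sel = (z_mm >= floor_depth_range_mm[0]) & (z_mm <= floor_depth_range_mm[1])
        if floor_line_range is None:
            lo = n_el // 4
            hi = n_el - n_el // 4
        else:
            lo, hi = floor_line_range[0] - 1, floor_line_range[1]
        noise_floor_db = float(db[np.ix_(sel, np.arange(lo, hi))].mean())
    db = db - noise_floor_db

    return BModeImage(
        db_values=db,
        axial_mm=z_mm,
        lateral_mm=x,
        receive_f_number=receive_f_number,
        noise_floor_db=float(noise_floor_db),
    )


def optimal_receive_fnum(sensitivity_half_angle: float) -> float:
    """Receive f-number matched to the element sensitivity cone: 1 / (2 tan a)."""
    if not 0 < sensitivity_half_angle < np.pi / 2:
        raise ValueError("sensitivity half-angle must lie in (0, pi/2)")
    return float(1.0 / (2.0 * np.tan(sensitivity_half_angle)))
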