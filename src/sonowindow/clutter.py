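"""Off-axis clutter quantification before and after receive beamforming.

Pre-beamforming clutter is the per-frame maximum of the log-compressed
envelope in a region at the optical-window depth but laterally far from the
transmission axis (the ringing window re-emits there; the specular
wavefront does not reach it).  Post-beamforming clutter is the mean B-mode
level in a thin band just above the window front face.  Both are referenced
to the acquisition's noise floor, and condition means can be normalized to
a reference condition (the glass / rayline / dry scan in the study design).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .beamforming import BModeImage, EchoMatrix, log_compress

__all__ = [
    "ClutterROI",
    "ClutterResult",
    "prebf_offaxis_clutter",
    "postbf_clutter",
    "normalize_to_reference",
]

# One 0.115-us pulse length expressed as depth, used as the half-extent of
# the pre-beamforming ROI around the window depth.
PULSE_WINDOW_S = 0.115e-6


@dataclass(frozen=True)
class ClutterROI:
    """Clutter region of interest.

    ``lateral_spec`` is ``("offset", min_offset_mm)`` for pre-beamforming
    frames (keep receive elements farther than this from the transmit axis)
    or ``("width", width_mm)`` for a laterally centered post-beamforming ROI.
    """

    axial_range_mm: tuple[float, float]
    lateral_spec: tuple[str, float]
    description: str = ""

    def __post_init__(self):
        if self.axial_range_mm[0] >= self.axial_range_mm[1]:
            raise ValueError("axial range must be non-empty")
        if self.lateral_spec[0] not in ("offset", "width"):
            raise ValueError("lateral_spec kind must be 'offset' or 'width'")


@dataclass
class ClutterResult:
    """Per-transmission clutter values (dB relative to the noise floor)."""

    per_tx_values_db: np.ndarray
    tx_indices: np.ndarray
    mean_db: float
    std_db: float
    roi: ClutterROI
    condition: str = ""
    reference_label: str | None = None

    @classmethod
    def from_values(cls, values, tx_indices, roi, condition=""):
        v = np.asarray(values, dtype=float)
        return cls(
            per_tx_values_db=v,
            tx_indices=np.asarray(tx_indices, dtype=int),
            mean_db=float(v.mean()),
            std_db=float(v.std(ddof=1)) if v.size > 1 else 0.0,
            roi=roi,
            condition=condition,
        )


def prebf_offaxis_clutter(
    frm: EchoMatrix,
    window_depth_mm: float,
    noise_floor_db: float,
    min_lateral_offset_mm: float = 5.0,
    tx_index_range: tuple[int, int] = (24, 104),
    axial_half_extent_mm: float | None = None,
    condition: str = "",
) -> ClutterResult:
    """Maximum off-axis log-envelope per RF frame at the window depth.

    For each transmission index in ``tx_index_range`` (1-based, inclusive)
    the ROI holds the samples within one pulse length of the window depth on
    receive elements more than ``min_lateral_offset_mm`` from the transmit
    axis.  The per-frame maximum of 20 log10(env + 1), minus the noise
    floor, is summarized over the retained frames.  Accepts focused (FRM)
    or single-element (IRM) matrices: the raw single-element frames are the
    synthetic-aperture acquisition's pre-beamforming measurement.
    """
    if not frm.is_analytic:
        raise TypeError("pre-beamforming clutter needs the analytic signal")
    geom = frm.geometry
    if axial_half_extent_mm is None:
        axial_half_extent_mm = PULSE_WINDOW_S * geom.c_mps / 2.0 * 1e3
    depth = geom.depth_mm
    rows = (depth >= window_depth_mm - axial_half_extent_mm) & (
        depth <= window_depth_mm + axial_half_extent_mm
    )
    if not np.any(rows):
        raise ValueError("window depth outside the acquisition range")
    x = geom.element_x_mm
    roi = ClutterROI(
        (window_depth_mm - axial_half_extent_mm, window_depth_mm + axial_half_extent_mm),
        ("offset", min_lateral_offset_mm),
        "pre-beamforming off-axis ROI at the window depth",
    )

    lo, hi = tx_index_range
    values, kept = [], []
    for i in range(lo, hi + 1):
        cols = np.abs(x - x[i - 1]) > min_lateral_offset_mm
        if not np.any(cols):
            warnings.warn(f"transmission {i}: empty off-axis ROI, frame skipped",
                          stacklevel=2)
            continue
        block = frm.data[i - 1][np.ix_(cols, rows)]
        values.append(log_compress(block).max() - noise_floor_db)
        kept.append(i)
    if not values:
        raise ValueError("no frames with a non-empty off-axis ROI")
    return ClutterResult.from_values(values, kept, roi, condition)


def postbf_clutter(
    bmode: BModeImage,
    window_depth_mm: float,
    axial_band_above_mm: tuple[float, float] = (0.15, 0.6),
    lateral_width_mm: float = 4.0,
) -> float:
    """Mean floor-referenced B-mode level in a band just above the window.

    The ROI spans ``axial_band_above_mm`` (distances above the window front
    face; the study uses 0.15 to 0.6 mm) and ``lateral_width_mm`` centered
    laterally.  Raises if the ROI is clipped by the image edge.
    """
    lo_off, hi_off = axial_band_above_mm
    if not 0 <= lo_off < hi_off:
        raise ValueError("axial band must be an increasing interval above the window")
    z_lo = window_depth_mm - hi_off
    z_hi = window_depth_mm - lo_off
    rows = (bmode.axial_mm >= z_lo) & (bmode.axial_mm <= z_hi)
    half = lateral_width_mm / 2.0
    cols = np.abs(bmode.lateral_mm) <= half
    if z_lo < bmode.axial_mm[0] or z_hi > bmode.axial_mm[-1] or (
        -half < bmode.lateral_mm[0] or half > bmode.lateral_mm[-1]
    ):
        raise ValueError("clutter ROI clipped by the image edge")
    if not (np.any(rows) and np.any(cols)):
        raise ValueError("empty clutter ROI")
    return float(bmode.db_values[np.ix_(rows, cols)].mean())


def normalize_to_reference(result: ClutterResult, reference: ClutterResult) -> ClutterResult:
    """Express a clutter result relative to a reference condition's mean.

    The reference condition becomes 0 dB by construction.  Re-normalizing a
    result already tagged with the same reference label is a no-op, and the
    ROI definitions must match.
    """
    if result.roi != reference.roi:
        raise ValueError("clutter results computed with different ROI definitions")
    label = reference.condition or "reference"
    if result.reference_label == label:
        return replace(result)
    return replace(
        result,
        per_tx_values_db=result.per_tx_values_db - reference.mean_db,
        mean_db=result.mean_db - reference.mean_db,
        reference_label=label,
    )
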