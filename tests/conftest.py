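"""Shared simulation fixtures.

Heavy scenes are simulated once per session at a reduced study scale
(64 elements / 768 samples / window at 4 mm) that preserves every
geometric relation of the full 128x128x1792 profile: the f/6 transmit
aperture, the ROI placement relative to the window, and the off-axis
rule scaled with the array span.
"""

from __future__ import annotations

import numpy as np
import pytest

import sonowindow as sw
from sonowindow import beamforming as bf
from sonowindow import clutter as cl

# Reduced-scale acquisition profile shared across suites.
GEOM = sw.ArrayGeometry(n_elements=64, pitch_mm=0.1, sample_rate_hz=62.5e6,
                        n_samples=768)
WINDOW_MM = 4.0
TX_RANGE = (17, 48)              # central-lines analog of 24..104
FLOOR_RANGE = (1.0, 2.5)         # anechoic water band above the window
MIN_OFFSET_MM = 2.6              # off-axis rule scaled to the array span
POST_ROI_WIDTH_MM = 2.0


def ring_plate(gamma_front=0.797, **kw):
    args = dict(depth_mm=WINDOW_MM, gamma_front=gamma_front,
                ring_lateral_extent_mm=3.0, ring_amplitude=100.0)
    args.update(kw)
    return sw.PlateSpec(**args)


def prebf_mean(em, min_offset=MIN_OFFSET_MM):
    floor = bf.estimate_noise_floor_frm(em, depth_range_mm=FLOOR_RANGE,
                                        tx_index_range=TX_RANGE)
    return cl.prebf_offaxis_clutter(
        em, WINDOW_MM, floor, min_lateral_offset_mm=min_offset,
        tx_index_range=TX_RANGE,
    ).mean_db


def postbf_mean(frm, rx_fnum):
    bm = bf.das_receive(frm, rx_fnum, floor_depth_range_mm=FLOOR_RANGE,
                        floor_line_range=TX_RANGE)
    return cl.postbf_clutter(bm, WINDOW_MM, lateral_width_mm=POST_ROI_WIDTH_MM)


@pytest.fixture(scope="session")
def eq_bundle():
    """Noiseless 3-scatterer + ringing-plate scene imaged both ways:
    physically focused FRM and IRM->synthetic FRM, plus their B-modes."""
    scene = sw.ScatteringScene(
        plate=ring_plate(),
        point_scatterers=[(-1.0, 2.5, 5.0), (0.0, 3.0, 5.0), (0.8, 2.0, 5.0)],
        noise_sigma=0.0,
        seed=0,
    )
    frm_p = sw.to_analytic(sw.gen_frm_physical(scene, GEOM, 6.0, WINDOW_MM))
    irm = sw.to_analytic(sw.gen_irm(scene, GEOM))
    frm_s = sw.irm_to_frm(irm, f_number=6.0, focal_depth_mm=WINDOW_MM)
    bm_p = bf.das_receive(frm_p, 2.0, floor_depth_range_mm=FLOOR_RANGE,
                          floor_line_range=TX_RANGE)
    bm_s = bf.das_receive(frm_s, 2.0, floor_depth_range_mm=FLOOR_RANGE,
                          floor_line_range=TX_RANGE)
    central = slice(TX_RANGE[0] - 1, TX_RANGE[1])
    return {"scene": scene, "frm_p": frm_p, "irm": irm, "frm_s": frm_s,
            "bm_p": bm_p, "bm_s": bm_s, "central": central}


@pytest.fixture(scope="session")
def point_frm():
    """Single on-axis point scatterer at the transmit focus, noiseless."""
    geom = sw.ArrayGeometry(n_elements=64, pitch_mm=0.1, sample_rate_hz=62.5e6,
                            n_samples=640)
    scene = sw.ScatteringScene(plate=None, point_scatterers=[(0.0, 4.0, 10.0)],
                               noise_sigma=0.0, seed=0)
    frm = sw.to_analytic(sw.gen_frm_physical(scene, geom, 6.0, 4.0))
    return frm


@pytest.fixture(scope="session")
def clutter_suite():
    """Condition comparison over 10 seeds: rayline vs synthetic-aperture
    transmit, glass vs COC window, dry vs wet back face, receive f/1 vs f/2.

    Electronic noise sigma 0.05 (about -26 dB of the ringing envelope)
    gives each seed an independent realization.
    """
    coc = dict(gamma_front=0.2408, alpha_slope=2.92, alpha_30=98.3,
               thickness_um=240.0, c_plate_mps=2400.0)
    rows = []
    first_frm = None
    for seed in range(10):
        sc_glass = sw.ScatteringScene(plate=ring_plate(), noise_sigma=0.05, seed=seed)
        sc_coc = sw.ScatteringScene(plate=ring_plate(**coc), noise_sigma=0.05, seed=seed)
        sc_wet = sw.ScatteringScene(plate=ring_plate(), coupling="wet",
                                    noise_sigma=0.05, seed=seed)
        frm_glass = sw.to_analytic(sw.gen_frm_physical(sc_glass, GEOM, 6.0, WINDOW_MM))
        frm_coc = sw.to_analytic(sw.gen_frm_physical(sc_coc, GEOM, 6.0, WINDOW_MM))
        frm_wet = sw.to_analytic(sw.gen_frm_physical(sc_wet, GEOM, 6.0, WINDOW_MM))
        irm_glass = sw.to_analytic(sw.gen_irm(sc_glass, GEOM))
        rows.append({
            "pre_rayline_glass_dry": prebf_mean(frm_glass),
            "pre_rayline_coc_dry": prebf_mean(frm_coc),
            "pre_rayline_glass_wet": prebf_mean(frm_wet),
            "pre_sa_glass_dry": prebf_mean(irm_glass),
            "post_f1_glass_dry": postbf_mean(frm_glass, 1.0),
            "post_f2_glass_dry": postbf_mean(frm_glass, 2.0),
        })
        if first_frm is None:
            first_frm = frm_glass
    return {"rows": rows, "frm_glass_dry_seed0": first_frm}


def paired_margin(rows, key_hi, key_lo):
    """Mean per-seed difference and its standard error."""
    d = np.array([r[key_hi] - r[key_lo] for r in rows])
    se = d.std(ddof=1) / np.sqrt(d.size) if d.size > 1 else 0.0
    return float(d.mean()), float(se)
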