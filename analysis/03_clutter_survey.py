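#!/usr/bin/env python
"""Off-axis clutter under different windows, transmit schemes, coupling,
and receive f-numbers.

Simulates the condition grid on a reduced 64-element profile (window at
4 mm): pre-beamforming clutter for rayline (focused FRM frames) vs
synthetic aperture (raw single-element frames) on glass / COC / PMP-like
windows under dry and wet back-face coupling, normalized to the
glass/rayline/dry reference; post-beamforming clutter across receive
f-numbers; and one-sided pooled t-tests of each condition against the
reference.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

import sonowindow as sw
from sonowindow import beamforming as bf
from sonowindow import clutter as cl
from sonowindow import metrics as m

GEOM = sw.ArrayGeometry(n_elements=64, n_samples=768)
WINDOW_MM = 4.0
TX_RANGE = (17, 48)
FLOOR = dict(depth_range_mm=(1.0, 2.5), tx_index_range=TX_RANGE)

MATERIALS = {
    "glass": dict(gamma_front=0.797),
    "COC": dict(gamma_front=0.2408, alpha_slope=2.92, alpha_30=98.3,
                thickness_um=240.0, c_plate_mps=2400.0),
    "PMP": dict(gamma_front=0.0664, alpha_slope=2.8, alpha_30=123.0,
                thickness_um=250.0, c_plate_mps=2200.0),
}


def plate(**kw):
    args = dict(depth_mm=WINDOW_MM, ring_lateral_extent_mm=3.0)
    args.update(kw)
    return sw.PlateSpec(**args)


def prebf(em):
    floor = bf.estimate_noise_floor_frm(em, **FLOOR)
    return cl.prebf_offaxis_clutter(
        em, WINDOW_MM, floor, min_lateral_offset_mm=2.6,
        tx_index_range=TX_RANGE)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    results, frms = {}, {}
    for name, matkw in MATERIALS.items():
        for coupling in ("dry", "wet"):
            scene = sw.ScatteringScene(plate=plate(**matkw), coupling=coupling,
                                       noise_sigma=0.05, seed=args.seed)
            frm = sw.to_analytic(sw.gen_frm_physical(scene, GEOM, 6.0, WINDOW_MM))
            res = prebf(frm)
            res.condition = f"{name}/rayline/{coupling}"
            results[res.condition] = res
            frms[(name, coupling)] = frm
            irm = sw.to_analytic(sw.gen_irm(scene, GEOM))
            res_sa = prebf(irm)
            res_sa.condition = f"{name}/SA/{coupling}"
            results[res_sa.condition] = res_sa

    reference = results["glass/rayline/dry"]
    rows = []
    for label, res in results.items():
        norm = cl.normalize_to_reference(res, reference)
        t = m.one_sided_ttest(res.per_tx_values_db,
                              reference.per_tx_values_db, "a_less")
        rows.append({"condition": label, "mean_db": norm.mean_db,
                     "std_db": norm.std_db, "n_frames": norm.per_tx_values_db.size,
                     "t": t.t_statistic, "p_one_sided": t.p_value})
        print(f"{label:22s} {norm.mean_db:+7.2f} dB  (p={t.p_value:.2g})")
    pd.DataFrame(rows).to_csv(args.out / "clutter_conditions.csv", index=False)

    print("\nReceive f-number sweep (glass/rayline/dry, post-beamforming ROI "
          "0.15-0.6 mm above the window):")
    sweep = []
    for fn in (1.0, 1.4, 2.0, 3.0, 4.0, 6.0):
        bm = bf.das_receive(frms[("glass", "dry")], fn,
                            floor_depth_range_mm=(1.0, 2.5),
                            floor_line_range=TX_RANGE)
        val = cl.postbf_clutter(bm, WINDOW_MM, lateral_width_mm=2.0)
        sweep.append({"rx_fnum": fn, "roi_mean_db": val})
        print(f"  f/{fn:<4g} {val:6.2f} dB above floor")
    pd.DataFrame(sweep).to_csv(args.out / "fnum_sweep.csv", index=False)
    print("\nWide receive apertures (f/1) admit the off-axis ringing; the "
          "sweep flattens from f/2 up — f/2 is the working recommendation.")


if __name__ == "__main__":
    main()
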