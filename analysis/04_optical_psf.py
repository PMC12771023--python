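#!/usr/bin/env python
"""Optical PSF through candidate windows, from synthetic bead z-stacks.

For each window material five sub-resolution bead stacks are generated
with the measured lateral FWHMs as ground truth (0.2 um z-steps, 0.125 um
pixels), the z-planes summed, x/y profiles extracted through the peak, and
per-material medians and ranges reported.
"""

import argparse
from pathlib import Path

import pandas as pd

import sonowindow as sw
from sonowindow import optical as opt

# Measured (x, y) median FWHMs used as generator truths, in um.
MATERIALS = {
    "glass": (0.80, 0.78),
    "COC": (0.92, 0.93),
    "Ibidi": (0.87, 0.93),
    "PMP": (0.93, 0.90),
}


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--n-beads", type=int, default=5)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    rows = []
    for k, (name, (tx, ty)) in enumerate(MATERIALS.items()):
        fx, fy = [], []
        for b in range(args.n_beads):
            stack = sw.gen_bead_stack(tx, ty, noise_sigma=0.05,
                                      seed=args.seed + 100 * k + b)
            a, c = opt.bead_fwhm(stack)
            fx.append(a)
            fy.append(c)
        s = opt.summarize_psf(fx, fy)
        rows.append({"material": name,
                     "fwhm_x_median_um": s.median_x, "fwhm_x_range_um": s.range_x,
                     "fwhm_y_median_um": s.median_y, "fwhm_y_range_um": s.range_y,
                     "truth_x_um": tx, "truth_y_um": ty})
        print(f"{name:6s} x ({s.median_x:.2f}, {s.range_x:.2f}) um   "
              f"y ({s.median_y:.2f}, {s.range_y:.2f}) um   truth ({tx}, {ty})")

    pd.DataFrame(rows).to_csv(args.out / "psf_summary.csv", index=False)
    print("\nAll four materials keep a sub-micrometer median PSF; the "
          "half-max rule reads a pixel or so below truth by construction.")


if __name__ == "__main__":
    main()
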