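"""File formats, configuration validation, and the summary report table.

Echo matrices and pulse-echo sets live in HDF5; bead stacks in multi-page
TIFF with a YAML sidecar; tables in CSV; B-modes additionally as 0-60 dB
grayscale PNG.  All round trips are lossless for array data.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml

from .beamforming import ArrayGeometry, BModeImage, EchoMatrix
from .material import MaterialAcousticProperties, PulseEchoDataset
from .optical import BeadStack

__all__ = [
    "save_echo_matrix",
    "load_echo_matrix",
    "save_pulse_echo",
    "load_pulse_echo",
    "save_bead_stack",
    "load_bead_stack",
    "save_bmode",
    "load_bmode",
    "save_bmode_png",
    "material_table",
    "save_material_table",
    "run_summary_report",
    "validate_config",
    "load_yaml_config",
]


def save_echo_matrix(path, em: EchoMatrix) -> None:
    with h5py.File(path, "w") as f:
        if em.is_analytic:
            ds = f.create_dataset("iq", data=np.stack([em.data.real, em.data.imag]))
        else:
            ds = f.create_dataset("rf", data=em.data)
        g = em.geometry
        ds.attrs.update(
            kind=em.kind,
            pitch_mm=g.pitch_mm,
            sample_rate_hz=g.sample_rate_hz,
            c_mps=g.c_mps,
            tx_focal_mm=em.tx_focal_depth_mm,
            tx_fnum=em.tx_f_number,
            sensitivity_half_angle_rad=g.sensitivity_half_angle_rad,
        )


def load_echo_matrix(path) -> EchoMatrix:
    with h5py.File(path, "r") as f:
        if "iq" in f:
            ds = f["iq"]
            data = ds[0] + 1j * ds[1]
        elif "rf" in f:
            ds = f["rf"]
            data = ds[()]
        else:
            raise ValueError(f"{path}: missing 'rf' or 'iq' dataset")
        a = dict(ds.attrs)
        for key in ("kind", "pitch_mm", "sample_rate_hz", "c_mps"):
            if key not in a:
                raise ValueError(f"{path}: missing attribute {key!r}")
        geom = ArrayGeometry(
            n_elements=data.shape[0],
            pitch_mm=float(a["pitch_mm"]),
            sample_rate_hz=float(a["sample_rate_hz"]),
            n_samples=data.shape[2],
            c_mps=float(a["c_mps"]),
            sensitivity_half_angle_rad=float(a.get("sensitivity_half_angle_rad", 0.34)),
        )
        kind = a["kind"]
        kind = kind.decode() if isinstance(kind, bytes) else str(kind)
        return EchoMatrix(data, kind, geom,
                          float(a.get("tx_focal_mm", 8.0)), float(a.get("tx_fnum", 6.0)))


def save_pulse_echo(path, ds: PulseEchoDataset) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("rf", data=ds.waveforms)
        d.attrs.update(sample_rate_hz=ds.sample_rate, role=ds.role)


def load_pulse_echo(path) -> PulseEchoDataset:
    with h5py.File(path, "r") as f:
        if "rf" not in f:
            raise ValueError(f"{path}: missing 'rf' dataset")
        d = f["rf"]
        role = d.attrs["role"]
        role = role.decode() if isinstance(role, bytes) else str(role)
        return PulseEchoDataset(d[()], float(d.attrs["sample_rate_hz"]), role=role)


def save_bead_stack(path, stack: BeadStack) -> None:
    path = Path(path)
    tifffile.imwrite(path, stack.voxels.astype(np.float32))
    sidecar = path.with_suffix(path.suffix + ".yaml")
    sidecar.write_text(yaml.safe_dump(
        {"pixel_size_um": stack.pixel_size_um, "z_step_um": stack.z_step_um}
    ))


def load_bead_stack(path) -> BeadStack:
    path = Path(path)
    vox = tifffile.imread(path)
    meta = yaml.safe_load(path.with_suffix(path.suffix + ".yaml").read_text())
    return BeadStack(np.asarray(vox, dtype=float),
                     pixel_size_um=float(meta["pixel_size_um"]),
                     z_step_um=float(meta["z_step_um"]))


def save_bmode(path, bm: BModeImage) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("db", data=bm.db_values)
        f.create_dataset("axial_mm", data=bm.axial_mm)
        f.create_dataset("lateral_mm", data=bm.lateral_mm)
        d.attrs.update(receive_f_number=bm.receive_f_number,
                       noise_floor_db=bm.noise_floor_db)


def load_bmode(path) -> BModeImage:
    with h5py.File(path, "r") as f:
        d = f["db"]
        return BModeImage(
            d[()], f["axial_mm"][()], f["lateral_mm"][()],
            float(d.attrs["receive_f_number"]), float(d.attrs["noise_floor_db"]),
        )


def save_bmode_png(path, bm: BModeImage, dynamic_range_db: tuple[float, float] = (0.0, 60.0)) -> None:
    """Grayscale PNG over the display dynamic range (default 0-60 dB)."""
    import matplotlib.image

    lo, hi = dynamic_range_db
    img = np.clip((bm.db_values - lo) / (hi - lo), 0.0, 1.0)
    matplotlib.image.imsave(path, img, cmap="gray", vmin=0.0, vmax=1.0)


def material_table(props: list[MaterialAcousticProperties]) -> pd.DataFrame:
    """Table-layout material properties: value and SE column per property."""
    rows = []
    for p in props:
        se = p.standard_errors
        rows.append(
            {
                "material": p.material,
                "gamma_s": p.gamma_s,
                "gamma_s_se": se.get("gamma_s", np.nan),
                "z_s_mrayl": p.z_s,
                "z_s_se": se.get("z_s", np.nan),
                "alpha_slope": p.alpha_slope,
                "alpha_slope_se": se.get("alpha_slope", np.nan),
                "alpha_30": p.alpha_30,
                "alpha_30_se": se.get("alpha_30", np.nan),
            }
        )
    return pd.DataFrame(rows)


def save_material_table(path, props: list[MaterialAcousticProperties]) -> None:
    material_table(props).to_csv(path, index=False)


def run_summary_report(conditions: list[dict]) -> pd.DataFrame:
    """Summary table: one row per material condition.

    Each entry may provide ``material``, ``gamma_s`` (+``gamma_s_se``),
    per-condition clutter means/stds in dB relative to the reference, and
    PSF medians/ranges.  Missing stages yield explicit NaN markers.
    """
    cols = [
        "material", "gamma_s", "gamma_s_se",
        "clutter_rayline_dry_db", "clutter_rayline_dry_std",
        "clutter_sa_dry_db", "clutter_sa_dry_std",
        "clutter_sa_wet_db", "clutter_sa_wet_std",
        "psf_x_median_um", "psf_x_range_um",
        "psf_y_median_um", "psf_y_range_um",
    ]
    rows = []
    for cond in conditions:
        unknown = set(cond) - set(cols)
        if unknown:
            raise ValueError(f"unknown report fields: {sorted(unknown)}")
        rows.append({c: cond.get(c, np.nan) for c in cols})
    return pd.DataFrame(rows, columns=cols)


def validate_config(config: dict, allowed: dict) -> dict:
    """Reject unknown keys; recurse into nested mappings of ``allowed``."""
    if not isinstance(config, dict):
        raise ValueError("configuration must be a mapping")
    unknown = set(config) - set(allowed)
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    for key, sub in allowed.items():
        if isinstance(sub, dict) and key in config and config[key] is not None:
            validate_config(config[key], sub)
    return config


def load_yaml_config(path, allowed: dict | None = None) -> dict:
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    if allowed is not None:
        validate_config(cfg, allowed)
    return cfg
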