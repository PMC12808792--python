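"""Readers and writers for the package's on-disk dialects.

Formats
-------
* Displacement / traction / stress fields: plain CSV with physical-unit
  columns (``x_um, y_um, ux_um, uy_um, valid`` / ``tx_Pa, ty_Pa`` /
  ``sxx_Pa, sxy_Pa, syy_Pa``) plus an optional key-value sidecar
  (``<name>.meta.yaml``) carrying pixel size and substrate constants.
* Images: 16-bit TIFF.  Internally arrays are stored with the y axis
  increasing with the row index (origin at the lower-left corner); TIFF
  rows are flipped on write/read so saved images follow the usual
  top-row-first viewing convention.
* AFM force curves: two-column delimited text (Z_nm, d_nm), ``#`` comment
  headers; vendor-neutral.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .afm import ForceCurve
from .dic import DisplacementField
from .elastic import SubstrateModel
from .fttc import TractionField
from .stress import StressField

__all__ = [
    "write_image",
    "read_image",
    "write_displacement_csv",
    "read_displacement_csv",
    "write_traction_csv",
    "read_traction_csv",
    "write_stress_csv",
    "read_force_curve",
    "write_force_curve",
]


def _write_sidecar(path: Path, meta: dict) -> None:
    side = path.with_suffix(path.suffix + ".meta.yaml")
    side.write_text(yaml.safe_dump(meta, sort_keys=True))


def _read_sidecar(path: Path) -> dict:
    side = path.with_suffix(path.suffix + ".meta.yaml")
    if side.exists():
        return yaml.safe_load(side.read_text()) or {}
    return {}


def write_image(path, image: np.ndarray, pixel_size: float | None = None) -> None:
    """Save an intensity array as 16-bit TIFF (rows flipped to view order)."""
    path = Path(path)
    img = np.asarray(image)
    if img.dtype != np.uint16:
        lo, hi = float(img.min()), float(img.max())
        scale = 65535.0 / (hi - lo) if hi > lo else 1.0
        img = ((img - lo) * scale).round().astype(np.uint16)
    tifffile.imwrite(path, img[::-1])
    if pixel_size is not None:
        _write_sidecar(path, {"pixel_size_um": float(pixel_size)})


def read_image(path) -> np.ndarray:
    """Load a TIFF/PNG image into the package's row-up orientation."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        img = tifffile.imread(path)
    else:
        from imageio.v3 import imread

        img = imread(path)
    return np.asarray(img)[::-1]


def write_displacement_csv(path, field: DisplacementField) -> None:
    path = Path(path)
    X, Y = np.meshgrid(field.x, field.y)
    pd.DataFrame(
        {
            "x_um": X.ravel(),
            "y_um": Y.ravel(),
            "ux_um": field.u.ravel(),
            "uy_um": field.v.ravel(),
            "valid": field.valid.ravel().astype(int),
        }
    ).to_csv(path, index=False)
    _write_sidecar(
        path,
        {
            "pixel_size_um": float(field.pixel_size),
            "window_px": field.window,
            "overlap_px": field.overlap,
        },
    )


def read_displacement_csv(path) -> DisplacementField:
    path = Path(path)
    df = pd.read_csv(path)
    x = np.unique(df["x_um"].to_numpy())
    y = np.unique(df["y_um"].to_numpy())
    shape = (y.size, x.size)
    if len(df) != y.size * x.size:
        raise ValueError("displacement CSV is not a complete grid")
    order = np.lexsort((df["x_um"].to_numpy(), df["y_um"].to_numpy()))
    meta = _read_sidecar(path)
    return DisplacementField(
        x=x,
        y=y,
        u=df["ux_um"].to_numpy()[order].reshape(shape),
        v=df["uy_um"].to_numpy()[order].reshape(shape),
        valid=df["valid"].to_numpy()[order].reshape(shape).astype(bool),
        pixel_size=float(meta.get("pixel_size_um", np.diff(x).mean() if x.size > 1 else 1.0)),
        window=meta.get("window_px"),
        overlap=meta.get("overlap_px"),
    )


def write_traction_csv(path, traction: TractionField) -> None:
    path = Path(path)
    X, Y = np.meshgrid(traction.x, traction.y)
    pd.DataFrame(
        {
            "x_um": X.ravel(),
            "y_um": Y.ravel(),
            "tx_Pa": traction.tx.ravel(),
            "ty_Pa": traction.ty.ravel(),
        }
    ).to_csv(path, index=False)
    meta = {"pixel_size_um": float(traction.pixel_size)}
    if traction.substrate is not None:
        meta["substrate_youngs_modulus_pa"] = float(traction.substrate.youngs_modulus)
        meta["substrate_poisson_ratio"] = float(traction.substrate.poisson_ratio)
    if traction.regularization is not None:
        meta["regularization_lambda"] = float(traction.regularization)
    _write_sidecar(path, meta)


def read_traction_csv(path) -> TractionField:
    path = Path(path)
    df = pd.read_csv(path)
    x = np.unique(df["x_um"].to_numpy())
    y = np.unique(df["y_um"].to_numpy())
    shape = (y.size, x.size)
    if len(df) != y.size * x.size:
        raise ValueError("traction CSV is not a complete grid")
    order = np.lexsort((df["x_um"].to_numpy(), df["y_um"].to_numpy()))
    meta = _read_sidecar(path)
    substrate = None
    if "substrate_youngs_modulus_pa" in meta:
        substrate = SubstrateModel(
            meta["substrate_youngs_modulus_pa"], meta.get("substrate_poisson_ratio", 0.45)
        )
    return TractionField(
        x=x,
        y=y,
        tx=df["tx_Pa"].to_numpy()[order].reshape(shape),
        ty=df["ty_Pa"].to_numpy()[order].reshape(shape),
        pixel_size=float(meta.get("pixel_size_um", np.diff(x).mean() if x.size > 1 else 1.0)),
        substrate=substrate,
        regularization=meta.get("regularization_lambda"),
    )


def write_stress_csv(path, stress: StressField) -> None:
    path = Path(path)
    X, Y = np.meshgrid(stress.x, stress.y)
    pd.DataFrame(
        {
            "x_um": X.ravel(),
            "y_um": Y.ravel(),
            "sxx_Pa": stress.sxx.ravel(),
            "sxy_Pa": stress.sxy.ravel(),
            "syy_Pa": stress.syy.ravel(),
            "in_mask": stress.mask.ravel().astype(int),
        }
    ).to_csv(path, index=False)
    _write_sidecar(path, {"pixel_size_um": float(stress.pixel_size)})


def read_force_curve(path, spring_constant: float) -> ForceCurve:
    """Read a two-column (Z_nm, d_nm) delimited text force curve.

    Lines starting with ``#`` are headers; the delimiter is sniffed from
    commas/whitespace.
    """
    path = Path(path)
    data = np.loadtxt(path, comments="#", delimiter=None if _is_whitespace(path) else ",")
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError("force-curve file must have two columns (Z_nm, d_nm)")
    return ForceCurve(z=data[:, 0], d=data[:, 1], spring_constant=spring_constant)


def _is_whitespace(path: Path) -> bool:
    for line in path.read_text().splitlines():
        if line.startswith("#") or not line.strip():
            continue
        return "," not in line
    return True


def write_force_curve(path, curve: ForceCurve) -> None:
    path = Path(path)
    header = f"# AFM force curve; spring_constant_N_per_m = {curve.spring_constant}\n# Z_nm d_nm"
    np.savetxt(path, np.column_stack([curve.z, curve.d]), header=header, comments="")
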