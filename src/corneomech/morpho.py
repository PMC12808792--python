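"""Closed-form morphometric and clinical scores.

Implements the scalar scores used alongside the biomechanical measurements:
cell circularity from rasterized masks, corneal hydration rate from wet/dry
weights, the 0-3 fluorescein punctate-staining grade, and the
nuclear/cytoplasmic intensity ratio of a stained protein (e.g. YAP).

Perimeter estimation uses the Crofton multi-directional estimator: naive
boundary-pixel counting systematically overestimates the perimeter of smooth
shapes (a rasterized disc would score a circularity well below 1), whereas
the Crofton estimate converges to the true Euclidean perimeter and keeps the
isoperimetric check (disc -> circularity 1) meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.measure import label, perimeter_crofton

__all__ = [
    "CellMask",
    "MorphometricRecord",
    "FluoresceinObservation",
    "measure_mask",
    "circularity",
    "hydration_rate",
    "grade_fluorescein",
    "nc_ratio",
    "measure_cells",
]


@dataclass
class CellMask:
    """Boolean raster of a single cell footprint.

    ``area_analytic`` / ``perimeter_analytic`` (um^2 / um) are attached by
    the synthetic generators when the shape family admits closed forms;
    ``perimeter_is_approximate`` flags closed forms that are themselves
    approximations (e.g. Ramanujan's ellipse perimeter).
    """

    mask: np.ndarray
    pixel_size: float  # um per pixel
    area_analytic: float | None = None
    perimeter_analytic: float | None = None
    perimeter_is_approximate: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be a 2D raster")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class MorphometricRecord:
    cell_id: str
    area_um2: float
    perimeter_um: float
    circularity: float
    perimeter_method: str = "crofton-4"


@dataclass(frozen=True)
class FluoresceinObservation:
    """Slit-lamp observation: punctate stain count and whether stains fuse."""

    punctate_count: int
    fusion: bool = False

    def __post_init__(self) -> None:
        if self.punctate_count < 0:
            raise ValueError("punctate_count must be non-negative")


def measure_mask(cell: CellMask) -> tuple[float, float]:
    """Area (um^2) and perimeter (um) of a cell mask.

    Area is the pixel count scaled by the pixel area; perimeter is the
    4-direction Crofton estimate scaled by the pixel size.
    """
    if cell.n_pixels == 0:
        raise ValueError("empty mask")
    area = cell.n_pixels * cell.pixel_size**2
    perim = perimeter_crofton(cell.mask, directions=4) * cell.pixel_size
    return float(area), float(perim)


def circularity(area: float, perimeter: float) -> float:
    """Circularity 4*pi*A / P^2: 1 for a circle, < 1 for any other shape."""
    if perimeter <= 0:
        raise ValueError("perimeter must be positive")
    return float(4.0 * np.pi * area / perimeter**2)


def hydration_rate(wet_weight_g: float, dry_weight_g: float) -> float:
    """Corneal hydration rate (wet - dry) / wet * 100, in percent."""
    if wet_weight_g <= 0:
        raise ValueError("wet weight must be positive")
    if dry_weight_g < 0 or dry_weight_g > wet_weight_g:
        raise ValueError("dry weight must lie in [0, wet weight]")
    return float((wet_weight_g - dry_weight_g) / wet_weight_g * 100.0)


def grade_fluorescein(obs: FluoresceinObservation) -> int:
    """Fluorescein staining grade on the 0-3 scale.

    Fusion of punctate stains dominates any count (grade 3); otherwise
    0 stains -> 0, 1-30 stains -> 1, more than 30 -> 2.
    """
    if obs.fusion:
        return 3
    if obs.punctate_count == 0:
        return 0
    if obs.punctate_count <= 30:
        return 1
    return 2


def nc_ratio(
    intensity: np.ndarray, nuclear_mask: np.ndarray, cytoplasmic_mask: np.ndarray
) -> float:
    """Nuclear/cytoplasmic mean-intensity ratio.

    The two masks must be disjoint, non-empty and congruent with the image.
    """
    intensity = np.asarray(intensity, dtype=float)
    nuc = np.asarray(nuclear_mask, dtype=bool)
    cyt = np.asarray(cytoplasmic_mask, dtype=bool)
    if not (intensity.shape == nuc.shape == cyt.shape):
        raise ValueError("image and masks must be congruent")
    if np.any(nuc & cyt):
        raise ValueError("nuclear and cytoplasmic masks overlap")
    if not nuc.any() or not cyt.any():
        raise ValueError("masks must be non-empty")
    mu_c = intensity[cyt].mean()
    if mu_c == 0:
        raise ValueError("cytoplasmic mean intensity is zero")
    return float(intensity[nuc].mean() / mu_c)


def measure_cells(labeled: np.ndarray, pixel_size: float) -> list[MorphometricRecord]:
    """Per-cell morphometrics from a labeled raster.

    Cells touching the image border are excluded (their perimeter is
    truncated by the field of view), as are labels that are not a single
    connected component.  Touching cells are expected to have been excluded
    upstream; no splitting is attempted.
    """
    labeled = np.asarray(labeled)
    if labeled.ndim != 2:
        raise ValueError("labeled image must be 2D")
    records: list[MorphometricRecord] = []
    for lab in np.unique(labeled):
        if lab == 0:
            continue
        m = labeled == lab
        if m[0, :].any() or m[-1, :].any() or m[:, 0].any() or m[:, -1].any():
            continue
        if label(m).max() != 1:
            continue
        cell = CellMask(m, pixel_size)
        area, perim = measure_mask(cell)
        records.append(
            MorphometricRecord(
                cell_id=str(int(lab)),
                area_um2=area,
                perimeter_um=perim,
                circularity=circularity(area, perim),
            )
        )
    return records
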