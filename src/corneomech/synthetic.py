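"""Synthetic data with known ground truth for every pipeline stage.

Each inverse stage of the measurement stack (bead images -> displacement ->
traction -> intracellular stress; force curve -> modulus) is testable by
parameter recovery against the generators here:

* traction scenes built from Gaussian force patches, net-force balanced;
* their induced substrate surface displacements (exact half-space forward
  solution, shared kernel with the FTTC inverse);
* noisy rendered bead image pairs;
* Hertz-law force curves with baseline slope, contact offset and force
  noise, following a fixed acquisition protocol (500 nm/s ramp, 1.7 kHz
  sampling, 1.2 um loading displacement);
* rasterized cell masks with analytic area/perimeter where available;
* two-group exposure cohorts with prescribed mean shifts.

All generators draw from one seeded ``numpy.random.Generator`` per call and
are bitwise reproducible for a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .afm import ForceCurve, HertzModelParams
from .dic import DisplacementField
from .elastic import SubstrateModel, forward_displacement_arrays
from .fttc import TractionField
from .morpho import CellMask

__all__ = [
    "TractionPatch",
    "TractionScene",
    "BeadImagePair",
    "SyntheticCurveSpec",
    "SyntheticCohortSpec",
    "make_traction_field",
    "forward_displacement",
    "render_bead_images",
    "simulate_force_curve",
    "make_cell_mask",
    "simulate_cohort",
    "standard_dipole_scene",
    "DEFAULT_SUBSTRATE",
]

# Typical soft polyacrylamide TFM substrate; configurable everywhere.
DEFAULT_SUBSTRATE = SubstrateModel(youngs_modulus=10_000.0, poisson_ratio=0.45)


@dataclass(frozen=True)
class TractionPatch:
    """One Gaussian traction patch: centre (um), peak amplitude (Pa),
    width = Gaussian sigma (um), unit direction vector."""

    center_um: tuple[float, float]
    amplitude_pa: float
    width_um: float
    direction: tuple[float, float]

    def __post_init__(self) -> None:
        if not np.isfinite(self.amplitude_pa):
            raise ValueError("patch amplitude must be finite")
        if self.width_um <= 0:
            raise ValueError("patch width must be positive")
        norm = float(np.hypot(*self.direction))
        if not np.isclose(norm, 1.0, atol=1e-6):
            raise ValueError("patch direction must be a unit vector")


@dataclass(frozen=True)
class TractionScene:
    grid_shape: tuple[int, int]  # (rows, cols)
    pixel_size: float  # um
    patches: tuple[TractionPatch, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_shape[0] < 1 or self.grid_shape[1] < 1:
            raise ValueError("grid must be nonempty")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")


@dataclass
class BeadImagePair:
    """Fluorescent bead images before (cell removed) / after seeding.

    ``image_pre`` is the reference (relaxed substrate) state and
    ``image_post`` the deformed state, so the correlation pre -> post
    measures the displacement the cell induces.
    """

    image_pre: np.ndarray
    image_post: np.ndarray
    pixel_size: float
    bead_positions_true: np.ndarray | None = None
    noise_model: tuple[float, float] = (0.0, 0.0)  # (gaussian sigma, background)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.image_pre.shape != self.image_post.shape:
            raise ValueError("images must have the same shape")
        if (self.image_pre < 0).any() or (self.image_post < 0).any():
            raise ValueError("intensities must be non-negative")


@dataclass(frozen=True)
class SyntheticCurveSpec:
    """Ground-truth parameters of one synthetic AFM approach/withdraw cycle.

    The default ramp follows the acquisition protocol: 500 nm/s loading
    speed, 1.7 kHz sampling, 1.2 um total loading displacement.
    """

    e_true_pa: float = 2000.0
    half_angle_deg: float = 35.0
    poisson_ratio: float = 0.5
    contact_z0_nm: float = 300.0
    baseline_slope: float = 0.0  # deflection nm per nm of Z
    noise_sigma_nn: float = 0.0  # force noise
    speed_nm_s: float = 500.0
    rate_hz: float = 1700.0
    total_displacement_nm: float = 1200.0
    spring_constant: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if self.e_true_pa <= 0:
            raise ValueError("E_true must be positive")
        if not 0 < self.half_angle_deg < 90:
            raise ValueError("half angle must be in (0, 90)")
        if self.total_displacement_nm <= self.contact_z0_nm:
            raise ValueError("total displacement must exceed the contact offset")

    @property
    def n_approach_samples(self) -> int:
        return int(np.floor(self.total_displacement_nm / self.speed_nm_s * self.rate_hz)) + 1


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Two-group cohort with per-parameter group means/SDs and a PM2.5
    exposure distribution per group (uniform within stated bounds)."""

    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"high": 113, "low": 105}
    )
    parameter_means: dict[str, dict[str, float]] = field(default_factory=dict)
    parameter_sds: dict[str, dict[str, float]] = field(default_factory=dict)
    pm25_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"high": (75.0, 150.0), "low": (5.0, 34.9)}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.n_per_group.items():
            if n < 2:
                raise ValueError(f"group {g!r} needs n >= 2")
        for p, sds in self.parameter_sds.items():
            for g, s in sds.items():
                if s < 0:
                    raise ValueError(f"sd of {p!r} in group {g!r} must be >= 0")


def make_traction_field(scene: TractionScene) -> TractionField:
    """Rasterize a traction scene and balance its net force.

    Gaussian patches are summed on the grid and the area-weighted mean
    vector is subtracted, so the integrated traction vanishes exactly (a
    cell in equilibrium exerts no net force on its substrate).  The
    uncorrected field is kept in ``meta["tx_raw"]``/``meta["ty_raw"]``.
    """
    ny, nx = scene.grid_shape
    x = (np.arange(nx) + 0.5) * scene.pixel_size
    y = (np.arange(ny) + 0.5) * scene.pixel_size
    X, Y = np.meshgrid(x, y)
    tx = np.zeros((ny, nx))
    ty = np.zeros((ny, nx))
    for ip, p in enumerate(scene.patches):
        cx, cy = p.center_um
        if not (0 <= cx <= nx * scene.pixel_size and 0 <= cy <= ny * scene.pixel_size):
            raise ValueError(
                f"patch {ip} centre {p.center_um} outside the "
                f"{nx * scene.pixel_size} x {ny * scene.pixel_size} um grid"
            )
        g = p.amplitude_pa * np.exp(
            -((X - cx) ** 2 + (Y - cy) ** 2) / (2.0 * p.width_um**2)
        )
        tx += g * p.direction[0]
        ty += g * p.direction[1]
    tx_raw, ty_raw = tx.copy(), ty.copy()
    tx = tx - tx.mean()
    ty = ty - ty.mean()
    return TractionField(
        x=x, y=y, tx=tx, ty=ty, pixel_size=scene.pixel_size,
        meta={"scene": scene, "tx_raw": tx_raw, "ty_raw": ty_raw},
    )


def forward_displacement(
    traction: TractionField,
    substrate: SubstrateModel = DEFAULT_SUBSTRATE,
    pad_factor: int = 2,
) -> DisplacementField:
    """Substrate surface displacement induced by a traction field (um).

    Exact discrete half-space convolution (see
    :func:`corneomech.elastic.forward_displacement_arrays`); linear in the
    traction.
    """
    ux, uy = forward_displacement_arrays(
        traction.tx, traction.ty, traction.pixel_size, substrate, pad_factor
    )
    f = DisplacementField.from_dense(ux, uy, traction.pixel_size)
    f.x = traction.x.copy()
    f.y = traction.y.copy()
    f.meta["substrate"] = substrate
    return f


def render_bead_images(
    displacement: DisplacementField,
    bead_density: float = 0.05,  # beads per px^2
    psf_sigma_um: float | None = None,
    noise_sigma: float = 0.0,
    background: float = 0.0,
    peak_intensity: float = 1000.0,
    seed: int = 0,
) -> BeadImagePair:
    """Render a pre/post fluorescent bead image pair from a displacement field.

    Beads are placed uniformly at random over the field of view; in the post
    image each bead is moved by the displacement interpolated at its
    position.  Each bead is drawn as a symmetric Gaussian spot (default PSF
    sigma: 1.5 image pixels); Gaussian read noise and a constant background
    are added, and intensities clipped at zero.  Deterministic per seed.
    """
    if bead_density <= 0:
        raise ValueError("bead density must be positive")
    ps = displacement.pixel_size
    if psf_sigma_um is None:
        psf_sigma_um = 1.5 * ps
    if psf_sigma_um <= 0:
        raise ValueError("psf_sigma must be positive")
    ny, nx = displacement.shape
    width_um = nx * ps
    height_um = ny * ps
    max_disp = float(np.hypot(displacement.u, displacement.v).max())
    if max_disp > 0.25 * min(width_um, height_um):
        warnings.warn(
            "displacements exceed a quarter of the field of view; "
            "window correlation will fail",
            stacklevel=2,
        )

    rng = np.random.default_rng(seed)
    n_beads = rng.poisson(bead_density * nx * ny)
    pos = rng.uniform([0.0, 0.0], [width_um, height_um], size=(n_beads, 2))

    interp_u = RegularGridInterpolator(
        (displacement.y, displacement.x), displacement.u,
        bounds_error=False, fill_value=None,
    )
    interp_v = RegularGridInterpolator(
        (displacement.y, displacement.x), displacement.v,
        bounds_error=False, fill_value=None,
    )
    disp = np.column_stack(
        [interp_u(pos[:, ::-1]), interp_v(pos[:, ::-1])]
    )
    pos_post = pos + disp

    def paint(points: np.ndarray) -> np.ndarray:
        img = np.zeros((ny, nx))
        sig_px = psf_sigma_um / ps
        half = int(np.ceil(4 * sig_px))
        for px, py in points:
            cx, cy = px / ps - 0.5, py / ps - 0.5  # pixel-centre coordinates
            i0, j0 = int(round(cx)), int(round(cy))
            i_lo, i_hi = max(i0 - half, 0), min(i0 + half + 1, nx)
            j_lo, j_hi = max(j0 - half, 0), min(j0 + half + 1, ny)
            if i_lo >= i_hi or j_lo >= j_hi:
                continue
            ii = np.arange(i_lo, i_hi)
            jj = np.arange(j_lo, j_hi)
            gx = np.exp(-((ii - cx) ** 2) / (2 * sig_px**2))
            gy = np.exp(-((jj - cy) ** 2) / (2 * sig_px**2))
            img[j_lo:j_hi, i_lo:i_hi] += peak_intensity * gy[:, None] * gx[None, :]
        return img

    pre = paint(pos) + background
    post = paint(pos_post) + background
    if noise_sigma > 0:
        pre = pre + rng.normal(0.0, noise_sigma, pre.shape)
        post = post + rng.normal(0.0, noise_sigma, post.shape)
    return BeadImagePair(
        image_pre=np.clip(pre, 0.0, None),
        image_post=np.clip(post, 0.0, None),
        pixel_size=ps,
        bead_positions_true=pos,
        noise_model=(noise_sigma, background),
        meta={"seed": seed, "bead_density": bead_density, "psf_sigma_um": psf_sigma_um},
    )


def simulate_force_curve(spec: SyntheticCurveSpec) -> ForceCurve:
    """Generate one AFM approach/withdraw cycle obeying the Hertz cone law.

    Pre-contact deflection is the baseline (slope times Z plus force noise);
    post-contact the deflection solves the implicit contact relation
    d = (A/k) * ((Z - z0) - d)^2 exactly, so the reconstructed indentation
    delta = Z - d reproduces the Hertz law with ``e_true_pa``.  The withdraw
    segment retraces the same elastic law (no adhesion or hysteresis).
    """
    params = HertzModelParams(spec.half_angle_deg, spec.poisson_ratio)
    dz = spec.speed_nm_s / spec.rate_hz
    n = spec.n_approach_samples
    z_app = np.arange(n) * dz
    z = np.concatenate([z_app, z_app[-2::-1]])

    c = spec.e_true_pa * params.prefactor / spec.spring_constant  # per nm
    s = np.clip(z - spec.contact_z0_nm, 0.0, None)
    d_elastic = np.where(
        s > 0,
        ((2.0 * c * s + 1.0) - np.sqrt(4.0 * c * s + 1.0)) / (2.0 * c),
        0.0,
    )
    d = d_elastic + spec.baseline_slope * z
    if spec.noise_sigma_nn > 0:
        rng = np.random.default_rng(spec.seed)
        d = d + rng.normal(0.0, spec.noise_sigma_nn / spec.spring_constant, d.shape)
    return ForceCurve(
        z=z,
        d=d,
        spring_constant=spec.spring_constant,
        meta={
            "spec": spec,
            "apex_index": n - 1,
            "sampling_rate_hz": spec.rate_hz,
            "speed_nm_s": spec.speed_nm_s,
        },
    )


def _ramanujan_perimeter(a: float, b: float) -> float:
    h = ((a - b) / (a + b)) ** 2
    return float(np.pi * (a + b) * (1.0 + 3.0 * h / (10.0 + np.sqrt(4.0 - 3.0 * h))))


def make_cell_mask(
    shape: str,
    grid_shape: tuple[int, int],
    pixel_size: float = 1.0,
    seed: int = 0,
    **params,
) -> CellMask:
    """Rasterize a cell-shaped mask with analytic geometry where available.

    Families: ``disc`` (radius_um), ``ellipse`` (a_um, b_um; Ramanujan
    perimeter, flagged approximate), ``superellipse`` (a_um, b_um, n),
    ``blob`` (radius_um plus seeded Fourier boundary perturbations; no
    closed form).  Shapes are centred on the grid.
    """
    ny, nx = grid_shape
    x = (np.arange(nx) + 0.5 - nx / 2.0) * pixel_size
    y = (np.arange(ny) + 0.5 - ny / 2.0) * pixel_size
    X, Y = np.meshgrid(x, y)
    area = perim = None
    approx = False
    if shape == "disc":
        r = params["radius_um"]
        if r <= 0:
            raise ValueError("degenerate disc: radius must be positive")
        m = X**2 + Y**2 <= r**2
        area, perim = np.pi * r**2, 2.0 * np.pi * r
    elif shape == "ellipse":
        a, b = params["a_um"], params["b_um"]
        if a <= 0 or b <= 0:
            raise ValueError("degenerate ellipse: axes must be positive")
        m = (X / a) ** 2 + (Y / b) ** 2 <= 1.0
        area, perim = np.pi * a * b, _ramanujan_perimeter(a, b)
        approx = True
    elif shape == "superellipse":
        a, b, n = params["a_um"], params["b_um"], params.get("n", 4.0)
        if a <= 0 or b <= 0 or n <= 0:
            raise ValueError("degenerate superellipse parameters")
        m = np.abs(X / a) ** n + np.abs(Y / b) ** n <= 1.0
    elif shape == "blob":
        r0 = params["radius_um"]
        if r0 <= 0:
            raise ValueError("degenerate blob: radius must be positive")
        n_modes = params.get("n_modes", 5)
        rough = params.get("roughness", 0.15)
        rng = np.random.default_rng(seed)
        amps = rng.normal(0.0, rough / np.sqrt(n_modes), n_modes)
        phases = rng.uniform(0.0, 2.0 * np.pi, n_modes)
        theta = np.arctan2(Y, X)
        rb = r0 * (
            1.0
            + sum(
                amps[i] * np.cos((i + 2) * theta + phases[i]) for i in range(n_modes)
            )
        )
        m = np.hypot(X, Y) <= rb
    else:
        raise ValueError(f"unknown shape family {shape!r}")
    if not m.any():
        raise ValueError("degenerate parameters produced an empty mask")
    return CellMask(
        mask=m,
        pixel_size=pixel_size,
        area_analytic=area,
        perimeter_analytic=perim,
        perimeter_is_approximate=approx,
        meta={"shape": shape, "seed": seed, **params},
    )


def simulate_cohort(spec: SyntheticCohortSpec) -> pd.DataFrame:
    """Draw a per-subject cohort table with exposure metadata.

    One row per synthetic subject: ``subject_id``, ``group``, ``daily_pm25``
    (drawn uniformly within the group's range) and one column per
    biomechanical parameter, drawn normally with the group's mean and SD.
    """
    rng = np.random.default_rng(spec.seed)
    frames = []
    offset = 0
    for group, n in spec.n_per_group.items():
        lo, hi = spec.pm25_ranges[group]
        rows = {
            "subject_id": [f"S{offset + i:04d}" for i in range(n)],
            "group": group,
            "daily_pm25": rng.uniform(lo, hi, n),
        }
        for pname, means in spec.parameter_means.items():
            sd = spec.parameter_sds.get(pname, {}).get(group, 0.0)
            rows[pname] = rng.normal(means[group], sd, n) if sd > 0 else np.full(
                n, means[group]
            )
        frames.append(pd.DataFrame(rows))
        offset += n
    return pd.concat(frames, ignore_index=True)


def standard_dipole_scene(
    n: int = 256,
    pixel_size: float = 0.2,
    amplitude_pa: float = 300.0,
    width_um: float = 5.0,
    separation_um: float = 24.0,
    seed: int = 0,
) -> TractionScene:
    """The package's reference benchmark: a contractile traction dipole.

    Two equal Gaussian patches pulling toward each other (as a contractile
    cell pulls its substrate inward), centred on the field of view.  With
    the defaults the peak substrate displacement on the default 10 kPa gel
    is about 0.5 um (~2.5 image pixels), typical of soft-gel TFM.
    """
    cx = n * pixel_size / 2.0
    cy = n * pixel_size / 2.0
    half = separation_um / 2.0
    return TractionScene(
        grid_shape=(n, n),
        pixel_size=pixel_size,
        patches=(
            TractionPatch((cx - half, cy), amplitude_pa, width_um, (1.0, 0.0)),
            TractionPatch((cx + half, cy), amplitude_pa, width_um, (-1.0, 0.0)),
        ),
        seed=seed,
    )
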