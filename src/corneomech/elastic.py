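"""Surface elasticity of a semi-infinite half-space.

Single source of truth for the tangential Boussinesq/Cerruti surface Green's
function used by both the forward problem (traction -> substrate surface
displacement) and the inverse problem (FTTC, displacement -> traction).

Two representations of the Green tensor are provided:

``greens_tensor_fourier``
    The analytic per-wavevector tensor of the continuum half-space solution.
``discrete_greens_tensor_fourier``
    The DFT of the real-space kernel integrated analytically over each square
    grid cell.  Multiplying by this tensor performs the *exact* discrete
    convolution of a pixel-constant traction field with the continuum
    kernel, so the forward solution carries no near-field sampling error
    (the analytic k-space tensor, sampled at the grid wavevectors, loses a
    few percent within several pixels of a concentrated load because of the
    Nyquist truncation of its slowly decaying 1/k tail).

The discrete tensor is the default for both directions, which keeps the
forward and inverse maps exact mutual inverses per wavevector.

Conventions
-----------
* In-plane positions and displacements in micrometres, tractions and elastic
  moduli in pascals.  Wavevectors are angular (rad/um).
* Arrays are indexed ``[iy, ix]`` with y increasing with the row index, i.e.
  the array origin is the lower-left corner of the physical field of view.
* Only the tangential 2x2 block of the half-space Green tensor is used: the
  standard 2D traction-force-microscopy approximation that neglects normal
  tractions and out-of-plane displacement.

For a tangential point force ``F`` (Pa*um^2) at the origin the surface
displacement is

    u_i(r) = (1 + nu) / (pi E r^3) * [(1 - nu) r^2 delta_ij + nu x_i x_j] F_j

whose continuum Fourier transform is

    G(k) = 2 (1 + nu) / (E k^3) * [[(1-nu) k^2 + nu ky^2,  -nu kx ky],
                                   [-nu kx ky,  (1-nu) k^2 + nu kx^2]].

Both forms are regular at nu = 1/2 (incompressible limit): no (1 - 2 nu)
division appears in the tangential block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SubstrateModel",
    "greens_tensor_fourier",
    "discrete_greens_tensor_fourier",
    "cerruti_point_displacement",
    "forward_displacement_arrays",
]


@dataclass(frozen=True)
class SubstrateModel:
    """Linear-elastic semi-infinite substrate (e.g. a polyacrylamide gel).

    Parameters
    ----------
    youngs_modulus :
        Young's modulus E in Pa.  Must be positive.
    poisson_ratio :
        Poisson's ratio nu, in [0, 0.5]; 0.5 is the incompressible limit and
        is fully supported.
    """

    youngs_modulus: float
    poisson_ratio: float = 0.45
    geometry: str = field(default="semi-infinite half-space")

    def __post_init__(self) -> None:
        if not np.isfinite(self.youngs_modulus) or self.youngs_modulus <= 0:
            raise ValueError(f"Young's modulus must be positive, got {self.youngs_modulus}")
        if not (0.0 <= self.poisson_ratio <= 0.5):
            raise ValueError(f"Poisson ratio must be in [0, 0.5], got {self.poisson_ratio}")
        if self.geometry != "semi-infinite half-space":
            raise ValueError("only the semi-infinite half-space geometry is supported")


def greens_tensor_fourier(
    kx: np.ndarray, ky: np.ndarray, substrate: SubstrateModel
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Analytic tangential Green tensor at angular wavevectors (kx, ky).

    Returns ``(Gxx, Gxy, Gyy)`` in um/Pa.  The k = 0 entry is set to zero:
    the zero mode (rigid in-plane translation) carries no elastic information
    and is handled explicitly by the solvers.
    """
    E = substrate.youngs_modulus
    nu = substrate.poisson_ratio
    k = np.hypot(kx, ky)
    with np.errstate(divide="ignore", invalid="ignore"):
        pref = 2.0 * (1.0 + nu) / (E * k**3)
        gxx = pref * ((1.0 - nu) * k**2 + nu * ky**2)
        gyy = pref * ((1.0 - nu) * k**2 + nu * kx**2)
        gxy = -pref * nu * kx * ky
    zero = k == 0
    for g in (gxx, gxy, gyy):
        g[zero] = 0.0
    return gxx, gxy, gyy


def cerruti_point_displacement(
    x: np.ndarray,
    y: np.ndarray,
    force: tuple[float, float],
    substrate: SubstrateModel,
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form surface displacement of a tangential point force.

    ``force`` is (Fx, Fy) in Pa*um^2 applied at the origin; positions in um.
    This is the independent analytic oracle for the FFT forward solver.
    """
    E = substrate.youngs_modulus
    nu = substrate.poisson_ratio
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    r = np.hypot(x, y)
    with np.errstate(divide="ignore", invalid="ignore"):
        pref = (1.0 + nu) / (np.pi * E * r**3)
        gxx = pref * ((1.0 - nu) * r**2 + nu * x**2)
        gyy = pref * ((1.0 - nu) * r**2 + nu * y**2)
        gxy = pref * nu * x * y
    fx, fy = force
    ux = gxx * fx + gxy * fy
    uy = gxy * fx + gyy * fy
    return ux, uy


def _stable_log_a_plus_r(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """log(a + sqrt(a^2 + b^2)), stable for a < 0 where cancellation occurs.

    For a < 0, a + r = b^2 / (r - a).  Entries with a <= 0 and b == 0 return
    0; callers only use them multiplied by a coefficient that vanishes there.
    """
    r = np.hypot(a, b)
    out = np.empty_like(r)
    pos = a >= 0
    np.log(a + r, where=pos, out=out)
    neg = ~pos
    with np.errstate(divide="ignore", invalid="ignore"):
        np.copyto(out, np.log(b**2) - np.log(r - a), where=neg)
    out[(b == 0) & (a <= 0)] = 0.0
    return out


def _corner_eval(f, x1, x2, y1, y2):
    return f(x2, y2) - f(x1, y2) - f(x2, y1) + f(x1, y1)


def _pixel_integrated_kernel(
    dx: np.ndarray, dy: np.ndarray, pixel_size: float, substrate: SubstrateModel
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Boussinesq tangential kernel integrated over an h x h cell at (dx, dy).

    Returns (Kxx, Kxy, Kyy) in um/Pa per unit traction on one cell, i.e. the
    displacement at offset (dx, dy) from the centre of a cell carrying unit
    traction.  Uses the exact antiderivatives

        I1 = integral 1/r      -> x log(y+r) + y log(x+r)
        I2 = integral x^2/r^3  =  I1 - corner[x log(y+r)]
        I3 = integral y^2/r^3  =  I1 - corner[y log(x+r)]
        I4 = integral xy/r^3   -> corner[-r]
    """
    h = pixel_size / 2.0
    x1, x2 = dx - h, dx + h
    y1, y2 = dy - h, dy + h

    def f_xlog(x, y):
        return x * _stable_log_a_plus_r(y, x)

    def f_ylog(x, y):
        return y * _stable_log_a_plus_r(x, y)

    def f_negr(x, y):
        return -np.hypot(x, y)

    c_xlog = _corner_eval(f_xlog, x1, x2, y1, y2)
    c_ylog = _corner_eval(f_ylog, x1, x2, y1, y2)
    i1 = c_xlog + c_ylog
    i2 = i1 - c_xlog
    i3 = i1 - c_ylog
    i4 = _corner_eval(f_negr, x1, x2, y1, y2)

    E = substrate.youngs_modulus
    nu = substrate.poisson_ratio
    pref = (1.0 + nu) / (np.pi * E)
    kxx = pref * ((1.0 - nu) * i1 + nu * i2)
    kyy = pref * ((1.0 - nu) * i1 + nu * i3)
    kxy = pref * nu * i4
    return kxx, kxy, kyy


def discrete_greens_tensor_fourier(
    shape: tuple[int, int], pixel_size: float, substrate: SubstrateModel
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """DFT of the pixel-integrated real-space Green kernel on ``shape``.

    The kernel is laid out in FFT wrap-around order (offset 0 at index 0,
    negative offsets at the top end), so multiplying ``fft2(t)`` by the
    returned arrays and inverse-transforming performs the discrete circular
    convolution with the exact cell-integrated continuum kernel.
    """
    ny, nx = shape
    dx = np.fft.fftfreq(nx, d=1.0 / nx) * pixel_size  # 0, h, ..., -h
    dy = np.fft.fftfreq(ny, d=1.0 / ny) * pixel_size
    DX, DY = np.meshgrid(dx, dy)
    kxx, kxy, kyy = _pixel_integrated_kernel(DX, DY, pixel_size, substrate)
    return np.fft.fft2(kxx), np.fft.fft2(kxy), np.fft.fft2(kyy)


def forward_displacement_arrays(
    tx: np.ndarray,
    ty: np.ndarray,
    pixel_size: float,
    substrate: SubstrateModel,
    pad_factor: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """Surface displacement (um) induced by a gridded traction field (Pa).

    The traction grid is zero-padded by ``pad_factor`` and convolved with the
    pixel-integrated half-space kernel by per-wavevector multiplication.
    With ``pad_factor >= 2`` every source-target separation that survives the
    final crop is within the non-wrapped part of the kernel, so the result is
    the exact aperiodic discrete convolution: the true half-space solution
    for a pixel-constant traction field, with no periodicity artefact.  At
    ``pad_factor = 1`` the solution is that of the periodically repeated
    scene (useful for exact round-trip checks against the inverse solver).
    """
    tx = np.asarray(tx, dtype=float)
    ty = np.asarray(ty, dtype=float)
    if tx.shape != ty.shape or tx.ndim != 2:
        raise ValueError("tx and ty must be congruent 2D arrays")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    if pad_factor < 1:
        raise ValueError("pad_factor must be >= 1")
    ny, nx = tx.shape
    pny, pnx = ny * pad_factor, nx * pad_factor
    tpx = np.zeros((pny, pnx))
    tpy = np.zeros((pny, pnx))
    tpx[:ny, :nx] = tx
    tpy[:ny, :nx] = ty

    gxx, gxy, gyy = discrete_greens_tensor_fourier((pny, pnx), pixel_size, substrate)
    ftx = np.fft.fft2(tpx)
    fty = np.fft.fft2(tpy)
    ux = np.fft.ifft2(gxx * ftx + gxy * fty).real[:ny, :nx]
    uy = np.fft.ifft2(gxy * ftx + gyy * fty).real[:ny, :nx]
    return ux, uy
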