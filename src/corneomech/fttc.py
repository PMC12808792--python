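"""Fourier-transform traction cytometry: displacement -> traction.

Inverts the substrate surface displacement field for the shear stress the
cell exerts on the gel, by per-wavevector inversion of the tangential
half-space Green tensor (optionally Tikhonov-regularized).  The tensor used
is the DFT of the cell-integrated real-space Boussinesq kernel (see
:mod:`corneomech.elastic`), the exact adjoint of the package's forward
solver, so forward followed by inverse on the same periodic grid is the
identity up to the zero mode.

The zero-frequency traction is always set to zero: a rigid in-plane
translation of the substrate carries no traction information, and a cell in
mechanical equilibrium exerts zero net force.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dic import DisplacementField
from .elastic import SubstrateModel, discrete_greens_tensor_fourier
from .morpho import CellMask

__all__ = ["TractionField", "fttc_invert", "net_force", "traction_summary", "suggest_lambda"]


@dataclass
class TractionField:
    """Gridded planar traction (shear stress on the substrate surface), Pa.

    ``x``/``y`` are node coordinates in um; ``pixel_size`` is the node
    spacing.  ``regularization`` records the dimensionless Tikhonov lambda
    used in the inversion (0 for a plain inverse, None for ground-truth
    fields from the generator).
    """

    x: np.ndarray
    y: np.ndarray
    tx: np.ndarray
    ty: np.ndarray
    pixel_size: float
    substrate: SubstrateModel | None = None
    regularization: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.tx = np.asarray(self.tx, dtype=float)
        self.ty = np.asarray(self.ty, dtype=float)
        shape = (self.y.size, self.x.size)
        if self.tx.shape != shape or self.ty.shape != shape:
            raise ValueError("tx/ty must have shape (len(y), len(x))")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.regularization is not None and self.regularization < 0:
            raise ValueError("regularization must be >= 0")

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.tx, self.ty)

    @property
    def shape(self) -> tuple[int, int]:
        return self.tx.shape


def _spectral_inverse(
    u: np.ndarray,
    v: np.ndarray,
    spacing: float,
    substrate: SubstrateModel,
    lam: float,
    pad_factor: int,
    boundary: str,
) -> tuple[np.ndarray, np.ndarray]:
    """One per-wavevector inversion pass of the padded displacement field."""
    ny, nx = u.shape
    if pad_factor > 1:
        qy, qx = ny * (pad_factor - 1) // 2, nx * (pad_factor - 1) // 2
        mode = {"mirror": "symmetric", "zero": "constant"}[boundary]
        up = np.pad(u, ((qy, qy), (qx, qx)), mode=mode)
        vp = np.pad(v, ((qy, qy), (qx, qx)), mode=mode)
    else:
        qy = qx = 0
        up, vp = u, v

    gxx, gxy, gyy = discrete_greens_tensor_fourier(up.shape, spacing, substrate)
    fu = np.fft.fft2(up)
    fv = np.fft.fft2(vp)
    if lam == 0.0:
        det = gxx * gyy - gxy * gxy
        ftx = (gyy * fu - gxy * fv) / det
        fty = (-gxy * fu + gxx * fv) / det
    else:
        # (G'G + (lam*g0)^2 I)^-1 G', with G the 2x2 tensor per wavevector
        g0 = float(max(np.abs(gxx).max(), np.abs(gxy).max(), np.abs(gyy).max()))
        mu = (lam * g0) ** 2
        hxx = np.conj(gxx) * gxx + np.conj(gxy) * gxy + mu
        hxy = np.conj(gxx) * gxy + np.conj(gxy) * gyy
        hyy = np.conj(gxy) * gxy + np.conj(gyy) * gyy + mu
        hdet = hxx * hyy - hxy * np.conj(hxy)
        bx = np.conj(gxx) * fu + np.conj(gxy) * fv
        by = np.conj(gxy) * fu + np.conj(gyy) * fv
        ftx = (hyy * bx - hxy * by) / hdet
        fty = (-np.conj(hxy) * bx + hxx * by) / hdet
    ftx[0, 0] = 0.0
    fty[0, 0] = 0.0
    tx = np.fft.ifft2(ftx).real
    ty = np.fft.ifft2(fty).real
    return tx[qy : qy + ny, qx : qx + nx], ty[qy : qy + ny, qx : qx + nx]


def fttc_invert(
    field: DisplacementField,
    substrate: SubstrateModel,
    lam: float = 0.0,
    pad_factor: int = 2,
    boundary: str = "mirror",
    refine_iterations: int = 5,
) -> TractionField:
    """Recover traction from a complete displacement field.

    Per wavevector the 2x2 Green tensor G satisfies u = G t; with lam = 0
    the tensor is inverted directly, otherwise the Tikhonov-regularized
    inverse (G'G + (lam*g0)^2 I)^-1 G' is used, where g0 is the largest
    Green-tensor norm on the grid, making ``lam`` dimensionless.  The
    zero-frequency traction is set to zero: a rigid in-plane translation
    carries no traction information.

    The measured field of view is aperiodic while the FFT assumes
    periodicity, so the field is padded by ``pad_factor`` before the
    transform (``boundary="mirror"``: symmetric extension, continuous at
    the seam; ``"zero"``: plain zero padding) and cropped after.  Because a
    cropped-and-repadded field is never exactly the half-space solution on
    the padded grid, the spectral inverse at lam = 0 is additionally
    refined by ``refine_iterations`` Richardson steps against the exact
    aperiodic forward operator (each step inverts the forward-model
    residual and converges geometrically to the traction whose half-space
    displacement matches the data on the field of view).  Refinement is
    skipped when lam > 0: the regularized solution is the spectral Tikhonov
    inverse itself.  ``pad_factor=1`` treats the data as exactly periodic
    (the exact inverse of the forward solver at equal padding, useful for
    round-trip checks).
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if boundary not in ("mirror", "zero"):
        raise ValueError("boundary must be 'mirror' or 'zero'")
    if not field.valid.all():
        raise ValueError("displacement field has invalid nodes; interpolate gaps first")
    if np.isnan(field.u).any() or np.isnan(field.v).any():
        raise ValueError("NaNs in displacement field")
    spacing = field.spacing  # raises on non-uniform grids

    tx, ty = _spectral_inverse(
        field.u, field.v, spacing, substrate, lam, pad_factor, boundary
    )
    if lam == 0.0 and pad_factor > 1:
        from .elastic import forward_displacement_arrays

        for _ in range(refine_iterations):
            ru, rv = forward_displacement_arrays(tx, ty, spacing, substrate, 2)
            dtx, dty = _spectral_inverse(
                field.u - ru, field.v - rv, spacing, substrate, 0.0, pad_factor, boundary
            )
            tx = tx + dtx
            ty = ty + dty
    return TractionField(
        x=field.x.copy(),
        y=field.y.copy(),
        tx=tx,
        ty=ty,
        pixel_size=spacing,
        substrate=substrate,
        regularization=lam,
        meta={
            "pad_factor": pad_factor,
            "boundary": boundary,
            "refine_iterations": refine_iterations if lam == 0.0 else 0,
        },
    )


def net_force(traction: TractionField) -> tuple[float, float]:
    """Area-weighted vector sum of the traction field, in nN.

    A cell in mechanical equilibrium exerts zero net force on its substrate;
    this is the standard physical sanity check on a recovered field.
    """
    area = traction.pixel_size**2  # um^2
    # Pa * um^2 = 1e-12 N = 1e-3 nN
    fx = float(traction.tx.sum() * area * 1e-3)
    fy = float(traction.ty.sum() * area * 1e-3)
    return fx, fy


def traction_summary(
    traction: TractionField,
    mask: CellMask | np.ndarray | None = None,
    displacement: DisplacementField | None = None,
) -> dict:
    """Scalar per-cell summaries of a traction field.

    Mean and RMS traction magnitude under the cell mask (the whole grid if
    no mask is given), net force, and — when the matching displacement field
    is supplied — the strain energy U = 1/2 sum(t . u) dA transferred to the
    substrate, in femtojoules.
    """
    if mask is None:
        m = np.ones(traction.shape, dtype=bool)
    else:
        m = mask.mask if isinstance(mask, CellMask) else np.asarray(mask, dtype=bool)
    if m.shape != traction.shape:
        raise ValueError("mask not congruent with the traction grid")
    if not m.any():
        raise ValueError("empty mask")
    mag = traction.magnitude[m]
    out = {
        "mean_traction_pa": float(mag.mean()),
        "rms_traction_pa": float(np.sqrt((mag**2).mean())),
        "max_traction_pa": float(mag.max()),
        "net_force_nn": net_force(traction),
        "n_nodes": int(m.sum()),
    }
    if displacement is not None:
        if displacement.shape != traction.shape:
            raise ValueError("displacement grid not congruent with traction grid")
        area = traction.pixel_size**2
        dot = traction.tx * displacement.u + traction.ty * displacement.v
        # Pa * um * um^2 = 1e-18 J = 1e-3 fJ
        out["strain_energy_fj"] = float(0.5 * dot.sum() * area * 1e-3)
    return out


def suggest_lambda(
    field: DisplacementField,
    substrate: SubstrateModel,
    lambdas: np.ndarray | None = None,
    pad_factor: int = 2,
) -> tuple[float, np.ndarray]:
    """L-curve corner heuristic for the Tikhonov parameter.

    Scans candidate lambdas, records (residual norm, solution norm) and
    returns the lambda maximizing the curvature of the log-log L-curve,
    along with the scanned table ``(lam, residual, norm)``.
    """
    if lambdas is None:
        lambdas = np.logspace(-4, 0, 17)
    rows = []
    for lam in lambdas:
        t = fttc_invert(field, substrate, lam=float(lam), pad_factor=pad_factor)
        from .synthetic import forward_displacement  # local import to avoid a cycle

        u_model = forward_displacement(t, substrate, pad_factor=pad_factor)
        resid = np.sqrt(
            ((u_model.u - field.u) ** 2 + (u_model.v - field.v) ** 2).mean()
        )
        norm = np.sqrt((t.tx**2 + t.ty**2).mean())
        rows.append((float(lam), float(resid), float(norm)))
    tab = np.array(rows)
    lr = np.log10(tab[:, 1] + 1e-300)
    ln = np.log10(tab[:, 2] + 1e-300)
    # discrete curvature of the parametric curve (lr, ln)
    d1r, d1n = np.gradient(lr), np.gradient(ln)
    d2r, d2n = np.gradient(d1r), np.gradient(d1n)
    curv = (d1r * d2n - d1n * d2r) / (d1r**2 + d1n**2) ** 1.5
    best = int(np.nanargmax(curv[1:-1])) + 1
    return float(tab[best, 0]), tab
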