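"""In-plane stress recovery over the cell footprint (monolayer stress style).

The traction the cell exerts on the substrate is, by Newton's third law,
balanced by internal stress in the cell sheet.  Modelling the cell as a thin
plane-stress elastic sheet of unit reference thickness, mechanical
equilibrium

    div(sigma) + f = 0,      f = -t  (reaction to the traction t)

is solved over the cell mask with a stress-free boundary, i.e. the recovered
sheet stress satisfies div(sigma) = t inside the footprint.  The problem is
pure-Neumann; the three rigid-body modes (two translations, one rotation)
are removed by Lagrange constraints.  Because the load is an equilibrated
force balance, the stress field is statically determinate up to the sheet's
Poisson-driven redistribution: the reported summaries are insensitive to the
sheet's Young's modulus (which is therefore arbitrary, default 1 Pa) and
only weakly dependent on its Poisson ratio (default 0.5).

Discretization: bilinear quadrilateral (Q4) finite elements on the traction
grid, one element per grid cell, 2x2 Gauss integration; stresses evaluated
at element centres, so the stress grid is congruent with the traction grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.ndimage import binary_erosion, binary_fill_holes
from scipy.sparse.linalg import spsolve

from .fttc import TractionField
from .morpho import CellMask

__all__ = ["SheetParams", "StressField", "TensionSummary", "recover_stress", "mean_tension"]


@dataclass(frozen=True)
class SheetParams:
    """Constitutive constants of the model cell sheet (plane stress).

    The Young's modulus sets only the (unreported) displacement scale; the
    stress summaries are independent of it.
    """

    youngs_modulus: float = 1.0
    poisson_ratio: float = 0.5

    def __post_init__(self) -> None:
        if self.youngs_modulus <= 0:
            raise ValueError("sheet Young's modulus must be positive")
        if not 0 <= self.poisson_ratio < 1:
            raise ValueError("sheet Poisson ratio must be in [0, 1)")


@dataclass
class StressField:
    """Sheet-averaged in-plane stress tensor (Pa), zero outside the mask."""

    x: np.ndarray
    y: np.ndarray
    sxx: np.ndarray
    sxy: np.ndarray
    syy: np.ndarray
    mask: np.ndarray
    pixel_size: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shape = self.sxx.shape
        for name in ("sxy", "syy", "mask"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"{name} not congruent with sxx")

    def principal(self) -> tuple[np.ndarray, np.ndarray]:
        """Principal stresses (sigma1 >= sigma2) per node."""
        mean = 0.5 * (self.sxx + self.syy)
        rad = np.sqrt((0.5 * (self.sxx - self.syy)) ** 2 + self.sxy**2)
        return mean + rad, mean - rad


@dataclass(frozen=True)
class TensionSummary:
    """Scalar tension summaries over the cell footprint.

    ``mean_tension`` is the spatial mean of (sigma1 + sigma2)/2 (the
    monolayer-stress "tension" convention); ``mean_max_principal`` the mean
    of sigma1, which for quasi-1D stress states equals the mean axial
    tension; ``max_principal`` the maximum of sigma1 over the mask.
    """

    mean_tension_pa: float
    mean_max_principal_pa: float
    max_principal_pa: float


def _q4_stiffness(e: float, nu: float, h: float) -> np.ndarray:
    """Stiffness of a square bilinear plane-stress element of side h."""
    d = e / (1.0 - nu**2) * np.array(
        [[1.0, nu, 0.0], [nu, 1.0, 0.0], [0.0, 0.0, (1.0 - nu) / 2.0]]
    )
    gp = np.array([-1.0, 1.0]) / np.sqrt(3.0)
    ke = np.zeros((8, 8))
    for xi in gp:
        for eta in gp:
            dn_dxi = 0.25 * np.array(
                [-(1 - eta), (1 - eta), (1 + eta), -(1 + eta)]
            )
            dn_deta = 0.25 * np.array(
                [-(1 - xi), -(1 + xi), (1 + xi), (1 - xi)]
            )
            dn_dx = dn_dxi * 2.0 / h
            dn_dy = dn_deta * 2.0 / h
            b = np.zeros((3, 8))
            b[0, 0::2] = dn_dx
            b[1, 1::2] = dn_dy
            b[2, 0::2] = dn_dy
            b[2, 1::2] = dn_dx
            ke += b.T @ d @ b * (h / 2.0) ** 2
    return ke


def _q4_centre_b(h: float) -> np.ndarray:
    dn_dx = np.array([-1.0, 1.0, 1.0, -1.0]) / (2.0 * h)
    dn_dy = np.array([-1.0, -1.0, 1.0, 1.0]) / (2.0 * h)
    b = np.zeros((3, 8))
    b[0, 0::2] = dn_dx
    b[1, 1::2] = dn_dy
    b[2, 0::2] = dn_dy
    b[2, 1::2] = dn_dx
    return b


def recover_stress(
    traction: TractionField,
    mask: CellMask | np.ndarray,
    sheet: SheetParams | None = None,
    net_force_tolerance: float = 0.01,
) -> StressField:
    """Solve plane-stress equilibrium div(sigma) = t over the cell mask.

    The traction enters with reversed sign as an in-plane body load on the
    sheet (reaction to what the cell exerts on the substrate); the cell
    boundary is stress-free (natural boundary condition).  A non-equilibrated
    traction (net force above ``net_force_tolerance`` of sum|t| dA) triggers
    a warning and is balanced by removing the area-weighted mean vector over
    the mask before the solve.  The discrete interior equilibrium residual
    is reported in ``meta["equilibrium_residual_rms_rel"]``.
    """
    sheet = sheet or SheetParams()
    m = mask.mask if isinstance(mask, CellMask) else np.asarray(mask, dtype=bool)
    if m.shape != traction.shape:
        raise ValueError("mask not congruent with the traction grid")
    filled = binary_fill_holes(m)
    if (filled & ~m).any():
        warnings.warn("cell mask has holes; filling them for the solve", stacklevel=2)
        m = filled
    nelem = int(m.sum())
    if nelem < 16:
        raise ValueError(f"mask too small for a stress solve ({nelem} < 16 elements)")

    h = traction.pixel_size
    tx = traction.tx.copy()
    ty = traction.ty.copy()
    total = float(np.hypot(tx[m], ty[m]).sum() * h**2)
    netx = float(tx[m].sum() * h**2)
    nety = float(ty[m].sum() * h**2)
    removed = (0.0, 0.0)
    if total > 0 and np.hypot(netx, nety) > net_force_tolerance * total:
        warnings.warn(
            "traction is not force-balanced; removing the net force before the solve",
            stacklevel=2,
        )
        tx[m] -= netx / (nelem * h**2)
        ty[m] -= nety / (nelem * h**2)
        removed = (netx, nety)

    nrows, ncols = m.shape
    nnx = ncols + 1  # nodes per row

    def nid(j, i):
        return j * nnx + i

    ej, ei = np.nonzero(m)
    nodes = np.stack(
        [nid(ej, ei), nid(ej, ei + 1), nid(ej + 1, ei + 1), nid(ej + 1, ei)], axis=1
    )
    dofs = np.empty((nelem, 8), dtype=np.int64)
    dofs[:, 0::2] = 2 * nodes
    dofs[:, 1::2] = 2 * nodes + 1

    ke = _q4_stiffness(sheet.youngs_modulus, sheet.poisson_ratio, h)
    rows = np.repeat(dofs, 8, axis=1).ravel()
    cols = np.tile(dofs, (1, 8)).ravel()
    data = np.tile(ke.ravel(), nelem)
    ndof_full = 2 * (nrows + 1) * nnx
    k_full = sparse.coo_matrix((data, (rows, cols)), shape=(ndof_full, ndof_full)).tocsr()

    # consistent nodal load for constant body force f = -t on each element
    f_full = np.zeros(ndof_full)
    fe = h**2 / 4.0
    np.add.at(f_full, dofs[:, 0::2], (-tx[m] * fe)[:, None])
    np.add.at(f_full, dofs[:, 1::2], (-ty[m] * fe)[:, None])

    active_nodes = np.unique(nodes)
    active_dofs = np.empty(2 * active_nodes.size, dtype=np.int64)
    active_dofs[0::2] = 2 * active_nodes
    active_dofs[1::2] = 2 * active_nodes + 1
    k = k_full[active_dofs][:, active_dofs]
    f = f_full[active_dofs]

    # rigid-body removal: mean u = mean v = mean rotation = 0 (Lagrange)
    node_j, node_i = np.divmod(active_nodes, nnx)
    xn = (node_i - node_i.mean()) * h
    yn = (node_j - node_j.mean()) * h
    na = active_nodes.size
    c = sparse.lil_matrix((3, 2 * na))
    c[0, 0::2] = 1.0
    c[1, 1::2] = 1.0
    c[2, 0::2] = -yn
    c[2, 1::2] = xn
    c = c.tocsr()
    kkt = sparse.bmat([[k, c.T], [c, None]], format="csc")
    rhs = np.concatenate([f, np.zeros(3)])
    sol = spsolve(kkt, rhs)
    u_active = sol[: 2 * na]

    u_full = np.zeros(ndof_full)
    u_full[active_dofs] = u_active
    bc = _q4_centre_b(h)
    d = sheet.youngs_modulus / (1.0 - sheet.poisson_ratio**2) * np.array(
        [[1.0, sheet.poisson_ratio, 0.0],
         [sheet.poisson_ratio, 1.0, 0.0],
         [0.0, 0.0, (1.0 - sheet.poisson_ratio) / 2.0]]
    )
    ue = u_full[dofs]  # (nelem, 8)
    se = ue @ (d @ bc).T  # (nelem, 3): sxx, syy, sxy
    sxx = np.zeros(m.shape)
    syy = np.zeros(m.shape)
    sxy = np.zeros(m.shape)
    sxx[m] = se[:, 0]
    syy[m] = se[:, 1]
    sxy[m] = se[:, 2]

    resid = _equilibrium_residual(sxx, sxy, syy, tx, ty, m, h)
    return StressField(
        x=traction.x.copy(),
        y=traction.y.copy(),
        sxx=sxx,
        sxy=sxy,
        syy=syy,
        mask=m,
        pixel_size=h,
        meta={
            "equilibrium_residual_rms_rel": resid,
            "net_force_removed_nn": (removed[0] * 1e-3, removed[1] * 1e-3),
            "sheet": sheet,
        },
    )


def _equilibrium_residual(sxx, sxy, syy, tx, ty, m, h) -> float:
    """RMS of (div(sigma) - t) over interior elements, relative to RMS |t|."""
    interior = binary_erosion(m)
    interior[[0, -1], :] = False
    interior[:, [0, -1]] = False
    if not interior.any():
        return float("nan")
    div_x = np.gradient(sxx, h, axis=1) + np.gradient(sxy, h, axis=0)
    div_y = np.gradient(sxy, h, axis=1) + np.gradient(syy, h, axis=0)
    rx = div_x[interior] - tx[interior]
    ry = div_y[interior] - ty[interior]
    t_rms = np.sqrt((tx[m] ** 2 + ty[m] ** 2).mean())
    if t_rms == 0:
        return 0.0 if np.allclose([rx, ry], 0) else float("inf")
    return float(np.sqrt((rx**2 + ry**2).mean()) / t_rms)


def mean_tension(stress: StressField) -> TensionSummary:
    """Tension summaries from the principal stresses over the mask."""
    if not stress.mask.any():
        raise ValueError("empty mask")
    s1, s2 = stress.principal()
    m = stress.mask
    return TensionSummary(
        mean_tension_pa=float((0.5 * (s1 + s2))[m].mean()),
        mean_max_principal_pa=float(s1[m].mean()),
        max_principal_pa=float(s1[m].max()),
    )
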