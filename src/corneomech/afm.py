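"""AFM force-curve processing and Hertz conical-indenter fitting.

Estimates the cortical Young's modulus of a cell from force-indentation
curves acquired with a soft cantilever.  The contact model is the Hertz
solution for a rigid cone of semi-included angle theta indenting an
incompressible elastic half-space:

    F = E * tan(theta) / (sqrt(2) * (1 - nu^2)) * delta^2

with the indentation depth defined as delta = Z - d, the difference between
piezo extension Z and cantilever deflection d (both in nm after sensitivity
calibration); force follows from the spring constant, F = k * d.

Processing protocol: only the approach segment is used; the deflection
baseline is removed by a linear fit to the pre-contact samples; the contact
point is estimated (several methods, see :func:`detect_contact_point`); the
modulus is fit by least squares over the indentation window
0 <= delta <= ``max_fit_depth`` (600 nm by default).  Because the model is
linear in E the windowed fit is closed-form; the contact point can
optionally be refined by minimizing the full-curve piecewise residual.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "ForceCurve",
    "HertzModelParams",
    "HertzFitResult",
    "CellModulus",
    "ContactNotFoundError",
    "calibrate_deflection",
    "split_segments",
    "correct_baseline",
    "detect_contact_point",
    "compute_indentation",
    "hertz_force",
    "fit_hertz",
    "process_curve",
    "aggregate_cell_modulus",
]

DEFAULT_SPRING_CONSTANT = 0.08  # N/m, soft pyramidal-tip cantilever


class ContactNotFoundError(RuntimeError):
    """Raised when no tip-sample contact can be located in a curve."""


@dataclass
class ForceCurve:
    """One force curve: piezo extension Z and calibrated deflection d, in nm.

    ``spring_constant`` is in N/m, so force in nN is simply ``k * d`` with d
    in nm.  ``meta`` carries acquisition settings (sampling rate, speed) and,
    for synthetic curves, the ground-truth parameters.
    """

    z: np.ndarray
    d: np.ndarray
    spring_constant: float = DEFAULT_SPRING_CONSTANT
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.d = np.asarray(self.d, dtype=float)
        if self.z.shape != self.d.shape or self.z.ndim != 1:
            raise ValueError("z and d must be congruent 1D arrays")
        if self.z.size < 10:
            raise ValueError("curve must contain at least 10 samples")
        if self.spring_constant <= 0:
            raise ValueError("spring constant must be positive")

    @property
    def force_nn(self) -> np.ndarray:
        """Cantilever force in nN (k [N/m] * d [nm])."""
        return self.spring_constant * self.d


@dataclass(frozen=True)
class HertzModelParams:
    """Cone half-angle (deg), Poisson ratio and indentation fit window (nm).

    nu defaults to 0.5 (incompressible cytoplasm) and is never fitted: it is
    unidentifiable jointly with E in this model.  theta defaults to 35 deg.
    """

    half_angle_deg: float = 35.0
    poisson_ratio: float = 0.5
    max_fit_depth_nm: float = 600.0

    def __post_init__(self) -> None:
        if not 0 < self.half_angle_deg < 90:
            raise ValueError("half angle must be in (0, 90) degrees")
        if not 0 <= self.poisson_ratio <= 0.5:
            raise ValueError("Poisson ratio must be in [0, 0.5]")
        if self.max_fit_depth_nm <= 0:
            raise ValueError("max_fit_depth_nm must be positive")

    @property
    def prefactor(self) -> float:
        """Geometric prefactor: F[nN] = E[Pa] * prefactor * delta[nm]^2."""
        return (
            np.tan(np.radians(self.half_angle_deg))
            / (np.sqrt(2.0) * (1.0 - self.poisson_ratio**2))
            * 1e-9
        )


@dataclass(frozen=True)
class HertzFitResult:
    modulus_pa: float
    contact_point_nm: float
    fit_depth_used_nm: float
    residual_rms_nn: float
    r_squared: float
    n_points_fit: int
    contact_method: str = ""


@dataclass(frozen=True)
class CellModulus:
    cell_id: str
    per_curve_e_pa: tuple[float, ...]
    summary_e_pa: float
    summary_rule: str


def calibrate_deflection(raw_volts: np.ndarray, sensitivity_nm_per_v: float) -> np.ndarray:
    """Convert photodiode voltage to deflection in nm."""
    if sensitivity_nm_per_v <= 0:
        raise ValueError("sensitivity must be positive")
    return np.asarray(raw_volts, dtype=float) * sensitivity_nm_per_v


def split_segments(curve: ForceCurve) -> tuple[ForceCurve, ForceCurve]:
    """Split a curve into (approach, withdraw) at the global maximum of Z."""
    apex = int(np.argmax(curve.z))
    if apex == 0 or apex >= curve.z.size - 1:
        raise ValueError("single-segment curve: no turnaround found")
    approach = ForceCurve(
        curve.z[: apex + 1], curve.d[: apex + 1], curve.spring_constant,
        {**curve.meta, "segment": "approach"},
    )
    withdraw = ForceCurve(
        curve.z[apex:], curve.d[apex:], curve.spring_constant,
        {**curve.meta, "segment": "withdraw"},
    )
    return approach, withdraw


def correct_baseline(curve: ForceCurve, pre_contact_fraction: float = 0.25) -> ForceCurve:
    """Subtract a linear baseline fit to the first fraction of the approach.

    Removes photodiode offset and optical-interference slope.  The fitted
    slope and intercept are recorded in ``meta``.
    """
    if not 0 < pre_contact_fraction < 1:
        raise ValueError("pre_contact_fraction must be in (0, 1)")
    n = int(curve.z.size * pre_contact_fraction)
    if n < 5:
        raise ValueError("pre-contact fraction selects fewer than 5 samples")
    slope, intercept = np.polyfit(curve.z[:n], curve.d[:n], 1)
    d = curve.d - (slope * curve.z + intercept)
    return ForceCurve(
        curve.z, d, curve.spring_constant,
        {**curve.meta, "baseline_slope": float(slope), "baseline_intercept": float(intercept),
         "baseline_n": n},
    )


def _rov_contact_index(d: np.ndarray, window: int) -> int:
    """Index maximizing var(d[i:i+w]) / var(d[i-w:i])."""
    from numpy.lib.stride_tricks import sliding_window_view

    var = sliding_window_view(d, window).var(axis=1)
    idx = np.arange(window, d.size - window)
    if idx.size == 0:
        raise ContactNotFoundError("curve too short for the ratio-of-variances window")
    rov = var[idx] / (var[idx - window] + 1e-30)
    return int(idx[np.argmax(rov)])


def _threshold_contact_index(d: np.ndarray, sigma: float, factor: float, min_run: int) -> int:
    above = d > factor * sigma
    run = 0
    for i, a in enumerate(above):
        run = run + 1 if a else 0
        if run >= min_run:
            return i - min_run + 1
    raise ContactNotFoundError("no sustained threshold crossing: contact not detected")


def _piecewise_sse(
    z: np.ndarray, f: np.ndarray, d: np.ndarray, z0: float, prefactor: float, max_depth: float
) -> tuple[float, float]:
    """Full-curve SSE of the piecewise (baseline zero / Hertz) model at z0.

    E is the closed-form least-squares solution on the indentation window
    0 < delta <= max_depth, but the residual extends the fitted model over
    the entire curve so that SSE values at different candidate z0 are
    comparable (a windowed residual silently drops high-force samples for
    late candidates and biases the scan).
    """
    d0 = np.interp(z0, z, d)
    post = z >= z0
    delta = np.where(post, (z - z0) - (d - d0), 0.0)
    delta = np.clip(delta, 0.0, None)
    sel = post & (delta > 0) & (delta <= max_depth)
    if sel.sum() < 10:
        return np.inf, 0.0
    dl = delta[sel]
    e_hat = float((f[sel] * dl**2).sum() / (prefactor * (dl**4).sum()))
    if e_hat <= 0:
        return np.inf, 0.0
    model = np.where(post, e_hat * prefactor * delta**2, 0.0)
    return float(((f - model) ** 2).sum()), e_hat


def detect_contact_point(
    approach: ForceCurve,
    params: HertzModelParams | None = None,
    method: str = "piecewise",
    rov_window: int | None = None,
    noise_factor: float = 3.0,
    min_run: int = 5,
    coarse_step_nm: float = 10.0,
) -> tuple[float, str]:
    """Locate the contact point z0 (nm) on a baseline-corrected approach.

    Methods
    -------
    ``"piecewise"`` (default)
        Scans candidate contact points on a coarse grid, scoring each by the
        full-curve residual of a zero-baseline + Hertz-onset piecewise model
        (modulus closed-form per candidate), then refines the best candidate
        by bounded 1-D minimization.  Accurate even for soft samples whose
        deflection rises only gently out of the noise.
    ``"rov"``
        Window-based ratio of variances: maximizes
        var(d[i:i+w])/var(d[i-w:i]).  Lags the true contact for gently
        curving onsets; kept for auditability and cross-checking.
    ``"threshold"``
        First sustained excursion of d above ``noise_factor`` times the
        baseline noise.

    All methods raise :class:`ContactNotFoundError` when the curve shows no
    contact (deflection never rises above the baseline noise).  Returns
    ``(z0, method_name)``; the method name is recorded downstream.
    """
    z, d = approach.z, approach.d
    n = z.size
    nb = max(5, n // 4)
    sigma = float(d[:nb].std())
    tail = float(d[-max(5, n // 20):].mean())
    noise_floor = max(sigma, 1e-12)
    if tail < noise_factor * noise_floor:
        raise ContactNotFoundError(
            "deflection never rises above baseline noise: no contact in curve"
        )

    if method == "threshold":
        i = _threshold_contact_index(d, noise_floor, noise_factor, min_run)
        return float(z[max(i - 1, 0)]), "threshold"
    if method == "rov":
        w = rov_window or max(20, n // 4)
        return float(z[_rov_contact_index(d, w)]), "rov"
    if method != "piecewise":
        raise ValueError(f"unknown contact method {method!r}")

    params = params or HertzModelParams()
    pref = params.prefactor
    f = approach.force_nn
    max_depth = params.max_fit_depth_nm
    zmin, zmax = float(z[0]), float(z[-1])
    cands = np.arange(zmin + coarse_step_nm, zmax - 0.1 * max_depth, coarse_step_nm)
    if cands.size == 0:
        raise ContactNotFoundError("curve shorter than the fit window")
    sses = np.array([_piecewise_sse(z, f, d, z0, pref, max_depth)[0] for z0 in cands])
    if not np.isfinite(sses).any():
        raise ContactNotFoundError("piecewise contact scan found no valid candidate")
    zc = float(cands[np.argmin(sses)])
    res = minimize_scalar(
        lambda z0: _piecewise_sse(z, f, d, z0, pref, max_depth)[0],
        bounds=(zc - 1.5 * coarse_step_nm, zc + 1.5 * coarse_step_nm),
        method="bounded",
        options={"xatol": 1e-4},
    )
    z0 = float(res.x) if res.fun <= sses.min() else zc
    return z0, "piecewise"


def compute_indentation(
    approach: ForceCurve, z0: float
) -> tuple[np.ndarray, np.ndarray]:
    """Indentation depth delta = (Z - z0) - (d - d(z0)) for Z >= z0.

    Returns ``(delta_nm, force_nn)`` restricted to the post-contact samples
    with non-negative indentation.
    """
    z, d = approach.z, approach.d
    if not (z.min() <= z0 <= z.max()):
        raise ValueError("contact point outside curve range")
    d0 = np.interp(z0, z, d)
    post = z >= z0
    if not post.any():
        raise ValueError("empty post-contact region")
    delta = (z[post] - z0) - (d[post] - d0)
    force = approach.force_nn[post]
    keep = delta >= 0
    return delta[keep], force[keep]


def hertz_force(
    modulus_pa: float, params: HertzModelParams, delta_nm: np.ndarray
) -> np.ndarray:
    """Hertz cone force (nN) at indentation delta (nm)."""
    delta_nm = np.asarray(delta_nm, dtype=float)
    if np.any(delta_nm < 0):
        raise ValueError("indentation must be non-negative")
    return modulus_pa * params.prefactor * delta_nm**2


def fit_hertz(
    approach: ForceCurve,
    z0: float,
    params: HertzModelParams | None = None,
    refine_contact: bool = False,
    refine_half_width_nm: float = 30.0,
    contact_method: str = "",
) -> HertzFitResult:
    """Least-squares Hertz fit of E over 0 <= delta <= max_fit_depth.

    The model is linear in E, so the windowed fit is closed form.  With
    ``refine_contact`` the contact point is additionally refined around
    ``z0`` by minimizing the full-curve piecewise residual (recommended when
    z0 comes from a coarse detector; the piecewise detector already refines).
    """
    params = params or HertzModelParams()
    if refine_contact:
        res = minimize_scalar(
            lambda zc: _piecewise_sse(
                approach.z, approach.force_nn, approach.d, zc,
                params.prefactor, params.max_fit_depth_nm,
            )[0],
            bounds=(z0 - refine_half_width_nm, z0 + refine_half_width_nm),
            method="bounded",
            options={"xatol": 1e-6},
        )
        z0 = float(res.x)
        contact_method = (contact_method + "+refined").lstrip("+")

    delta, force = compute_indentation(approach, z0)
    sel = delta <= params.max_fit_depth_nm
    if sel.sum() < 10:
        raise ValueError(
            f"only {int(sel.sum())} points inside the fit window; need >= 10"
        )
    dl, fl = delta[sel], force[sel]
    denom = params.prefactor * (dl**4).sum()
    e_hat = float((fl * dl**2).sum() / denom)
    if e_hat <= 0 or not np.isfinite(e_hat):
        raise ValueError("Hertz fit did not converge to a positive modulus")
    resid = fl - e_hat * params.prefactor * dl**2
    ss_tot = ((fl - fl.mean()) ** 2).sum()
    r2 = 1.0 - (resid**2).sum() / ss_tot if ss_tot > 0 else 1.0
    return HertzFitResult(
        modulus_pa=e_hat,
        contact_point_nm=float(z0),
        fit_depth_used_nm=float(dl.max()),
        residual_rms_nn=float(np.sqrt((resid**2).mean())),
        r_squared=float(min(max(r2, 0.0), 1.0)),
        n_points_fit=int(sel.sum()),
        contact_method=contact_method,
    )


def process_curve(
    curve: ForceCurve,
    params: HertzModelParams | None = None,
    pre_contact_fraction: float = 0.25,
    contact_method: str = "piecewise",
    split: bool = True,
) -> HertzFitResult:
    """Full single-curve pipeline: split, baseline, contact, Hertz fit."""
    params = params or HertzModelParams()
    approach = split_segments(curve)[0] if split else curve
    approach = correct_baseline(approach, pre_contact_fraction)
    z0, method = detect_contact_point(approach, params, method=contact_method)
    refine = method != "piecewise"  # piecewise already refines
    return fit_hertz(
        approach, z0, params, refine_contact=refine, contact_method=method
    )


def aggregate_cell_modulus(
    cell_id: str, fits: list[HertzFitResult], rule: str = "mean"
) -> CellModulus:
    """Summarize replicate curve fits (typically three) into one cell value."""
    if not fits:
        raise ValueError("at least one fit per cell is required")
    es = tuple(f.modulus_pa for f in fits)
    if rule == "mean":
        summary = float(np.mean(es))
    elif rule == "median":
        summary = float(np.median(es))
    else:
        raise ValueError(f"unknown summary rule {rule!r}")
    return CellModulus(cell_id, es, summary, rule)
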