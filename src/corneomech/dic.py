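"""Substrate displacement by windowed digital image correlation.

Bead image pairs (before/after cell removal) are divided into interrogation
windows; each window of the pre image is cross-correlated with the same
window of the post image and the correlation peak, refined to subpixel
precision, gives the local substrate displacement.

Coordinate convention (shared across the package): arrays are indexed
``[iy, ix]`` with the physical y axis increasing with the row index, so the
array origin is the lower-left corner of the field of view and displacements
(u, v) are the physical x/y components in micrometres.  TIFF I/O flips rows
so that saved images follow the usual top-row-first viewing convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import griddata

__all__ = [
    "DisplacementField",
    "cross_correlate_windows",
    "filter_outliers",
    "interpolate_gaps",
    "smooth_field",
]


@dataclass
class DisplacementField:
    """Gridded surface displacement with a per-node validity mask.

    ``x`` and ``y`` are 1D node coordinates in um; ``u``/``v`` are the x/y
    displacement components (um) on the (len(y), len(x)) grid; ``valid``
    marks nodes whose correlation succeeded.  ``pixel_size`` is the size of
    one *image* pixel in um (the node spacing is ``spacing``).
    """

    x: np.ndarray
    y: np.ndarray
    u: np.ndarray
    v: np.ndarray
    valid: np.ndarray
    pixel_size: float
    window: int | None = None
    overlap: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        shape = (self.y.size, self.x.size)
        for name, arr in (("u", self.u), ("v", self.v), ("valid", self.valid)):
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @classmethod
    def from_dense(cls, u: np.ndarray, v: np.ndarray, pixel_size: float) -> "DisplacementField":
        """Wrap per-pixel displacement arrays (e.g. forward-solver output)."""
        u = np.asarray(u, dtype=float)
        ny, nx = u.shape
        return cls(
            x=(np.arange(nx) + 0.5) * pixel_size,
            y=(np.arange(ny) + 0.5) * pixel_size,
            u=u,
            v=np.asarray(v, dtype=float),
            valid=np.ones((ny, nx), dtype=bool),
            pixel_size=pixel_size,
        )

    @property
    def spacing(self) -> float:
        """Node spacing in um; the grid must be uniform and square."""
        dx = np.diff(self.x)
        dy = np.diff(self.y)
        if dx.size == 0 or dy.size == 0:
            raise ValueError("grid too small to define a spacing")
        if not (np.allclose(dx, dx[0]) and np.allclose(dy, dy[0]) and np.isclose(dx[0], dy[0])):
            raise ValueError("non-uniform grid")
        return float(dx[0])

    @property
    def shape(self) -> tuple[int, int]:
        return self.u.shape


def _subpixel_offset(cm1: float, c0: float, cp1: float) -> float:
    """Peak offset in (-0.5, 0.5) from three samples around a maximum.

    Three-point Gaussian estimator; parabolic fallback when a neighbour is
    non-positive (log undefined).
    """
    if cm1 > 0 and c0 > 0 and cp1 > 0:
        lm1, l0, lp1 = np.log(cm1), np.log(c0), np.log(cp1)
        denom = lm1 - 2.0 * l0 + lp1
        if denom < 0:
            return float(0.5 * (lm1 - lp1) / denom)
    denom = cm1 - 2.0 * c0 + cp1
    if denom < 0:
        return float(0.5 * (cm1 - cp1) / denom)
    return 0.0


def _circular_peak(a: np.ndarray, b: np.ndarray, max_shift: int) -> tuple[int, int, np.ndarray, int]:
    """Integer peak of the circular cross-correlation of two equal windows.

    Returns ``(dy, dx, c, cen)`` with the correlation plane ``c`` in
    fftshift layout (zero shift at index ``cen``).
    """
    c = np.fft.ifft2(np.fft.fft2(b) * np.conj(np.fft.fft2(a))).real
    c = np.fft.fftshift(c)
    cen = a.shape[0] // 2
    sub = c[cen - max_shift : cen + max_shift + 1, cen - max_shift : cen + max_shift + 1]
    pj, pi = np.unravel_index(np.argmax(sub), sub.shape)
    return pj + cen - max_shift - cen, pi + cen - max_shift - cen, c, cen


def cross_correlate_windows(
    pair,
    window: int = 32,
    overlap: int = 16,
    pixel_size: float | None = None,
    apodize: bool = True,
) -> DisplacementField:
    """Windowed normalized cross-correlation of a bead image pair.

    ``pair`` is a :class:`~corneomech.synthetic.BeadImagePair` or any object
    with ``image_pre``, ``image_post`` and ``pixel_size`` attributes, or a
    tuple ``(pre, post)`` with ``pixel_size`` given explicitly.

    Two-stage estimation per window (discrete window offset): a first
    circular correlation of the co-located windows gives the integer
    displacement; the post window is then re-cut at that integer offset, so
    the residual correlation peak is symmetric about zero, and refined by a
    three-point Gaussian fit in x and y.  Re-cutting removes the edge
    asymmetry that content entering/leaving a co-located window induces in
    the peak shape, which otherwise costs a few tenths of a pixel at
    displacements of several pixels.  Windows are mean-subtracted (rejecting
    uneven illumination); the residual pass is Hann-apodized by default.
    Windows with zero variance in either image are marked invalid.
    """
    if hasattr(pair, "image_pre"):
        pre, post = pair.image_pre, pair.image_post
        pixel_size = pair.pixel_size if pixel_size is None else pixel_size
    else:
        pre, post = pair
    if pixel_size is None:
        raise ValueError("pixel_size required when passing raw arrays")
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("images must have the same shape")
    if window < 16:
        raise ValueError("window must be >= 16 px")
    if not 0 <= overlap < window:
        raise ValueError("overlap must satisfy 0 <= overlap < window")
    if window > min(pre.shape):
        raise ValueError("window larger than image")

    step = window - overlap
    h, w = pre.shape
    iy0s = np.arange(0, h - window + 1, step)
    ix0s = np.arange(0, w - window + 1, step)
    ny, nx = len(iy0s), len(ix0s)
    u = np.zeros((ny, nx))
    v = np.zeros((ny, nx))
    valid = np.zeros((ny, nx), dtype=bool)
    max_shift = window // 2 - 1
    hann = np.hanning(window)[:, None] * np.hanning(window)[None, :]

    for j, iy0 in enumerate(iy0s):
        for i, ix0 in enumerate(ix0s):
            a = pre[iy0 : iy0 + window, ix0 : ix0 + window]
            b = post[iy0 : iy0 + window, ix0 : ix0 + window]
            if a.std() == 0 or b.std() == 0:
                continue
            dy0, dx0, _, _ = _circular_peak(a - a.mean(), b - b.mean(), max_shift)
            # Re-cut the post window at the integer offset (clamped to the
            # image) and correlate for the residual; repeat while the
            # residual keeps an integer part, so a first-pass peak error
            # cannot leave an asymmetric (biased) subpixel fit.
            a2 = a - a.mean()
            if apodize:
                a2 = a2 * hann
            degenerate = False
            for attempt in range(3):
                oy = int(np.clip(iy0 + dy0, 0, h - window))
                ox = int(np.clip(ix0 + dx0, 0, w - window))
                # widen the residual search by however much the clamp ate
                deficit = max(abs(iy0 + dy0 - oy), abs(ix0 + dx0 - ox))
                radius = int(min(2 + deficit, window // 2 - 2))
                dy0, dx0 = oy - iy0, ox - ix0
                b2 = post[oy : oy + window, ox : ox + window]
                if b2.std() == 0:
                    degenerate = True
                    break
                b2 = b2 - b2.mean()
                if apodize:
                    b2 = b2 * hann
                rdy, rdx, c, cen = _circular_peak(a2, b2, radius)
                if (rdy == 0 and rdx == 0) or attempt == 2:
                    break
                next_dy = int(np.clip(iy0 + dy0 + rdy, 0, h - window)) - iy0
                next_dx = int(np.clip(ix0 + dx0 + rdx, 0, w - window)) - ix0
                if (next_dy, next_dx) == (dy0, dx0):
                    break  # clamped at the frame: cannot move closer
                dy0, dx0 = next_dy, next_dx
            if degenerate:
                continue
            pj, pi = cen + rdy, cen + rdx
            dy = dy0 + rdy + _subpixel_offset(c[pj - 1, pi], c[pj, pi], c[pj + 1, pi])
            dx = dx0 + rdx + _subpixel_offset(c[pj, pi - 1], c[pj, pi], c[pj, pi + 1])
            u[j, i] = dx * pixel_size
            v[j, i] = dy * pixel_size
            valid[j, i] = True

    # node at the window centre; pixel i is centred at (i + 0.5) * pixel_size
    half = window / 2.0
    return DisplacementField(
        x=(ix0s + half) * pixel_size,
        y=(iy0s + half) * pixel_size,
        u=u,
        v=v,
        valid=valid,
        pixel_size=pixel_size,
        window=window,
        overlap=overlap,
    )


def filter_outliers(
    field: DisplacementField, threshold: float = 2.0, eps_px: float = 0.1
) -> DisplacementField:
    """Normalized-median outlier test over 8-neighbourhoods.

    A node fails when the norm of its (u, v) residual relative to the median
    of its valid neighbours, normalized by the median absolute neighbour
    residual plus ``eps_px`` (in pixels), exceeds ``threshold``.  Failing
    nodes are marked invalid; the count is recorded in ``meta``.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if not field.valid.any():
        warnings.warn("all nodes invalid; nothing to filter", stacklevel=2)
        return replace(field, meta={**field.meta, "outliers_removed": 0})

    ny, nx = field.shape
    u_px = field.u / field.pixel_size
    v_px = field.v / field.pixel_size
    r2 = np.zeros((ny, nx))
    for j in range(ny):
        for i in range(nx):
            if not field.valid[j, i]:
                continue
            js = slice(max(j - 1, 0), min(j + 2, ny))
            is_ = slice(max(i - 1, 0), min(i + 2, nx))
            nb = field.valid[js, is_].copy()
            nb[j - js.start, i - is_.start] = False
            if nb.sum() < 3:
                continue
            r_comp = []
            for comp in (u_px, v_px):
                vals = comp[js, is_][nb]
                med = np.median(vals)
                resid = np.median(np.abs(vals - med))
                r_comp.append((comp[j, i] - med) / (resid + eps_px))
            r2[j, i] = np.hypot(*r_comp)
    bad = r2 > threshold
    out = replace(
        field,
        valid=field.valid & ~bad,
        meta={**field.meta, "outliers_removed": int(bad.sum())},
    )
    return out


def interpolate_gaps(field: DisplacementField) -> DisplacementField:
    """Fill invalid nodes by linear interpolation of the valid ones.

    Piecewise-linear (Delaunay) interpolation reproduces linear fields
    exactly; nodes outside the convex hull of valid data fall back to
    nearest-neighbour.  Requires at least 50% valid nodes.
    """
    nvalid = int(field.valid.sum())
    if nvalid == field.valid.size:
        return replace(field)
    if nvalid < 0.5 * field.valid.size:
        raise ValueError(
            f"only {nvalid}/{field.valid.size} nodes valid; need >= 50% to interpolate"
        )
    X, Y = np.meshgrid(field.x, field.y)
    pts = np.column_stack([X[field.valid], Y[field.valid]])
    hole_pts = np.column_stack([X[~field.valid], Y[~field.valid]])
    u = field.u.copy()
    v = field.v.copy()
    for comp in (u, v):
        vals = comp[field.valid]
        filled = griddata(pts, vals, hole_pts, method="linear")
        nn = np.isnan(filled)
        if nn.any():
            filled[nn] = griddata(pts, vals, hole_pts[nn], method="nearest")
        comp[~field.valid] = filled
    return replace(
        field,
        u=u,
        v=v,
        valid=np.ones_like(field.valid),
        meta={**field.meta, "interpolated_nodes": int((~field.valid).sum())},
    )


def smooth_field(field: DisplacementField, sigma_nodes: float = 0.8) -> DisplacementField:
    """Gaussian smoothing of a complete displacement grid (PIV hygiene).

    When windows overlap by more than half, adjacent nodes share most of
    their interrogation content and the grid oversamples the window-limited
    resolution; a Gaussian at sub-window scale (``sigma_nodes`` in units of
    the node spacing) suppresses node-to-node estimation noise without
    removing information the windows could resolve.  Intended before a
    lambda = 0 traction inversion, which otherwise amplifies single-node
    errors at the grid Nyquist.  Requires a gap-free field.
    """
    from scipy.ndimage import gaussian_filter

    if sigma_nodes < 0:
        raise ValueError("sigma_nodes must be >= 0")
    if not field.valid.all():
        raise ValueError("smooth_field needs a complete field; interpolate gaps first")
    if sigma_nodes == 0:
        return replace(field)
    return replace(
        field,
        u=gaussian_filter(field.u, sigma_nodes, mode="nearest"),
        v=gaussian_filter(field.v, sigma_nodes, mode="nearest"),
        meta={**field.meta, "smooth_sigma_nodes": sigma_nodes},
    )
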