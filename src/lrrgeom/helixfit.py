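"""Circular-helix and 3D-circle fitting for solenoid repeat geometry.

The central object is the total-least-squares fit of a circular helix to the
ordered reference points of a repeat protein (one point per repeat unit).
The fitted helix is described by an axis (point + oriented unit direction),
a signed pitch ``P`` (axial advance per full turn; positive = right-handed
screw), a radius ``R`` and the number of repeat units per turn ``N``.  From
these follow the rise per unit ``dz = P/N``, the rotation per unit
``dphi = 360/N``, the fit quality ``rmsd`` and the length-independent
regularity ``p = rmsd / sqrt(n - 1)``.

The objective is the sum of squared Euclidean distances from each data point
to the helix *curve* (not to an assigned phase), minimised over axis
position and direction, radius, pitch and the per-point curve parameters.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "FitError",
    "DegenerateGeometryError",
    "NoRotationalProgressionError",
    "HelixFit",
    "CircleFit",
    "SpacingSummary",
    "fit_helix",
    "fit_circle_3d",
    "spacing_summary",
    "helix_curve_point",
]

_TWO_PI = 2.0 * math.pi


class FitError(RuntimeError):
    """A geometry fit could not be completed."""


class DegenerateGeometryError(FitError):
    """Input points are geometrically degenerate (e.g. collinear)."""


class NoRotationalProgressionError(FitError):
    """The point sequence shows no usable azimuthal progression."""


def _as_xyz(points) -> np.ndarray:
    """Accept a ReferencePointSet-like object or a plain (n, 3) array."""
    xyz = getattr(points, "points", points)
    xyz = np.asarray(xyz, dtype=float)
    if xyz.ndim != 2 or xyz.shape[1] != 3:
        raise ValueError(f"expected an (n, 3) point array, got shape {xyz.shape}")
    if not np.all(np.isfinite(xyz)):
        raise ValueError("points contain non-finite coordinates")
    return xyz


def _unit(v: np.ndarray) -> np.ndarray:
    nrm = np.linalg.norm(v)
    if nrm == 0.0:
        raise ValueError("zero vector has no direction")
    return v / nrm


def _perp_frame(axis: np.ndarray, u_ref: np.ndarray | None = None):
    """Orthonormal in-plane frame (u, v) with v = axis x u.

    When ``u_ref`` is given, u is its projection onto the plane normal to
    ``axis`` — continuous in ``axis`` near the reference, which keeps the
    least-squares parameterisation smooth.
    """
    if u_ref is None:
        k = int(np.argmin(np.abs(axis)))
        u_ref = np.zeros(3)
        u_ref[k] = 1.0
    u = u_ref - (u_ref @ axis) * axis
    u = _unit(u)
    v = np.cross(axis, u)
    return u, v


@dataclasses.dataclass(frozen=True)
class HelixFit:
    """A fitted circular helix and its derived repeat parameters.

    ``axis_dir`` is oriented so that the point sequence advances from the
    first to the last repeat (N- to C-terminal).  For an (almost exactly)
    flat fit the tie is broken so the sequence turns counterclockwise about
    ``axis_dir``.  ``azimuths`` holds the fitted curve parameter of every
    point, in degrees, in the frame returned by :meth:`frame`.
    """

    axis_point: np.ndarray
    axis_dir: np.ndarray
    P: float
    R: float
    N: float
    rmsd: float
    n: int
    azimuths: np.ndarray
    _u_ref: np.ndarray

    @property
    def dz(self) -> float:
        """Rise per repeat unit, P/N (signed, Å)."""
        return self.P / self.N

    @property
    def dphi(self) -> float:
        """Rotation per repeat unit, 360/N (degrees, > 0)."""
        return 360.0 / self.N

    @property
    def p(self) -> float:
        """Helix regularity, rmsd/(n - 1)^1/2 (Å)."""
        return self.rmsd / math.sqrt(self.n - 1)

    @property
    def handedness(self) -> str:
        if self.P > 0:
            return "right"
        if self.P < 0:
            return "left"
        return "flat"

    def frame(self):
        """Orthonormal frame (u, v, axis_dir) in which azimuths are measured."""
        u, v = _perp_frame(self.axis_dir, self._u_ref)
        return u, v, self.axis_dir

    def curve_point(self, azimuth_deg: float) -> np.ndarray:
        return helix_curve_point(self, azimuth_deg)


@dataclasses.dataclass(frozen=True)
class CircleFit:
    """A circle fitted to 3D points: least-squares plane, then in-plane circle."""

    center: np.ndarray
    radius: float
    normal: np.ndarray
    rmsd: float


@dataclasses.dataclass(frozen=True)
class SpacingSummary:
    """Adjacent reference-point spacing, observed and implied by the fit.

    ``D_eq1`` is the spacing a perfect helix with the fitted parameters
    would have: D = [(2 R sin(dphi/2))^2 + dz^2]^(1/2).
    """

    D_mean: float
    D_eq1: float


def helix_curve_point(fit: HelixFit, azimuth_deg: float) -> np.ndarray:
    """Point on the fitted helix at the given azimuth (degrees)."""
    u, v, a = fit.frame()
    th = np.deg2rad(np.asarray(azimuth_deg, dtype=float))
    radial = fit.R * (np.multiply.outer(np.cos(th), u) + np.multiply.outer(np.sin(th), v))
    axial = np.multiply.outer(fit.P * th / _TWO_PI, a)
    return fit.axis_point + radial + axial


# ---------------------------------------------------------------------------
# 2D circle fit (Kasa initialisation + geometric Gauss-Newton polish)

def _fit_circle_2d(x: np.ndarray, y: np.ndarray):
    A = np.column_stack([x, y, np.ones_like(x)])
    b = x * x + y * y
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy = sol[0] / 2.0, sol[1] / 2.0
    r2 = sol[2] + cx * cx + cy * cy
    r = math.sqrt(max(r2, 1e-30))
    # geometric refinement: minimise sum (|p - c| - r)^2
    for _ in range(20):
        dx, dy = x - cx, y - cy
        d = np.hypot(dx, dy)
        d = np.where(d < 1e-12, 1e-12, d)
        r_new = d.mean()
        J = np.column_stack([-dx / d, -dy / d])
        res = d - r_new
        g = J.T @ res
        H = J.T @ J + 1e-12 * np.eye(2)
        step = np.linalg.solve(H, -g)
        cx += step[0]
        cy += step[1]
        r = r_new
        if np.linalg.norm(step) < 1e-12 * max(1.0, r):
            break
    dx, dy = x - cx, y - cy
    r = float(np.hypot(dx, dy).mean())
    return float(cx), float(cy), r


def fit_circle_3d(points, *, collinearity_tol: float = 1e-8) -> CircleFit:
    """Fit a circle to >= 3 points in 3D.

    The plane is the total-least-squares plane through the points; the
    circle is then fitted to the in-plane projections.  ``rmsd`` is the
    root-mean-square in-plane radial residual.  The normal is oriented so
    the projected point sequence advances counterclockwise.
    """
    X = _as_xyz(points)
    if len(X) < 3:
        raise DegenerateGeometryError("circle fit requires at least 3 points")
    c0 = X.mean(axis=0)
    Y = X - c0
    _, s, vt = np.linalg.svd(Y, full_matrices=False)
    if s[1] <= collinearity_tol * max(s[0], 1.0):
        raise DegenerateGeometryError("points are collinear; no circle is defined")
    e1, e2 = vt[0], vt[1]
    normal = np.cross(e1, e2)  # right-handed frame; vt[2] may be its negation
    x = Y @ e1
    y = Y @ e2
    cx, cy, r = _fit_circle_2d(x, y)
    center = c0 + cx * e1 + cy * e2
    radial = np.hypot(x - cx, y - cy)
    rmsd = float(np.sqrt(np.mean((radial - r) ** 2)))
    theta = np.unwrap(np.arctan2(y - cy, x - cx))
    if theta[-1] < theta[0]:
        normal = -normal
    return CircleFit(center=center, radius=float(r), normal=_unit(normal), rmsd=rmsd)


# ---------------------------------------------------------------------------
# helix fit

def _initial_axes(X: np.ndarray) -> list[np.ndarray]:
    """Candidate axis directions, best first.

    The primary estimate is the principal eigenvector of the second-moment
    matrix of successive chord cross-products (sign-invariant, so no
    alignment step can cancel terms).  The principal directions of the
    point cloud are appended as fallbacks: for shallow arcs the axis is
    near the smallest-variance direction, for steep helices near the
    largest.
    """
    chords = np.diff(X, axis=0)
    w = np.cross(chords[:-1], chords[1:])
    norms = np.linalg.norm(w, axis=1)
    keep = norms > 1e-12 * np.linalg.norm(chords, axis=1).max() ** 2
    if not np.any(keep):
        raise DegenerateGeometryError("points are collinear; helix axis undefined")
    w = w[keep] / norms[keep, None]
    moment = w.T @ w
    eigvals, eigvecs = np.linalg.eigh(moment)
    primary = eigvecs[:, -1]
    Y = X - X.mean(axis=0)
    _, _, vt = np.linalg.svd(Y, full_matrices=False)
    out = [primary, vt[2], vt[0]]
    # sign-fix each candidate against the mean raw cross-product (the
    # rotation sense of the sequence), so the whole computation is
    # equivariant under rigid motions of the input
    ref = w.sum(axis=0)
    out = [a if a @ ref >= 0 else -a for a in out]
    # drop candidates nearly parallel to an earlier one
    uniq: list[np.ndarray] = []
    for a in out:
        if all(abs(a @ b) < 0.999 for b in uniq):
            uniq.append(a)
    return uniq


def _axis_profile(X: np.ndarray, axis: np.ndarray):
    """Closed-form helix estimate for a fixed axis direction.

    Projects onto the plane normal to ``axis``, fits a circle, unwraps the
    azimuths and regresses the axial coordinate on azimuth.  Returns
    (center3d, R, P, theta) with theta in radians.
    """
    u, v = _perp_frame(axis)
    x, y, z = X @ u, X @ v, X @ axis
    cx, cy, r = _fit_circle_2d(x, y)
    theta = np.unwrap(np.arctan2(y - cy, x - cx))
    total = theta[-1] - theta[0]
    if abs(total) < 1e-3:
        raise NoRotationalProgressionError(
            "no rotational progression about the candidate axis"
        )
    slope, z0 = np.polyfit(theta, z, 1)
    P = slope * _TWO_PI
    center = cx * u + cy * v + z0 * axis
    return center, r, P, theta, u, v


def point_to_helix_distances(
    X: np.ndarray,
    axis_point: np.ndarray,
    axis: np.ndarray,
    R: float,
    P: float,
    theta0: np.ndarray,
    n_newton: int = 40,
    u_ref: np.ndarray | None = None,
):
    """Closest distance from each point to the helix curve.

    ``theta0`` (radians, one per point) seeds a Newton iteration on the
    stationarity condition of the squared distance along the curve.
    Returns ``(distances, curve_parameters)``.
    """
    u, v = _perp_frame(axis, u_ref)
    Y = X - axis_point
    xu, xv, xz = Y @ u, Y @ v, Y @ axis
    r_p = np.hypot(xu, xv)
    phi_p = np.arctan2(xv, xu)
    b = P / _TWO_PI
    # d^2(t) = r_p^2 + R^2 - 2 r_p R cos(t - phi_p) + (b t - xz)^2
    t = theta0.astype(float).copy()
    k = np.round((phi_p - t) / _TWO_PI)
    phi = phi_p - k * _TWO_PI  # representative nearest t
    for _ in range(n_newton):
        s = t - phi
        g = 2.0 * r_p * R * np.sin(s) + 2.0 * b * (b * t - xz)
        h = 2.0 * r_p * R * np.cos(s) + 2.0 * b * b
        h = np.where(np.abs(h) < 1e-12, 1e-12, h)
        step = np.clip(g / h, -0.5, 0.5)
        t = t - step
        if np.max(np.abs(step)) < 1e-14:
            break
    # evaluate the distance by explicit vector difference: the cylindrical
    # closed form cancels catastrophically when the fit is near-exact
    curve = (
        axis_point
        + R * (np.cos(t)[:, None] * u + np.sin(t)[:, None] * v)
        + (b * t)[:, None] * axis
    )
    return np.linalg.norm(curve - X, axis=1), t


def _refine_from_axis(X: np.ndarray, a0: np.ndarray, *, ftol: float, max_iter: int):
    """Nonlinear refinement of all helix parameters from one initial axis.

    Returns (objective, axis, center, R, P, curve_params, u_ref).
    """
    center0, R0, P0, _, _, _ = _axis_profile(X, a0)
    # in-plane reference frame built from the data (not from coordinate
    # axes), keeping the optimisation path equivariant under rigid motions
    scale = float(np.linalg.norm(X, axis=1).max()) or 1.0
    u_ref = None
    for probe in (X[0] - center0, X[-1] - center0, X[len(X) // 2] - center0):
        perp = probe - (probe @ a0) * a0
        if np.linalg.norm(perp) > 1e-6 * scale:
            u_ref = perp
            break
    u0, v0 = _perp_frame(a0, u_ref)

    def unpack(p):
        axis = _unit(a0 + p[0] * u0 + p[1] * v0)
        return axis, p[2:5], p[5], p[6], p[7:]

    def residuals(p):
        axis, c, R, P, t = unpack(p)
        u, v = _perp_frame(axis, u0)
        curve = (
            c
            + R * (np.cos(t)[:, None] * u + np.sin(t)[:, None] * v)
            + (P / _TWO_PI) * t[:, None] * axis
        )
        return (curve - X).ravel()

    n = len(X)

    def jacobian(p):
        q = a0 + p[0] * u0 + p[1] * v0
        nq = np.linalg.norm(q)
        a = q / nq
        R, P, t = p[5], p[6], p[7:]
        b = P / _TWO_PI
        w = u0 - (u0 @ a) * a
        nw = np.linalg.norm(w)
        u = w / nw
        v = np.cross(a, u)
        cos_t, sin_t = np.cos(t), np.sin(t)
        e = cos_t[:, None] * u + sin_t[:, None] * v  # radial direction
        f = -sin_t[:, None] * u + cos_t[:, None] * v  # tangential direction

        def axis_block(basis):
            d_a = (basis - (a @ basis) * a) / nq
            d_w = -(u0 @ d_a) * a - (u0 @ a) * d_a
            d_u = (d_w - (u @ d_w) * u) / nw
            d_v = np.cross(d_a, u) + np.cross(a, d_u)
            d_e = cos_t[:, None] * d_u + sin_t[:, None] * d_v
            return R * d_e + b * t[:, None] * d_a

        J = np.zeros((3 * n, 7 + n))
        J[:, 0] = axis_block(u0).ravel()
        J[:, 1] = axis_block(v0).ravel()
        J[0::3, 2] = 1.0
        J[1::3, 3] = 1.0
        J[2::3, 4] = 1.0
        J[:, 5] = e.ravel()
        J[:, 6] = (t[:, None] * a / _TWO_PI).ravel()
        dt = R * f + b * a  # per-point curve tangent
        rows = np.repeat(3 * np.arange(n), 3) + np.tile(np.arange(3), n)
        J[rows, 7 + np.repeat(np.arange(n), 3)] = dt.ravel()
        return J

    # initial azimuths in the (u0, v0) frame used by the optimiser
    Y0 = X - center0
    th_init = np.unwrap(np.arctan2(Y0 @ v0, Y0 @ u0))
    p0 = np.concatenate([[0.0, 0.0], center0, [R0, P0], th_init])
    lb = np.full_like(p0, -np.inf)
    ub = np.full_like(p0, np.inf)
    lb[5] = 1e-9  # R > 0
    sol = least_squares(
        residuals,
        p0,
        bounds=(lb, ub),
        method="trf",
        jac=jacobian,
        ftol=ftol,
        xtol=1e-15,
        gtol=1e-15,
        max_nfev=max_iter * len(p0),
    )
    if not np.all(np.isfinite(sol.x)):
        raise FitError(f"helix fit did not converge: {sol.message}")
    axis, c, R, P, t = unpack(sol.x)
    return (
        2.0 * sol.cost,
        axis,
        np.asarray(c, dtype=float),
        float(R),
        float(P),
        np.asarray(t, dtype=float),
        u0,
    )


def fit_helix(
    points,
    *,
    min_points: int = 5,
    ftol: float = 1e-14,
    max_iter: int = 500,
) -> HelixFit:
    """Total-least-squares circular-helix fit to an ordered point set.

    Minimises the sum of squared distances from every point to the helix
    curve over axis position and direction, radius, pitch and the per-point
    curve parameters.  ``N`` (units per turn) comes from the total unwrapped
    azimuth spanned by the fitted curve parameters:
    N = 360 (n - 1) / |total azimuth change|.
    """
    X = _as_xyz(points)
    n = len(X)
    if n < min_points:
        raise FitError(f"helix fit requires at least {min_points} points, got {n}")
    # Canonicalise the pose before fitting: work about the centroid, in the
    # principal-axis frame of the point cloud with signs fixed from the
    # data (rotation sense, end-to-end chord).  The optimiser then runs on
    # numerically identical inputs for any rigid motion of the same points,
    # so the fitted scalars are reproducible to rounding even along the
    # nearly flat pitch/axis directions of the objective.
    centroid = X.mean(axis=0)
    X = X - centroid
    chords = np.diff(X, axis=0)
    w = np.cross(chords[:-1], chords[1:])
    wnorm = np.linalg.norm(w, axis=1)
    good = wnorm > 1e-12 * max(float(np.abs(X).max()) ** 2, 1.0)
    if not np.any(good):
        raise DegenerateGeometryError("points are collinear; helix axis undefined")
    wn = w[good] / wnorm[good, None]
    _, eigvecs = np.linalg.eigh(wn.T @ wn)
    r3 = eigvecs[:, -1]
    if r3 @ w.sum(axis=0) < 0:  # rotation sense of the sequence
        r3 = -r3
    scale = float(np.abs(X).max()) or 1.0
    r1 = None
    for probe in (X[0], X[-1], X[len(X) // 2]):
        perp = probe - (probe @ r3) * r3
        if np.linalg.norm(perp) > 1e-6 * scale:
            r1 = perp / np.linalg.norm(perp)
            break
    if r1 is None:
        raise DegenerateGeometryError("points are degenerate about the axis")
    rot = np.array([r1, np.cross(r3, r1), r3])
    X = X @ rot.T

    # score candidate axes by the closed-form profile objective; refine the
    # best and any other candidate whose profile is not clearly hopeless
    scored = []
    err: Exception | None = None
    for a0 in _initial_axes(X):
        try:
            center0, R0, P0, theta0, _, _ = _axis_profile(X, a0)
        except FitError as exc:
            err = exc
            continue
        d, _ = point_to_helix_distances(X, center0, a0, R0, P0, theta0)
        scored.append((float(d @ d), a0))
    scored.sort(key=lambda s: s[0])
    best = None
    for prof_obj, a0 in scored:
        if best is not None and prof_obj > 4.0 * best[0]:
            continue
        try:
            result = _refine_from_axis(X, a0, ftol=ftol, max_iter=max_iter)
        except (FitError, np.linalg.LinAlgError) as exc:
            err = exc
            continue
        if best is None or result[0] < best[0]:
            best = result
    if best is None:
        if isinstance(err, FitError):
            raise err
        raise FitError(f"helix fit failed from every initial axis: {err}")
    _, axis, c, R, P, t, u0 = best

    # polish curve parameters against the final helix and measure residuals
    d, t = point_to_helix_distances(X, c, axis, R, P, t, u_ref=u0)
    rmsd = float(np.sqrt(np.mean(d * d)))

    total = t[-1] - t[0]
    if abs(total) < 1e-6:
        raise NoRotationalProgressionError("fit collapsed to zero azimuthal span")
    # orient axis N->C (tie-break: counterclockwise progression)
    axial_advance = (P / _TWO_PI) * total
    flip = axial_advance < 0 if abs(axial_advance) > 1e-9 else total < 0
    u_ref = u0
    if flip:
        axis = -axis
        t = -t
        total = -total
    N = 360.0 * (n - 1) / abs(np.rad2deg(total))
    if N <= 2.0:
        raise FitError(f"units per turn N = {N:.3f} <= 2; not a resolvable helix")
    return HelixFit(
        axis_point=rot.T @ c + centroid,
        axis_dir=rot.T @ axis,
        P=float(P),
        R=float(R),
        N=float(N),
        rmsd=rmsd,
        n=n,
        azimuths=np.rad2deg(t),
        _u_ref=rot.T @ u_ref,
    )


def spacing_summary(points, fit: HelixFit) -> SpacingSummary:
    """Observed mean adjacent spacing and the spacing implied by the fit."""
    X = _as_xyz(points)
    d_mean = float(np.linalg.norm(np.diff(X, axis=0), axis=1).mean())
    chord = 2.0 * fit.R * math.sin(math.radians(fit.dphi) / 2.0)
    d_eq1 = math.sqrt(chord * chord + fit.dz * fit.dz)
    return SpacingSummary(D_mean=d_mean, D_eq1=d_eq1)
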