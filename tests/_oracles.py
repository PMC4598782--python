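"""Independent brute-force references used by the tests.

The helix-fit oracle searches axis directions on a 2°-spaced spherical
grid; for each candidate axis the helix follows in closed form (algebraic
circle fit in the orthogonal plane, linear regression of the axial
coordinate on unwrapped azimuth) and the objective is the exact sum of
squared point-to-curve distances.  The minimum over the grid bounds the
least-squares optimum from above and must be matched (within a small
factor) by the package's nonlinear fit.
"""

from __future__ import annotations

import numpy as np

_TWO_PI = 2.0 * np.pi


def sphere_grid(step_deg: float = 2.0) -> np.ndarray:
    """Axis directions covering the hemisphere at the given angular spacing."""
    thetas = np.deg2rad(np.arange(0.0, 90.0 + 1e-9, step_deg))
    axes = [np.array([0.0, 0.0, 1.0])]
    for th in thetas[1:]:
        for ph in np.deg2rad(np.arange(0.0, 360.0, step_deg)):
            axes.append(
                np.array([np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)])
            )
    return np.asarray(axes)


def _closest_distance_sq(xu, xv, xz, cx, cy, slope, intercept, r, t0):
    """Squared distance from points to helix, batched over axes.

    Coordinates are cylindrical about each candidate axis: ``xu/xv/xz`` are
    (n, A); circle centers, regression coefficients and radii are (A,).
    The curve is (r cos t, r sin t, slope*t + intercept); minimisation over
    t is damped Newton seeded at the point's own unwrapped azimuth ``t0``,
    which pins each point to its own turn of the helix (an infinite
    shallow-pitch curve would otherwise wind arbitrarily close to
    everything).
    """
    du = xu - cx
    dv = xv - cy
    rp = np.hypot(du, dv)
    phi = np.arctan2(dv, du)
    phi = phi + _TWO_PI * np.round((t0 - phi) / _TWO_PI)
    zres = xz - intercept
    t = t0.copy()
    for _ in range(30):
        s = t - phi
        g = rp * r * np.sin(s) + slope * (slope * t - zres)
        h = rp * r * np.cos(s) + slope * slope
        h = np.where(np.abs(h) < 1e-12, 1e-12, h)
        t = t - np.clip(g / h, -0.5, 0.5)
    s = t - phi
    return rp**2 + r**2 - 2.0 * rp * r * np.cos(s) + (slope * t - zres) ** 2


def grid_min_objective(X: np.ndarray, step_deg: float = 2.0) -> float:
    """Minimum Σdᵢ² over the spherical axis grid with closed-form fits."""
    X = np.asarray(X, dtype=float)
    n = len(X)
    axes = sphere_grid(step_deg)
    # in-plane frames: u ⟂ axis, chosen from whichever basis vector is least aligned
    ref = np.where(
        np.abs(axes[:, 2:3]) < 0.9,
        np.array([0.0, 0.0, 1.0]),
        np.array([1.0, 0.0, 0.0]),
    )
    u = np.cross(axes, ref)
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    v = np.cross(axes, u)

    xu = X @ u.T  # (n, A)
    xv = X @ v.T
    xz = X @ axes.T

    # algebraic (Kasa) circle fit per axis: [x y 1] [2cx 2cy c]ᵀ = x²+y²
    ones = np.ones_like(xu)
    b = xu**2 + xv**2
    design = np.stack([xu, xv, ones], axis=2)  # (n, A, 3)
    At = design.transpose(1, 2, 0)  # (A, 3, n)
    AtA = At @ design.transpose(1, 0, 2)
    Atb = np.einsum("aij,ja->ai", At, b)
    sol = np.linalg.solve(AtA, Atb[..., None])[..., 0]  # (A, 3)
    cx, cy = sol[:, 0] / 2.0, sol[:, 1] / 2.0
    r = np.sqrt(np.maximum(sol[:, 2] + cx**2 + cy**2, 1e-12))

    theta = np.unwrap(np.arctan2(xv - cy, xu - cx), axis=0)
    tm = theta.mean(axis=0)
    zm = xz.mean(axis=0)
    var = ((theta - tm) ** 2).sum(axis=0)
    var = np.where(var < 1e-12, 1e-12, var)
    slope = ((theta - tm) * (xz - zm)).sum(axis=0) / var
    intercept = zm - slope * tm

    d2 = _closest_distance_sq(xu, xv, xz, cx, cy, slope, intercept, r, theta)
    return float(d2.sum(axis=0).min())
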