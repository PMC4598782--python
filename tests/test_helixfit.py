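"""Unit tests of the circular-helix and 3D-circle fits."""

import math
import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lrrgeom.helixfit import (
    DegenerateGeometryError,
    FitError,
    fit_circle_3d,
    fit_helix,
    helix_curve_point,
    spacing_summary,
)

from conftest import canonical_helix, random_rotation

sys.path.insert(0, str(Path(__file__).parent))
from _oracles import grid_min_objective  # noqa: E402


@pytest.mark.parametrize(
    "P,R,N,n",
    [
        (36.0, 15.0, 8.0, 24),
        (-36.0, 15.0, 8.0, 24),
        (4.84, 20.09, 25.13, 7),
        (-0.5, 20.0, 25.0, 9),
        (41.6, 27.1, 35.2, 19),
    ],
)
def test_noiseless_recovery(P, R, N, n):
    """An exact helix is recovered to machine precision in any orientation."""
    X = canonical_helix(P, R, N, n) @ random_rotation(3).T + np.array([7.0, -4.0, 2.0])
    f = fit_helix(X)
    assert f.P == pytest.approx(P, rel=1e-9, abs=1e-9)
    assert f.R == pytest.approx(R, rel=1e-9)
    assert f.N == pytest.approx(N, rel=1e-9)
    assert f.rmsd < 1e-10
    assert f.n == n


def test_mirror_reflection_flips_handedness():
    X = canonical_helix(36.0, 15.0, 8.0, 24)
    f = fit_helix(X * np.array([1.0, 1.0, -1.0]))
    assert f.P == pytest.approx(-36.0, rel=1e-9)
    assert f.R == pytest.approx(15.0, rel=1e-9)
    assert f.N == pytest.approx(8.0, rel=1e-9)


def test_rigid_motion_leaves_scalars(rng):
    Q = random_rotation(11)
    t = np.array([12.0, -30.0, 5.0])
    # noiseless: every parameter is sharply determined and must agree to 1e-9
    X = canonical_helix(-22.0, 21.0, 27.0, 16)
    f0, f1 = fit_helix(X), fit_helix(X @ Q.T + t)
    for attr in ("P", "R", "N", "rmsd", "p"):
        assert getattr(f1, attr) == pytest.approx(getattr(f0, attr), abs=1e-9)
    assert Q @ f0.axis_dir == pytest.approx(f1.axis_dir, abs=1e-6)
    # noisy: the pitch/axis directions of the objective are soft, so the
    # minimum location is only defined to ~1e-7 in double precision
    Xn = X + rng.normal(0, 0.2, (16, 3))
    f0, f1 = fit_helix(Xn), fit_helix(Xn @ Q.T + t)
    for attr in ("P", "R", "N", "rmsd", "p"):
        assert getattr(f1, attr) == pytest.approx(getattr(f0, attr), abs=1e-6)


def test_order_reversal_flips_axis_not_parameters(rng):
    X = canonical_helix(30.0, 18.0, 24.0, 14) + rng.normal(0, 0.1, (14, 3))
    f = fit_helix(X)
    g = fit_helix(X[::-1])
    assert g.axis_dir @ f.axis_dir == pytest.approx(-1.0, abs=1e-6)
    assert g.P == pytest.approx(f.P, abs=1e-6)
    assert g.R == pytest.approx(f.R, abs=1e-6)
    assert g.N == pytest.approx(f.N, abs=1e-6)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(
    P=st.floats(-45.0, 45.0),
    R=st.floats(12.0, 30.0),
    N=st.floats(5.0, 38.0),
    n=st.integers(6, 28),
    sigma=st.floats(0.0, 0.4),
    seed=st.integers(0, 10_000),
)
def test_regularity_identity_and_spacing_closure(P, R, N, n, sigma, seed):
    """p = rmsd/(n-1)^1/2 exactly; observed spacing matches the helix formula."""
    rng = np.random.default_rng(seed)
    X = canonical_helix(P, R, N, n) + rng.normal(0, sigma, (n, 3))
    try:
        f = fit_helix(X)
    except FitError:
        return  # gross noise relative to geometry; fit validly refuses
    assert f.p == f.rmsd / math.sqrt(f.n - 1)
    assert f.dz * f.N == pytest.approx(f.P, rel=1e-12, abs=1e-12)
    assert f.dphi * f.N == pytest.approx(360.0, rel=1e-12)
    s = spacing_summary(X, f)
    assert abs(s.D_eq1 - s.D_mean) <= 3.0 * sigma + 1e-9


def test_curve_point_identities():
    X = canonical_helix(36.0, 15.0, 8.0, 24) @ random_rotation(5).T
    f = fit_helix(X)
    p0 = helix_curve_point(f, 0.0)
    p360 = helix_curve_point(f, 360.0)
    # one full turn advances by the pitch along the axis
    assert (p360 - p0) @ f.axis_dir == pytest.approx(f.P, rel=1e-9)
    assert np.linalg.norm(np.cross(p360 - p0, f.axis_dir)) == pytest.approx(0.0, abs=1e-8)
    # distance from axis equals the radius
    radial = p0 - f.axis_point
    radial -= (radial @ f.axis_dir) * f.axis_dir
    assert np.linalg.norm(radial) == pytest.approx(f.R, rel=1e-9)


def test_rmsd_matches_independent_residuals(rng):
    """Distances recomputed by dense sampling of the curve reproduce rmsd."""
    X = canonical_helix(-28.0, 22.0, 29.0, 12) + rng.normal(0, 0.25, (12, 3))
    f = fit_helix(X)
    ts = np.linspace(f.azimuths.min() - 30.0, f.azimuths.max() + 30.0, 400_001)
    curve = helix_curve_point(f, ts)
    d2 = ((X[:, None, :] - curve[None, :, :]) ** 2).sum(axis=2).min(axis=1)
    assert math.sqrt(d2.mean()) == pytest.approx(f.rmsd, rel=1e-5)


def test_too_few_points_and_collinear_errors():
    with pytest.raises(FitError):
        fit_helix(canonical_helix(36, 15, 8, 4))
    line = np.outer(np.arange(8.0), np.array([1.0, 2.0, 3.0]))
    with pytest.raises(FitError):
        fit_helix(line)


def test_oracle_equivalence_small(rng):
    """The nonlinear fit matches the spherical-grid brute-force minimum."""
    for seed in range(5):
        X = canonical_helix(-30.0, 22.0, 28.0, 12) @ random_rotation(seed).T
        X = X + np.random.default_rng(seed).normal(0, 0.2, (12, 3))
        f = fit_helix(X)
        assert f.rmsd**2 * f.n <= 1.01 * grid_min_objective(X)


# --- 3D circle fit -----------------------------------------------------------


def test_circle_exact_recovery():
    th = np.deg2rad(np.arange(8) * 40.0)
    X = np.column_stack([20 * np.cos(th), 20 * np.sin(th), np.zeros(8)])
    X = X @ random_rotation(2).T + np.array([1.0, 2.0, 3.0])
    c = fit_circle_3d(X)
    assert c.radius == pytest.approx(20.0, abs=1e-9)
    assert c.rmsd < 1e-10


def test_circle_noisy_recovery(rng):
    th = np.deg2rad(np.arange(8) * 40.0)
    base = np.column_stack([20 * np.cos(th), 20 * np.sin(th), np.zeros(8)])
    errs = [
        abs(fit_circle_3d(base + rng.normal(0, 0.1, (8, 3))).radius - 20.0)
        for _ in range(200)
    ]
    assert np.median(errs) < 0.15


def test_circle_orientation_follows_sequence():
    th = np.deg2rad(np.arange(8) * 40.0)
    X = np.column_stack([20 * np.cos(th), 20 * np.sin(th), np.zeros(8)])
    assert fit_circle_3d(X).normal @ [0, 0, 1] > 0.99
    assert fit_circle_3d(X[::-1]).normal @ [0, 0, 1] < -0.99


def test_circle_collinear_error():
    with pytest.raises(DegenerateGeometryError):
        fit_circle_3d(np.outer(np.arange(3.0), [1.0, 1.0, 0.0]))


def test_spacing_flat_circle_reduces_to_chord():
    X = canonical_helix(0.0, 17.0, 20.0, 10)
    f = fit_helix(X)
    s = spacing_summary(X, f)
    chord = 2.0 * f.R * math.sin(math.radians(f.dphi) / 2.0)
    assert s.D_eq1 == pytest.approx(chord, rel=1e-9)
    assert s.D_mean == pytest.approx(s.D_eq1, rel=1e-9)
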