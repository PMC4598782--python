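"""Subdomain decomposition, dimer geometry and shape classification."""

import numpy as np
import pytest

from lrrgeom.assembly import (
    classify_shape,
    detect_subdomains,
    dimer_geometry,
    subdomain_angle,
)
from lrrgeom.helixfit import fit_helix
from lrrgeom.simulate import (
    DimerSpec,
    HelixSpec,
    make_dimer,
    make_helix_points,
    make_kinked_domain,
)

from conftest import canonical_helix, random_rotation


def test_identical_fits_have_zero_angle():
    pts, _ = make_helix_points(HelixSpec(P=30, R=18, N=24, n=12))
    f = fit_helix(pts)
    # arccos near 1 resolves angles only to ~sqrt(eps) radians
    assert subdomain_angle(f, f) == pytest.approx(0.0, abs=1e-5)


def test_kink_angle_recovery_with_noise():
    """A 20° kink between two well-determined subdomains is recovered to 1°."""
    errs = []
    for seed in range(12):
        sa = HelixSpec(P=-25, R=22, N=28, n=16, noise_sd=0.2, seed=seed)
        sb = HelixSpec(P=-25, R=22, N=28, n=16)
        pts, truth = make_kinked_domain(sa, sb, 20.0)
        split = detect_subdomains(pts, split_points=(truth["split_start"],))
        errs.append(split.omega[0] - 20.0)
    assert abs(np.mean(errs)) < 1.0
    assert np.median(np.abs(errs)) < 1.0


def test_split_detection_recovers_generator_split():
    """The exhaustive search finds the kink (the junction point itself lies
    on both helices, so the split may land on either side of it)."""
    sa = HelixSpec(P=33, R=15, N=20, n=8, noise_sd=0.1, seed=1)
    sb = HelixSpec(P=33, R=15, N=20, n=8)
    pts, truth = make_kinked_domain(sa, sb, 40.0)
    split = detect_subdomains(pts)
    assert len(split.split_indices) == 1
    assert split.split_indices[0] in (truth["split_start"], truth["split_start"] + 1)


def test_user_split_matches_auto_detection():
    sa = HelixSpec(P=33, R=15, N=20, n=8, noise_sd=0.1, seed=3)
    sb = HelixSpec(P=33, R=15, N=20, n=8)
    pts, truth = make_kinked_domain(sa, sb, 40.0)
    auto = detect_subdomains(pts)
    manual = detect_subdomains(pts, split_points=auto.split_indices)
    assert manual.omega[0] == pytest.approx(auto.omega[0], abs=1e-9)
    assert manual.weighted_rmsd == pytest.approx(auto.weighted_rmsd, abs=1e-12)


def test_ideal_helix_stays_single_domain():
    pts, _ = make_helix_points(HelixSpec(P=36, R=15, N=8, n=24))
    split = detect_subdomains(pts)
    assert split.split_indices == () and split.omega == ()


def test_split_never_increases_weighted_rmsd(rng):
    for seed in range(5):
        X = canonical_helix(20, 18, 26, 16) + np.random.default_rng(seed).normal(
            0, 0.6, (16, 3)
        )
        whole = fit_helix(X)
        split = detect_subdomains(X)
        assert split.weighted_rmsd <= whole.rmsd + 1e-12


def test_angles_invariant_under_common_rigid_motion():
    sa = HelixSpec(P=33, R=15, N=20, n=8, noise_sd=0.1, seed=5)
    sb = HelixSpec(P=33, R=15, N=20, n=8)
    pts, truth = make_kinked_domain(sa, sb, 16.3)
    s0 = detect_subdomains(pts, split_points=(9,))
    Q = random_rotation(7)
    s1 = detect_subdomains(pts.points @ Q.T + np.array([5.0, 6.0, 7.0]), split_points=(9,))
    assert s1.omega[0] == pytest.approx(s0.omega[0], abs=1e-7)


def test_dimer_pure_translation():
    """A copy translated 50 Å perpendicular to the axis: L = 50, ψ = 0."""
    pts, _ = make_helix_points(HelixSpec(P=30, R=20, N=28, n=16))
    shifted = pts.points + np.array([50.0, 0.0, 0.0])
    g = dimer_geometry(pts.points, shifted)
    assert g.L == pytest.approx(50.0, abs=1e-9)
    assert g.psi == pytest.approx(0.0, abs=1e-9)


def test_dimer_twofold_symmetry_across_configurations():
    """ψ and L are symmetric and recovered across seeded two-fold dimers."""
    rng = np.random.default_rng(0)
    for _ in range(10):
        L = float(rng.uniform(20, 90))
        psi = float(rng.uniform(90, 175))
        m = HelixSpec(P=float(rng.uniform(-35, 35)), R=22, N=29, n=18,
                      noise_sd=0.1, seed=int(rng.integers(1 << 16)))
        a, b, _ = make_dimer(DimerSpec(monomer=m, L_true=L, psi_true=psi))
        g, g2 = dimer_geometry(a, b), dimer_geometry(b, a)
        assert g.L == pytest.approx(g2.L) and g.psi == pytest.approx(g2.psi)
        assert g.L == pytest.approx(L, abs=1.0)
        assert g.psi == pytest.approx(psi, abs=2.5)


@pytest.mark.parametrize(
    "dz,expected",
    [(1.6, "right"), (-1.1, "left"), (0.19, "flat"), (-0.29, "flat")],
)
def test_classify_handedness(dz, expected):
    N = 25.0
    pts, _ = make_helix_points(HelixSpec(P=dz * N, R=20, N=N, n=10))
    label = classify_shape(fit_helix(pts), flat_threshold=0.3)
    assert label.handedness == expected


def test_classify_nearest_centroid_group():
    centroids = {"TLR3_8_9": (0.05, 5.0), "TLR1_2_6": (-1.05, 4.9)}
    pts, _ = make_helix_points(HelixSpec(P=-30, R=22.5, N=28.7, n=20))
    label = classify_shape(fit_helix(pts), group_centroids=centroids)
    assert label.tlr_group == "TLR1_2_6"
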