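"""Subdomain and dimer geometry, plus handedness/flatness classification.

A distorted solenoid (regularity p above threshold) is decomposed into
subdomains, each refitted as its own helix; adjacent subdomain axes define
the inter-axis angle Ω.  For dimers, ψ is the angle between the two
monomers' oriented (N→C) helix axes and L the distance between their
3D-circle-fit centers.  Handedness is read from the sign of the rise per
unit Δz, with |Δz| below a flatness threshold classed as flat.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np

from .helixfit import (
    CircleFit,
    FitError,
    HelixFit,
    fit_circle_3d,
    fit_helix,
)

__all__ = [
    "SubdomainSplit",
    "DimerGeometry",
    "ShapeLabel",
    "subdomain_angle",
    "detect_subdomains",
    "dimer_geometry",
    "classify_shape",
]

log = logging.getLogger(__name__)


def _xyz(points) -> np.ndarray:
    return np.asarray(getattr(points, "points", points), dtype=float)


@dataclasses.dataclass(frozen=True)
class SubdomainSplit:
    """Subdomain decomposition: start indices, per-subdomain fits, angles.

    ``split_indices`` holds the 1-based repeat index at which each
    subdomain after the first starts (empty for a single-domain fit).
    ``omega`` holds the inter-axis angle in degrees for each adjacent
    subdomain pair.  ``weighted_rmsd`` is the length-weighted combined
    rmsd, sqrt(sum of squared residuals / total points).
    """

    split_indices: tuple[int, ...]
    fits: tuple[HelixFit, ...]
    omega: tuple[float, ...]
    weighted_rmsd: float


@dataclasses.dataclass(frozen=True)
class DimerGeometry:
    """Pairwise monomer arrangement: center distance L and axis angle ψ."""

    L: float  # Å, >= 0
    psi: float  # degrees, in [0, 180]
    fit_a: HelixFit
    fit_b: HelixFit
    circle_a: CircleFit
    circle_b: CircleFit


@dataclasses.dataclass(frozen=True)
class ShapeLabel:
    handedness: str  # "right" | "left" | "flat"
    tlr_group: str = "none"


def subdomain_angle(fit_a: HelixFit, fit_b: HelixFit) -> float:
    """Angle Ω between two oriented (N→C) helix axes, degrees in [0, 180]."""
    c = float(np.clip(fit_a.axis_dir @ fit_b.axis_dir, -1.0, 1.0))
    return math.degrees(math.acos(c))


def _combined_rmsd(fits: list[HelixFit]) -> float:
    ss = sum(f.rmsd**2 * f.n for f in fits)
    n = sum(f.n for f in fits)
    return math.sqrt(ss / n)


def _search_split(X: np.ndarray, offset: int, min_len: int, depth: int,
                  p_threshold: float) -> list[tuple[int, HelixFit]]:
    """Return [(start_repeat_index, fit), ...] covering X, splitting greedily.

    ``offset`` is the 1-based repeat index of X[0].  Exhaustive single-split
    search minimising the length-weighted combined rmsd, recursing at most
    ``depth`` more times per side (so three subdomains are reachable).
    """
    n = len(X)
    whole = fit_helix(X)
    if whole.p <= p_threshold or depth == 0 or n < 2 * min_len:
        return [(offset, whole)]
    best = None
    for s in range(min_len, n - min_len + 1):  # X[s] starts the second side
        try:
            fa = fit_helix(X[:s])
            fb = fit_helix(X[s:])
        except FitError:
            continue
        cost = _combined_rmsd([fa, fb])
        if best is None or cost < best[0]:
            best = (cost, s, fa, fb)
    if best is None or best[0] >= whole.rmsd:
        return [(offset, whole)]
    _, s, fa, fb = best
    left = (
        _search_split(X[:s], offset, min_len, depth - 1, p_threshold)
        if fa.p > p_threshold and s >= 2 * min_len
        else [(offset, fa)]
    )
    right = (
        _search_split(X[s:], offset + s, min_len, depth - 1, p_threshold)
        if fb.p > p_threshold and n - s >= 2 * min_len
        else [(offset + s, fb)]
    )
    return left + right


def detect_subdomains(
    points,
    min_len: int = 5,
    p_threshold: float = 0.2,
    split_points: tuple[int, ...] | None = None,
) -> SubdomainSplit:
    """Decompose a repeat domain into helical subdomains.

    If the whole-domain fit is regular (p <= ``p_threshold``, Å) a single
    subdomain is returned.  Otherwise every single split point with both
    sides >= ``min_len`` is tried and the length-weighted combined rmsd
    minimised; each side may be split once more, allowing up to three
    subdomains.  User-supplied ``split_points`` (1-based repeat indices at
    which a new subdomain starts) bypass the search.
    """
    X = _xyz(points)
    n = len(X)
    if split_points:
        bounds = [1] + sorted(split_points) + [n + 1]
        fits = tuple(
            fit_helix(X[a - 1 : b - 1]) for a, b in zip(bounds, bounds[1:])
        )
        starts = tuple(bounds[1:-1])
    elif n < 2 * min_len:
        if n >= min_len:
            log.warning("only %d points; subdomain search skipped", n)
            fits = (fit_helix(X),)
            starts = ()
        else:
            raise FitError(f"too few points ({n}) for subdomain analysis")
    else:
        parts = _search_split(X, 1, min_len, depth=2, p_threshold=p_threshold)
        starts = tuple(s for s, _ in parts[1:])
        fits = tuple(f for _, f in parts)
    omega = tuple(
        subdomain_angle(fa, fb) for fa, fb in zip(fits, fits[1:])
    )
    return SubdomainSplit(
        split_indices=starts,
        fits=fits,
        omega=omega,
        weighted_rmsd=_combined_rmsd(list(fits)),
    )


def dimer_geometry(points_a, points_b) -> DimerGeometry:
    """Geometry of a two-monomer arrangement.

    ψ is computed from the oriented helix axes (N→C of each monomer) and L
    from the centers of the 3D circle fits.  Both are symmetric in the
    argument order.
    """
    fit_a = fit_helix(points_a)
    fit_b = fit_helix(points_b)
    circle_a = fit_circle_3d(points_a)
    circle_b = fit_circle_3d(points_b)
    L = float(np.linalg.norm(circle_a.center - circle_b.center))
    psi = subdomain_angle(fit_a, fit_b)
    return DimerGeometry(
        L=L, psi=psi, fit_a=fit_a, fit_b=fit_b,
        circle_a=circle_a, circle_b=circle_b,
    )


def classify_shape(
    fit: HelixFit,
    flat_threshold: float = 0.3,
    group_centroids: dict[str, tuple[float, float]] | None = None,
) -> ShapeLabel:
    """Handedness/flatness label, optionally with a nearest-centroid group.

    Handedness is the sign of Δz; |Δz| <= ``flat_threshold`` (Å) is flat.
    When ``group_centroids`` maps group names to (Δz, 2R·sin(ΔΦ/2))
    centroids, the nearest one in that plane names the group.
    """
    dz = fit.dz
    if abs(dz) <= flat_threshold:
        handedness = "flat"
    else:
        handedness = "right" if dz > 0 else "left"
    group = "none"
    if group_centroids:
        chord = 2.0 * fit.R * math.sin(math.radians(fit.dphi) / 2.0)
        group = min(
            group_centroids,
            key=lambda g: (dz - group_centroids[g][0]) ** 2
            + (chord - group_centroids[g][1]) ** 2,
        )
    return ShapeLabel(handedness=handedness, tlr_group=group)
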