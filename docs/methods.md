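# Methods

## The model

An LRR solenoid is idealised as a circular helix sampled once per repeat
unit.  The reference point of repeat *i* is the Cα of the consensus
residue at position 4 of the highly conserved segment (HCS) — the middle
residue of the short β-strand — so a domain of *n* repeats yields an
ordered set of *n* points.  The helix is parameterised by a point **c**
on the axis, a unit axis direction **a**, radius *R* > 0, signed pitch
*P* (axial advance per 360° turn; positive means a right-handed screw)
and one curve parameter tᵢ per point:

x(t) = **c** + R·(cos t·**u** + sin t·**v**) + (P·t/360°)·**a**

with (**u**, **v**, **a**) orthonormal.  The fit minimises Σᵢ |x(tᵢ) − pᵢ|²
over all of (**c**, **a**, R, P, t₁…tₙ).  Because the tᵢ are free, each
residual is (at the optimum) the true closest distance from the point to
the helix curve, restricted to the point's own turn: an *infinite*
near-flat helix winds arbitrarily close to any point set, so each tᵢ is
kept on the azimuth branch the ordered sequence assigns it.

Derived quantities: rmsd = (Σdᵢ²/n)^½; regularity p = rmsd/(n − 1)^½
(length-independent); units per turn N = 360°·(n − 1)/|t_n − t₁|;
rise per unit Δz = P/N; rotation per unit ΔΦ = 360°/N.  The identities
Δz·N = P and ΔΦ·N = 360° hold by construction.  The axis is oriented so
the repeat sequence advances N→C along it; for an almost exactly flat
fit the tie is broken so the sequence turns counterclockwise.  Handedness
(the sign of P) is intrinsic — it does not depend on the axis
orientation and flips only under reflection.

The 3D circle fit projects the points onto their total-least-squares
plane and fits a circle there (algebraic initialisation, geometric
Gauss–Newton refinement); its rmsd is the in-plane radial residual and
its normal is oriented by the sequence's sense of rotation.  The circle
center is the anchor for the dimer distance *L*.

Assembly parameters: Ω = arccos(**a**₁·**a**₂) between the oriented axes
of two subdomains; ψ the same between two monomers of a dimer; *L* the
distance between the monomers' circle centers.  The oriented-axis
convention matters: nearly antiparallel dimer arrangements give ψ near
180° only when both axes are oriented N→C.

## Fitting algorithm

1. **Pose canonicalisation.**  The points are centred and rotated into a
   frame built from the data: third axis = principal eigenvector of the
   second-moment matrix of successive chord cross-products (sign-fixed by
   the sequence's rotation sense), first axis = the first point's radial
   direction.  All subsequent arithmetic is then identical for any rigid
   motion of the same points, which makes the fitted scalars reproducible
   across poses to rounding — important because the objective is nearly
   flat along some pitch/axis combinations (below).
2. **Initial axes.**  Candidates: the cross-product moment axis plus the
   smallest- and largest-variance principal directions of the cloud.
   Each candidate is scored by a closed-form profile (project onto the
   orthogonal plane → algebraic circle fit → unwrap azimuths → regress
   the axial coordinate on azimuth, slope = P/360°); clearly hopeless
   candidates (profile objective > 4× the best refined objective) are
   skipped.
3. **Refinement.**  Full nonlinear least squares (scipy trust-region
   reflective, analytic Jacobian, R > 0 bound) over axis perturbation
   (2 dof), **c**, R, P and all tᵢ; the best candidate's result is kept.
   Convergence: ftol 1e-14, xtol/gtol 1e-15, max 500 iterations ×
   parameters.  A final per-point Newton polish re-solves each tᵢ and the
   distances are evaluated by explicit vector difference (the cylindrical
   closed form cancels catastrophically when residuals approach machine
   precision).

Failure modes raise typed errors: fewer than 5 points (the axis/pitch
problem is ill-posed below that), collinear points, or near-zero total
azimuth change ("no rotational progression").

## Conditioning and a known bias

Noiseless points are recovered to ~1e-13 relative in (P, R, N).  With
noise, two regimes matter:

- **Soft pitch for short, shallow arcs.**  For a 7–8-point arc covering
  ~90–130° of turn, tilting the axis trades almost exactly against pitch:
  at 0.05–0.2 Å noise the pitch of a nearly flat domain is determined
  only to ±2–5 Å even at the information-theoretic limit (verified
  against a truth-initialised, equal-spacing-constrained fit, which shows
  the same scatter).  This is a property of the data, not the optimiser —
  equivalent chains of real near-flat trimers show pitch spreads of the
  same magnitude.  It also bounds numerical reproducibility: for noisy
  inputs the optimum's location along the soft direction is only defined
  to ~1e-7 in double precision (noiseless fits reproduce to 1e-9 and
  better across rigid motions).
- **Upward bias of inter-axis angles.**  Ω and ψ are angles between two
  *estimated* axes.  Perpendicular axis errors add in quadrature, so for
  small true angles and large axis scatter the estimate is biased upward.
  With 8-point subdomains at σ = 0.2 Å (per-axis scatter ~4°), a true
  16.3° kink is recovered at ≈ 18.2° on average (+1.9° bias, ~5° sd).
  Dimer configurations fitted from 20–25-point monomers have ~0.4° axis
  scatter and recover ψ essentially unbiased (< 0.06° mean error).  The
  package reports the plain angle between fitted axes — no bias
  correction is applied — and the synthetic-assembly analysis
  (analysis/03) prints the measured distribution.

## Subdomain search

A domain whose single-helix fit has p > 0.2 Å is decomposed: every
single split point with both sides ≥ 5 points is tried exhaustively and
the length-weighted combined rmsd, (ΣΣdᵢ²/n)^½, minimised; each side may
be split once more, allowing up to three subdomains.  The search never
returns a split worse than the single-domain fit (the single fit is the
fallback), and user-supplied split points bypass it.  At a
tangent-continuous kink the junction point lies on both helices, so the
detected split can land on either side of it.

## Synthetic data

Generators produce exactly what the analysis assumes: helix points at
equal azimuth steps plus isotropic Gaussian noise (σ per coordinate;
the model has no preferred direction and neither does the fit
objective), rigid motions drawn uniformly, kinked domains joined
tangent-continuously at an exact inter-axis angle, two-fold dimers
placed so the noiseless circle centers are exactly *L* apart and the
oriented axes meet at exactly ψ, and consensus sequences with known HCS
starts (x-positions drawn from residues outside the L/N classes so the
ground truth stays unambiguous, with an option to substitute random
residues).  All generators are bit-reproducible from (spec, seed).

What they deliberately do not emulate: correlated coordinate error,
missing residues and alternate conformations beyond what the I/O layer
handles, repeat-length irregularity within a domain, and real curvature
deviations (elliptical arcs).  Passing tests therefore demonstrate
correctness of the geometry and its estimators under the stated noise
model, not robustness to every artefact of deposited structures.

The study cohort (`simulate.study_cohort`) instantiates one spec per
receptor family/endpoint at the published helical parameters (pitch,
radius, units per turn, repeat count) with 0.1 Å noise — the scale of
coordinate uncertainty in well-refined crystal structures.  Its grand
mean adjacent-repeat spacing computes to ≈ 5.0 Å, the conserved
β-strand stacking distance.

## Problem sizes and defaults

Defaults, all configurable: minimum 5 points per helix fit; p threshold
0.2 Å for subdomain search; flatness threshold |Δz| ≤ 0.3 Å (chosen
between the ≈0.2 Å rises called "nearly flat" and the ≥0.7 Å rises
called left-handed in this family; the boundary is descriptive, not
physical); scanner minimum inter-match spacing 12 residues and default
last-unit length 24.  Test and acceptance runs use 16–512 seeded
replicates per configuration, sized so that each verdict's sampling
error is small against its tolerance; a single fit takes ~5–20 ms, so
the whole suite runs in well under a minute of fitting time.

## Structure input conventions

Model 1 only; alternate locations resolved to the highest occupancy
(ties → first in file); non-standard amino acids with a Cα (e.g.
selenomethionine) kept under their parent one-letter code; author
residue numbering with insertion codes throughout; annotation position 4
found by walking three residues along the chain from the HCS start.
Units whose position-4 Cα is missing are dropped (never interpolated)
and recorded as gaps.  Fetching by accession is off unless a cache
directory is configured; all tests run from local synthetic fixtures.
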