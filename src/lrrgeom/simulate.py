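"""Ground-truth generators for helices, kinked domains, dimers and sequences.

These generators produce the inputs the analysis assumes: ordered reference
points on circular helices of known pitch/radius/units-per-turn with
isotropic Gaussian positional noise, two-subdomain domains at a known
inter-axis angle, two-fold-related dimers at known center distance L and
axis angle ψ, and LRR-consensus sequences with known HCS starts.  All
output is bit-reproducible given the spec and seed.

The generators can also emit Cα-only PDB/mmCIF files plus the matching
annotation TSV, so the file-reading and annotation paths are exercised
end to end without downloads.
"""

from __future__ import annotations

import dataclasses
import math

import gemmi
import numpy as np

from .helixfit import _perp_frame, fit_circle_3d
from .repeats import ReferencePointSet

__all__ = [
    "RigidMotion",
    "HelixSpec",
    "DimerSpec",
    "make_helix_points",
    "make_kinked_domain",
    "make_dimer",
    "make_lrr_sequence",
    "write_ca_structure",
    "write_annotation_tsv",
    "study_cohort",
]

_TWO_PI = 2.0 * math.pi


@dataclasses.dataclass(frozen=True)
class RigidMotion:
    rotation: np.ndarray  # (3, 3) proper rotation
    translation: np.ndarray  # (3,)

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        return xyz @ np.asarray(self.rotation).T + np.asarray(self.translation)

    @staticmethod
    def identity() -> "RigidMotion":
        return RigidMotion(np.eye(3), np.zeros(3))

    @staticmethod
    def random(rng: np.random.Generator, translation_scale: float = 50.0) -> "RigidMotion":
        # uniform rotation via QR of a Gaussian matrix, sign-corrected
        q, r = np.linalg.qr(rng.normal(size=(3, 3)))
        q *= np.sign(np.diag(r))
        if np.linalg.det(q) < 0:
            q[:, 0] = -q[:, 0]
        return RigidMotion(q, rng.normal(scale=translation_scale, size=3))


@dataclasses.dataclass(frozen=True)
class HelixSpec:
    """Generative counterpart of the fitted helix parameters."""

    P: float  # pitch, Å, signed (positive = right-handed)
    R: float  # radius, Å, > 0
    N: float  # units per turn, > 2
    n: int  # number of points, >= 5
    phase: float = 0.0  # starting azimuth, degrees
    noise_sd: float = 0.0  # isotropic Gaussian σ per coordinate, Å
    seed: int = 0
    frame: RigidMotion | None = None  # rigid motion applied after generation

    def __post_init__(self):
        if self.R <= 0 or self.N <= 2 or self.n < 5 or self.noise_sd < 0:
            raise ValueError(f"invalid helix spec: {self}")

    @property
    def dz(self) -> float:
        return self.P / self.N

    @property
    def dphi(self) -> float:
        return 360.0 / self.N

    @property
    def D(self) -> float:
        """Adjacent-point spacing implied by the parameters."""
        chord = 2.0 * self.R * math.sin(math.radians(self.dphi) / 2.0)
        return math.sqrt(chord * chord + self.dz * self.dz)


@dataclasses.dataclass(frozen=True)
class DimerSpec:
    monomer: HelixSpec
    L_true: float  # Å, >= 0
    psi_true: float  # degrees, in [0, 180]
    seed: int = 0

    def __post_init__(self):
        if self.L_true < 0 or not 0.0 <= self.psi_true <= 180.0:
            raise ValueError(f"invalid dimer spec: {self}")


def _canonical_points(spec: HelixSpec) -> np.ndarray:
    """Noiseless helix points in the canonical frame (axis = +z)."""
    th = np.deg2rad(spec.phase + np.arange(spec.n) * spec.dphi)
    return np.column_stack(
        [spec.R * np.cos(th), spec.R * np.sin(th), spec.P * th / _TWO_PI]
    )


def _finish(xyz: np.ndarray, spec: HelixSpec, chain: str,
            rng: np.random.Generator | None = None) -> ReferencePointSet:
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    if spec.noise_sd > 0:
        xyz = xyz + rng.normal(scale=spec.noise_sd, size=xyz.shape)
    frame = spec.frame or RigidMotion.identity()
    xyz = frame.apply(xyz)
    labels = tuple((chain, i + 1) for i in range(len(xyz)))
    return ReferencePointSet(points=xyz, labels=labels)


def make_helix_points(spec: HelixSpec, chain: str = "A") -> tuple[ReferencePointSet, HelixSpec]:
    """Reference points on a circular helix; the truth record is the spec."""
    return _finish(_canonical_points(spec), spec, chain), spec


def make_kinked_domain(
    spec_a: HelixSpec,
    spec_b: HelixSpec,
    omega_true: float,
    chain: str = "A",
) -> tuple[ReferencePointSet, dict]:
    """A two-subdomain point set whose oriented axes meet at ``omega_true``.

    The second segment is rotated so its (N→C oriented) axis makes exactly
    ``omega_true`` degrees with the first and is joined continuously: its
    first point sits where the first helix's next point would have been.
    Noise and frame come from ``spec_a``.
    """
    if not 0.0 <= omega_true <= 180.0:
        raise ValueError("omega_true must be in [0, 180] degrees")
    A = _canonical_points(spec_a)
    B = _canonical_points(spec_b)
    # phase-advance B to the junction azimuth so that omega_true = 0 with
    # identical specs continues A's helix exactly (tangent-continuous join)
    phi_j = math.radians(spec_a.phase + spec_a.n * spec_a.dphi - spec_b.phase)
    cj, sj = math.cos(phi_j), math.sin(phi_j)
    rz = np.array([[cj, -sj, 0], [sj, cj, 0], [0, 0, 1]], dtype=float)
    B = B @ rz.T
    # oriented axis of a canonical helix is sign(P) * z (flat: +z)
    sa = 1.0 if spec_a.P >= 0 else -1.0
    sb = 1.0 if spec_b.P >= 0 else -1.0
    # rotate B about x so that angle(sa*z, sb*Rot(z)) = omega_true
    ang = math.radians(omega_true if sa * sb > 0 else 180.0 - omega_true)
    c, s = math.cos(ang), math.sin(ang)
    rot = np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)
    B = B @ rot.T
    # continuous join: B starts at A's (n+1)-th position
    next_a = _canonical_points(
        dataclasses.replace(spec_a, n=spec_a.n + 1)
    )[-1]
    B = B + (next_a - B[0])
    xyz = np.vstack([A, B])
    truth = {
        "omega": omega_true,
        "split_start": spec_a.n + 1,
        "spec_a": spec_a,
        "spec_b": spec_b,
    }
    return _finish(xyz, spec_a, chain), truth


def make_dimer(spec: DimerSpec) -> tuple[ReferencePointSet, ReferencePointSet, dict]:
    """A two-fold-related dimer with exact center distance L and axis angle ψ.

    Monomer B is the image of monomer A under a two-fold rotation whose
    axis is inclined at ψ/2 to A's oriented helix axis and positioned so
    the (noiseless) circle-fit centers are exactly L apart.  Noise is then
    drawn independently per monomer; a common random frame follows.
    """
    m = spec.monomer
    A = _canonical_points(m)
    c_a = fit_circle_3d(A).center
    a_axis = np.array([0.0, 0.0, 1.0 if m.P >= 0 else -1.0])
    beta = math.radians(spec.psi_true) / 2.0
    axis2 = math.cos(beta) * a_axis + math.sin(beta) * np.array([1.0, 0.0, 0.0])
    axis2 /= np.linalg.norm(axis2)
    # direction perpendicular to the two-fold axis for the center offset
    e = np.array([1.0, 0.0, 0.0]) - (axis2[0]) * axis2
    if np.linalg.norm(e) < 1e-12:
        e = np.array([0.0, 1.0, 0.0]) - (axis2[1]) * axis2
    e /= np.linalg.norm(e)
    q = c_a + (spec.L_true / 2.0) * e
    M = 2.0 * np.outer(axis2, axis2) - np.eye(3)  # rotation by 180° about axis2
    B = (A - q) @ M.T + q
    rng = np.random.default_rng(spec.seed)
    ra, rb = rng.spawn(2)
    set_a = _finish(A, m, "A", rng=ra)
    set_b = _finish(B, m, "B", rng=rb)
    truth = {"L": spec.L_true, "psi": spec.psi_true, "monomer": m}
    return set_a, set_b, truth


# ---------------------------------------------------------------------------
# sequences

TYPICAL_CONSENSUS = "LxxLxLxxNxLxxLpxxoFxxLxx"

_L_CHOICES = "LIVF"
_N_CHOICES = "NTSC"
_X_SAFE = "ADEGHKPQR"  # never matches the L or N position classes
_ALL_AA = "ACDEFGHIKLMNPQRSTVWY"


def make_lrr_sequence(
    n_units: int,
    unit_length: int = 24,
    class_consensus: str = TYPICAL_CONSENSUS,
    seed: int = 0,
    max_x_substitutions: int = 0,
) -> tuple[str, list[int]]:
    """Concatenated LRR units instantiating the class consensus.

    Conserved L/N positions are drawn from their residue classes, ``p``
    becomes Pro, ``o``/``F`` become Phe, and ``x`` positions are drawn from
    residues outside both classes so the true HCS starts stay unambiguous.
    ``max_x_substitutions`` x-positions per unit may be replaced by fully
    random residues.  Returns the sequence and the 0-based true HCS starts.
    """
    if unit_length < 12:
        raise ValueError("unit_length must be >= 12")
    rng = np.random.default_rng(seed)
    template = (class_consensus + "x" * unit_length)[:unit_length]
    seq_parts: list[str] = []
    starts: list[int] = []
    pos = 0
    for _ in range(n_units):
        unit = []
        for ch in template:
            if ch == "L":
                unit.append(_L_CHOICES[rng.integers(len(_L_CHOICES))])
            elif ch == "N":
                unit.append(_N_CHOICES[rng.integers(len(_N_CHOICES))])
            elif ch == "p":
                unit.append("P")
            elif ch in ("o", "F"):
                unit.append("F")
            else:
                unit.append(_X_SAFE[rng.integers(len(_X_SAFE))])
        if max_x_substitutions > 0:
            x_pos = [i for i, ch in enumerate(template) if ch == "x"]
            k = int(rng.integers(max_x_substitutions + 1))
            for i in rng.choice(x_pos, size=min(k, len(x_pos)), replace=False):
                unit[i] = _ALL_AA[rng.integers(len(_ALL_AA))]
        starts.append(pos)
        seq_parts.append("".join(unit))
        pos += unit_length
    return "".join(seq_parts), starts


# ---------------------------------------------------------------------------
# fixture emission (Cα-only structures + annotation TSV)


def write_ca_structure(
    chains: dict[str, ReferencePointSet],
    path: str,
    *,
    unit_length: int = 24,
    structure_id: str = "SYNTH",
) -> None:
    """Write reference points as a Cα-only structure (PDB or mmCIF by suffix).

    Each reference point becomes the position-4 Cα of a repeat unit: four
    leucine residues are emitted per unit (HCS positions 1-4) so the
    annotation path hcs_start → hcs_start+3 resolves; positions 1-3 get
    placeholder Cα positions near the reference point.
    """
    st = gemmi.Structure()
    st.name = structure_id
    model = gemmi.Model("1")
    for chain_id, refset in chains.items():
        chain = gemmi.Chain(chain_id)
        for i, pt in enumerate(np.asarray(refset.points, dtype=float)):
            start = 1 + i * unit_length
            for k in range(4):
                res = gemmi.Residue()
                res.name = "LEU"
                res.seqid = gemmi.SeqId(start + k, " ")
                atom = gemmi.Atom()
                atom.name = "CA"
                atom.element = gemmi.Element("C")
                atom.occ = 1.0
                # quantise to the PDB fixed-format precision so the PDB and
                # mmCIF dialects carry byte-identical coordinates
                xyz = np.round(pt + (k - 3) * np.array([0.8, 0.0, 0.0]), 3)
                atom.pos = gemmi.Position(*xyz)
                res.add_atom(atom)
                chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    if str(path).endswith(".cif"):
        st.make_mmcif_document().write_file(str(path))
    else:
        st.write_pdb(str(path))


def write_annotation_tsv(
    chains: dict[str, ReferencePointSet], path: str, *, unit_length: int = 24
) -> None:
    """Annotation TSV matching :func:`write_ca_structure` numbering."""
    lines = ["chain\trepeat_index\thcs_start\tunit_length"]
    for chain_id, refset in chains.items():
        for i in range(len(refset)):
            lines.append(f"{chain_id}\t{i + 1}\t{1 + i * unit_length}\t{unit_length}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# the synthetic study cohort


def study_cohort(noise_sd: float = 0.1, base_seed: int = 0) -> dict[str, HelixSpec]:
    """Helix specs emulating the receptor families under study.

    One spec per family/endpoint, instantiated at the published helical
    parameters of the NLR/TLR leucine-rich-repeat ectodomains (pitch P,
    radius R, units per turn N, repeat count n).  NLR family members are
    right-handed or nearly flat; TLR-family members are left-handed or
    nearly flat.  Noise of 0.1 Å models coordinate uncertainty of
    well-refined crystal structures.
    """
    raw: dict[str, tuple[float, float, float, int]] = {
        # name: (P, R, N, n)
        "NLRP1": (4.84, 20.09, 25.13, 7),
        "NLRX1_lo": (-6.31, 24.10, 30.56, 8),
        "NLRX1_hi": (10.06, 24.84, 31.58, 8),
        "NLRC4_lo": (32.12, 14.67, 19.45, 16),
        "NLRC4_hi": (34.14, 15.40, 20.38, 16),
        "TLR1_2_6_lo": (-20.93, 22.02, 28.23, 20),
        "TLR1_2_6_hi": (-40.49, 22.96, 29.17, 21),
        "TLR4_lo": (-4.78, 22.64, 28.40, 23),
        "TLR4_hi": (-20.80, 23.98, 30.32, 23),
        "RP105_lo": (-4.27, 21.56, 26.45, 23),
        "RP105_hi": (-10.09, 22.43, 27.91, 24),
        "CD14_dimer": (-32.31, 22.59, 28.86, 22),
        "Toll_lo": (40.25, 26.64, 34.77, 19),
        "Toll_hi": (41.60, 27.12, 35.19, 19),
    }
    return {
        name: HelixSpec(P=P, R=R, N=N, n=n, noise_sd=noise_sd, seed=base_seed + k)
        for k, (name, (P, R, N, n)) in enumerate(raw.items())
    }
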