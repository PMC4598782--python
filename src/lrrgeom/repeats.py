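"""LRR repeat units: curated annotations, consensus scanning, reference points.

An LRR repeat unit is a highly conserved segment (HCS, consensus
``LxxLxLxxNx(x/-)L``) followed by a variable segment.  Every geometric fit
in this package consumes one reference point per repeat: the Cα of the
consensus residue at HCS position 4, which sits in the middle of the short
β-strand (HCS positions 3-5).

Curated annotations (a TSV of HCS start positions) are the primary input;
:func:`scan_hcs_motif` proposes candidate units from sequence alone and is
advisory — repeat boundaries in deposited structures were historically
finalised from the 3D structure, which a sequence scan cannot replicate.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .structure_io import ChainResidues

__all__ = [
    "AnnotationError",
    "RepeatUnit",
    "RepeatAnnotation",
    "ReferencePointSet",
    "read_annotation",
    "read_annotations",
    "scan_hcs_motif",
    "reference_points",
]

log = logging.getLogger(__name__)

# consensus position classes: "L" is any of Leu/Ile/Val/Phe, "N" any of
# Asn/Thr/Ser/Cys; x is unconstrained
L_CLASS = frozenset("LIVF")
N_CLASS = frozenset("NTSC")

MIN_UNIT_LENGTH = 12
MAX_UNIT_LENGTH = 50


class AnnotationError(ValueError):
    """A repeat annotation is malformed or empty."""


@dataclasses.dataclass(frozen=True)
class RepeatUnit:
    """One LRR repeat: HCS start, the position-4 residue, and unit length."""

    index: int
    hcs_start: int
    unit_length: int

    @property
    def pos4_seq(self) -> int:
        """Author sequence number of the consensus residue at HCS position 4."""
        return self.hcs_start + 3

    def __post_init__(self):
        if self.index < 1:
            raise AnnotationError(f"repeat index must be >= 1, got {self.index}")
        if not MIN_UNIT_LENGTH <= self.unit_length <= MAX_UNIT_LENGTH:
            log.warning(
                "repeat %d: unit length %d outside the plausible range [%d, %d]",
                self.index, self.unit_length, MIN_UNIT_LENGTH, MAX_UNIT_LENGTH,
            )


@dataclasses.dataclass(frozen=True)
class RepeatAnnotation:
    """Ordered repeat units of one chain."""

    structure_id: str
    chain_id: str
    units: tuple[RepeatUnit, ...]

    def __post_init__(self):
        if not self.units:
            raise AnnotationError("no repeat units")
        starts = [u.hcs_start for u in self.units]
        for a, b in zip(starts, starts[1:]):
            if b <= a:
                raise AnnotationError(
                    f"hcs_start not strictly increasing: {a} followed by {b}"
                )
        indices = [u.index for u in self.units]
        if indices != list(range(1, len(indices) + 1)):
            raise AnnotationError(
                f"repeat_index must be contiguous from 1, got {indices}"
            )

    @property
    def n(self) -> int:
        return len(self.units)


@dataclasses.dataclass(frozen=True)
class ReferencePointSet:
    """Ordered position-4 Cα coordinates, one per resolvable repeat unit."""

    points: np.ndarray  # (n, 3), Å
    labels: tuple[tuple[str, int], ...]  # (chain_id, repeat_index) per point
    gaps: tuple[int, ...] = ()  # repeat indices dropped for missing Cα

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        object.__setattr__(self, "points", pts)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError("points must be an (n, 3) array")
        if len(pts) != len(self.labels):
            raise ValueError("one label per point required")
        if not np.all(np.isfinite(pts)):
            raise ValueError("reference points must be finite")

    def __len__(self) -> int:
        return len(self.points)


# ---------------------------------------------------------------------------
# annotation I/O

_REQUIRED_COLUMNS = ("chain", "repeat_index", "hcs_start", "unit_length")


def read_annotations(path, structure_id: str = "") -> dict[str, RepeatAnnotation]:
    """Read a repeat-annotation TSV into per-chain annotations.

    Columns: chain, repeat_index, hcs_start, unit_length.  The position-4
    residue is derived as hcs_start + 3 (three residues along the chain).
    """
    df = pd.read_csv(path, sep="\t", dtype={"chain": str})
    for col in _REQUIRED_COLUMNS:
        if col not in df.columns:
            raise AnnotationError(f"annotation file is missing column '{col}'")
    if df.empty:
        raise AnnotationError("no repeat units")
    out: dict[str, RepeatAnnotation] = {}
    for chain_id, sub in df.groupby("chain", sort=False):
        sub = sub.sort_values("repeat_index")
        units = tuple(
            RepeatUnit(
                index=int(r.repeat_index),
                hcs_start=int(r.hcs_start),
                unit_length=int(r.unit_length),
            )
            for r in sub.itertuples()
        )
        out[str(chain_id)] = RepeatAnnotation(
            structure_id=structure_id, chain_id=str(chain_id), units=units
        )
    return out


def read_annotation(
    path, chain_id: str | None = None, structure_id: str = ""
) -> RepeatAnnotation:
    """Read the annotation for one chain (the only chain if unambiguous)."""
    anns = read_annotations(path, structure_id=structure_id)
    if chain_id is None:
        if len(anns) != 1:
            raise AnnotationError(
                f"annotation holds chains {sorted(anns)}; specify chain_id"
            )
        return next(iter(anns.values()))
    try:
        return anns[chain_id]
    except KeyError:
        raise AnnotationError(
            f"chain '{chain_id}' not in annotation (has {sorted(anns)})"
        ) from None


# ---------------------------------------------------------------------------
# consensus scanner


def _match_at(seq: str, i: int) -> int:
    """Length of the HCS consensus match starting at i, or 0.

    Checks the 12-residue form LxxLxLxxNxxL and the 11-residue form with a
    deletion at the (x/-) site, LxxLxLxxNxL.  Prefers the longer form.
    """
    if i + 11 > len(seq):
        long_ok = False
    else:
        long_ok = (
            seq[i] in L_CLASS
            and seq[i + 3] in L_CLASS
            and seq[i + 5] in L_CLASS
            and seq[i + 8] in N_CLASS
            and i + 11 < len(seq)
            and seq[i + 11] in L_CLASS
        )
    if long_ok:
        return 12
    if (
        i + 10 < len(seq)
        and seq[i] in L_CLASS
        and seq[i + 3] in L_CLASS
        and seq[i + 5] in L_CLASS
        and seq[i + 8] in N_CLASS
        and seq[i + 10] in L_CLASS
    ):
        return 11
    return 0


def scan_hcs_motif(
    sequence: str,
    offset: int = 1,
    *,
    min_spacing: int = 12,
    default_last_length: int = 24,
) -> list[RepeatUnit]:
    """Propose repeat units by scanning for the HCS consensus.

    Matches are resolved greedily left to right with a minimum spacing of
    ``min_spacing`` residues between HCS starts.  The unit length of each
    candidate is the distance to the next match; the last unit gets
    ``default_last_length``.  ``offset`` is the author sequence number of
    the first residue of ``sequence``.
    """
    seq = sequence.upper()
    starts: list[int] = []
    i = 0
    while i <= len(seq) - 11:
        if _match_at(seq, i):
            starts.append(i)
            i += min_spacing
        else:
            i += 1
    units = []
    for k, s in enumerate(starts):
        length = (starts[k + 1] - s) if k + 1 < len(starts) else default_last_length
        units.append(RepeatUnit(index=k + 1, hcs_start=offset + s, unit_length=length))
    return units


# ---------------------------------------------------------------------------
# reference-point extraction


def reference_points(chain: ChainResidues, ann: RepeatAnnotation) -> ReferencePointSet:
    """Extract the position-4 Cα of every annotated repeat unit.

    Position 4 is found by walking three residues along the chain from the
    HCS start (author numbering with insertion codes; nothing is skipped).
    Units whose position-4 Cα is unresolved are dropped with a warning and
    recorded in ``gaps`` — interpolated points would bias the fit.
    """
    if ann.chain_id != chain.chain_id:
        raise AnnotationError(
            f"annotation is for chain '{ann.chain_id}', structure chain is "
            f"'{chain.chain_id}'"
        )
    index_of = {}
    for k, res in enumerate(chain.residues):
        index_of.setdefault(res.seq_num, k)
    pts, labels, gaps = [], [], []
    for unit in ann.units:
        k = index_of.get(unit.hcs_start)
        ca = None
        if k is not None and k + 3 < len(chain.residues):
            ca = chain.residues[k + 3].ca_xyz
        if ca is None:
            log.warning(
                "chain %s repeat %d: position-4 Cα unresolved; unit dropped",
                chain.chain_id, unit.index,
            )
            gaps.append(unit.index)
            continue
        pts.append(ca)
        labels.append((chain.chain_id, unit.index))
    if len(pts) < 2:
        raise AnnotationError(
            f"insufficient reference points ({len(pts)}) for chain {chain.chain_id}"
        )
    return ReferencePointSet(
        points=np.asarray(pts, dtype=float), labels=tuple(labels), gaps=tuple(gaps)
    )
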