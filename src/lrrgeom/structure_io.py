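"""Macromolecular structure reading and run-manifest parsing.

Structures (PDB or mmCIF) are read with gemmi; only model 1 is used and
alternate conformations are resolved to the highest-occupancy location
(ties go to the first in file order).  Non-standard amino acids with a Cα
(e.g. selenomethionine) are kept and mapped to the parent one-letter code,
since they occur in deposited receptor structures and carry valid
reference points.
"""

from __future__ import annotations

import dataclasses
import logging
import os
import urllib.request

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "StructureFormatError",
    "ManifestError",
    "Residue",
    "ChainResidues",
    "AnalysisTask",
    "load_structure",
    "read_manifest",
]

log = logging.getLogger(__name__)

TASK_KINDS = ("monomer", "subdomains", "dimer", "merged")


class StructureFormatError(ValueError):
    """A structure file could not be parsed or holds no polymer."""


class ManifestError(ValueError):
    """A run manifest is malformed."""


@dataclasses.dataclass(frozen=True)
class Residue:
    seq_num: int
    icode: str  # insertion code, " " when absent
    aa: str  # one-letter code, "X" for unknown
    ca_xyz: np.ndarray | None  # (3,) in Å, or None when no Cα is present


@dataclasses.dataclass(frozen=True)
class ChainResidues:
    """Ordered amino-acid residues of one chain, with Cα coordinates."""

    structure_id: str
    chain_id: str
    residues: tuple[Residue, ...]

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclasses.dataclass(frozen=True)
class AnalysisTask:
    """One row of the run manifest."""

    structure_source: str
    chain_ids: tuple[str, ...]
    annotation_path: str
    task_kind: str
    split_points: tuple[int, ...] | None = None
    merge_order: tuple[str, ...] | None = None
    label: str = ""

    def __post_init__(self):
        if self.task_kind not in TASK_KINDS:
            raise ManifestError(
                f"unknown task_kind '{self.task_kind}' (expected one of {TASK_KINDS})"
            )
        if not self.chain_ids:
            raise ManifestError("task lists no chains")
        if self.task_kind == "dimer" and len(self.chain_ids) != 2:
            raise ManifestError(
                f"dimer task requires exactly 2 chains, got {len(self.chain_ids)}"
            )
        if self.merge_order is not None and any(
            m not in ("forward", "reverse") for m in self.merge_order
        ):
            raise ManifestError("merge_order entries must be 'forward' or 'reverse'")


def _one_letter(name: str) -> str:
    info = gemmi.find_tabulated_residue(name)
    if info is None:
        return "X"
    code = info.one_letter_code.upper()
    return code if code.isalpha() else "X"


def _is_amino_acid(name: str) -> bool:
    info = gemmi.find_tabulated_residue(name)
    return info is not None and info.is_amino_acid()


def _pick_ca(res: gemmi.Residue) -> np.ndarray | None:
    """Highest-occupancy Cα of the residue; altloc ties go to file order."""
    best = None
    for atom in res:
        if atom.name != "CA" or atom.element != gemmi.Element("C"):
            continue
        if best is None or atom.occ > best.occ:
            if best is not None:
                log.debug(
                    "residue %s %s: altloc resolved to '%s' (occ %.2f)",
                    res.name, res.seqid, atom.altloc, atom.occ,
                )
            best = atom
    if best is None:
        return None
    return np.array([best.pos.x, best.pos.y, best.pos.z], dtype=float)


_FETCH_URL = "https://files.rcsb.org/download/{}.cif"


def _resolve_source(path_or_accession: str, cache_dir: str | None) -> str:
    if os.path.exists(path_or_accession):
        return path_or_accession
    acc = path_or_accession.strip().upper()
    if len(acc) != 4 or cache_dir is None:
        raise FileNotFoundError(
            f"structure source '{path_or_accession}' is not a file; fetching "
            "requires a 4-character accession and a configured cache directory"
        )
    os.makedirs(cache_dir, exist_ok=True)
    dest = os.path.join(cache_dir, f"{acc}.cif")
    if not os.path.exists(dest):
        log.info("fetching %s", acc)
        urllib.request.urlretrieve(_FETCH_URL.format(acc), dest)
    return dest


def load_structure(
    path_or_accession: str,
    format_hint: str | None = None,
    *,
    cache_dir: str | None = None,
) -> dict[str, ChainResidues]:
    """Read a structure and return its amino-acid chains keyed by chain id.

    Uses model 1 only.  Residues lacking a Cα record are kept with
    ``ca_xyz = None``.  Waters, ligands and nucleic acids are ignored.
    """
    path = _resolve_source(path_or_accession, cache_dir)
    fmt = {
        "pdb": gemmi.CoorFormat.Pdb,
        "mmcif": gemmi.CoorFormat.Mmcif,
        None: gemmi.CoorFormat.Detect,
    }[format_hint]
    try:
        st = gemmi.read_structure(path, format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"cannot parse '{path}': {exc}") from exc
    structure_id = st.name or os.path.splitext(os.path.basename(path))[0]
    if len(st) == 0:
        raise StructureFormatError(f"'{path}' contains no polymer chains")
    if len(st) > 1:
        log.info("%s: %d models; using model 1", structure_id, len(st))
    model = st[0]
    chains: dict[str, ChainResidues] = {}
    for chain in model:
        residues = []
        seen: set[tuple[int, str]] = set()
        for res in chain:
            if not _is_amino_acid(res.name):
                continue
            key = (res.seqid.num, res.seqid.icode or " ")
            if key in seen:
                continue
            seen.add(key)
            residues.append(
                Residue(
                    seq_num=res.seqid.num,
                    icode=res.seqid.icode or " ",
                    aa=_one_letter(res.name),
                    ca_xyz=_pick_ca(res),
                )
            )
        if residues:
            chains[chain.name] = ChainResidues(
                structure_id=structure_id,
                chain_id=chain.name,
                residues=tuple(residues),
            )
    if not chains:
        raise StructureFormatError(f"'{path}' contains no polymer chains")
    return chains


# ---------------------------------------------------------------------------
# run manifest

_MANIFEST_REQUIRED = ("structure", "chains", "annotation", "task_kind")
_MANIFEST_KNOWN = _MANIFEST_REQUIRED + ("split_points", "merge_order", "label")


def _split_field(value, sep: str = "+") -> tuple[str, ...]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return ()
    return tuple(s.strip() for s in str(value).replace(",", sep).split(sep) if s.strip())


def read_manifest(path: str) -> list[AnalysisTask]:
    """Read a TSV/CSV run manifest into an ordered task list.

    Columns: structure, chains, annotation, task_kind, and optionally
    split_points, merge_order, label.  Chains are separated by '+' (or
    ','); row order is preserved.  Unknown columns are ignored with a
    warning.
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str)
    for col in _MANIFEST_REQUIRED:
        if col not in df.columns:
            raise ManifestError(f"manifest is missing required column '{col}'")
    unknown = [c for c in df.columns if c not in _MANIFEST_KNOWN]
    if unknown:
        log.warning("manifest columns ignored: %s", unknown)
    tasks = []
    for row in df.itertuples(index=False):
        split = _split_field(getattr(row, "split_points", None))
        merge = _split_field(getattr(row, "merge_order", None))
        tasks.append(
            AnalysisTask(
                structure_source=row.structure,
                chain_ids=_split_field(row.chains),
                annotation_path=row.annotation,
                task_kind=row.task_kind,
                split_points=tuple(int(s) for s in split) or None,
                merge_order=merge or None,
                label=str(getattr(row, "label", "") or ""),
            )
        )
    return tasks
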