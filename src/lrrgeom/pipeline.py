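"""Batch orchestration: manifest → per-task fits → parameter table.

Each manifest row becomes one :class:`ParameterRecord` carrying the nine
geometric parameters (P, Δz, ΔΦ, N, R, p, Ω, L, ψ) plus the spacing D and
a handedness label.  Per-task failures produce an error record and never
abort the batch.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import time

import numpy as np
import pandas as pd

from . import assembly, helixfit, repeats, structure_io

__all__ = [
    "AnalysisConfig",
    "ParameterRecord",
    "run_analysis",
    "run_task",
    "export_table",
    "export_circle_plot_data",
]

log = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class AnalysisConfig:
    """Tunable thresholds of the batch analysis (Å unless noted)."""

    p_threshold: float = 0.2  # regularity above which subdomains are sought
    flat_threshold: float = 0.3  # |Δz| at or below this is classed flat
    min_points: int = 5  # fewest reference points for a helix fit
    min_subdomain_len: int = 5
    group_centroids: dict[str, tuple[float, float]] | None = None
    cache_dir: str | None = None  # enables accession fetch when set


@dataclasses.dataclass
class ParameterRecord:
    """One output row: identifiers, the nine parameters, D, classification."""

    structure_id: str
    chain_ids: str
    task_kind: str
    n: int | None = None
    P: float | None = None
    dz: float | None = None
    dphi: float | None = None
    N: float | None = None
    R: float | None = None
    rmsd: float | None = None
    p: float | None = None
    D_mean: float | None = None
    D_eq1: float | None = None
    omega: tuple[float, ...] = ()
    split_indices: tuple[int, ...] = ()
    L: float | None = None
    psi: float | None = None
    handedness: str | None = None
    tlr_group: str | None = None
    error: str | None = None
    warnings: tuple[str, ...] = ()

    NUMERIC_FIELDS = ("n", "P", "dz", "dphi", "N", "R", "rmsd", "p",
                      "D_mean", "D_eq1", "L", "psi")


def _fill_from_fit(rec: ParameterRecord, fit: helixfit.HelixFit, points,
                   config: AnalysisConfig) -> None:
    spacing = helixfit.spacing_summary(points, fit)
    label = assembly.classify_shape(
        fit, flat_threshold=config.flat_threshold,
        group_centroids=config.group_centroids,
    )
    rec.n = fit.n
    rec.P, rec.dz, rec.dphi = fit.P, fit.dz, fit.dphi
    rec.N, rec.R, rec.rmsd, rec.p = fit.N, fit.R, fit.rmsd, fit.p
    rec.D_mean, rec.D_eq1 = spacing.D_mean, spacing.D_eq1
    rec.handedness, rec.tlr_group = label.handedness, label.tlr_group


def _chain_points(task: structure_io.AnalysisTask, config: AnalysisConfig):
    chains = structure_io.load_structure(
        task.structure_source, cache_dir=config.cache_dir
    )
    anns = repeats.read_annotations(task.annotation_path)
    out = []
    for cid in task.chain_ids:
        if cid not in chains:
            raise structure_io.StructureFormatError(
                f"chain '{cid}' not found in {task.structure_source}"
            )
        if cid not in anns:
            raise repeats.AnnotationError(f"chain '{cid}' not annotated")
        out.append(repeats.reference_points(chains[cid], anns[cid]))
    return out


def run_task(task: structure_io.AnalysisTask, config: AnalysisConfig) -> ParameterRecord:
    """Analyze one manifest task; raises on failure (see run_analysis)."""
    rec = ParameterRecord(
        structure_id=task.label or str(task.structure_source),
        chain_ids="+".join(task.chain_ids),
        task_kind=task.task_kind,
    )
    point_sets = _chain_points(task, config)

    if task.task_kind == "dimer":
        geom = assembly.dimer_geometry(point_sets[0], point_sets[1])
        _fill_from_fit(rec, geom.fit_a, point_sets[0], config)
        rec.L, rec.psi = geom.L, geom.psi
        rec.warnings = ("helix fields describe the first chain",)
        return rec

    if task.task_kind == "merged":
        order = task.merge_order or ("forward",) * len(point_sets)
        arrays = [
            ps.points[::-1] if mo == "reverse" else ps.points
            for ps, mo in zip(point_sets, order)
        ]
        merged = np.vstack(arrays)
        fit = helixfit.fit_helix(merged, min_points=config.min_points)
        _fill_from_fit(rec, fit, merged, config)
        return rec

    (points,) = point_sets
    fit = helixfit.fit_helix(points, min_points=config.min_points)
    _fill_from_fit(rec, fit, points, config)
    if task.task_kind == "subdomains" or (
        task.task_kind == "monomer" and fit.p > config.p_threshold
    ):
        split = assembly.detect_subdomains(
            points,
            min_len=config.min_subdomain_len,
            p_threshold=config.p_threshold,
            split_points=task.split_points,
        )
        rec.omega = split.omega
        rec.split_indices = split.split_indices
    return rec


def run_analysis(
    manifest, config: AnalysisConfig | None = None
) -> list[ParameterRecord]:
    """Run every task of a manifest (path or task list), in order.

    A failing task yields a record with its ``error`` field set; the batch
    continues.
    """
    config = config or AnalysisConfig()
    if isinstance(manifest, (str,)) or hasattr(manifest, "__fspath__"):
        tasks = structure_io.read_manifest(manifest)
    else:
        tasks = list(manifest)
    records = []
    for i, task in enumerate(tasks):
        t0 = time.perf_counter()
        try:
            rec = run_task(task, config)
            status = "ok"
        except Exception as exc:  # noqa: BLE001 - isolation is the contract
            rec = ParameterRecord(
                structure_id=task.label or str(task.structure_source),
                chain_ids="+".join(task.chain_ids),
                task_kind=task.task_kind,
                error=f"{type(exc).__name__}: {exc}",
            )
            status = "error"
        log.info(
            "task %d/%d %s [%s] %s (%.2fs)",
            i + 1, len(tasks), rec.structure_id, rec.task_kind, status,
            time.perf_counter() - t0,
        )
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# exports

_DISPLAY_COLUMNS = [
    "structure_id", "chain_ids", "task_kind", "n",
    "P", "dz", "dphi", "N", "R", "rmsd", "p",
    "D_mean", "D_eq1", "omega", "split_indices", "L", "psi",
    "handedness", "tlr_group", "error",
]


def records_frame(records: list[ParameterRecord]) -> pd.DataFrame:
    """Records as a DataFrame: display columns (2 decimals) plus full-
    precision ``*_raw`` columns for machine consumption."""
    rows = []
    for rec in records:
        row = {c: getattr(rec, c) for c in _DISPLAY_COLUMNS}
        row["omega"] = ";".join(f"{o:.2f}" for o in rec.omega)
        row["split_indices"] = ";".join(str(s) for s in rec.split_indices)
        for c in ParameterRecord.NUMERIC_FIELDS:
            val = getattr(rec, c)
            row[f"{c}_raw"] = val
            if c != "n" and val is not None:
                row[c] = round(val, 2)
        row["omega_raw"] = ";".join(repr(o) for o in rec.omega)
        rows.append(row)
    columns = _DISPLAY_COLUMNS + [f"{c}_raw" for c in ParameterRecord.NUMERIC_FIELDS] + ["omega_raw"]
    return pd.DataFrame(rows, columns=columns)


def export_table(records: list[ParameterRecord], path, fmt: str | None = None) -> None:
    """Write the parameter table as TSV (default) or CSV."""
    fmt = fmt or ("csv" if str(path).endswith(".csv") else "tsv")
    sep = {"tsv": "\t", "csv": ","}[fmt]
    records_frame(records).to_csv(path, sep=sep, index=False)


def read_table(path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep)


def export_circle_plot_data(records: list[ParameterRecord], path) -> None:
    """Per-record (Δz, 2·R·sin(ΔΦ/2)) pairs for the circular-correlation plot.

    On an ideal solenoid these points fall on a circle of radius D (the
    adjacent-repeat spacing) centered at the origin of that plane.
    """
    rows = []
    for rec in records:
        if rec.error or rec.dz is None:
            continue
        chord = 2.0 * rec.R * math.sin(math.radians(rec.dphi) / 2.0)
        rows.append(
            {
                "label": f"{rec.structure_id}:{rec.chain_ids}",
                "dz": rec.dz,
                "chord": chord,
                "group": rec.tlr_group or "none",
            }
        )
    pd.DataFrame(rows, columns=["label", "dz", "chord", "group"]).to_csv(
        path, index=False
    )
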