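"""Annotation reading, HCS consensus scanning, reference-point extraction."""

import numpy as np
import pytest

from lrrgeom.repeats import (
    AnnotationError,
    read_annotation,
    read_annotations,
    reference_points,
    scan_hcs_motif,
)
from lrrgeom.simulate import make_lrr_sequence
from lrrgeom.structure_io import ChainResidues, Residue


def _write(tmp_path, text, name="ann.tsv"):
    path = tmp_path / name
    path.write_text(text)
    return path


HEADER = "chain\trepeat_index\thcs_start\tunit_length\n"


def test_read_annotation_seven_units(tmp_path):
    rows = "".join(f"A\t{i + 1}\t{810 + 29 * i}\t29\n" for i in range(7))
    ann = read_annotation(_write(tmp_path, HEADER + rows), "A")
    assert ann.n == 7
    assert ann.units[0].pos4_seq == 813
    assert [u.index for u in ann.units] == list(range(1, 8))


def test_read_annotation_empty_errors(tmp_path):
    with pytest.raises(AnnotationError, match="no repeat units"):
        read_annotation(_write(tmp_path, HEADER), "A")


def test_read_annotation_nonmonotone_errors(tmp_path):
    text = HEADER + "A\t1\t100\t24\nA\t2\t90\t24\n"
    with pytest.raises(AnnotationError, match="100"):
        read_annotation(_write(tmp_path, text), "A")


def test_read_annotation_extreme_unit_length_warns_not_errors(tmp_path, caplog):
    rows = "".join(f"A\t{i + 1}\t{1 + 30 * i}\t{50 if i == 5 else 28}\n" for i in range(16))
    with caplog.at_level("WARNING"):
        ann = read_annotation(_write(tmp_path, HEADER + rows), "A")
    assert ann.n == 16


def test_read_annotations_multichain(tmp_path):
    text = HEADER + "A\t1\t10\t24\nA\t2\t34\t24\nB\t1\t10\t24\nB\t2\t34\t24\n"
    anns = read_annotations(_write(tmp_path, text))
    assert sorted(anns) == ["A", "B"]
    with pytest.raises(AnnotationError):
        read_annotation(_write(tmp_path, text))  # ambiguous without chain_id


# --- scanner -----------------------------------------------------------------

TLR3_SEGMENT = "LTMLDLSYNNLNVVGNDSFAWLPQLEYFFLEYNNIQHLFSHSLHGLFN"


def test_scanner_finds_tlr3_repeat_heads():
    """The two consensus heads of a two-repeat TLR3 segment are found."""
    units = scan_hcs_motif(TLR3_SEGMENT, offset=276)
    assert [u.hcs_start for u in units] == [276, 300]
    assert units[0].unit_length == 24


def test_scanner_polyalanine_empty():
    assert scan_hcs_motif("A" * 100) == []


def test_scanner_recovers_typical_consensus_units():
    seq, starts = make_lrr_sequence(10, 24, seed=1)
    units = scan_hcs_motif(seq, offset=0)
    assert [u.hcs_start for u in units] == starts
    assert all(u.unit_length == 24 for u in units[:-1])


def test_scanner_single_unit():
    seq, starts = make_lrr_sequence(1, 24, seed=2)
    units = scan_hcs_motif(seq, offset=0)
    assert len(units) == 1 and units[0].hcs_start == 0


def test_scanner_recall_with_substitutions():
    """>= 95% of true HCS starts recovered with up to 2 random x-substitutions."""
    hits = total = 0
    for seed in range(100):
        seq, starts = make_lrr_sequence(8, 24, seed=seed, max_x_substitutions=2)
        found = {u.hcs_start for u in scan_hcs_motif(seq, offset=0)}
        hits += len(found & set(starts))
        total += len(starts)
    assert hits / total >= 0.95


# --- reference points --------------------------------------------------------


def _chain(points, start=1, spacing=24, drop_ca=()):
    residues = []
    for i, pt in enumerate(points):
        num = start + i * spacing
        for k in range(4):
            ca = None
            if k == 3 and i not in drop_ca:
                ca = np.asarray(pt, dtype=float)
            elif k < 3:
                ca = np.asarray(pt, dtype=float) + [k + 1.0, 0.0, 0.0]
            residues.append(Residue(seq_num=num + k, icode=" ", aa="L", ca_xyz=ca))
    return ChainResidues(structure_id="SYN", chain_id="A", residues=tuple(residues))


def _ann(tmp_path, n, start=1, spacing=24, shuffle=False):
    rows = [f"A\t{i + 1}\t{start + i * spacing}\t{spacing}" for i in range(n)]
    if shuffle:
        rows = rows[::-1]
    return read_annotation(
        _write(tmp_path, HEADER + "\n".join(rows) + "\n"), "A"
    )


def test_reference_points_full_extraction(tmp_path):
    pts = np.arange(21, dtype=float).reshape(7, 3)
    rp = reference_points(_chain(pts), _ann(tmp_path, 7))
    assert len(rp) == 7
    np.testing.assert_array_equal(rp.points, pts)
    assert rp.labels[0] == ("A", 1)


def test_reference_points_drop_missing_ca(tmp_path):
    pts = np.arange(21, dtype=float).reshape(7, 3)
    rp = reference_points(_chain(pts, drop_ca={2}), _ann(tmp_path, 7))
    assert len(rp) == 6
    assert rp.gaps == (3,)
    np.testing.assert_array_equal(rp.points, np.delete(pts, 2, axis=0))


def test_reference_points_order_independent_of_file_order(tmp_path):
    """Output follows repeat index even if annotation rows are shuffled."""
    pts = np.arange(18, dtype=float).reshape(6, 3)
    rp0 = reference_points(_chain(pts), _ann(tmp_path, 6))
    rp1 = reference_points(_chain(pts), _ann(tmp_path, 6, shuffle=True))
    np.testing.assert_array_equal(rp0.points, rp1.points)


def test_reference_points_too_few_errors(tmp_path):
    pts = np.arange(6, dtype=float).reshape(2, 3)
    with pytest.raises(AnnotationError, match="insufficient"):
        reference_points(_chain(pts, drop_ca={0}), _ann(tmp_path, 2))
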