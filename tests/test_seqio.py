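"""I/O round trips and format-contract enforcement."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dbpred.seqio import (
    FormatError,
    Label,
    ProteinRecord,
    PSSMatrix,
    ResidueAnnotationTrack,
    read_annotation_tsv,
    read_fasta,
    read_feature_matrix,
    read_pssm,
    write_annotation_tsv,
    write_fasta,
    write_feature_matrix,
    write_pssm,
)


class _Vec:
    def __init__(self, names, values):
        self.names = names
        self.values = np.asarray(values, dtype=float)


# --- FASTA ------------------------------------------------------------------


def test_fasta_single_record_and_case_normalization(tmp_path):
    p = tmp_path / "a.fasta"
    p.write_text(">p1 some description\nmkv\n")
    records = read_fasta(p)
    assert len(records) == 1
    assert records[0].id == "p1"
    assert records[0].sequence == "MKV"
    assert records[0].label is Label.UNKNOWN


def test_fasta_empty_file(tmp_path):
    p = tmp_path / "empty.fasta"
    p.write_text("")
    assert read_fasta(p) == []


def test_fasta_duplicate_ids_rejected(tmp_path):
    p = tmp_path / "dup.fasta"
    p.write_text(">p1\nMKV\n>p1\nACD\n")
    with pytest.raises(FormatError, match="duplicate"):
        read_fasta(p)


def test_fasta_round_trip_preserves_ids_sequences_labels(tmp_path):
    records = [
        ProteinRecord("p1", "MKVACDEFGH", Label.BINDING),
        ProteinRecord("p2", "WYWYWY", Label.NONBINDING),
        ProteinRecord("p3", "ACDEFG"),
    ]
    path = tmp_path / "rt.fasta"
    write_fasta(records, path)
    back = read_fasta(path)
    assert back == records


def test_invalid_letters_flagged_not_altered():
    rec = ProteinRecord("p1", "MKVXZ")
    assert not rec.is_valid
    assert rec.sequence == "MKVXZ"  # not silently scrubbed


# --- annotation TSV ---------------------------------------------------------


def _tsv(tmp_path, rows):
    p = tmp_path / "ann.tsv"
    body = "\n".join("\t".join(map(str, r)) for r in rows)
    p.write_text("protein_id\tposition\tpredicted_class\tri\n" + body + "\n")
    return p


def test_annotation_tsv_happy_path(tmp_path):
    p = _tsv(tmp_path, [("p1", 1, "B", 10), ("p1", 2, "N", 7)])
    (track,) = read_annotation_tsv(p)
    assert len(track) == 2
    assert track.binding.tolist() == [True, False]
    assert track.ri.tolist() == [10, 7]


@pytest.mark.parametrize(
    "rows, message",
    [
        ([("p1", 1, "B", 11)], "0..10"),
        ([("p1", 1, "B", -1)], "0..10"),
        ([("p1", 1, "B", 5), ("p1", 3, "B", 5)], "contiguous"),
        ([("p1", 1, "B", 5), ("p1", 1, "N", 5)], "contiguous"),
        ([("p1", 2, "B", 5)], "contiguous"),
        ([("p1", 1, "Q", 5)], "class"),
    ],
)
def test_annotation_tsv_rejects_invariant_violations(tmp_path, rows, message):
    with pytest.raises(FormatError, match=message):
        read_annotation_tsv(_tsv(tmp_path, rows))


@settings(derandomize=True, max_examples=40)
@given(
    n=st.integers(2, 15),
    ris=st.data(),
    corruption=st.sampled_from(["ri_high", "ri_low", "gap", "dup"]),
)
def test_annotation_tsv_rejects_randomized_corruptions(tmp_path_factory, n, ris, corruption):
    """Any corruption of RI range or positional contiguity is rejected."""
    tmp_path = tmp_path_factory.mktemp("corrupt")
    rows = [
        ["p1", i + 1, "B" if i % 2 else "N", ris.draw(st.integers(0, 10))]
        for i in range(n)
    ]
    victim = ris.draw(st.integers(0, n - 1))
    if corruption == "ri_high":
        rows[victim][3] = 11
    elif corruption == "ri_low":
        rows[victim][3] = -3
    elif corruption == "gap":
        rows[victim][1] = n + 5
    else:
        rows[victim][1] = rows[(victim + 1) % n][1]
    with pytest.raises(FormatError):
        read_annotation_tsv(_tsv(tmp_path, [tuple(r) for r in rows]))


def test_annotation_tsv_round_trip(tmp_path):
    rng = np.random.default_rng(5)
    tracks = [
        ResidueAnnotationTrack(
            protein_id=f"p{i}",
            binding=rng.random(20) < 0.4,
            ri=rng.integers(0, 11, 20),
        )
        for i in range(3)
    ]
    path = tmp_path / "rt.tsv"
    write_annotation_tsv(tracks, path)
    back = read_annotation_tsv(path)
    for a, b in zip(tracks, back):
        assert a.protein_id == b.protein_id
        assert np.array_equal(a.binding, b.binding)
        assert np.array_equal(a.ri, b.ri)


# --- PSSM -------------------------------------------------------------------


def test_pssm_round_trip_synthetic_matrix(tmp_path):
    rng = np.random.default_rng(11)
    seq = "MKVACDEFGH"
    m = PSSMatrix("p1", rng.integers(-10, 14, size=(10, 20)), residues=seq)
    path = tmp_path / "p1.pssm"
    write_pssm(m, path, sequence=seq)
    back = read_pssm(path, protein_id="p1")
    assert np.array_equal(back.scores, m.scores)
    assert back.residues == seq


def test_pssm_all_zero_scores(tmp_path):
    m = PSSMatrix("p1", np.zeros((3, 20), dtype=int), residues="MKV")
    path = tmp_path / "z.pssm"
    write_pssm(m, path)
    assert np.array_equal(read_pssm(path).scores, np.zeros((3, 20)))


def test_pssm_truncated_row_names_the_row(tmp_path):
    m = PSSMatrix("p1", np.zeros((3, 20), dtype=int), residues="MKV")
    path = tmp_path / "t.pssm"
    write_pssm(m, path)
    lines = path.read_text().splitlines()
    # chop the last data row (line index 5: blank, 2 headers, 3 rows) short
    lines[5] = " ".join(lines[5].split()[:12])
    path.write_text("\n".join(lines) + "\n")
    with pytest.raises(FormatError, match="row 3"):
        read_pssm(path)


def test_pssm_empty_body_rejected(tmp_path):
    path = tmp_path / "e.pssm"
    path.write_text("Last position-specific scoring matrix computed\n\n")
    with pytest.raises(FormatError, match="no PSSM rows"):
        read_pssm(path)


# --- feature matrices -------------------------------------------------------


def test_feature_matrix_csv_round_trips_bit_exactly(tmp_path):
    rng = np.random.default_rng(3)
    names = ["f.a", "f.b", "f.c", "f.d"]
    vecs = [_Vec(names, rng.random(4) * 100) for _ in range(2)]
    path = tmp_path / "m.csv"
    write_feature_matrix(vecs, [Label.BINDING, Label.NONBINDING], path)
    assert len(path.read_text().splitlines()) == 3
    df, labels = read_feature_matrix(path)
    assert list(df.columns) == names
    assert labels == ["binding", "nonbinding"]
    for i, v in enumerate(vecs):
        assert (df.iloc[i].to_numpy() == v.values).all()  # bit-exact


def test_feature_matrix_arff_declarations(tmp_path):
    names = ["f.a", "f.b", "f.c", "f.d"]
    vecs = [_Vec(names, np.arange(4.0)), _Vec(names, np.arange(4.0) + 1)]
    path = tmp_path / "m.arff"
    write_feature_matrix(vecs, ["binding", "nonbinding"], path, fmt="arff")
    text = path.read_text()
    assert text.count("@ATTRIBUTE") == 5  # 4 numeric + class
    assert "{binding,nonbinding}" in text


def test_feature_matrix_mismatched_names_rejected(tmp_path):
    vecs = [_Vec(["a", "b"], [1, 2]), _Vec(["a", "c"], [1, 2])]
    with pytest.raises(ValueError, match="inconsistent"):
        write_feature_matrix(vecs, ["x", "y"], tmp_path / "m.csv")
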