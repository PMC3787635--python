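"""Readers and writers for every external format the toolkit touches.

Formats
-------
* FASTA (via Biopython) for protein sequences, with an optional
  ``label=binding|nonbinding`` tag in the header description;
* a TSV dialect for per-residue binding predictions with reliability
  indices (columns ``protein_id, position, predicted_class, ri``; positions
  1-based and contiguous; class ``B`` or ``N``; RI an integer in 0..10) —
  the canonical surrogate for residue-predictor output, since upstream
  tools do not share a single layout (``read_annotation_tsv`` is the
  documented adapter point for other layouts);
* PSI-BLAST ASCII position-specific scoring matrices (the query-profile
  dump: header lines, one row per residue with position, residue letter,
  20 integer log-odds columns, then percentage columns that are ignored);
* CSV / ARFF feature matrices.

Positions are 1-based in all external files and 0-based internally;
conversion happens only in this module.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 standard amino acids in alphabetical one-letter order.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

#: PSI-BLAST profile column ordering (also used for EI block ordering).
PSIBLAST_ALPHABET = "ARNDCQEGHILKMFPSTWYV"

_STANDARD_SET = frozenset(STANDARD_AA)


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


class Label(enum.Enum):
    """Protein-level class label."""

    BINDING = "binding"
    NONBINDING = "nonbinding"
    UNKNOWN = "unknown"


class ResidueClass(enum.Enum):
    """Residue-level predicted class."""

    BINDING = "B"
    NONBINDING = "N"


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with an identifier and an optional class label.

    Sequences are stored uppercased exactly as read. Records whose sequence
    contains letters outside the 20 standard amino acids are *not* rejected
    at load time: they are flagged via :attr:`is_valid` so that dataset
    filtering stays observable (see :mod:`dbpred.datasetprep`). Feature
    extraction refuses invalid records.
    """

    id: str
    sequence: str
    label: Label = Label.UNKNOWN

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"protein {self.id!r}: empty sequence")

    @property
    def is_valid(self) -> bool:
        """True iff every letter is one of the 20 standard amino acids."""
        return set(self.sequence) <= _STANDARD_SET

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ResidueAnnotationTrack:
    """Per-residue binding predictions for one protein.

    ``binding`` holds the predicted class per position (True = binding) and
    ``ri`` the integer reliability index in 0..10, both 0-based arrays of
    equal length. RI = 0 calls are legitimate (zero-confidence) and
    contribute zero weight to the propensity descriptors.
    """

    protein_id: str
    binding: np.ndarray
    ri: np.ndarray

    def __post_init__(self) -> None:
        binding = np.asarray(self.binding, dtype=bool)
        ri = np.asarray(self.ri, dtype=np.int64)
        if binding.shape != ri.shape or binding.ndim != 1:
            raise ValueError(
                f"track {self.protein_id!r}: binding and ri must be equal-length 1-D arrays"
            )
        if binding.size < 1:
            raise ValueError(f"track {self.protein_id!r}: empty track")
        if ri.min() < 0 or ri.max() > 10:
            raise ValueError(
                f"track {self.protein_id!r}: reliability index outside 0..10"
            )
        object.__setattr__(self, "binding", binding)
        object.__setattr__(self, "ri", ri)

    @property
    def calls(self) -> list[tuple[ResidueClass, int]]:
        """The track as a list of (predicted class, RI) per position."""
        return [
            (ResidueClass.BINDING if b else ResidueClass.NONBINDING, int(r))
            for b, r in zip(self.binding, self.ri)
        ]

    def __len__(self) -> int:
        return int(self.binding.size)


@dataclass(frozen=True)
class PSSMatrix:
    """An N x 20 integer substitution-score profile for one protein.

    Columns follow the PSI-BLAST alphabet ``A R N D C Q E G H I L K M F P
    S T W Y V``; rows align with sequence positions. ``residues`` keeps the
    residue letters read from the file for cross-checking against the
    sequence.
    """

    protein_id: str
    scores: np.ndarray
    residues: str = ""
    column_order: str = field(default=PSIBLAST_ALPHABET)

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=np.int64)
        if scores.ndim != 2 or scores.shape[1] != 20:
            raise ValueError(
                f"PSSM {self.protein_id!r}: expected an N x 20 matrix, got {scores.shape}"
            )
        if scores.shape[0] < 1:
            raise ValueError(f"PSSM {self.protein_id!r}: empty matrix")
        if self.residues and len(self.residues) != scores.shape[0]:
            raise ValueError(
                f"PSSM {self.protein_id!r}: {len(self.residues)} residue letters "
                f"for {scores.shape[0]} rows"
            )
        object.__setattr__(self, "scores", scores)

    @property
    def n_rows(self) -> int:
        return int(self.scores.shape[0])


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

_LABEL_TAGS = {
    "label=binding": Label.BINDING,
    "label=nonbinding": Label.NONBINDING,
}


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein records from a FASTA file.

    The header token before the first whitespace becomes the record id; a
    ``label=binding`` / ``label=nonbinding`` tag anywhere in the rest of
    the header sets the class label, otherwise the label is unknown.
    Sequences are uppercased. Duplicate ids raise :class:`FormatError`.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise FormatError(f"{path}: duplicate record id {entry.id!r}")
        seen.add(entry.id)
        label = Label.UNKNOWN
        for tag, lab in _LABEL_TAGS.items():
            if tag in entry.description:
                label = lab
                break
        records.append(
            ProteinRecord(id=entry.id, sequence=str(entry.seq).upper(), label=label)
        )
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records to FASTA, embedding non-unknown labels in the header."""
    out = []
    for rec in records:
        desc = "" if rec.label is Label.UNKNOWN else f"label={rec.label.value}"
        out.append(SeqRecord(Seq(rec.sequence), id=rec.id, description=desc))
    SeqIO.write(out, str(path), "fasta")


# ---------------------------------------------------------------------------
# Residue-annotation TSV
# ---------------------------------------------------------------------------

_ANNOTATION_COLUMNS = ["protein_id", "position", "predicted_class", "ri"]


def read_annotation_tsv(path: str | Path) -> list[ResidueAnnotationTrack]:
    """Read residue-annotation tracks from the TSV dialect.

    One track per protein; positions must be contiguous from 1 (gaps and
    duplicates are errors), classes ``B``/``N``, RI in 0..10.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    missing = [c for c in _ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    tracks: list[ResidueAnnotationTrack] = []
    for pid, grp in df.groupby("protein_id", sort=False):
        grp = grp.sort_values("position")
        positions = grp["position"].to_numpy(dtype=np.int64)
        expected = np.arange(1, len(positions) + 1)
        if not np.array_equal(positions, expected):
            bad = int(expected[positions != expected][0]) if len(positions) == len(expected) else len(expected)
            raise FormatError(
                f"{path}: protein {pid!r}: positions must be contiguous from 1 "
                f"(problem at position {bad})"
            )
        classes = grp["predicted_class"].astype(str).to_numpy()
        unknown = set(classes) - {"B", "N"}
        if unknown:
            raise FormatError(f"{path}: protein {pid!r}: unknown class codes {sorted(unknown)}")
        ri = grp["ri"].to_numpy(dtype=np.int64)
        if ri.min() < 0 or ri.max() > 10:
            raise FormatError(f"{path}: protein {pid!r}: reliability index outside 0..10")
        tracks.append(
            ResidueAnnotationTrack(protein_id=str(pid), binding=classes == "B", ri=ri)
        )
    return tracks


def write_annotation_tsv(tracks: Iterable[ResidueAnnotationTrack], path: str | Path) -> None:
    """Write tracks in the annotation TSV dialect (1-based positions)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_ANNOTATION_COLUMNS)
        for track in tracks:
            for i, (b, r) in enumerate(zip(track.binding, track.ri)):
                writer.writerow([track.protein_id, i + 1, "B" if b else "N", int(r)])


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII PSSM
# ---------------------------------------------------------------------------


def read_pssm(path: str | Path, protein_id: str | None = None) -> PSSMatrix:
    """Read a PSI-BLAST ASCII PSSM (query-profile dump).

    Header lines are skipped; each body line carries the 1-based position,
    the residue letter and at least 20 integer log-odds scores — only the
    first 20 score columns are consumed (the percentage columns and the
    two trailing information-content fields are ignored). The footer
    (lines not starting with a position number) ends the body.
    """
    path = Path(path)
    rows: list[list[int]] = []
    residues: list[str] = []
    expected_pos = 1
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if len(tokens) < 2:
                continue
            try:
                pos = int(tokens[0])
            except ValueError:
                continue
            letter = tokens[1]
            if len(letter) != 1 or not letter.isalpha():
                continue
            if pos != expected_pos:
                raise FormatError(
                    f"{path}:{lineno}: expected position {expected_pos}, found {pos}"
                )
            try:
                scores = [int(t) for t in tokens[2 : 2 + 20]]
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-integer score in PSSM row {pos}: {exc}"
                ) from None
            if len(scores) != 20:
                raise FormatError(
                    f"{path}:{lineno}: PSSM row {pos} has {len(scores)} scores, expected 20"
                )
            rows.append(scores)
            residues.append(letter.upper())
            expected_pos += 1
    if not rows:
        raise FormatError(f"{path}: no PSSM rows found")
    return PSSMatrix(
        protein_id=protein_id if protein_id is not None else path.stem,
        scores=np.array(rows, dtype=np.int64),
        residues="".join(residues),
    )


def write_pssm(pssm: PSSMatrix, path: str | Path, sequence: str | None = None) -> None:
    """Write a PSSM in the PSI-BLAST ASCII layout (scores only are meaningful)."""
    seq = sequence or pssm.residues or "X" * pssm.n_rows
    if len(seq) != pssm.n_rows:
        raise ValueError(
            f"PSSM {pssm.protein_id!r}: sequence length {len(seq)} != {pssm.n_rows} rows"
        )
    with open(path, "w") as fh:
        fh.write("\n")
        fh.write(
            "Last position-specific scoring matrix computed, weighted observed "
            "percentages rounded down, information per position, and relative "
            "weight of gapless real matches to pseudocounts\n"
        )
        header = " ".join(f"{a:>3}" for a in PSIBLAST_ALPHABET)
        fh.write(f"          {header}  {header}\n")
        for i, row in enumerate(pssm.scores):
            scores = " ".join(f"{int(v):>3d}" for v in row)
            pct = " ".join(f"{0:>3d}" for _ in range(20))
            fh.write(f"{i + 1:>5d} {seq[i]} {scores}  {pct}  0.00 0.00\n")
        fh.write("\n")


# ---------------------------------------------------------------------------
# Feature matrices (CSV / ARFF)
# ---------------------------------------------------------------------------


def _check_vectors(vectors: Sequence) -> list[str]:
    if not vectors:
        raise ValueError("no feature vectors to write")
    names = list(vectors[0].names)
    for v in vectors[1:]:
        if list(v.names) != names:
            raise ValueError("inconsistent feature names across vectors")
    return names


def write_feature_matrix(
    vectors: Sequence,
    labels: Sequence[Label | str],
    path: str | Path,
    fmt: str = "csv",
) -> None:
    """Write feature vectors and class labels as CSV or ARFF.

    ``vectors`` are objects exposing ``names`` (feature-name list, identical
    across vectors) and ``values`` (numeric array); ``labels`` are
    :class:`Label` or their string values. The CSV dialect uses ``repr``
    float formatting so that read-back reproduces the values bit-exactly.
    """
    names = _check_vectors(vectors)
    if len(labels) != len(vectors):
        raise ValueError(f"{len(vectors)} vectors but {len(labels)} labels")
    labels = [lab.value if isinstance(lab, Label) else str(lab) for lab in labels]
    fmt = fmt.lower()
    if fmt == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, lineterminator="\n")
            writer.writerow(names + ["label"])
            for vec, lab in zip(vectors, labels):
                writer.writerow([repr(float(x)) for x in vec.values] + [lab])
    elif fmt == "arff":
        classes = sorted(set(labels))
        with open(path, "w") as fh:
            fh.write("@RELATION dbpred_features\n\n")
            for name in names:
                fh.write(f"@ATTRIBUTE {name} NUMERIC\n")
            fh.write(f"@ATTRIBUTE class {{{','.join(classes)}}}\n\n@DATA\n")
            for vec, lab in zip(vectors, labels):
                fh.write(",".join(repr(float(x)) for x in vec.values) + f",{lab}\n")
    else:
        raise ValueError(f"unknown feature-matrix format {fmt!r}")


def read_feature_matrix(path: str | Path) -> tuple[pd.DataFrame, list[str]]:
    """Read back a CSV feature matrix; returns (features, labels)."""
    df = pd.read_csv(path)
    if "label" not in df.columns:
        raise FormatError(f"{path}: feature CSV lacks a 'label' column")
    labels = df.pop("label").astype(str).tolist()
    return df, labels
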