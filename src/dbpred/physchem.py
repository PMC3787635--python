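"""Amino acid composition and composition/transition/distribution (CTD)
descriptors over six physicochemical properties.

Each property (hydrophobicity, normalized Van der Waals volume, polarity,
polarizability, secondary-structure preference, solvent accessibility)
partitions the 20 amino acids into labeled groups (three by default; the
standard partitions ship as ``data/ctd_groups.json`` and may be overridden
by a file of the same shape). Per property, the sequence is summarized by

* **C** (composition): percent of residues falling in each group;
* **T** (transition): percent of adjacent residue pairs whose two members
  fall in *different* groups, pooled over the two orders, one value per
  unordered group pair, normalized by N-1;
* **D** (distribution): for each group, the percent of the sequence length
  at which the first 25%, 50%, 75% and 100% of that group's residues have
  appeared (the occurrence index for point p over c occurrences is
  ``ceil(p*c/100)``, minimum 1; absent groups emit 0 for every point).

The full physicochemical block is the 20-value amino acid composition
followed by C/T/D for each property: 20 + 6*(3+3+12) = 128 features under
the default configuration. The dimension is always derived from the
configuration, never hard-coded; the optional 5-point distribution variant
(adding the first occurrence) gives 20 + 6*21 = 146.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from dbpred.seqio import STANDARD_AA, _STANDARD_SET


@dataclass(frozen=True)
class PropertyScheme:
    """An ordered partition of the 20 amino acids into labeled groups."""

    name: str
    groups: tuple[tuple[str, str], ...]  # (group label, member letters)

    def __post_init__(self) -> None:
        if len(self.groups) < 2:
            raise ValueError(f"property {self.name!r}: need at least 2 groups")
        seen: set[str] = set()
        for label, members in self.groups:
            overlap = seen & set(members)
            if overlap:
                raise ValueError(
                    f"property {self.name!r}: letters {sorted(overlap)} in multiple groups"
                )
            seen |= set(members)
        if seen != _STANDARD_SET:
            raise ValueError(
                f"property {self.name!r}: groups must cover exactly the 20 standard "
                f"amino acids (missing {sorted(_STANDARD_SET - seen)}, "
                f"extra {sorted(seen - _STANDARD_SET)})"
            )

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def group_index(self) -> dict[str, int]:
        """Map each amino acid letter to its 0-based group number."""
        idx: dict[str, int] = {}
        for g, (_, members) in enumerate(self.groups):
            for letter in members:
                idx[letter] = g
        return idx


def load_schemes(path: str | Path | None = None) -> tuple[PropertyScheme, ...]:
    """Load property schemes from a JSON group table (default: packaged table)."""
    if path is None:
        text = (
            resources.files("dbpred").joinpath("data/ctd_groups.json").read_text()
        )
    else:
        text = Path(path).read_text()
    raw = json.loads(text)
    return tuple(
        PropertyScheme(name=prop, groups=tuple(groups.items()))
        for prop, groups in raw["properties"].items()
    )


@dataclass(frozen=True)
class PPConfig:
    """Configuration of the physicochemical block.

    ``distribution_points`` are cumulative-percentage checkpoints; the
    default four (25, 50, 75, 100) follow the descriptor's common printed
    definition, and ``(0, 25, 50, 75, 100)`` selects the 5-point variant
    where point 0 marks the first occurrence.
    """

    distribution_points: tuple[int, ...] = (25, 50, 75, 100)
    groups_path: str | None = None
    schemes: tuple[PropertyScheme, ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        if not self.schemes:
            object.__setattr__(self, "schemes", load_schemes(self.groups_path))

    @property
    def dimension(self) -> int:
        """Total PP feature count implied by this configuration."""
        total = 20
        npts = len(self.distribution_points)
        for scheme in self.schemes:
            g = scheme.n_groups
            total += g + (g * (g - 1)) // 2 + g * npts
        return total

    def feature_names(self) -> list[str]:
        names = [f"pp.aac.{a}" for a in STANDARD_AA]
        for scheme in self.schemes:
            labels = [label for label, _ in scheme.groups]
            names += [f"pp.{scheme.name}.composition.{lab}" for lab in labels]
            for i in range(len(labels)):
                for j in range(i + 1, len(labels)):
                    names.append(
                        f"pp.{scheme.name}.transition.{labels[i]}-{labels[j]}"
                    )
            for lab in labels:
                for p in self.distribution_points:
                    names.append(f"pp.{scheme.name}.distribution.{lab}.p{p}")
        return names


def _validate(sequence: str) -> str:
    bad = set(sequence) - _STANDARD_SET
    if bad:
        raise ValueError(f"sequence contains non-standard letters {sorted(bad)}")
    if not sequence:
        raise ValueError("empty sequence")
    return sequence


def amino_acid_composition(sequence: str) -> np.ndarray:
    """Percent frequency of each of the 20 amino acids, alphabetical order."""
    seq = _validate(sequence)
    counts = np.array([seq.count(a) for a in STANDARD_AA], dtype=float)
    return 100.0 * counts / len(seq)


def _group_sequence(sequence: str, scheme: PropertyScheme) -> np.ndarray:
    idx = scheme.group_index()
    return np.fromiter((idx[a] for a in sequence), dtype=np.int64, count=len(sequence))


def composition_index(sequence: str, scheme: PropertyScheme) -> np.ndarray:
    """Percent of residues in each property group (sums to 100)."""
    gs = _group_sequence(_validate(sequence), scheme)
    counts = np.bincount(gs, minlength=scheme.n_groups).astype(float)
    return 100.0 * counts / len(gs)


def transition_index(sequence: str, scheme: PropertyScheme) -> np.ndarray:
    """Percent of adjacent pairs crossing each unordered group pair, over N-1."""
    seq = _validate(sequence)
    if len(seq) < 2:
        raise ValueError("transition index needs a sequence of length >= 2")
    gs = _group_sequence(seq, scheme)
    a, b = gs[:-1], gs[1:]
    lo, hi = np.minimum(a, b), np.maximum(a, b)
    g = scheme.n_groups
    out = []
    for i in range(g):
        for j in range(i + 1, g):
            out.append(np.count_nonzero((lo == i) & (hi == j)))
    return 100.0 * np.array(out, dtype=float) / (len(seq) - 1)


def distribution_index(
    sequence: str,
    scheme: PropertyScheme,
    points: tuple[int, ...] = (25, 50, 75, 100),
) -> np.ndarray:
    """Positional checkpoints of each group's occurrences, as percent of N.

    For group g with c > 0 occurrences and point p, the value is the
    1-based sequence position of the ``max(1, ceil(p*c/100))``-th
    occurrence, times 100/N. Groups absent from the sequence emit 0.
    """
    seq = _validate(sequence)
    gs = _group_sequence(seq, scheme)
    n = len(seq)
    out = np.zeros(scheme.n_groups * len(points))
    for g in range(scheme.n_groups):
        positions = np.flatnonzero(gs == g)  # 0-based
        c = positions.size
        if c == 0:
            continue
        for k, p in enumerate(points):
            occ = max(1, math.ceil(p * c / 100))
            out[g * len(points) + k] = 100.0 * (positions[occ - 1] + 1) / n
    return out


@dataclass(frozen=True)
class PPVector:
    """The assembled physicochemical feature block for one protein."""

    names: tuple[str, ...]
    values: np.ndarray

    def __len__(self) -> int:
        return len(self.names)


def pp_vector(sequence: str, config: PPConfig | None = None) -> PPVector:
    """Amino acid composition + per-property C/T/D blocks, concatenated."""
    config = config or PPConfig()
    seq = _validate(sequence)
    if len(seq) < 2:
        raise ValueError("physicochemical block needs a sequence of length >= 2")
    parts = [amino_acid_composition(seq)]
    for scheme in config.schemes:
        parts.append(composition_index(seq, scheme))
        parts.append(transition_index(seq, scheme))
        parts.append(distribution_index(seq, scheme, config.distribution_points))
    values = np.concatenate(parts)
    names = tuple(config.feature_names())
    assert values.size == len(names) == config.dimension
    return PPVector(names=names, values=values)
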