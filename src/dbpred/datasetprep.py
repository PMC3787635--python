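"""Dataset-construction filters: length, alphabet, redundancy, balancing.

The canonical preparation pipeline for a binding/nonbinding corpus:

1. keep sequences of 50..6000 residues (inclusive bounds);
2. drop sequences containing letters outside the 20 standard amino acids
   (X, Z, B, J, U, O, gaps, stops);
3. reduce redundancy by greedy clustering at a pairwise-identity
   threshold (default 40%), keeping the longest sequence of each cluster;
4. subsample the negative class to the positive class size and draw a
   stratified train/test split.

Clustering against an external alignment tool is deliberately pluggable:
the default ``identity_fn`` is a global edit-distance identity
(``1 - d/max_len`` via edlib); precomputed cluster assignments from
BLAST/CD-HIT can be substituted through the ``identity_fn`` hook.
Every filter returns a :class:`FilterReport` whose accounting balances
exactly, so no record is ever dropped silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import edlib
import numpy as np

from dbpred.seqio import ProteinRecord


@dataclass
class FilterReport:
    """Accounting of one filter application."""

    rule: str
    input_count: int
    retained_count: int
    excluded_ids: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        excluded = sum(len(v) for v in self.excluded_ids.values())
        if self.input_count != self.retained_count + excluded:
            raise ValueError(
                f"filter {self.rule!r}: accounting imbalance "
                f"({self.input_count} != {self.retained_count} + {excluded})"
            )

    @property
    def excluded_count(self) -> int:
        return sum(len(v) for v in self.excluded_ids.values())

    def as_dict(self) -> dict:
        return {
            "rule": self.rule,
            "input_count": self.input_count,
            "retained_count": self.retained_count,
            "excluded": {k: list(v) for k, v in self.excluded_ids.items()},
        }


def length_filter(
    records: Sequence[ProteinRecord], min_len: int = 50, max_len: int = 6000
) -> tuple[list[ProteinRecord], FilterReport]:
    """Keep records whose length lies in [min_len, max_len], both inclusive."""
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    kept, too_short, too_long = [], [], []
    for rec in records:
        if len(rec) < min_len:
            too_short.append(rec.id)
        elif len(rec) > max_len:
            too_long.append(rec.id)
        else:
            kept.append(rec)
    report = FilterReport(
        rule=f"length[{min_len},{max_len}]",
        input_count=len(records),
        retained_count=len(kept),
        excluded_ids={"too_short": too_short, "too_long": too_long},
    )
    return kept, report


def alphabet_filter(
    records: Sequence[ProteinRecord],
) -> tuple[list[ProteinRecord], FilterReport]:
    """Drop records with any letter outside the 20 standard amino acids."""
    kept, irregular = [], []
    for rec in records:
        if rec.is_valid:
            kept.append(rec)
        else:
            irregular.append(rec.id)
    report = FilterReport(
        rule="alphabet",
        input_count=len(records),
        retained_count=len(kept),
        excluded_ids={"irregular_characters": irregular},
    )
    return kept, report


def edlib_identity(a: str, b: str) -> float:
    """Global-alignment identity: 1 - edit_distance / max(len(a), len(b))."""
    if not a or not b:
        return 0.0
    dist = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return 1.0 - dist / max(len(a), len(b))


def reduce_redundancy(
    records: Sequence[ProteinRecord],
    identity_threshold: float = 0.40,
    identity_fn: Callable[[str, str], float] = edlib_identity,
) -> tuple[list[ProteinRecord], dict[str, str]]:
    """Greedy identity clustering; keep the longest sequence per cluster.

    Records are visited by descending length (ties broken by id for
    determinism); each joins the first existing cluster whose
    representative is at least ``identity_threshold`` identical, else
    founds a new cluster. Because founders are visited longest-first, the
    representative of every cluster is its longest member. Returns the
    representatives (in founding order) and a member-id -> representative-id
    map.
    """
    if not (0.0 < identity_threshold <= 1.0):
        raise ValueError(f"identity threshold {identity_threshold} outside (0, 1]")
    ordered = sorted(records, key=lambda r: (-len(r), r.id))
    representatives: list[ProteinRecord] = []
    cluster_map: dict[str, str] = {}
    for rec in ordered:
        for rep in representatives:
            if identity_fn(rec.sequence, rep.sequence) >= identity_threshold:
                cluster_map[rec.id] = rep.id
                break
        else:
            representatives.append(rec)
            cluster_map[rec.id] = rec.id
    return representatives, cluster_map


def balance_and_split(
    positives: Sequence[ProteinRecord],
    negatives: Sequence[ProteinRecord],
    test_fraction: float = 0.2,
    seed: int = 0,
) -> tuple[list[ProteinRecord], list[ProteinRecord]]:
    """Subsample negatives to the positive count, then split train/test.

    Negatives are drawn without replacement; the test split is stratified
    (equal class counts, sizes rounded per class) and disjoint from the
    train split. Fully reproducible from the seed.
    """
    if len(negatives) < len(positives):
        raise ValueError(
            f"need at least {len(positives)} negatives, have {len(negatives)}"
        )
    if not (0.0 <= test_fraction < 1.0):
        raise ValueError(f"test_fraction {test_fraction} outside [0, 1)")
    rng = np.random.default_rng(seed)
    neg_idx = rng.choice(len(negatives), size=len(positives), replace=False)
    balanced_neg = [negatives[i] for i in sorted(neg_idx)]
    train: list[ProteinRecord] = []
    test: list[ProteinRecord] = []
    for group in (list(positives), balanced_neg):
        n_test = int(round(test_fraction * len(group)))
        perm = rng.permutation(len(group))
        test.extend(group[i] for i in sorted(perm[:n_test]))
        train.extend(group[i] for i in sorted(perm[n_test:]))
    return train, test
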