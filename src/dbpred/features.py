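"""Assembly of hybrid feature vectors and named ablation subsets.

A full hybrid vector concatenates, in fixed order, the feature blocks

* ``BP`` (2): binding propensity descriptors,
* ``NBP`` (2): nonbinding propensity descriptors,
* ``PP`` (scheme-determined, 128 by default): physicochemical block,
* ``EI`` (400): pooled evolutionary profile,

for a default hybrid dimension of 4 + 128 + 400 = 532. The six named
subsets in :data:`SUBSETS` are the standard ablation grid (PP; EI;
BP+NBP+PP; BP+NBP+EI; PP+EI; BP+NBP+PP+EI). No scaling is applied at
assembly; standardization is a modelling concern.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from dbpred.evolution import EI_FEATURE_NAMES, ei_vector
from dbpred.physchem import PPConfig, pp_vector
from dbpred.propensity import propensity_vector
from dbpred.seqio import Label, ProteinRecord, PSSMatrix, ResidueAnnotationTrack

logger = logging.getLogger(__name__)

BLOCK_ORDER = ("BP", "NBP", "PP", "EI")

#: Named feature subsets of the ablation grid, keyed by their display name.
SUBSETS: dict[str, tuple[str, ...]] = {
    "PP": ("PP",),
    "EI": ("EI",),
    "BP+NBP+PP": ("BP", "NBP", "PP"),
    "BP+NBP+EI": ("BP", "NBP", "EI"),
    "PP+EI": ("PP", "EI"),
    "BP+NBP+PP+EI": ("BP", "NBP", "PP", "EI"),
}


@dataclass(frozen=True)
class FeatureVector:
    """Block-structured named features for one protein."""

    protein_id: str
    blocks: dict[str, tuple[tuple[str, ...], np.ndarray]]

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(
            n for b in BLOCK_ORDER if b in self.blocks for n in self.blocks[b][0]
        )

    @property
    def values(self) -> np.ndarray:
        return np.concatenate(
            [self.blocks[b][1] for b in BLOCK_ORDER if b in self.blocks]
        )

    def __len__(self) -> int:
        return sum(len(names) for names, _ in self.blocks.values())


def _normalize_subset(subset: str | tuple[str, ...]) -> tuple[str, ...]:
    if isinstance(subset, str):
        if subset not in SUBSETS:
            raise KeyError(
                f"unknown subset {subset!r}; known subsets: {sorted(SUBSETS)}"
            )
        return SUBSETS[subset]
    unknown = set(subset) - set(BLOCK_ORDER)
    if unknown:
        raise KeyError(f"unknown feature blocks {sorted(unknown)}")
    return tuple(b for b in BLOCK_ORDER if b in subset)


def build_features(
    protein: ProteinRecord,
    track: ResidueAnnotationTrack | None = None,
    pssm: PSSMatrix | None = None,
    subset: str | tuple[str, ...] = "BP+NBP+PP+EI",
    config: PPConfig | None = None,
) -> FeatureVector:
    """Compute the requested feature blocks for one protein.

    Only the inputs a subset needs must be supplied: PP needs the sequence
    alone, BP/NBP need ``track``, EI needs ``pssm``. Missing required
    inputs and invalid sequences raise ``ValueError``.
    """
    blocks_wanted = _normalize_subset(subset)
    if not protein.is_valid:
        raise ValueError(
            f"protein {protein.id!r}: sequence contains non-standard letters"
        )
    blocks: dict[str, tuple[tuple[str, ...], np.ndarray]] = {}
    if "BP" in blocks_wanted or "NBP" in blocks_wanted:
        if track is None:
            raise ValueError(
                f"protein {protein.id!r}: subset requires a residue-annotation track"
            )
        if len(track) != len(protein):
            raise ValueError(
                f"protein {protein.id!r}: track length {len(track)} != sequence "
                f"length {len(protein)}"
            )
        pv = propensity_vector(track)
        if "BP" in blocks_wanted:
            blocks["BP"] = (("bp.bp1", "bp.bp2"), np.array([pv.bp1, pv.bp2]))
        if "NBP" in blocks_wanted:
            blocks["NBP"] = (("nbp.nbp1", "nbp.nbp2"), np.array([pv.nbp1, pv.nbp2]))
    if "PP" in blocks_wanted:
        ppv = pp_vector(protein.sequence, config)
        blocks["PP"] = (ppv.names, ppv.values)
    if "EI" in blocks_wanted:
        if pssm is None:
            raise ValueError(f"protein {protein.id!r}: subset requires a PSSM")
        blocks["EI"] = (EI_FEATURE_NAMES, ei_vector(pssm, protein.sequence))
    return FeatureVector(protein_id=protein.id, blocks=blocks)


def batch_features(
    proteins: list[ProteinRecord],
    tracks: dict[str, ResidueAnnotationTrack] | None = None,
    pssms: dict[str, PSSMatrix] | None = None,
    subset: str | tuple[str, ...] = "BP+NBP+PP+EI",
    config: PPConfig | None = None,
) -> tuple[pd.DataFrame, list[Label]]:
    """Feature matrix and labels for a dataset, in input row order.

    Proteins with invalid sequences are excluded with a logged reason;
    an empty resulting matrix is an error.
    """
    tracks = tracks or {}
    pssms = pssms or {}
    rows: list[FeatureVector] = []
    labels: list[Label] = []
    for protein in proteins:
        if not protein.is_valid:
            logger.warning(
                "excluding protein %s: non-standard letters in sequence", protein.id
            )
            continue
        rows.append(
            build_features(
                protein,
                track=tracks.get(protein.id),
                pssm=pssms.get(protein.id),
                subset=subset,
                config=config,
            )
        )
        labels.append(protein.label)
    if not rows:
        raise ValueError("no valid proteins: resulting feature matrix is empty")
    matrix = pd.DataFrame(
        np.vstack([fv.values for fv in rows]),
        columns=list(rows[0].names),
        index=[fv.protein_id for fv in rows],
    )
    return matrix, labels
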