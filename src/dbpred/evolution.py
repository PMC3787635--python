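"""Fixed-length evolutionary-information feature from a PSSM.

A position-specific scoring matrix has one 20-column row per residue, so
its size varies with sequence length. The EI feature converts it to a
fixed 400-vector in three steps:

1. squash every integer log-odds score through the logistic sigmoid
   ``p(x) = 1 / (1 + exp(-x))``;
2. pool the normalized rows by the amino acid type at each sequence
   position, giving one Na x 20 sub-matrix per amino acid ``a`` (possibly
   empty);
3. sum each sub-matrix column-wise (plain sums, not means, so the block
   scales with how often ``a`` occurs) and concatenate the twenty
   20-vectors.

Both the amino-acid block order and the profile-column order follow the
PSI-BLAST alphabet ``A R N D C Q E G H I L K M F P S T W Y V``. Amino
acids absent from the sequence contribute an all-zero block.
"""

from __future__ import annotations

import numpy as np

from dbpred.seqio import PSIBLAST_ALPHABET, PSSMatrix

#: Feature names of the 400-dimensional EI block, fixed across proteins.
EI_FEATURE_NAMES: tuple[str, ...] = tuple(
    f"ei.{a}.{c}" for a in PSIBLAST_ALPHABET for c in PSIBLAST_ALPHABET
)


def normalize_pssm(pssm: PSSMatrix | np.ndarray) -> np.ndarray:
    """Elementwise logistic sigmoid of the PSSM scores; shape preserved."""
    scores = pssm.scores if isinstance(pssm, PSSMatrix) else np.asarray(pssm)
    return 1.0 / (1.0 + np.exp(-scores.astype(float)))


def pool_by_amino_acid(normalized: np.ndarray, sequence: str) -> dict[str, np.ndarray]:
    """Split normalized PSSM rows by the amino acid at each position.

    Returns one (Na, 20) block per amino acid in PSI-BLAST alphabet order;
    blocks for absent amino acids have zero rows.
    """
    normalized = np.asarray(normalized)
    if normalized.shape[0] != len(sequence):
        raise ValueError(
            f"PSSM has {normalized.shape[0]} rows but sequence has {len(sequence)} residues"
        )
    seq = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    return {
        a: normalized[seq == ord(a)] for a in PSIBLAST_ALPHABET
    }


def ei_vector(pssm: PSSMatrix, sequence: str) -> np.ndarray:
    """The 400-dimensional evolutionary-information feature.

    Entry ``20*i + j`` is the sum of normalized profile column ``j`` over
    all positions carrying amino acid ``i`` (both indices in PSI-BLAST
    alphabet order). The grand total of all 400 entries equals the sum of
    the whole normalized matrix, and the vector is invariant to permuting
    sequence positions together with their PSSM rows.
    """
    if pssm.residues and pssm.residues != sequence:
        raise ValueError(
            f"PSSM {pssm.protein_id!r}: residue letters disagree with the sequence"
        )
    blocks = pool_by_amino_acid(normalize_pssm(pssm), sequence)
    return np.concatenate(
        [blocks[a].sum(axis=0) if blocks[a].size else np.zeros(20) for a in PSIBLAST_ALPHABET]
    )
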