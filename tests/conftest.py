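import numpy as np
import pytest

from dbpred.seqio import ResidueAnnotationTrack
from dbpred.synthetic import GeneratorConfig, gen_proteins


def make_track(pattern: str, ris, pid: str = "p1") -> ResidueAnnotationTrack:
    """Build a track from a 'BNB...' pattern string and a list of RIs."""
    binding = np.array([c == "B" for c in pattern], dtype=bool)
    return ResidueAnnotationTrack(protein_id=pid, binding=binding, ri=np.asarray(ris))


def brute_force_pair_score(binding, ri, select_binding: bool) -> float:
    """O(N^2) enumeration oracle for the distance-decayed pair descriptors.

    Walks every unordered position pair once, applies the dyadic distance
    weight to the pair's mean RI, and divides by 10(N-1). Independent of
    the implementation under test.
    """
    binding = np.asarray(binding, dtype=bool)
    mask = binding if select_binding else ~binding
    ri = np.asarray(ri, dtype=float)
    n = len(ri)
    total = 0.0
    for a in range(n):
        for b in range(a + 1, n):
            if mask[a] and mask[b]:
                total += 2.0 ** (1 - (b - a)) * (ri[a] + ri[b]) / 2.0
    return total / (10.0 * (n - 1))


@pytest.fixture(scope="session")
def small_corpus():
    """A tiny labeled corpus with strong annotation-channel class signal."""
    cfg = GeneratorConfig(seed=123, n_per_class=12, min_length=30, max_length=60)
    return gen_proteins(cfg)
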