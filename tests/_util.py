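"""Shared test helpers: independent oracles and tiny constructors.

The alignment oracle is a vectorised exhaustive Hamming scan over every
allele, offset and orientation — deliberately independent of the k-mer
seeded implementation it checks.
"""

from __future__ import annotations

import numpy as np

from mhctyper.align import FORWARD, REVCOMP, reverse_complement

_N = ord("N")


def _window_mismatches(ref: str, read: str) -> np.ndarray:
    """Mismatch count of the read against every offset of ref (Hamming,
    N always mismatching)."""
    r = np.frombuffer(ref.encode(), dtype=np.uint8)
    q = np.frombuffer(read.encode(), dtype=np.uint8)
    L = q.shape[0]
    if r.shape[0] < L:
        return np.zeros(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(r, L)
    neq = windows != q[None, :]
    both_n = (windows == _N) & (q[None, :] == _N)
    return (neq | both_n).sum(axis=1)


def brute_force_hits(read_seq: str, catalogue, max_mismatches: int):
    """Every (allele_id, offset, orientation, mismatches) within budget."""
    hits = []
    for orientation, seq in (
        (FORWARD, read_seq.upper()),
        (REVCOMP, reverse_complement(read_seq.upper())),
    ):
        for allele in catalogue:
            mms = _window_mismatches(allele.sequence, seq)
            for off in np.flatnonzero(mms <= max_mismatches):
                hits.append((allele.allele_id, int(off), orientation, int(mms[off])))
    return hits


def best_stratum(hits):
    if not hits:
        return []
    best = min(h[3] for h in hits)
    return [h for h in hits if h[3] == best]


def hit_tuples(alignment_hits):
    return [(h.allele_id, h.offset, h.orientation, h.mismatches)
            for h in alignment_hits]


def random_catalogue(rng, n_alleles: int = 20, length: int = 400):
    """Uniform random allele sequences (no biological structure)."""
    from mhctyper.catalogue import Allele, AlleleCatalogue

    alleles = []
    for i in range(n_alleles):
        seq = "".join("ACGT"[b] for b in rng.integers(0, 4, size=length))
        alleles.append(Allele(allele_id=f"R{i:02d}", sequence=seq))
    return AlleleCatalogue(alleles=alleles, version_tag="random")


def mutate(seq: str, n: int, rng) -> str:
    out = list(seq)
    for pos in rng.choice(len(seq), size=n, replace=False):
        out[pos] = [b for b in "ACGT" if b != out[pos]][int(rng.integers(3))]
    return "".join(out)
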