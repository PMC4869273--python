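"""Ungapped end-to-end short-read alignment against the allele catalogue.

The contract mirrors the two stringency settings the typing method uses:
zero mismatches for allele calling, and up to three mismatches keeping only
the best stratum for novel-allele candidate detection.  Candidate loci are
found by pigeonhole k-mer seeding (``max_mismatches + 1`` disjoint seeds
guarantee that no locus within the mismatch budget is missed) and verified by
full-length Hamming comparison in both orientations.  ``N`` in read or
reference always counts as a mismatch.

Coordinates are 0-based half-open; the catalogue is always the forward
strand and orientation is recorded on the read.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np

from .catalogue import AlleleCatalogue

FORWARD = "forward"
REVCOMP = "reverse_complement"

_COMPLEMENT = bytes.maketrans(b"ACGTNacgtn", b"TGCANtgcan")
_N = 78  # ord("N")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class ReadRecord(NamedTuple):
    read_id: str
    mate: int  # 1, 2, or 0 for unpaired
    sequence: str
    qualities: str | None = None

    @property
    def key(self) -> tuple[str, int]:
        return (self.read_id, self.mate)


class AlignmentHit(NamedTuple):
    read_id: str
    mate: int
    allele_id: str
    offset: int
    orientation: str
    mismatches: int


class PairLink(NamedTuple):
    allele_id: str
    hit1: AlignmentHit
    hit2: AlignmentHit
    fragment_length: int


@dataclass
class KmerIndex:
    """Exhaustive k-mer -> (allele, position) map over the catalogue."""

    k: int
    allele_ids: list[str]
    arrays: list[np.ndarray]          # uint8 ASCII per allele, forward strand
    raw: list[bytes]                  # same sequences as bytes, for mm=0 fast path
    kmap: dict[bytes, list[tuple[int, int]]]
    catalogue_version: str
    has_n: list[bool] = field(default_factory=list)
    id_to_idx: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.id_to_idx:
            self.id_to_idx = {a: i for i, a in enumerate(self.allele_ids)}
        if not self.has_n:
            self.has_n = [b"N" in r for r in self.raw]

    @property
    def min_allele_length(self) -> int:
        return min(len(r) for r in self.raw) if self.raw else 0


def build_index(cat: AlleleCatalogue, k: int = 15) -> KmerIndex:
    """Build the exhaustive seed index (forward strand only; reads are
    reverse-complemented during search instead)."""
    if k < 8:
        raise ValueError(f"k={k} too small; need k >= 8")
    allele_ids, arrays, raw = [], [], []
    kmap: dict[bytes, list[tuple[int, int]]] = {}
    for idx, allele in enumerate(cat):
        seq = allele.sequence.encode()
        if len(seq) < k:
            raise ValueError(
                f"allele {allele.allele_id!r} (length {len(seq)}) shorter than k={k}"
            )
        allele_ids.append(allele.allele_id)
        raw.append(seq)
        arrays.append(np.frombuffer(seq, dtype=np.uint8))
        for pos in range(len(seq) - k + 1):
            kmap.setdefault(seq[pos : pos + k], []).append((idx, pos))
    return KmerIndex(
        k=k,
        allele_ids=allele_ids,
        arrays=arrays,
        raw=raw,
        kmap=kmap,
        catalogue_version=cat.version_tag,
    )


def _hamming(ref_arr: np.ndarray, off: int, read_arr: np.ndarray, check_n: bool) -> int:
    window = ref_arr[off : off + read_arr.shape[0]]
    mm = int(np.count_nonzero(window != read_arr))
    if check_n:
        # positions where both are N compare equal but still count as mismatch
        mm += int(np.count_nonzero((window == _N) & (read_arr == _N)))
    return mm


def _candidates_seeded(
    seq: bytes, index: KmerIndex, n_seeds: int
) -> set[tuple[int, int]]:
    k = index.k
    read_len = len(seq)
    cands: set[tuple[int, int]] = set()
    for i in range(n_seeds):
        s = i * k
        hits = index.kmap.get(seq[s : s + k])
        if not hits:
            continue
        for aidx, pos in hits:
            off = pos - s
            if 0 <= off <= len(index.raw[aidx]) - read_len:
                cands.add((aidx, off))
    return cands


def _candidates_exhaustive(read_len: int, index: KmerIndex) -> Iterable[tuple[int, int]]:
    for aidx, ref in enumerate(index.raw):
        for off in range(len(ref) - read_len + 1):
            yield (aidx, off)


def _align_oriented(
    seq: str, index: KmerIndex, max_mismatches: int
) -> list[tuple[int, int, int]]:
    """(allele_idx, offset, mismatches) for one read orientation."""
    raw = seq.encode()
    read_len = len(raw)
    n_seeds = max_mismatches + 1
    exhaustive = read_len < n_seeds * index.k
    out: list[tuple[int, int, int]] = []
    if max_mismatches == 0 and not exhaustive:
        # mm=0 fast path: seeded candidates verified by bytes equality
        has_n = b"N" in raw
        for aidx, off in _candidates_seeded(raw, index, 1):
            window = index.raw[aidx][off : off + read_len]
            if not has_n and b"N" not in window and window == raw:
                out.append((aidx, off, 0))
        return out
    read_arr = np.frombuffer(raw, dtype=np.uint8)
    check_n = b"N" in raw
    if exhaustive:
        cands = _candidates_exhaustive(read_len, index)
    else:
        cands = _candidates_seeded(raw, index, n_seeds)
    for aidx, off in cands:
        ref = index.arrays[aidx]
        mm = _hamming(ref, off, read_arr, check_n or index.has_n[aidx])
        if mm <= max_mismatches:
            out.append((aidx, off, mm))
    return out


def align_read(
    read: ReadRecord,
    index: KmerIndex,
    max_mismatches: int = 0,
    stratum: str = "best_only",
) -> list[AlignmentHit]:
    """Align one read end-to-end in both orientations.

    ``stratum="all_valid"`` returns every placement within the mismatch
    budget; ``"best_only"`` returns all placements tied at the minimal
    observed mismatch count (Bowtie ``--best`` semantics).
    """
    if stratum not in ("all_valid", "best_only"):
        raise ValueError(f"unknown stratum {stratum!r}")
    found: list[AlignmentHit] = []
    for orientation, seq in (
        (FORWARD, read.sequence.upper()),
        (REVCOMP, reverse_complement(read.sequence.upper())),
    ):
        for aidx, off, mm in _align_oriented(seq, index, max_mismatches):
            found.append(
                AlignmentHit(
                    read.read_id, read.mate, index.allele_ids[aidx], off, orientation, mm
                )
            )
    if stratum == "best_only" and found:
        best = min(h.mismatches for h in found)
        found = [h for h in found if h.mismatches == best]
    return found


def align_pair(
    r1: ReadRecord,
    r2: ReadRecord,
    index: KmerIndex,
    max_mismatches: int = 0,
    pairing: str = "independent",
    stratum: str = "best_only",
    max_fragment: int = 600,
) -> tuple[list[AlignmentHit], list[AlignmentHit], list[PairLink]]:
    """Align both mates; ``constrained`` additionally emits concordant links
    (same allele, opposite orientations, implied fragment within bounds),
    used for variant phasing."""
    if r1.read_id != r2.read_id:
        raise ValueError("mates must share a read_id")
    hits1 = align_read(r1, index, max_mismatches, stratum)
    hits2 = align_read(r2, index, max_mismatches, stratum)
    links: list[PairLink] = []
    if pairing == "constrained":
        len1, len2 = len(r1.sequence), len(r2.sequence)
        for h1 in hits1:
            for h2 in hits2:
                if h1.allele_id != h2.allele_id or h1.orientation == h2.orientation:
                    continue
                left = min(h1.offset, h2.offset)
                right = max(h1.offset + len1, h2.offset + len2)
                frag = right - left
                if max(len1, len2) <= frag <= max_fragment:
                    links.append(PairLink(h1.allele_id, h1, h2, frag))
    elif pairing != "independent":
        raise ValueError(f"unknown pairing mode {pairing!r}")
    return hits1, hits2, links


@dataclass
class Assignment:
    """Per-allele read placements produced by a multi-mapping policy.

    ``placements[allele_id]`` is a list of ``(offset, length, weight)``;
    ``counts[allele_id]`` is the summed weight, and ``n_assigned`` the number
    of reads that received any assignment.
    """

    placements: dict[str, list[tuple[int, int, float]]]
    counts: dict[str, float]
    n_assigned: int


def assign_reads(
    hits_per_read: dict[tuple, list[AlignmentHit]],
    read_lengths: dict[tuple, int],
    policy: str = "all",
    seed: int = 0,
) -> Assignment:
    """Resolve multi-mapping reads into per-allele placements.

    ``all``: each tied allele gets the read at weight 1 (coverage/calling);
    ``fractional``: weight 1/t across t tied alleles (quantification default);
    ``random``: one tied allele drawn uniformly under the seed (random-report
    emulation of the original aligner).
    """
    if policy not in ("all", "fractional", "random"):
        raise ValueError(f"unknown assignment policy {policy!r}")
    rng = np.random.default_rng(seed)
    placements: dict[str, list[tuple[int, int, float]]] = {}
    counts: dict[str, float] = {}
    n_assigned = 0
    for key in sorted(hits_per_read):
        hits = hits_per_read[key]
        if not hits:
            continue
        n_assigned += 1
        length = read_lengths[key]
        if policy == "random" and len(hits) > 1:
            hits = [hits[int(rng.integers(len(hits)))]]
        weight = 1.0 if policy != "fractional" else 1.0 / len(hits)
        for h in hits:
            placements.setdefault(h.allele_id, []).append((h.offset, length, weight))
            counts[h.allele_id] = counts.get(h.allele_id, 0.0) + weight
    return Assignment(placements=placements, counts=counts, n_assigned=n_assigned)


# ---------------------------------------------------------------------------
# I/O helpers


def read_fastq(path) -> list[ReadRecord]:
    """Read (optionally gzipped) FASTQ; mate inferred from a ``/1``/``/2``
    id suffix, else unpaired."""
    opener = gzip.open if str(path).endswith(".gz") else open
    reads: list[ReadRecord] = []
    with opener(str(path), "rt") as fh:
        while True:
            header = fh.readline().strip()
            if not header:
                break
            seq = fh.readline().strip()
            fh.readline()
            qual = fh.readline().strip()
            rid = header[1:].split()[0]
            mate = 0
            if rid.endswith("/1") or rid.endswith("/2"):
                mate = int(rid[-1])
                rid = rid[:-2]
            reads.append(ReadRecord(rid, mate, seq.upper(), qual or None))
    return reads


def write_sam(hits: Iterable[AlignmentHit], cat: AlleleCatalogue, path) -> None:
    """Minimal SAM export of hits with the catalogue as reference
    (NM tag carries the mismatch count)."""
    with open(str(path), "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for allele in cat:
            fh.write(f"@SQ\tSN:{allele.allele_id}\tLN:{len(allele)}\n")
        for h in hits:
            flag = 0
            if h.orientation == REVCOMP:
                flag |= 16
            if h.mate == 1:
                flag |= 64 | 1
            elif h.mate == 2:
                flag |= 128 | 1
            fh.write(
                f"{h.read_id}\t{flag}\t{h.allele_id}\t{h.offset + 1}\t255\t*\t*\t0\t0"
                f"\t*\t*\tNM:i:{h.mismatches}\n"
            )
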