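"""Novel-allele reconstruction.

Two discovery routes exist, mirroring how close and distant novel alleles
show up in the data:

* **variant route** — a novel allele a few substitutions away from a known
  "parent" leaves a consistent pile of mismatching reads on that parent after
  relaxed alignment.  Consistent pileup variants are detected, phased into
  haplotypes using reads and mate pairs that jointly cover two variant
  positions, and applied to the parent sequence.
* **de-novo route** — an allele too far from every catalogue entry leaves
  reads that align nowhere.  Starting from reads sharing a recurrent k-mer
  absent from the catalogue, the sequence is read directly off the reads by
  greedy bidirectional overlap extension.

Every candidate must survive validation: it must be distinct from the
catalogue, fully covered by a zero-mismatch re-alignment of the individual's
reads, and translate into either an intact open reading frame (classical) or
carry the documented non-classical features (early stop or VPI/IPI/VLIK
transmembrane motif).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass

from .align import REVCOMP, ReadRecord, align_read, build_index, reverse_complement
from .catalogue import (
    CLASSICAL,
    NONCLASSICAL,
    Allele,
    AlleleCatalogue,
    translate_allele,
)


@dataclass(frozen=True)
class VariantObservation:
    parent_allele_id: str
    position: int  # 0-based on parent
    ref_base: str
    alt_base: str
    support_reads: int
    pileup_depth: int

    @property
    def support_fraction(self) -> float:
        return self.support_reads / self.pileup_depth if self.pileup_depth else 0.0


@dataclass
class PhasedVariantSet:
    parent_allele_id: str
    variants: list[VariantObservation]  # positions strictly increasing
    linking_evidence: int = 0
    ambiguous: bool = False

    def __post_init__(self) -> None:
        self.variants = sorted(self.variants, key=lambda v: v.position)
        positions = [v.position for v in self.variants]
        if len(set(positions)) != len(positions):
            raise ValueError("phased set contains two variants at one position")


def pileup_variants(
    parent: Allele,
    placements,
    min_support: int = 3,
    min_fraction: float = 0.2,
) -> list[VariantObservation]:
    """Per-position base counts from oriented read placements on the parent.

    ``placements`` is an iterable of ``(sequence, offset)`` with the sequence
    already on the reference strand.  A variant is emitted when an alternate
    base reaches both the absolute support and the pileup-fraction threshold
    (automating what was originally a by-eye inspection of the pileup).
    """
    length = len(parent)
    counts = [defaultdict(int) for _ in range(length)]
    for seq, off in placements:
        for i, base in enumerate(seq):
            pos = off + i
            if 0 <= pos < length and base != "N":
                counts[pos][base] += 1
    variants = []
    for pos in range(length):
        col = counts[pos]
        depth = sum(col.values())
        if not depth:
            continue
        ref = parent.sequence[pos]
        for base, n in sorted(col.items()):
            if base == ref:
                continue
            if n >= min_support and n / depth >= min_fraction:
                variants.append(
                    VariantObservation(parent.allele_id, pos, ref, base, n, depth)
                )
    return variants


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def phase_variants(
    variants: list[VariantObservation],
    fragments,
    min_link: int = 2,
    hom_fraction: float = 0.8,
    conflict_fraction: float = 0.1,
) -> list[PhasedVariantSet]:
    """Group variants into haplotypes from joint read/mate-pair observations.

    ``fragments`` is an iterable of per-fragment placement lists (both mates
    of one sequenced fragment together), each ``(sequence, offset)`` on the
    reference strand.  Two variants are linked when at least ``min_link``
    fragments carry both alternate bases, and are held apart (anti-edge) when
    fragments carry one alternate with the other position at reference —
    repulsion evidence dominates and is never merged.  Repulsion is judged
    proportionately: at least ``min_link`` fragments and at least
    ``conflict_fraction`` of the joint observations, so a handful of
    sequencing-error reads cannot veto a deeply supported linkage.  Components in
    which every variant approaches fixation (support fraction >=
    ``hom_fraction``) and that show no mutual repulsion are additionally
    merged: when the novel allele replaces its parent entirely, all pileup
    columns are alternate and distant variants can never be read-linked, yet
    the absence of any reference reads identifies the single haplotype.
    Contradictory evidence above both thresholds flags the sets ambiguous
    rather than silently merging.
    """
    if not variants:
        return []
    variants = sorted(variants, key=lambda v: (v.position, v.alt_base))
    vidx = {(v.position, v.alt_base): i for i, v in enumerate(variants)}
    n = len(variants)
    pos_edges: Counter = Counter()
    anti_edges: Counter = Counter()
    by_position = defaultdict(list)
    for v in variants:
        by_position[v.position].append(v)

    for frag in fragments:
        seen: dict[int, str] = {}
        drop: set[int] = set()
        for seq, off in frag:
            for pos in by_position:
                i = pos - off
                if 0 <= i < len(seq):
                    base = seq[i]
                    if base == "N":
                        continue
                    if pos in seen and seen[pos] != base:
                        drop.add(pos)  # mates disagree: unusable position
                    seen[pos] = base
        for pos in drop:
            seen.pop(pos, None)
        observed = sorted(seen)
        for ai in range(len(observed)):
            for bi in range(ai + 1, len(observed)):
                pa, pb = observed[ai], observed[bi]
                base_a, base_b = seen[pa], seen[pb]
                for va in by_position[pa]:
                    for vb in by_position[pb]:
                        key = (vidx[(va.position, va.alt_base)],
                               vidx[(vb.position, vb.alt_base)])
                        a_alt = base_a == va.alt_base
                        b_alt = base_b == vb.alt_base
                        a_ref = base_a == va.ref_base
                        b_ref = base_b == vb.ref_base
                        if a_alt and b_alt:
                            pos_edges[key] += 1
                        elif (a_alt and b_ref) or (a_ref and b_alt):
                            anti_edges[key] += 1

    def anti(i: int, j: int) -> int:
        return anti_edges[(i, j)] + anti_edges[(j, i)]

    def linked(i: int, j: int) -> int:
        return pos_edges[(i, j)] + pos_edges[(j, i)]

    def in_repulsion(i: int, j: int) -> bool:
        a, p = anti(i, j), linked(i, j)
        return a >= min_link and a >= conflict_fraction * (a + p)

    uf = _UnionFind(n)
    ambiguous_pairs = []
    for i in range(n):
        for j in range(i + 1, n):
            if variants[i].position == variants[j].position:
                continue  # same-position alternates can never share a haplotype
            if linked(i, j) >= min_link:
                if in_repulsion(i, j):
                    ambiguous_pairs.append((i, j))
                else:
                    uf.union(i, j)

    components: dict[int, list[int]] = defaultdict(list)
    for i in range(n):
        components[uf.find(i)].append(i)

    # fixation merge: components of near-fixed variants without mutual repulsion
    comp_keys = sorted(components)
    fixed = [
        key
        for key in comp_keys
        if all(variants[i].support_fraction >= hom_fraction for i in components[key])
    ]
    mergeable = []
    for key in fixed:
        ok = True
        for other in mergeable:
            for i in components[key]:
                for j in components[other]:
                    if (
                        variants[i].position == variants[j].position
                        or in_repulsion(i, j)
                    ):
                        ok = False
        if ok:
            mergeable.append(key)
    if len(mergeable) > 1:
        base = mergeable[0]
        for key in mergeable[1:]:
            components[base].extend(components.pop(key))

    flagged = set()
    for i, j in ambiguous_pairs:
        flagged.add(uf.find(i))
        flagged.add(uf.find(j))

    out = []
    for key in sorted(components, key=lambda c: min(variants[i].position for i in components[c])):
        members = [variants[i] for i in components[key]]
        evidence = sum(
            linked(i, j)
            for ai, i in enumerate(components[key])
            for j in components[key][ai + 1 :]
        )
        out.append(
            PhasedVariantSet(
                parent_allele_id=members[0].parent_allele_id,
                variants=members,
                linking_evidence=evidence,
                ambiguous=key in flagged
                or any(uf.find(i) in flagged for i in components[key]),
            )
        )
    return out


def reconstruct_variant_allele(parent: Allele, phased: PhasedVariantSet) -> str:
    """Apply the phased substitutions to the parent sequence (length preserved)."""
    if not phased.variants:
        raise ValueError("phased variant set is empty")
    seq = list(parent.sequence)
    for v in phased.variants:
        if seq[v.position] != v.ref_base:
            raise ValueError(
                f"variant ref {v.ref_base} does not match parent at {v.position}"
            )
        seq[v.position] = v.alt_base
    return "".join(seq)


# ---------------------------------------------------------------------------
# de-novo assembly by greedy overlap extension


@dataclass
class AssemblyResult:
    sequence: str | None
    reason: str  # "ok", "ambiguous", "fragmentary"

    @property
    def ok(self) -> bool:
        return self.reason == "ok"


def assemble_de_novo(
    seed_reads: list[ReadRecord],
    all_reads: list[ReadRecord],
    min_overlap: int = 25,
    min_contig: int = 200,
    agree_fraction: float = 0.8,
    mate_min_overlap: int = 12,
    k: int = 15,
) -> AssemblyResult:
    """Read a novel sequence directly off the reads.

    Starting from a seed read, the contig is extended one base at a time in
    both directions.  Reads join the layout only through an exact overlap of
    at least ``min_overlap`` nt; each extension base must win at least
    ``agree_fraction`` of the votes of reads spanning it, otherwise the
    branch is ambiguous.  When ordinary extension stalls, mates of already
    placed reads may re-anchor with a reduced overlap (low-coverage rescue).
    Fails with ``"ambiguous"`` on a supported branch conflict and
    ``"fragmentary"`` when the final contig is shorter than ``min_contig``.
    """
    if not seed_reads:
        return AssemblyResult(None, "fragmentary")
    pool_seqs: list[str] = []
    pool_mate_of: list[tuple[str, int]] = []  # (read_id, mate) of the OTHER mate
    pool_self: list[tuple[str, int]] = []
    for r in all_reads:
        seq = r.sequence.upper()
        other = (r.read_id, 2 if r.mate == 1 else 1 if r.mate == 2 else 0)
        for s in (seq, reverse_complement(seq)):
            pool_seqs.append(s)
            pool_mate_of.append(other)
            pool_self.append(r.key)
    kindex: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for ridx, s in enumerate(pool_seqs):
        for p in range(len(s) - k + 1):
            kindex[s[p : p + k]].append((ridx, p))

    contig = seed_reads[0].sequence.upper()
    state = {"ambiguous": False}

    def extend_right(contig: str) -> str:
        placed: dict[int, int] = {}
        rejected: set[int] = set()
        placed_keys: set[tuple[str, int]] = set()

        def try_place(ridx: int, offset: int) -> None:
            if ridx in placed or ridx in rejected:
                return
            s = pool_seqs[ridx]
            lo = max(0, offset)
            hi = min(len(contig), offset + len(s))
            if hi - lo < min_overlap:
                return
            if contig[lo:hi] == s[lo - offset : hi - offset]:
                placed[ridx] = offset
                placed_keys.add(pool_self[ridx])
            else:
                rejected.add(ridx)

        def recruit(from_pos: int) -> None:
            for p in range(max(0, from_pos), len(contig) - k + 1):
                for ridx, rpos in kindex.get(contig[p : p + k], ()):
                    try_place(ridx, p - rpos)

        recruit(0)
        while True:
            p = len(contig)
            votes: Counter = Counter()
            voters: dict[str, list[int]] = defaultdict(list)
            for ridx, off in placed.items():
                s = pool_seqs[ridx]
                if off + len(s) > p:
                    base = s[p - off]
                    votes[base] += 1
                    voters[base].append(ridx)
            if not votes:
                ext = _mate_rescue(
                    contig, placed_keys, pool_seqs, pool_mate_of, pool_self,
                    mate_min_overlap, min_overlap,
                )
                if ext is None:
                    return contig
                ridx, offset = ext
                placed[ridx] = offset
                placed_keys.add(pool_self[ridx])
                continue
            (top, top_n), *rest = votes.most_common()
            total = sum(votes.values())
            if rest and top_n / total < agree_fraction and rest[0][1] >= 2:
                state["ambiguous"] = True
                return contig
            contig += top
            for base, ridxs in voters.items():
                if base != top:
                    for ridx in ridxs:
                        placed.pop(ridx, None)
                        rejected.add(ridx)
            recruit(len(contig) - k)

    def _mate_rescue(
        contig, placed_keys, pool_seqs, pool_mate_of, pool_self, min_ov, max_ov
    ):
        """Reduced-overlap re-anchoring of mates of placed reads."""
        candidates = []
        for ridx, s in enumerate(pool_seqs):
            if pool_mate_of[ridx] not in placed_keys or pool_self[ridx] in placed_keys:
                continue
            for ov in range(max_ov - 1, min_ov - 1, -1):
                if len(s) > ov and contig.endswith(s[:ov]):
                    candidates.append((ridx, len(contig) - ov))
                    break
        if not candidates:
            return None
        next_bases = {pool_seqs[r][len(contig) - off] for r, off in candidates}
        if len(next_bases) != 1:
            return None
        return candidates[0]

    contig = extend_right(contig)
    if not state["ambiguous"]:
        # extend left: reverse-complement trick reuses the right-extension code
        rc = reverse_complement(contig)
        contig = reverse_complement(extend_right(rc))
    if state["ambiguous"]:
        return AssemblyResult(None, "ambiguous")
    if len(contig) < min_contig:
        return AssemblyResult(None, "fragmentary")
    return AssemblyResult(contig, "ok")


# ---------------------------------------------------------------------------
# validation and the driver used by the typing loop


def validate_novel(
    candidate: str,
    cat: AlleleCatalogue,
    reads,
    config=None,
    class_kind_hint: str | None = None,
) -> tuple[bool, str, object]:
    """Accept a candidate novel allele or reject it with a reason.

    Acceptance requires (a) a sequence distinct from every catalogue allele,
    (b) complete coverage of the candidate by a zero-mismatch re-alignment of
    the reads, and (c) an intact open reading frame, or the documented
    non-classical features when the candidate is assigned non-classical.
    Returns ``(accepted, reason, ProteinReport)``.
    """
    from .calling import TypingConfig, call_alleles_exact

    config = config or TypingConfig()
    candidate = candidate.upper()
    existing = cat.find_by_sequence(candidate)
    if existing is not None:
        return False, f"duplicate of {existing.allele_id}", None
    probe = Allele(allele_id="candidate", sequence=candidate)
    tmp = AlleleCatalogue(alleles=[probe], version_tag="candidate")
    call, profiles = call_alleles_exact(reads, tmp, config=config)
    if "candidate" not in call.called:
        gaps = profiles["candidate"].uncovered_intervals
        return False, f"incomplete coverage ({len(gaps)} uncovered intervals)", None
    report = translate_allele(probe)
    intact_orf = report.has_orf and not report.early_stop
    if class_kind_hint == NONCLASSICAL:
        ok = intact_orf or report.nonclassical_features
    elif class_kind_hint == CLASSICAL:
        ok = intact_orf
    else:
        ok = intact_orf or report.nonclassical_features
    if not ok:
        return False, "no open reading frame and no non-classical features", report
    return True, "ok", report


def discover_from_parent(
    reads,
    cat: AlleleCatalogue,
    parent_id: str,
    index=None,
    config=None,
    relaxed_hits: dict | None = None,
) -> list[tuple[bool, str]]:
    """Variant-route discovery on one candidate parent.

    Aligns at the relaxed threshold (best stratum), piles up variants on the
    parent, phases them, reconstructs one candidate per phase set and
    validates each.  Returns ``[(accepted, sequence_or_reason), ...]``.
    ``relaxed_hits`` may carry a precomputed ``read.key -> hits`` map to
    avoid re-alignment.
    """
    from .calling import TypingConfig

    config = config or TypingConfig()
    if index is None:
        index = build_index(cat, config.k)
    parent = cat.get(parent_id)
    reads = list(reads)
    by_key = {r.key: r for r in reads}
    if relaxed_hits is None:
        relaxed_hits = {}
        for r in reads:
            hits = align_read(r, index, config.max_mismatches_relaxed, "best_only")
            if hits:
                relaxed_hits[r.key] = hits

    fragments: dict[str, list[tuple[str, int]]] = defaultdict(list)
    for key, hits in relaxed_hits.items():
        read = by_key[key]
        for h in hits:
            if h.allele_id != parent_id:
                continue
            seq = read.sequence.upper()
            if h.orientation == REVCOMP:
                seq = reverse_complement(seq)
            fragments[read.read_id].append((seq, h.offset))

    placements = [pl for frag in fragments.values() for pl in frag]
    variants = pileup_variants(
        parent, placements, config.min_support, config.min_fraction
    )
    if not variants:
        return []
    phased = phase_variants(
        variants, fragments.values(), config.min_link, config.hom_fraction
    )
    results: list[tuple[bool, str]] = []
    accepted_seqs: set[str] = set()
    for pset in phased:
        if pset.ambiguous:
            results.append((False, "ambiguous phasing"))
            continue
        candidate = reconstruct_variant_allele(parent, pset)
        if candidate in accepted_seqs:
            results.append((False, "duplicate of co-discovered candidate"))
            continue
        ok, reason, _report = validate_novel(
            candidate, cat, reads, config, parent.class_kind
        )
        if ok:
            accepted_seqs.add(candidate)
            results.append((True, candidate))
        else:
            results.append((False, reason))
    return results


def _orient_coding(contig: str) -> str:
    """Put an assembled contig on its coding strand.

    The assembly seed read may come from either mate, so the contig strand
    is arbitrary; the sense strand is recognised by its longer ATG-led open
    reading frame (class I cDNAs code essentially end to end).
    """

    def orf_span(seq: str) -> int:
        probe = Allele(allele_id="orient", sequence=seq)
        report = translate_allele(probe)
        return len(report.aa_sequence)

    rc = reverse_complement(contig)
    return contig if orf_span(contig) >= orf_span(rc) else rc


def discover_de_novo(
    reads,
    cat: AlleleCatalogue,
    index=None,
    config=None,
    max_assemblies: int = 4,
    relaxed_hits: dict | None = None,
) -> list[tuple[str, str]]:
    """De-novo route: assemble alleles from reads no catalogue entry explains.

    Unaligned reads (no placement within the relaxed mismatch budget) are
    scanned for recurrent k-mers absent from the catalogue; reads sharing the
    most frequent such k-mer seed a greedy overlap assembly.  Validated
    contigs are returned as ``(sequence, class_kind)``.
    """
    from .calling import TypingConfig

    config = config or TypingConfig()
    if index is None:
        index = build_index(cat, config.k)
    reads = list(reads)
    if relaxed_hits is not None:
        unaligned = [r for r in reads if r.key not in relaxed_hits]
    else:
        unaligned = [
            r
            for r in reads
            if not align_read(r, index, config.max_mismatches_relaxed, "best_only")
        ]
    if not unaligned:
        return []
    k = index.k
    kmer_counts: Counter = Counter()
    for r in unaligned:
        seq = r.sequence.upper()
        for variant_seq in (seq, reverse_complement(seq)):
            for p in range(len(variant_seq) - k + 1):
                kmer = variant_seq[p : p + k]
                if "N" not in kmer and kmer not in index.kmap:
                    kmer_counts[kmer] += 1

    accepted: list[tuple[str, str]] = []
    used_kmers: set[str] = set()
    for _ in range(max_assemblies):
        candidates = [
            (cnt, kmer)
            for kmer, cnt in kmer_counts.items()
            if cnt >= config.denovo_seed_support and kmer not in used_kmers
        ]
        if not candidates:
            break
        _, seed_kmer = max(candidates)
        seeds = [
            r
            for r in unaligned
            if seed_kmer in r.sequence.upper()
            or seed_kmer in reverse_complement(r.sequence.upper())
        ]
        result = assemble_de_novo(
            seeds,
            unaligned,
            min_overlap=config.min_overlap,
            min_contig=config.min_contig,
        )
        used_kmers.add(seed_kmer)
        if not result.ok:
            continue
        contig = _orient_coding(result.sequence)
        rc = reverse_complement(contig)
        for p in range(len(contig) - k + 1):
            used_kmers.add(contig[p : p + k])
            used_kmers.add(rc[p : p + k])
        ok, _reason, report = validate_novel(contig, cat, reads, config)
        if not ok:
            continue
        kind = (
            CLASSICAL
            if (report.has_orf and not report.early_stop and report.tm_motif == "none")
            else NONCLASSICAL
        )
        accepted.append((contig, kind))
    return accepted
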