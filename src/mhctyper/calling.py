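"""Coverage-based allele calling and the iterative typing loop.

An allele is declared present in an individual only when its entire cDNA
sequence is covered by reads accepted at zero mismatches ("complete-coverage
calling").  Novel-allele candidates are catalogue alleles that become fully
covered — or fully covered except one short gap (< 5 bp) — once the mismatch
budget is relaxed to three with best-stratum reporting.  The outer loop
alternates exact calling with novel-allele discovery, extending the catalogue
until an iteration adds nothing, classical genes first, then non-classical;
a final alignment restricted to the individual's called alleles produces the
read counts used for expression quantification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import novel as novel_mod
from .align import Assignment, KmerIndex, align_read, assign_reads, build_index
from .catalogue import CLASSICAL, NONCLASSICAL, AlleleCatalogue


@dataclass
class CoverageProfile:
    allele_id: str
    depth: np.ndarray  # one entry per allele base
    uncovered_intervals: list[tuple[int, int]]  # maximal 0-based half-open

    @property
    def fully_covered(self) -> bool:
        return not self.uncovered_intervals

    @property
    def mean_depth(self) -> float:
        return float(self.depth.mean()) if self.depth.size else 0.0


@dataclass
class AlleleEvidence:
    read_count: float
    mean_depth: float
    stage: str  # "exact" or "novel"


@dataclass
class GenotypeCall:
    individual_id: str
    called: dict[str, AlleleEvidence] = field(default_factory=dict)
    catalogue_version: str = ""

    @property
    def allele_ids(self) -> set[str]:
        return set(self.called)


@dataclass
class TypingConfig:
    """Tunable knobs of the typing pipeline (defaults follow the method)."""

    k: int = 15
    max_mismatches_relaxed: int = 3
    min_depth: int = 1          # depth required for a base to count as covered
    max_gap: int = 4            # "< 5 bp": single uncovered interval of <= 4 nt
    min_support: int = 3        # variant pileup support threshold
    min_fraction: float = 0.2   # variant pileup fraction threshold
    hom_fraction: float = 0.8   # fraction above which unlinked variants merge
    min_link: int = 2           # fragments needed for a phasing edge
    min_overlap: int = 25       # de-novo assembly overlap
    min_contig: int = 200       # de-novo minimal contig length
    denovo_seed_support: int = 3
    prune_min_unique: int = 2   # unique zero-mismatch reads a call must keep
    max_fragment: int = 600
    iteration_cap: int = 20
    lab_tag: str = "FBN"
    seed: int = 0


def _interval_from_depth(depth: np.ndarray, min_depth: int) -> list[tuple[int, int]]:
    uncov = depth < min_depth
    if not uncov.any():
        return []
    edges = np.flatnonzero(np.diff(np.concatenate(([0], uncov.view(np.int8), [0]))))
    return [(int(edges[i]), int(edges[i + 1])) for i in range(0, len(edges), 2)]


def compute_coverage(
    assignment: Assignment, cat: AlleleCatalogue, min_depth: int = 1
) -> dict[str, CoverageProfile]:
    """Exact per-base depth from read placements, with maximal uncovered
    intervals; placements out of allele bounds are a hard error."""
    profiles: dict[str, CoverageProfile] = {}
    for allele in cat:
        length = len(allele)
        diff = np.zeros(length + 1, dtype=np.int64)
        for off, read_len, _w in assignment.placements.get(allele.allele_id, ()):
            if off < 0 or off + read_len > length:
                raise ValueError(
                    f"placement [{off}, {off + read_len}) out of bounds for "
                    f"{allele.allele_id} (length {length})"
                )
            diff[off] += 1
            diff[off + read_len] -= 1
        depth = np.cumsum(diff[:-1])
        profiles[allele.allele_id] = CoverageProfile(
            allele.allele_id, depth, _interval_from_depth(depth, min_depth)
        )
    return profiles


def _align_all(
    reads, index: KmerIndex, max_mismatches: int, stratum: str
) -> tuple[dict, dict]:
    hits_per_read: dict[tuple, list] = {}
    read_lengths: dict[tuple, int] = {}
    for read in reads:
        hits = align_read(read, index, max_mismatches, stratum)
        if hits:
            hits_per_read[read.key] = hits
            read_lengths[read.key] = len(read.sequence)
    return hits_per_read, read_lengths


def call_alleles_exact(
    reads,
    cat: AlleleCatalogue,
    index: KmerIndex | None = None,
    config: TypingConfig | None = None,
    individual_id: str = "sample",
) -> tuple[GenotypeCall, dict[str, CoverageProfile]]:
    """Zero-mismatch alignment (every tied allele supported) and complete-
    coverage calling: an allele is called iff no base is uncovered."""
    config = config or TypingConfig()
    if index is None:
        index = build_index(cat, config.k)
    hits, lengths = _align_all(reads, index, 0, "all_valid")
    assignment = assign_reads(hits, lengths, policy="all")
    profiles = compute_coverage(assignment, cat, config.min_depth)
    call = GenotypeCall(individual_id=individual_id, catalogue_version=cat.version_tag)
    for allele_id, prof in profiles.items():
        if prof.fully_covered:
            call.called[allele_id] = AlleleEvidence(
                read_count=assignment.counts.get(allele_id, 0.0),
                mean_depth=prof.mean_depth,
                stage="exact",
            )
    return call, profiles


def find_novel_candidates(
    reads,
    cat: AlleleCatalogue,
    already_called: set[str],
    index: KmerIndex | None = None,
    config: TypingConfig | None = None,
    class_kind: str | None = None,
    relaxed: tuple[dict, dict] | None = None,
) -> list[str]:
    """Parent candidates for novel alleles after relaxed alignment.

    An uncalled allele qualifies when, at three mismatches / best stratum,
    it is fully covered or has exactly one uncovered interval of <= 4 nt.
    Classical candidates are listed before non-classical, then by
    descending mean depth.  ``relaxed`` may carry precomputed
    ``(hits_per_read, read_lengths)`` from the same index.
    """
    config = config or TypingConfig()
    if index is None:
        index = build_index(cat, config.k)
    hits, lengths = relaxed or _align_all(
        reads, index, config.max_mismatches_relaxed, "best_only"
    )
    assignment = assign_reads(hits, lengths, policy="all")
    profiles = compute_coverage(assignment, cat, config.min_depth)
    ranked = []
    for allele in cat:
        if allele.allele_id in already_called:
            continue
        if class_kind is not None and allele.class_kind != class_kind:
            continue
        prof = profiles[allele.allele_id]
        gaps = prof.uncovered_intervals
        ok = not gaps or (len(gaps) == 1 and gaps[0][1] - gaps[0][0] <= config.max_gap)
        if ok and assignment.placements.get(allele.allele_id):
            ranked.append(allele)
    ranked.sort(
        key=lambda a: (
            a.class_kind != CLASSICAL,
            -profiles[a.allele_id].mean_depth,
            a.allele_id,
        )
    )
    return [a.allele_id for a in ranked]


@dataclass
class TypingResult:
    genotype: GenotypeCall
    catalogue: AlleleCatalogue
    audit: list[dict]
    final_counts: dict[str, float]


def run_iterative_typing(
    reads,
    cat: AlleleCatalogue,
    config: TypingConfig | None = None,
    individual_id: str = "sample",
) -> TypingResult:
    """Full per-individual typing: exact calling, novel discovery to closure
    (classical pass first, then non-classical), catalogue extension, and the
    final restricted alignment for quantification.

    The catalogue object is extended in place with accepted novel alleles so
    that cohort-level sharing works naturally.
    """
    config = config or TypingConfig()
    audit: list[dict] = []
    reads = list(reads)

    for iteration in range(config.iteration_cap + 1):
        if iteration == config.iteration_cap:
            raise RuntimeError(
                f"iteration cap {config.iteration_cap} exceeded for "
                f"{individual_id}"
            )
        index = build_index(cat, config.k)
        call, _profiles = call_alleles_exact(reads, cat, index, config, individual_id)
        relaxed = _align_all(
            reads, index, config.max_mismatches_relaxed, "best_only"
        )
        entry = {
            "iteration": iteration,
            "called": sorted(call.allele_ids),
            "added": [],
            "rejected": [],
        }
        # classical genes are swept to closure before non-classical ones
        added = _discover_novel(
            reads, cat, index, call.allele_ids, config, CLASSICAL, entry, relaxed
        )
        if not added:
            added = _discover_novel(
                reads, cat, index, call.allele_ids, config, NONCLASSICAL, entry,
                relaxed,
            )
        if not added:
            added = _discover_de_novo_pass(reads, cat, index, config, entry, relaxed)
        audit.append(entry)
        if not added:
            break

    index = build_index(cat, config.k)
    final_call, _ = call_alleles_exact(reads, cat, index, config, individual_id)
    consolidated = _consolidate_partials(reads, cat, final_call, config)
    if consolidated:
        entry = {
            "iteration": "consolidation",
            "called": sorted(final_call.allele_ids),
            "added": consolidated,
            "rejected": [],
        }
        audit.append(entry)
        index = build_index(cat, config.k)
        final_call, _ = call_alleles_exact(reads, cat, index, config,
                                           individual_id)
    _parsimony_prune(reads, cat, final_call, config)
    _drop_orphan_novels(cat, final_call, audit)
    for allele_id, ev in final_call.called.items():
        if cat.get(allele_id).provenance != "database":
            ev.stage = "novel"

    final_counts: dict[str, float] = {}
    if final_call.called:
        from .quantify import final_alignment_counts

        final_counts = final_alignment_counts(
            reads, sorted(final_call.allele_ids), cat,
            policy="fractional", seed=config.seed, k=config.k,
        )
    return TypingResult(
        genotype=final_call, catalogue=cat, audit=audit, final_counts=final_counts
    )


def _discover_novel(
    reads,
    cat: AlleleCatalogue,
    index: KmerIndex,
    called: set[str],
    config: TypingConfig,
    phase: str,
    entry: dict,
    relaxed: tuple[dict, dict],
) -> bool:
    """One variant-route discovery sweep for one class, returning True when
    the catalogue grew (the caller then re-aligns before sweeping further).

    Called alleles are swept too: when an individual carries two sibling
    novel alleles of one parent (or a parent plus a variant of it), the
    parent can be completely covered at zero mismatches and is therefore
    called — yet its relaxed-stringency pileup still shows the recurrent
    variant nucleotides that betray the novel alleles.
    """
    added = False
    candidates = find_novel_candidates(
        reads, cat, called, index, config, phase, relaxed=relaxed
    )
    # reconstructed alleles first: an incomplete reconstruction is the most
    # likely carrier of residual variant evidence, and completing it stops
    # those reads from seeding chimeras on related database alleles
    called_in_phase = sorted(
        (a for a in called if cat.get(a).class_kind == phase),
        key=lambda a: (cat.get(a).provenance == "database", a),
    )
    for parent_id in candidates + called_in_phase:
        results = novel_mod.discover_from_parent(
            reads, cat, parent_id, index, config, relaxed_hits=relaxed[0]
        )
        for accepted, seq_or_reason in results:
            if accepted:
                cat, new_id = _add_variant(cat, seq_or_reason, parent_id, config)
                entry["added"].append(new_id)
                added = True
            else:
                entry["rejected"].append({"parent": parent_id, "reason": seq_or_reason})
        if added:
            # catalogue changed: re-align before touching further parents
            return True
    return False


def _discover_de_novo_pass(
    reads, cat, index, config, entry, relaxed
) -> bool:
    """Assemble alleles from reads no catalogue entry explains (runs once
    both variant sweeps have reached closure)."""
    from .catalogue import add_novel_allele

    added = False
    accepted_seq = novel_mod.discover_de_novo(
        reads, cat, index, config, relaxed_hits=relaxed[0]
    )
    for seq, kind in accepted_seq:
        cat, new_id = add_novel_allele(
            cat, seq, parent_id=None, lab_tag=config.lab_tag, class_kind=kind
        )
        entry["added"].append(new_id)
        added = True
    return added


def _consolidate_partials(reads, cat: AlleleCatalogue, call: GenotypeCall,
                          config: TypingConfig) -> list[str]:
    """Merge co-parental partial reconstructions that phasing could not join.

    When a novel allele carries variants farther apart than a sequenced
    fragment, the variant route can only recover them as separate
    single-variant alleles, and once both partials are in the catalogue each
    soaks up the other's variant reads at zero mismatches, freezing the
    split.  Two (or more) called reconstructions of one parent whose
    variants show no repulsion evidence on any fragment are therefore also
    proposed as one combined allele; if the combination validates, parsimony
    later removes the partials it makes redundant.  Observable repulsion
    always blocks the merge, so genuinely distinct sibling alleles are never
    collapsed.  Returns the added allele ids.
    """
    from .catalogue import add_novel_allele
    from .novel import validate_novel

    by_parent: dict[str, list] = {}
    for allele_id in call.called:
        allele = cat.get(allele_id)
        if allele.provenance == "novel_variant" and allele.parent_id in cat:
            by_parent.setdefault(allele.parent_id, []).append(allele)
    added: list[str] = []
    for parent_id, group in sorted(by_parent.items()):
        if len(group) < 2:
            continue
        parent = cat.get(parent_id)
        member_vars = []
        for allele in group:
            member_vars.append({
                i: allele.sequence[i]
                for i in range(len(parent))
                if allele.sequence[i] != parent.sequence[i]
            })
        union: dict[int, str] = {}
        conflict = False
        for vs in member_vars:
            for pos, base in vs.items():
                if union.get(pos, base) != base:
                    conflict = True
                union[pos] = base
        if conflict or not union:
            continue
        if _repulsion_evidence(reads, parent, member_vars, config) >= config.min_link:
            continue
        seq = list(parent.sequence)
        for pos, base in union.items():
            seq[pos] = base
        candidate = "".join(seq)
        ok, _reason, _rep = validate_novel(
            candidate, cat, reads, config, parent.class_kind
        )
        if ok:
            cat, new_id = add_novel_allele(
                cat, candidate, parent_id, lab_tag=config.lab_tag
            )
            added.append(new_id)
    return added


def _repulsion_evidence(reads, parent, member_vars: list[dict], config) -> int:
    """Fragments observing an alternate base from one member together with
    the reference base at another member's position (evidence that the two
    variant sets sit on different haplotypes)."""
    from collections import defaultdict

    from .align import REVCOMP, align_read, reverse_complement
    from .catalogue import Allele

    probe = AlleleCatalogue(
        alleles=[Allele(parent.allele_id, parent.sequence)],
        version_tag="repulsion-probe",
    )
    index = build_index(probe, config.k)
    positions = sorted({p for vs in member_vars for p in vs})
    frag_bases: dict[str, dict[int, str]] = defaultdict(dict)
    for read in reads:
        hits = align_read(read, index, config.max_mismatches_relaxed, "all_valid")
        for h in hits:
            seq = read.sequence.upper()
            if h.orientation == REVCOMP:
                seq = reverse_complement(seq)
            for pos in positions:
                i = pos - h.offset
                if 0 <= i < len(seq):
                    frag_bases[read.read_id].setdefault(pos, seq[i])
    anti = 0
    for bases in frag_bases.values():
        for mi, vi in enumerate(member_vars):
            for vj in member_vars[mi + 1 :]:
                for pi, alt_i in vi.items():
                    for pj, alt_j in vj.items():
                        if pi in bases and pj in bases:
                            i_alt = bases[pi] == alt_i
                            j_alt = bases[pj] == alt_j
                            i_ref = bases[pi] == parent.sequence[pi]
                            j_ref = bases[pj] == parent.sequence[pj]
                            if (i_alt and j_ref) or (i_ref and j_alt):
                                anti += 1
    return anti


def _parsimony_prune(reads, cat: AlleleCatalogue, call: GenotypeCall,
                     config: TypingConfig) -> None:
    """Drop called alleles without uniquely explained reads.

    Discovery is greedy: a partial reconstruction (a sub-haplotype of the
    true novel allele) or a parent spuriously covered by the union of two
    sibling alleles' reads can satisfy the complete-coverage criterion even
    though every read supporting it is equally explained by another called
    allele.  The kept genotype is the minimum explanation: alleles with at
    least ``prune_min_unique`` uniquely explained reads are forced, and
    remaining reads are covered greedily by largest marginal contribution —
    an allele whose marginal support stays below the threshold is dropped
    (one lone read can be a sequencing-error revertant that both completes
    a redundant allele's coverage and fakes support).
    """
    if len(call.called) < 2:
        return
    sub = cat.subset(sorted(call.allele_ids))
    index = build_index(sub, config.k)
    hits, _lengths = _align_all(reads, index, 0, "all_valid")
    read_sets: list[frozenset] = [
        frozenset(h.allele_id for h in hs) for hs in hits.values()
    ]
    unique: dict[str, int] = {a: 0 for a in call.called}
    for aset in read_sets:
        if len(aset) == 1:
            unique[next(iter(aset))] += 1
    kept = {a for a in call.called if unique[a] >= config.prune_min_unique}
    if not kept:
        return  # refuse to erase the whole genotype
    uncovered = [aset for aset in read_sets if not (aset & kept)]
    while uncovered:
        marginal: dict[str, int] = {}
        for aset in uncovered:
            for a in aset:
                marginal[a] = marginal.get(a, 0) + 1
        best = max(
            marginal,
            key=lambda a: (
                marginal[a],
                cat.get(a).provenance == "database",
                a,
            ),
        )
        if marginal[best] < config.prune_min_unique:
            break  # residual reads (errors/revertants) justify no allele
        kept.add(best)
        uncovered = [aset for aset in uncovered if best not in aset]
    for allele_id in list(call.called):
        if allele_id not in kept:
            del call.called[allele_id]


def _drop_orphan_novels(cat: AlleleCatalogue, call: GenotypeCall, audit) -> None:
    """Remove pruned, unreferenced novel alleles added during this run from
    the catalogue so intermediate reconstructions do not accumulate."""
    added_ids = [a for entry in audit for a in entry["added"]]
    parents_in_use = {
        a.parent_id for a in cat if a.parent_id and a.allele_id not in added_ids
    } | {a.parent_id for a in cat if a.parent_id and a.allele_id in call.called}
    for allele_id in reversed(added_ids):
        if allele_id in call.called or allele_id not in cat:
            continue
        if allele_id in parents_in_use:
            continue
        try:
            cat.remove(allele_id)
        except Exception:  # still referenced by a surviving variant
            pass


def _add_variant(cat, sequence, parent_id, config):
    from .catalogue import add_novel_allele

    return add_novel_allele(cat, sequence, parent_id, lab_tag=config.lab_tag)


def genotype_report(results: dict[str, TypingResult]) -> "pandas.DataFrame":  # noqa: F821
    """Cohort TSV-ready report: one row per individual x called allele."""
    import pandas as pd

    rows = []
    for individual, res in sorted(results.items()):
        for allele_id in sorted(res.genotype.allele_ids):
            ev = res.genotype.called[allele_id]
            rows.append(
                {
                    "individual": individual,
                    "allele_id": allele_id,
                    "stage": ev.stage,
                    "read_count": round(ev.read_count, 3),
                    "mean_depth": round(ev.mean_depth, 2),
                    "catalogue_version": res.genotype.catalogue_version,
                }
            )
    return pd.DataFrame(rows)
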