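"""Synthetic data generator: the hermetic test bed for the typing pipeline.

Emulates the structure the method assumes in real data: an MHC class I
allele catalogue in which alleles of a gene are a few percent diverged and
genes share an older common ancestor; copy-number-variable haplotypes
(2-3 classical and 2-5 non-classical genes per haplotype, duplications
allowed); full-sib/half-sib families with SNP flank markers over the MHC
region; co-dominant but unequal allele expression (Dirichlet weights,
shared between individuals with the same genotype); and paired-end 61-nt
reads with substitution errors.  Novel alleles are spawned from catalogue
parents and withheld from the public catalogue so the discovery machinery
can be scored against truth.

Everything is deterministic under the configured seed.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass

import numpy as np

from .align import ReadRecord, reverse_complement
from .catalogue import (
    CLASSICAL,
    NONCLASSICAL,
    Allele,
    AlleleCatalogue,
    translate_allele,
)
from .pedigree import Pedigree, PedigreeRecord, SnpMatrix

_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]
_MOTIF_CODONS = {
    "VPI": ("GTT", "CCT", "ATT"),
    "IPI": ("ATT", "CCT", "ATT"),
    "VLIK": ("GTG", "CTG", "ATC", "AAG"),
}
TM_MOTIF_NAMES = tuple(_MOTIF_CODONS)


@dataclass
class SimConfig:
    """Study-condition knobs of the generator.

    Defaults follow the sequencing design and haplotype structure the
    method was built for: 61-nt paired-end reads, ~1.1-kb class I cDNAs,
    2-3 classical / 2-5 non-classical genes per haplotype.
    """

    # pools are sized so four mutually allele-disjoint founder chromosomes
    # (up to 3 classical + 5 non-classical copies each) always fit
    n_classical_genes: int = 4
    n_nonclassical_genes: int = 5
    alleles_per_gene: int = 4
    allele_length: int = 1098  # codon multiple near the ~1.1 kb class I cDNA
    gene_divergence: float = 0.08    # per-base, gene ancestor vs family ancestor
    allele_divergence: float = 0.02  # per-base, allele vs gene ancestor
    n_novel: int = 1
    novel_substitutions: tuple[int, int] = (1, 3)
    classical_copy_range: tuple[int, int] = (2, 3)
    nonclassical_copy_range: tuple[int, int] = (2, 5)
    read_length: int = 61
    fragment_mean: float = 200.0
    fragment_sd: float = 20.0
    error_rate: float = 0.0
    n_pairs: int = 2000
    dirichlet_concentration: float = 5.0
    share_weights_by_genotype: bool = True
    nonclassical_early_stop_prob: float = 0.5
    decoy_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.gene_divergence, self.allele_divergence, self.error_rate,
                  self.decoy_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of [0,1]: {p}")
        if self.read_length > self.fragment_mean:
            raise ValueError("read_length must not exceed fragment_mean")
        if self.allele_length % 3:
            raise ValueError("allele_length must be a codon multiple")


# ---------------------------------------------------------------------------
# catalogue generation


def _mutate(codons: list[str], rate: float, rng) -> list[str]:
    seq = list("".join(codons))
    n = len(seq)
    k = rng.binomial(n, rate)
    for pos in rng.choice(n, size=k, replace=False):
        current = seq[pos]
        options = [b for b in "ACGT" if b != current]
        seq[pos] = options[int(rng.integers(3))]
    return ["".join(seq[i : i + 3]) for i in range(0, n, 3)]


def _enforce_features(
    codons: list[str],
    kind: str,
    rng,
    motif: str | None = None,
    motif_slot: int | None = None,
    early_stop: bool = False,
) -> list[str]:
    """Make a codon list a well-formed class I cDNA of the given kind.

    Classical: ATG start, stop only at the final codon, no VPI/IPI/VLIK in
    the translated product.  Non-classical: ATG start, the requested motif
    written at ``motif_slot``, optionally an early stop shortly after it.
    """
    codons = list(codons)
    codons[0] = "ATG"
    codons[-1] = "TAA"
    stop_at = None
    if kind == NONCLASSICAL:
        assert motif is not None and motif_slot is not None
        for i, codon in enumerate(_MOTIF_CODONS[motif]):
            codons[motif_slot + i] = codon
        if early_stop:
            stop_at = motif_slot + len(_MOTIF_CODONS[motif]) + 2
            codons[stop_at] = "TAA"
    guard = len(codons) - 1
    for i in range(1, guard):
        if codons[i] in _STOPS and i != stop_at:
            codons[i] = _CODONS[int(rng.integers(len(_CODONS)))]
            while codons[i] in ("ATG",):  # keep the start unique-ish, cosmetic
                codons[i] = _CODONS[int(rng.integers(len(_CODONS)))]
    if kind == CLASSICAL:
        # scrub accidental transmembrane motifs so feature checks stay crisp
        from Bio.Seq import Seq

        for _ in range(20):
            aa = str(Seq("".join(codons)).translate())
            hit = next((m for m in TM_MOTIF_NAMES if m in aa), None)
            if hit is None:
                break
            at = aa.index(hit)
            codons[at + 1] = _CODONS[int(rng.integers(len(_CODONS)))]
    return codons


def _haplotype_label(kind: str, i: int) -> str:
    return f"NC{i}" if kind == NONCLASSICAL else str(i)


def simulate_catalogue(cfg: SimConfig, rng=None) -> AlleleCatalogue:
    """Generate the public allele catalogue (family ancestor -> gene
    ancestors -> alleles, with class-specific protein features)."""
    rng = rng or np.random.default_rng(cfg.seed)
    n_codons = cfg.allele_length // 3
    ancestor = ["ATG"] + [
        _CODONS[int(rng.integers(len(_CODONS)))] for _ in range(n_codons - 2)
    ] + ["TAA"]
    alleles: list[Allele] = []
    seen: set[str] = set()
    genes = [(CLASSICAL, _haplotype_label(CLASSICAL, i + 1))
             for i in range(cfg.n_classical_genes)]
    genes += [(NONCLASSICAL, _haplotype_label(NONCLASSICAL, i + 1))
              for i in range(cfg.n_nonclassical_genes)]
    for kind, gene in genes:
        motif = TM_MOTIF_NAMES[int(rng.integers(len(TM_MOTIF_NAMES)))]
        motif_slot = n_codons - 45  # late in the coding sequence (TM region)
        gene_anc = _mutate(ancestor, cfg.gene_divergence, rng)
        gene_anc = _enforce_features(
            gene_anc, kind, rng, motif=motif, motif_slot=motif_slot,
            early_stop=False,
        )
        for a in range(cfg.alleles_per_gene):
            for attempt in range(100):
                early = kind == NONCLASSICAL and (
                    rng.random() < cfg.nonclassical_early_stop_prob
                )
                codons = _mutate(gene_anc, cfg.allele_divergence, rng)
                codons = _enforce_features(
                    codons, kind, rng, motif=motif, motif_slot=motif_slot,
                    early_stop=early,
                )
                seq = "".join(codons)
                if seq not in seen:
                    break
            else:
                raise RuntimeError(
                    "could not generate a distinct allele; lower divergence"
                )
            seen.add(seq)
            allele = Allele(
                allele_id=f"SIM-{gene}*{a + 1:03d}01",
                sequence=seq,
                gene_label=gene,
                class_kind=kind,
            )
            report = translate_allele(allele)
            if kind == NONCLASSICAL:
                assert report.nonclassical_features
            else:
                assert report.has_orf and not report.early_stop
            alleles.append(allele)
    return AlleleCatalogue(alleles=alleles, version_tag=f"sim-{cfg.seed}")


def spawn_novel_alleles(
    cat: AlleleCatalogue,
    n_novel: int,
    substitutions_range: tuple[int, int] = (1, 3),
    rng=None,
    seed: int = 0,
    class_kind: str | None = None,
    parents: list[str] | None = None,
    min_spacing: int | None = None,
) -> list[Allele]:
    """Derive withheld novel alleles from catalogue parents by k substitutions.

    k is drawn from ``substitutions_range`` (inclusive); substitutions avoid
    the start/stop/motif codons and are re-drawn if they break the parent's
    protein features, so the truth allele always passes validation.
    ``min_spacing`` forces variant positions at most this far apart (useful
    to generate read-linkable sibling alleles).  k = 0 is rejected: it would
    duplicate the parent.
    """
    rng = rng or np.random.default_rng(seed)
    lo, hi = substitutions_range
    if lo < 1:
        raise ValueError("novel alleles need at least one substitution")
    pool = [
        a
        for a in cat
        if (class_kind is None or a.class_kind == class_kind)
        and (parents is None or a.allele_id in parents)
    ]
    if not pool:
        raise ValueError("no eligible parent alleles")
    taken = {a.sequence for a in cat}
    novels: list[Allele] = []
    for i in range(n_novel):
        parent = pool[int(rng.integers(len(pool)))]
        k = int(rng.integers(lo, hi + 1))
        for attempt in range(200):
            seq = list(parent.sequence)
            length = len(seq)
            if min_spacing is not None:
                anchor = int(rng.integers(3, length - 3 - min_spacing))
                window = (anchor, anchor + min_spacing)
            else:
                window = (3, length - 3)
            positions = rng.choice(
                np.arange(window[0], window[1]), size=k, replace=False
            )
            for pos in positions:
                options = [b for b in "ACGT" if b != seq[pos]]
                seq[pos] = options[int(rng.integers(3))]
            candidate = "".join(seq)
            if candidate in taken:
                continue
            trial = Allele(
                allele_id=f"{parent.allele_id}_TRUE{i + 1}",
                sequence=candidate,
                gene_label=parent.gene_label,
                class_kind=parent.class_kind,
                provenance="novel_variant",
                parent_id=parent.allele_id,
            )
            report = translate_allele(trial)
            feature_ok = (
                report.nonclassical_features
                if parent.class_kind == NONCLASSICAL
                else report.has_orf and not report.early_stop
                and report.tm_motif == "none"
            )
            if feature_ok:
                taken.add(candidate)
                novels.append(trial)
                break
        else:
            raise RuntimeError("failed to spawn a feature-preserving novel allele")
    return novels


def spawn_distant_novel(
    cat: AlleleCatalogue,
    parent_id: str,
    divergence: float = 0.2,
    rng=None,
    seed: int = 0,
) -> Allele:
    """A novel allele far beyond the aligner's mismatch budget.

    At ~20% divergence essentially no 61-nt window of the new allele stays
    within three mismatches of the catalogue, so the allele is reachable
    only through de-novo assembly of unaligned reads.  Derived by
    codon-level mutation with the parent's class features re-imposed, so
    validation still accepts it.
    """
    rng = rng or np.random.default_rng(seed)
    parent = cat.get(parent_id)
    codons = [
        parent.sequence[i : i + 3] for i in range(0, len(parent.sequence), 3)
    ]
    n_codons = len(codons)
    taken = {a.sequence for a in cat}
    for _attempt in range(50):
        mutated = _mutate(codons, divergence, rng)
        mutated = _enforce_features(mutated, CLASSICAL, rng)
        seq = "".join(mutated)
        if seq in taken:
            continue
        trial = Allele(
            allele_id=f"{cat.prefix}_DIST1",
            sequence=seq,
            gene_label="UN",
            class_kind=CLASSICAL,
            provenance="novel_de_novo",
        )
        report = translate_allele(trial)
        if report.has_orf and not report.early_stop and report.tm_motif == "none":
            return trial
    raise RuntimeError("failed to spawn a distant novel allele")


def spawn_sibling_novel_pair(
    cat: AlleleCatalogue,
    parent_id: str,
    rng=None,
    seed: int = 0,
    variants_each: int = 2,
    span: int = 52,
) -> list[Allele]:
    """Two sibling novel alleles of one parent with variants in repulsion.

    All four variant positions fall inside one ``span``-nt window (sibling A
    in the first half, sibling B in the second), so same-haplotype linkage
    and cross-haplotype repulsion are both directly observable from 61-nt
    reads and mate pairs — the configuration phasing is meant to resolve.
    Feature checks are preserved as in :func:`spawn_novel_alleles`.
    """
    rng = rng or np.random.default_rng(seed)
    parent = cat.get(parent_id)
    length = len(parent.sequence)
    taken = {a.sequence for a in cat}
    half = span // 2
    for _attempt in range(200):
        anchor = int(rng.integers(3, length - 3 - span))
        windows = [(anchor, anchor + half), (anchor + half, anchor + span)]
        sibs = []
        for i, (lo, hi) in enumerate(windows):
            seq = list(parent.sequence)
            positions = rng.choice(np.arange(lo, hi), size=variants_each,
                                   replace=False)
            for pos in positions:
                options = [b for b in "ACGT" if b != seq[pos]]
                seq[pos] = options[int(rng.integers(3))]
            candidate = "".join(seq)
            if candidate in taken:
                break
            trial = Allele(
                allele_id=f"{parent_id}_SIB{i + 1}",
                sequence=candidate,
                gene_label=parent.gene_label,
                class_kind=parent.class_kind,
                provenance="novel_variant",
                parent_id=parent_id,
            )
            report = translate_allele(trial)
            feature_ok = (
                report.nonclassical_features
                if parent.class_kind == NONCLASSICAL
                else report.has_orf and not report.early_stop
                and report.tm_motif == "none"
            )
            if not feature_ok:
                break
            sibs.append(trial)
        if len(sibs) == 2 and sibs[0].sequence != sibs[1].sequence:
            return sibs
    raise RuntimeError("failed to spawn a feature-preserving sibling pair")


# ---------------------------------------------------------------------------
# families


@dataclass
class FamilyTruth:
    pedigree: Pedigree
    haplotypes: dict[str, frozenset]           # chromosome label -> allele ids
    genotypes: dict[str, set]                  # individual -> allele ids
    transmissions: dict[str, tuple[str, str]]  # offspring -> (pat, mat) labels
    weights: dict[str, dict[str, float]]       # individual -> allele -> weight
    snps: SnpMatrix


def _draw_haplotype(
    by_gene: dict[str, list[str]],
    genes: list[str],
    copy_range,
    rng,
    exclude: frozenset = frozenset(),
) -> frozenset:
    lo, hi = copy_range
    n_copies = int(rng.integers(lo, hi + 1))
    chosen: set[str] = set()
    for _ in range(n_copies):
        for _attempt in range(40):
            gene = genes[int(rng.integers(len(genes)))]
            pool = [a for a in by_gene[gene] if a not in chosen and a not in exclude]
            if pool:
                chosen.add(pool[int(rng.integers(len(pool)))])
                break
    return frozenset(chosen)


def simulate_family(
    cat: AlleleCatalogue,
    novels: list[Allele],
    cfg: SimConfig,
    rng=None,
    n_full_sibs: int = 8,
    n_half_sibs: int = 3,
    n_unrelated: int = 1,
    n_snps: int = 7,
    snp_region: tuple[int, int] = (27_545_231, 30_222_836),
) -> FamilyTruth:
    """Pedigree with founder haplotypes, offspring genotypes and SNP flanks.

    One sire x dam full sibship plus half sibs through the same sire (each
    with its own dam) and optional unrelated founders, mirroring a typical
    F2 family design.  SNP markers segregate with the MHC haplotypes (no
    recombination inside the short region).
    """
    rng = rng or np.random.default_rng(cfg.seed)
    by_gene: dict[str, list[str]] = {}
    for allele in list(cat) + list(novels):
        by_gene.setdefault(allele.gene_label, []).append(allele.allele_id)
    classical_genes = sorted(g for g in by_gene if not g.startswith("NC"))
    nonclassical_genes = sorted(g for g in by_gene if g.startswith("NC"))

    def full_haplotype(exclude: frozenset = frozenset()) -> frozenset:
        return _draw_haplotype(
            by_gene, classical_genes, cfg.classical_copy_range, rng, exclude
        ) | _draw_haplotype(
            by_gene, nonclassical_genes, cfg.nonclassical_copy_range, rng, exclude
        )

    haplotypes: dict[str, frozenset] = {}
    records: list[PedigreeRecord] = []
    genotypes: dict[str, set] = {}
    transmissions: dict[str, tuple[str, str]] = {}

    def add_founder(
        ind: str, labels: tuple[str, str], group: str,
        exclude: frozenset = frozenset(),
    ) -> None:
        # founder chromosomes are drawn allele-disjoint (within a parent and
        # against the excluded set): with hundreds of alleles per gene in
        # real populations two chromosomes carrying the identical allele is
        # the rare case, and fully distinct family haplotypes keep
        # pedigree-based haplotype derivation identifiable — the property
        # the validation machinery is built to test
        haplotypes[labels[0]] = full_haplotype(exclude=exclude)
        haplotypes[labels[1]] = full_haplotype(
            exclude=exclude | haplotypes[labels[0]]
        )
        records.append(PedigreeRecord(ind, None, None, group))
        genotypes[ind] = set(haplotypes[labels[0]] | haplotypes[labels[1]])

    add_founder("SIRE", ("P1", "P2"), "founder")
    sire_alleles = frozenset(haplotypes["P1"] | haplotypes["P2"])
    add_founder("DAM1", ("M1", "M2"), "founder", exclude=sire_alleles)
    extra_dams = [f"DAM{i + 2}" for i in range(n_half_sibs)]
    for j, dam in enumerate(extra_dams):
        add_founder(dam, (f"X{2 * j + 1}", f"X{2 * j + 2}"), "founder",
                    exclude=sire_alleles)

    def add_offspring(ind: str, sire: str, dam: str, pat_labels, mat_labels, group):
        pat = pat_labels[int(rng.integers(2))]
        mat = mat_labels[int(rng.integers(2))]
        records.append(PedigreeRecord(ind, sire, dam, group))
        genotypes[ind] = set(haplotypes[pat] | haplotypes[mat])
        transmissions[ind] = (pat, mat)

    for i in range(n_full_sibs):
        add_offspring(f"F2_{i + 1:02d}", "SIRE", "DAM1", ("P1", "P2"),
                      ("M1", "M2"), "fullsib")
    for j in range(n_half_sibs):
        add_offspring(
            f"HS_{j + 1:02d}", "SIRE", extra_dams[j], ("P1", "P2"),
            (f"X{2 * j + 1}", f"X{2 * j + 2}"), "halfsib",
        )
    for u in range(n_unrelated):
        add_founder(f"UNREL_{u + 1:02d}", (f"U{2 * u + 1}", f"U{2 * u + 2}"),
                    "control")

    # SNP flank markers: one biallelic vector per founder chromosome
    positions = sorted(
        int(p) for p in rng.integers(snp_region[0], snp_region[1], size=n_snps)
    )
    # Alternating marker informativity: even SNPs heterozygous in the sire
    # with a homozygous dam (paternal transmission readable), odd SNPs the
    # reverse — emulating the selection of family-informative chip markers.
    snp_alleles = {
        lab: ["AB"[int(b)] for b in rng.integers(0, 2, size=n_snps)]
        for lab in haplotypes
    }
    for s in range(n_snps):
        if s % 2 == 0:
            snp_alleles["P1"][s], snp_alleles["P2"][s] = "A", "B"
            hom = "AB"[int(rng.integers(2))]
            snp_alleles["M1"][s] = snp_alleles["M2"][s] = hom
        else:
            snp_alleles["M1"][s], snp_alleles["M2"][s] = "A", "B"
            hom = "AB"[int(rng.integers(2))]
            snp_alleles["P1"][s] = snp_alleles["P2"][s] = hom
    snp_alleles = {lab: "".join(v) for lab, v in snp_alleles.items()}
    chrom_of: dict[str, tuple[str, str]] = {}
    for rec in records:
        ind = rec.individual_id
        if ind in transmissions:
            chrom_of[ind] = transmissions[ind]
    chrom_of["SIRE"] = ("P1", "P2")
    chrom_of["DAM1"] = ("M1", "M2")
    for j, dam in enumerate(extra_dams):
        chrom_of[dam] = (f"X{2 * j + 1}", f"X{2 * j + 2}")
    for u in range(n_unrelated):
        chrom_of[f"UNREL_{u + 1:02d}"] = (f"U{2 * u + 1}", f"U{2 * u + 2}")

    import pandas as pd

    snp_rows = []
    individuals = [r.individual_id for r in records]
    for s in range(n_snps):
        row = {"snp_id": f"rs{s + 1:06d}", "chrom": "23", "pos": positions[s]}
        for ind in individuals:
            c1, c2 = chrom_of[ind]
            row[ind] = "".join(sorted(snp_alleles[c1][s] + snp_alleles[c2][s]))
        snp_rows.append(row)
    snps = SnpMatrix(pd.DataFrame(snp_rows))

    # expression weights: Dirichlet, shared across identical genotypes
    weights: dict[str, dict[str, float]] = {}
    by_genotype: dict[frozenset, dict[str, float]] = {}
    for ind in individuals:
        alleles = sorted(genotypes[ind])
        key = frozenset(alleles)
        if cfg.share_weights_by_genotype and key in by_genotype:
            weights[ind] = by_genotype[key]
            continue
        w = rng.dirichlet([cfg.dirichlet_concentration] * len(alleles))
        weights[ind] = dict(zip(alleles, w.tolist()))
        by_genotype[key] = weights[ind]

    return FamilyTruth(
        pedigree=Pedigree(records),
        haplotypes=haplotypes,
        genotypes=genotypes,
        transmissions=transmissions,
        weights=weights,
        snps=snps,
    )


# ---------------------------------------------------------------------------
# reads


@dataclass
class TruthPlacement:
    fragment_id: str
    allele_id: str
    start: int
    fragment_length: int


def simulate_reads(
    weights: dict[str, float],
    seq_of: dict[str, str],
    cfg: SimConfig,
    rng=None,
    id_prefix: str = "frag",
) -> tuple[list[ReadRecord], list[TruthPlacement]]:
    """Paired-end reads from an individual's weighted alleles.

    Fragments are drawn from alleles proportionally to expression weight,
    with normally distributed fragment lengths; mate 1 reads the fragment
    5' end forward, mate 2 the 3' end reverse-complemented.  Fragment
    placement models random fragmentation of whole transcript molecules: a
    molecule of length L yields ~L/f interior pieces plus the two terminal
    pieces, so a sampled fragment is anchored at the 5' (or 3') transcript
    end with probability f/L each, and uniform in between otherwise —
    without the terminal anchoring the first and last transcript bases
    would almost never be read and complete-coverage calling would be
    impossible at realistic depth.  Substitution
    errors are applied per base at ``error_rate``; base qualities are
    constant (unused downstream).  Oversized fragments are truncated to the
    allele.  A configurable fraction of random decoy pairs exercises the
    "unaligned reads are ignored" contract.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    allele_ids = sorted(weights)
    probs = np.array([weights[a] for a in allele_ids], dtype=float)
    if not np.isclose(probs.sum(), 1.0, atol=1e-6):
        raise ValueError("expression weights must sum to 1")
    probs = probs / probs.sum()
    rl = cfg.read_length
    reads: list[ReadRecord] = []
    truth: list[TruthPlacement] = []
    qual = "I" * rl

    def maybe_err(seq: str) -> str:
        if cfg.error_rate <= 0:
            return seq
        k = rng.binomial(len(seq), cfg.error_rate)
        if not k:
            return seq
        out = list(seq)
        for pos in rng.choice(len(seq), size=k, replace=False):
            options = [b for b in "ACGT" if b != out[pos]]
            out[pos] = options[int(rng.integers(3))]
        return "".join(out)

    choices = rng.choice(len(allele_ids), size=cfg.n_pairs, p=probs)
    lengths = np.maximum(
        rl, np.rint(rng.normal(cfg.fragment_mean, cfg.fragment_sd, cfg.n_pairs))
    ).astype(int)
    for i in range(cfg.n_pairs):
        allele_id = allele_ids[int(choices[i])]
        seq = seq_of[allele_id]
        frag_len = min(int(lengths[i]), len(seq))
        p_end = frag_len / len(seq)
        u = rng.random()
        if u < p_end:
            start = 0
        elif u < 2 * p_end:
            start = len(seq) - frag_len
        else:
            start = int(rng.integers(0, len(seq) - frag_len + 1))
        frag = seq[start : start + frag_len]
        rid = f"{id_prefix}{i:07d}"
        reads.append(ReadRecord(rid, 1, maybe_err(frag[:rl]), qual))
        reads.append(ReadRecord(rid, 2, maybe_err(reverse_complement(frag[-rl:])), qual))
        truth.append(TruthPlacement(rid, allele_id, start, frag_len))
    n_decoy = int(round(cfg.decoy_fraction * cfg.n_pairs))
    for d in range(n_decoy):
        rid = f"{id_prefix}decoy{d:05d}"
        for mate in (1, 2):
            seq = "".join("ACGT"[int(b)] for b in rng.integers(0, 4, size=rl))
            reads.append(ReadRecord(rid, mate, seq, qual))
    return reads, truth


def write_fastq(reads, path1, path2) -> None:
    """Write mate-split (optionally gzipped) FASTQ files."""

    def opener(p):
        return gzip.open(str(p), "wt") if str(p).endswith(".gz") else open(str(p), "w")

    with opener(path1) as f1, opener(path2) as f2:
        for r in reads:
            fh = f1 if r.mate != 2 else f2
            qual = r.qualities or "I" * len(r.sequence)
            fh.write(f"@{r.read_id}/{r.mate}\n{r.sequence}\n+\n{qual}\n")


def write_truth_json(truth: FamilyTruth, novels: list[Allele], path) -> None:
    payload = {
        "haplotypes": {k: sorted(v) for k, v in truth.haplotypes.items()},
        "genotypes": {k: sorted(v) for k, v in truth.genotypes.items()},
        "transmissions": truth.transmissions,
        "weights": truth.weights,
        "novel_alleles": {a.allele_id: a.sequence for a in novels},
    }
    with open(str(path), "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
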