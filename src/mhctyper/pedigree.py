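"""Pedigree-based validation of MHC genotypes.

The typing method is validated genetically: multi-allele MHC genotypes must
segregate as two parental haplotypes through full-sib/half-sib families, and
independently derived SNP haplotypes over the MHC region must partition the
offspring the same way.  This module provides SNP quality filtering (region,
call rate, minor allele frequency, Hardy-Weinberg exact test on founders),
Mendelian-consistency checks, exhaustive derivation of the four founder
haplotypes from full-sib data, and SNP-based flank tracking.

Recombination within the short MHC region is assumed absent; a violation
message notes recombination as a possible benign cause.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import product

import pandas as pd

log = logging.getLogger(__name__)

MISSING = "--"
GENOTYPES = ("AA", "AB", "BB")


@dataclass(frozen=True)
class PedigreeRecord:
    individual_id: str
    sire_id: str | None
    dam_id: str | None
    group_label: str = ""


@dataclass
class Pedigree:
    records: list[PedigreeRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._by_id = {r.individual_id: r for r in self.records}
        if len(self._by_id) != len(self.records):
            raise ValueError("duplicate individual in pedigree")
        for r in self.records:
            self._check_no_cycle(r.individual_id)

    def _check_no_cycle(self, start: str) -> None:
        frontier, seen = {start}, set()
        while frontier:
            nxt = set()
            for ind in frontier:
                rec = self._by_id.get(ind)
                if rec is None:
                    continue
                for parent in (rec.sire_id, rec.dam_id):
                    if parent == start:
                        raise ValueError(f"{start} is its own ancestor")
                    if parent and parent not in seen:
                        nxt.add(parent)
            seen |= frontier
            frontier = nxt

    def __iter__(self):
        return iter(self.records)

    def get(self, individual_id: str) -> PedigreeRecord:
        return self._by_id[individual_id]

    @property
    def individuals(self) -> list[str]:
        return [r.individual_id for r in self.records]

    def founders(self) -> list[str]:
        return [
            r.individual_id for r in self.records if not r.sire_id and not r.dam_id
        ]

    def full_sib_families(self) -> dict[tuple[str, str], list[str]]:
        """(sire, dam) -> offspring, restricted to pairs with >= 2 offspring."""
        fams: dict[tuple[str, str], list[str]] = {}
        for r in self.records:
            if r.sire_id and r.dam_id:
                fams.setdefault((r.sire_id, r.dam_id), []).append(r.individual_id)
        return {k: sorted(v) for k, v in fams.items() if len(v) >= 2}


def load_pedigree(path) -> Pedigree:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    records = [
        PedigreeRecord(
            row["individual"],
            row["sire"] or None,
            row["dam"] or None,
            row.get("group", ""),
        )
        for _, row in df.iterrows()
    ]
    return Pedigree(records)


def write_pedigree(ped: Pedigree, path) -> None:
    pd.DataFrame(
        [
            {
                "individual": r.individual_id,
                "sire": r.sire_id or "",
                "dam": r.dam_id or "",
                "group": r.group_label,
            }
            for r in ped
        ]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# SNP matrix and filtering


@dataclass
class SnpMatrix:
    """Biallelic genotypes: one row per SNP, columns snp_id/chrom/pos plus one
    column per individual with codes AA/AB/BB/--."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"snp_id", "chrom", "pos"}
        if not required <= set(self.table.columns):
            raise ValueError(f"SNP table needs columns {sorted(required)}")
        pos = self.table["pos"].to_numpy()
        if len(pos) > 1 and (pos[1:] < pos[:-1]).any():
            raise ValueError("SNP positions must be non-decreasing")
        bad = (
            self.table[self.individuals]
            .apply(lambda c: ~c.isin(GENOTYPES + (MISSING,)))
            .to_numpy()
            .any()
        )
        if bad:
            raise ValueError("genotype symbols outside {AA, AB, BB, --}")

    @property
    def individuals(self) -> list[str]:
        return [c for c in self.table.columns if c not in ("snp_id", "chrom", "pos")]

    def __len__(self) -> int:
        return len(self.table)


def load_snp_matrix(path) -> SnpMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna(MISSING)
    df["pos"] = df["pos"].astype(int)
    return SnpMatrix(df)


def write_snp_matrix(m: SnpMatrix, path) -> None:
    m.table.to_csv(path, sep="\t", index=False)


def hwe_exact_p(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Two-sided Hardy-Weinberg exact test.

    Sums, over all heterozygote counts compatible with the observed allele
    counts, the conditional probabilities not exceeding that of the observed
    configuration (the standard conditional exact test used for genotype-chip
    QC; chi-square approximations misbehave at the family-scale sample sizes
    this package deals with).
    """
    n = n_aa + n_ab + n_bb
    if n == 0:
        return 1.0
    n_a = 2 * n_aa + n_ab

    def log_prob(het: int) -> float:
        hom_a = (n_a - het) // 2
        hom_b = n - hom_a - het
        return (
            math.lgamma(n + 1)
            - math.lgamma(hom_a + 1)
            - math.lgamma(hom_b + 1)
            - math.lgamma(het + 1)
            + het * math.log(2)
            + math.lgamma(n_a + 1)
            + math.lgamma(2 * n - n_a + 1)
            - math.lgamma(2 * n + 1)
        )

    hets = [
        h for h in range(n_a % 2, min(n_a, 2 * n - n_a) + 1, 2)
    ]
    probs = {h: math.exp(log_prob(h)) for h in hets}
    observed = probs[n_ab]
    return min(1.0, sum(p for p in probs.values() if p <= observed + 1e-12))


def _genotype_counts(values) -> tuple[int, int, int]:
    vals = [v for v in values if v != MISSING]
    return vals.count("AA"), vals.count("AB"), vals.count("BB")


def filter_snps(
    m: SnpMatrix,
    region: tuple[int, int],
    call_rate_min: float = 0.98,
    maf_min: float = 0.05,
    hwe_p_min: float = 0.001,
    founders: list[str] | None = None,
) -> SnpMatrix:
    """Quality filter: genomic region, call rate, MAF and HWE exact test.

    The HWE test runs on founders only when a founder list is given, to
    avoid rejecting SNPs merely because of family structure.  An empty
    result is returned with a warning, not an error.
    """
    start, end = region
    if start >= end:
        raise ValueError("region start must be < end")
    individuals = m.individuals
    founder_cols = [f for f in (founders or individuals) if f in individuals]
    keep = []
    for _, row in m.table.iterrows():
        if not (start <= row["pos"] <= end):
            continue
        genos = [row[i] for i in individuals]
        called = [g for g in genos if g != MISSING]
        if not called or len(called) / len(genos) <= call_rate_min:
            continue
        n_a = sum(g.count("A") for g in called)
        n_b = sum(g.count("B") for g in called)
        maf = min(n_a, n_b) / (n_a + n_b) if n_a + n_b else 0.0
        if maf <= maf_min:
            continue
        f_aa, f_ab, f_bb = _genotype_counts(row[c] for c in founder_cols)
        if hwe_exact_p(f_aa, f_ab, f_bb) <= hwe_p_min:
            continue
        keep.append(row)
    if not keep:
        log.warning("SNP filter removed every marker")
        return SnpMatrix(m.table.iloc[0:0].copy())
    return SnpMatrix(pd.DataFrame(keep).reset_index(drop=True))


# ---------------------------------------------------------------------------
# Mendelian checks


@dataclass(frozen=True)
class Violation:
    individual_id: str
    kind: str  # "mhc_allele", "mhc_haplotype", "snp_trio"
    detail: str


@dataclass
class HaplotypeAssignment:
    """Four founder haplotypes and the per-offspring transmitted pair."""

    paternal: tuple[frozenset, frozenset]  # P1, P2
    maternal: tuple[frozenset, frozenset]  # M1, M2
    offspring_labels: dict[str, tuple[str, str]]  # id -> ("P1"|"P2", "M1"|"M2")
    status: str = "resolved"  # or "unresolvable"
    n_solutions: int = 1

    def haplotype(self, label: str) -> frozenset:
        side = self.paternal if label[0] == "P" else self.maternal
        return side[int(label[1]) - 1]


def check_mendelian(
    ped: Pedigree,
    genotypes: dict[str, set],
    assignment: HaplotypeAssignment | None = None,
) -> list[Violation]:
    """MHC allele-set consistency of offspring with their parents.

    Haplotype-free mode flags offspring alleles present in neither parent.
    With a haplotype assignment, the offspring set must additionally be
    explainable as (subset of one paternal haplotype) union (subset of one
    maternal haplotype).  Single-parent records check that parent only.
    """
    violations: list[Violation] = []
    for rec in ped:
        ind = rec.individual_id
        if ind not in genotypes or (not rec.sire_id and not rec.dam_id):
            continue
        child = set(genotypes[ind])
        sire = genotypes.get(rec.sire_id, None) if rec.sire_id else None
        dam = genotypes.get(rec.dam_id, None) if rec.dam_id else None
        parental = set()
        for p in (sire, dam):
            if p is not None:
                parental |= set(p)
        if sire is not None or dam is not None:
            orphan = child - parental if (sire is not None and dam is not None) else set()
            for allele in sorted(orphan):
                violations.append(
                    Violation(
                        ind,
                        "mhc_allele",
                        f"allele {allele} absent from both parents "
                        "(or an unscored recombination/mutation event)",
                    )
                )
        if assignment is not None and sire is not None and dam is not None:
            explained = any(
                child <= (assignment.paternal[i] | assignment.maternal[j])
                for i, j in product((0, 1), (0, 1))
            )
            if not explained:
                violations.append(
                    Violation(
                        ind,
                        "mhc_haplotype",
                        "allele set not explainable by one paternal plus one "
                        "maternal haplotype (possible recombination)",
                    )
                )
    return violations


def check_snp_trios(ped: Pedigree, m: SnpMatrix) -> list[Violation]:
    """Classic biallelic trio inconsistencies (e.g. AA x AA -> AB)."""
    violations: list[Violation] = []
    cols = set(m.individuals)
    for rec in ped:
        if rec.individual_id not in cols:
            continue
        sire_ok = rec.sire_id in cols
        dam_ok = rec.dam_id in cols
        if not sire_ok and not dam_ok:
            continue
        for _, row in m.table.iterrows():
            child = row[rec.individual_id]
            if child == MISSING:
                continue
            if sire_ok and dam_ok:
                sire_g, dam_g = row[rec.sire_id], row[rec.dam_id]
                if MISSING in (sire_g, dam_g):
                    continue
                # genotype symbols are sorted (AB, never BA)
                ok = any(
                    "".join(sorted(a + b)) == child for a in sire_g for b in dam_g
                )
            else:
                parent_g = row[rec.sire_id if sire_ok else rec.dam_id]
                if parent_g == MISSING:
                    continue
                ok = any(a in child for a in parent_g)
            if not ok:
                violations.append(
                    Violation(
                        rec.individual_id,
                        "snp_trio",
                        f"SNP {row['snp_id']}: child {child} impossible from parents",
                    )
                )
    return violations


# ---------------------------------------------------------------------------
# haplotype derivation


def _partitions(alleles: frozenset):
    """All 2-partitions of an allele set (first element anchored to half the
    space so each unordered pair appears once)."""
    items = sorted(alleles)
    if not items:
        yield frozenset(), frozenset()
        return
    head, rest = items[0], items[1:]
    for mask in range(2 ** len(rest)):
        h1 = {head}
        h2 = set()
        for i, allele in enumerate(rest):
            (h1 if mask >> i & 1 else h2).add(allele)
        yield frozenset(h1), frozenset(h2)


def derive_haplotypes(
    ped: Pedigree,
    genotypes: dict[str, set],
    family: tuple[str, str] | None = None,
    max_parent_alleles: int = 20,
) -> HaplotypeAssignment | list[Violation]:
    """Exhaustively derive the four founder haplotypes from full-sib data.

    Every 2-partition of each parent's allele set is scored against all
    offspring; an assignment is consistent when each offspring's set equals
    the union of one paternal and one maternal haplotype.  The unique
    solution (up to within-parent label swap) is returned; co-optimal
    distinct solutions are flagged ``unresolvable``; no solution yields a
    violation report.  Duplicated genes are supported naturally since
    haplotypes are allele sets keyed by allele (a haplotype may carry
    several alleles of one gene).
    """
    families = ped.full_sib_families()
    if family is None:
        if len(families) != 1:
            raise ValueError(
                f"expected exactly one full-sib family, found {len(families)}; "
                "pass family=(sire, dam)"
            )
        family = next(iter(families))
    sire_id, dam_id = family
    offspring = families[family]
    sire = frozenset(genotypes[sire_id])
    dam = frozenset(genotypes[dam_id])
    if len(sire) > max_parent_alleles or len(dam) > max_parent_alleles:
        raise ValueError("parent allele set too large for exhaustive search")

    child_sets = {c: frozenset(genotypes[c]) for c in offspring}

    def side_candidates(parent_set: frozenset) -> list[tuple[frozenset, frozenset]]:
        # every offspring inherits exactly one haplotype from this parent,
        # so that haplotype must be a subset of the offspring's allele set —
        # this necessary condition kills almost all of the 2^(n-1) partitions
        # before the joint sire x dam check
        out = []
        for h1, h2 in _partitions(parent_set):
            if all(h1 <= cs or h2 <= cs for cs in child_sets.values()):
                out.append((h1, h2))
        return out

    solutions = []
    for p1, p2 in side_candidates(sire):
        for m1, m2 in side_candidates(dam):
            labels = {}
            for child in offspring:
                child_set = child_sets[child]
                match = next(
                    (
                        (i, j)
                        for i, pat in enumerate((p1, p2))
                        for j, mat in enumerate((m1, m2))
                        if pat | mat == child_set
                    ),
                    None,
                )
                if match is None:
                    break
                labels[child] = (f"P{match[0] + 1}", f"M{match[1] + 1}")
            else:
                solutions.append(((p1, p2), (m1, m2), labels))

    if not solutions:
        return [
            Violation(
                child,
                "mhc_haplotype",
                f"no consistent 2x2 haplotype partition for family "
                f"{sire_id} x {dam_id} (possible recombination or miscall)",
            )
            for child in offspring
        ]

    def canonical(sol):
        (p1, p2), (m1, m2), _ = sol
        return (frozenset((p1, p2)), frozenset((m1, m2)))

    distinct = {canonical(s) for s in solutions}
    (p1, p2), (m1, m2), labels = solutions[0]
    return HaplotypeAssignment(
        paternal=(p1, p2),
        maternal=(m1, m2),
        offspring_labels=labels,
        status="resolved" if len(distinct) == 1 else "unresolvable",
        n_solutions=len(distinct),
    )


def gene_copy_counts(haplotype: frozenset, gene_of: dict[str, str]) -> dict[str, int]:
    """Copies per gene on one haplotype (reports duplication events)."""
    counts: dict[str, int] = {}
    for allele in haplotype:
        gene = gene_of.get(allele, "UN")
        counts[gene] = counts.get(gene, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# SNP flank tracking


def snp_haplotype_tracking(
    m: SnpMatrix, ped: Pedigree, family: tuple[str, str] | None = None
) -> pd.DataFrame:
    """Trace parental SNP flank haplotypes through a full-sib family.

    For each SNP at which a parent is heterozygous, the transmitted parental
    allele is inferred per offspring where unambiguous; offspring sharing a
    transmission vector share a flank label (P1/P2, M1/M2 by order of first
    appearance).  Returns one row per offspring with ``paternal_flank`` and
    ``maternal_flank`` labels, empty strings when no SNP is informative.
    """
    families = ped.full_sib_families()
    if family is None:
        if len(families) != 1:
            raise ValueError("pass family=(sire, dam) when multiple families exist")
        family = next(iter(families))
    sire_id, dam_id = family
    offspring = families[family]

    def transmitted(parent_g: str, other_g: str, child_g: str) -> str:
        if MISSING in (parent_g, other_g, child_g) or parent_g != "AB":
            return "?"
        options = set()
        for p_allele in set(parent_g):
            for o_allele in set(other_g):
                if "".join(sorted(p_allele + o_allele)) == child_g:
                    options.add(p_allele)
        return options.pop() if len(options) == 1 else "?"

    vectors: dict[str, dict[str, str]] = {"paternal": {}, "maternal": {}}
    for child in offspring:
        pat, mat = [], []
        for _, row in m.table.iterrows():
            pat.append(transmitted(row[sire_id], row[dam_id], row[child]))
            mat.append(transmitted(row[dam_id], row[sire_id], row[child]))
        vectors["paternal"][child] = "".join(pat)
        vectors["maternal"][child] = "".join(mat)

    def label_side(side: str, prefix: str) -> dict[str, str]:
        labels: dict[str, str] = {}
        classes: dict[str, str] = {}
        for child in offspring:
            vec = vectors[side][child]
            if not vec.strip("?"):
                labels[child] = ""
                continue
            matched = next(
                (
                    known
                    for known in classes
                    if all(a == b or "?" in (a, b) for a, b in zip(known, vec))
                ),
                None,
            )
            if matched is None:
                classes[vec] = f"{prefix}{len(classes) + 1}"
                labels[child] = classes[vec]
            else:
                labels[child] = classes[matched]
        return labels

    pat_labels = label_side("paternal", "P")
    mat_labels = label_side("maternal", "M")
    if all(v == "" for v in pat_labels.values()) and all(
        v == "" for v in mat_labels.values()
    ):
        log.warning("no informative SNP in family %s x %s", sire_id, dam_id)
    return pd.DataFrame(
        {
            "individual": offspring,
            "paternal_flank": [pat_labels[c] for c in offspring],
            "maternal_flank": [mat_labels[c] for c in offspring],
            "paternal_vector": [vectors["paternal"][c] for c in offspring],
            "maternal_vector": [vectors["maternal"][c] for c in offspring],
        }
    )
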