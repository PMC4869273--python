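"""Allele catalogue: data model and I/O for MHC class I cDNA allele collections.

The catalogue is the reference the whole pipeline aligns against.  It merges
classical (genes 1-6) and non-classical (NC1-NC5) class I alleles into a single
ordered collection, grows as novel alleles are discovered, and offers
protein-level utilities (translation, open-reading-frame and transmembrane
motif checks, group-discriminating residue scans) used to validate candidate
alleles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

UNASSIGNED = "UN"

CLASSICAL = "classical"
NONCLASSICAL = "nonclassical"

#: transmembrane motifs diagnostic for non-classical class I molecules,
#: checked longest first so VLIK wins over its IPI-free alternatives
TM_MOTIFS = ("VLIK", "VPI", "IPI")

_VALID_PROVENANCE = ("database", "novel_variant", "novel_de_novo")


class CatalogueError(ValueError):
    """Raised on malformed or inconsistent catalogue content."""


@dataclass(frozen=True)
class Allele:
    """One class I allele: identifier, gene assignment and cDNA sequence."""

    allele_id: str
    sequence: str
    gene_label: str = UNASSIGNED
    class_kind: str = CLASSICAL
    provenance: str = "database"
    parent_id: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise CatalogueError(f"allele {self.allele_id!r} has empty sequence")
        if self.provenance not in _VALID_PROVENANCE:
            raise CatalogueError(f"unknown provenance {self.provenance!r}")
        if (self.parent_id is not None) != (self.provenance == "novel_variant"):
            raise CatalogueError(
                f"allele {self.allele_id!r}: parent_id must be set exactly for "
                "novel_variant provenance"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def parse_gene_label(allele_id: str) -> str:
    """Extract the gene part of an IPD-style allele name.

    Names follow ``<prefix>-<gene>*<group><protein>`` (e.g. ``BoLA-2*01601``
    -> gene ``2``; ``BoLA-NC1*00101`` -> ``NC1``).  Anything that does not
    match the ``gene*group`` pattern is UNASSIGNED.
    """
    head, star, _ = allele_id.partition("*")
    if not star:
        return UNASSIGNED
    gene = head.rsplit("-", 1)[-1]
    return gene if gene else UNASSIGNED


@dataclass
class AlleleCatalogue:
    """Ordered, id-unique collection of alleles with a novel-allele counter."""

    alleles: list[Allele] = field(default_factory=list)
    version_tag: str = "v0"
    novel_counter: int = 1
    prefix: str = "BoLA"

    def __post_init__(self) -> None:
        self._by_id: dict[str, Allele] = {}
        for allele in self.alleles:
            if allele.allele_id in self._by_id:
                raise CatalogueError(f"duplicate allele id {allele.allele_id!r}")
            self._by_id[allele.allele_id] = allele

    def __len__(self) -> int:
        return len(self.alleles)

    def __contains__(self, allele_id: str) -> bool:
        return allele_id in self._by_id

    def __iter__(self):
        return iter(self.alleles)

    def get(self, allele_id: str) -> Allele:
        return self._by_id[allele_id]

    @property
    def ids(self) -> list[str]:
        return [a.allele_id for a in self.alleles]

    def find_by_sequence(self, sequence: str) -> Allele | None:
        sequence = sequence.upper()
        for allele in self.alleles:
            if allele.sequence == sequence:
                return allele
        return None

    def subset(self, allele_ids) -> "AlleleCatalogue":
        """New catalogue restricted to the given ids, original order kept."""
        wanted = set(allele_ids)
        missing = wanted - set(self._by_id)
        if missing:
            raise CatalogueError(f"unknown allele ids: {sorted(missing)}")
        return AlleleCatalogue(
            alleles=[a for a in self.alleles if a.allele_id in wanted],
            version_tag=self.version_tag,
            novel_counter=self.novel_counter,
            prefix=self.prefix,
        )

    def remove(self, allele_id: str) -> None:
        """Remove an allele (refused while another allele names it as parent)."""
        dependants = [
            a.allele_id for a in self.alleles if a.parent_id == allele_id
        ]
        if dependants:
            raise CatalogueError(
                f"cannot remove {allele_id!r}: parent of {dependants}"
            )
        allele = self._by_id.pop(allele_id)
        self.alleles.remove(allele)

    def _append(self, allele: Allele) -> None:
        if allele.allele_id in self._by_id:
            raise CatalogueError(f"duplicate allele id {allele.allele_id!r}")
        self.alleles.append(allele)
        self._by_id[allele.allele_id] = allele


def load_catalogue(
    fasta_source,
    class_kind: str | None = None,
    version_tag: str = "v0",
    max_n_fraction: float = 0.0,
) -> AlleleCatalogue:
    """Read an allele FASTA into a catalogue.

    Headers are IPD-style allele names; an optional ``gene=<label>
    class=<kind>`` pair in the description (as written by
    :func:`write_catalogue`) overrides inference.  Sequences are uppercased
    and U is converted to T.
    """
    cat = AlleleCatalogue(version_tag=version_tag)
    for rec in SeqIO.parse(str(fasta_source), "fasta"):
        seq = str(rec.seq).upper().replace("U", "T")
        if not seq:
            raise CatalogueError(f"record {rec.id!r} has empty sequence")
        n_frac = seq.count("N") / len(seq)
        if n_frac > max_n_fraction:
            raise CatalogueError(
                f"record {rec.id!r}: N fraction {n_frac:.3f} exceeds "
                f"allowed {max_n_fraction:.3f}"
            )
        attrs = dict(
            tok.split("=", 1) for tok in rec.description.split()[1:] if "=" in tok
        )
        gene = attrs.get("gene", parse_gene_label(rec.id))
        kind = attrs.get("class")
        if kind is None:
            kind = class_kind
        if kind is None:
            kind = NONCLASSICAL if gene.startswith("NC") else CLASSICAL
        if rec.id in cat:
            raise CatalogueError(f"duplicate allele id {rec.id!r}")
        cat._append(
            Allele(allele_id=rec.id, sequence=seq, gene_label=gene, class_kind=kind)
        )
    return cat


def write_catalogue(cat: AlleleCatalogue, path) -> None:
    """Write the catalogue as 60-column wrapped FASTA with gene/class attributes."""
    records = [
        SeqRecord(
            Seq(a.sequence),
            id=a.allele_id,
            description=f"gene={a.gene_label} class={a.class_kind}",
        )
        for a in cat
    ]
    SeqIO.write(records, str(path), "fasta")


def merge_catalogues(a: AlleleCatalogue, b: AlleleCatalogue) -> AlleleCatalogue:
    """Union of two catalogues, a-then-b order.

    Identical ids across the inputs are a hard error; identical sequences
    under distinct ids are retained (class I alleles assigned to different
    genes can share sequence stretches) with a logged warning.
    """
    collisions = set(a.ids) & set(b.ids)
    if collisions:
        raise CatalogueError(f"allele id collision on merge: {sorted(collisions)}")
    seen: dict[str, str] = {x.sequence: x.allele_id for x in a}
    for allele in b:
        if allele.sequence in seen:
            log.warning(
                "alleles %s and %s have identical sequences; both retained",
                seen[allele.sequence],
                allele.allele_id,
            )
    merged = AlleleCatalogue(
        alleles=list(a.alleles) + list(b.alleles),
        version_tag=f"{a.version_tag}+{b.version_tag}",
        novel_counter=max(a.novel_counter, b.novel_counter),
        prefix=a.prefix,
    )
    return merged


def add_novel_allele(
    cat: AlleleCatalogue,
    sequence: str,
    parent_id: str | None,
    lab_tag: str = "FBN",
    class_kind: str | None = None,
    de_novo: bool = False,
) -> tuple[AlleleCatalogue, str]:
    """Add a newly discovered allele, returning the extended catalogue and id.

    Variant alleles inherit gene and class from the parent and are named
    ``<parent_id>_<lab_tag><n>``; de-novo alleles without an assignable parent
    are named ``<prefix>_UN_<lab_tag><n>``.  The catalogue object is extended
    in place and also returned for convenience.
    """
    sequence = sequence.upper()
    existing = cat.find_by_sequence(sequence)
    if existing is not None:
        raise CatalogueError(
            f"sequence already present in catalogue as {existing.allele_id!r}"
        )
    n = cat.novel_counter
    if parent_id is not None and not de_novo:
        parent = cat.get(parent_id)
        allele = Allele(
            allele_id=f"{parent_id}_{lab_tag}{n}",
            sequence=sequence,
            gene_label=parent.gene_label,
            class_kind=class_kind or parent.class_kind,
            provenance="novel_variant",
            parent_id=parent_id,
        )
    else:
        allele = Allele(
            allele_id=f"{cat.prefix}_UN_{lab_tag}{n}",
            sequence=sequence,
            gene_label=UNASSIGNED,
            class_kind=class_kind or CLASSICAL,
            provenance="novel_de_novo",
        )
    cat._append(allele)
    cat.novel_counter = n + 1
    return cat, allele.allele_id


@dataclass(frozen=True)
class ProteinReport:
    allele_id: str
    aa_sequence: str
    has_orf: bool
    early_stop: bool
    tm_motif: str  # one of TM_MOTIFS or "none"

    @property
    def nonclassical_features(self) -> bool:
        """Early stop codon or a VPI/IPI/VLIK transmembrane motif."""
        return self.early_stop or self.tm_motif != "none"


def translate_allele(allele: Allele, frame_policy: str = "first_atg") -> ProteinReport:
    """Translate an allele cDNA and report class I protein features.

    ``first_atg`` starts at the first ATG (database cDNAs may carry 5' UTR);
    ``fixed_frame`` translates frame 0 from the first base.  The amino-acid
    sequence runs up to (excluding) the first stop codon; ``early_stop`` is
    set when that stop falls strictly before the final codon of the frame.
    """
    seq = allele.sequence.upper()
    if len(seq) < 3:
        raise CatalogueError(f"allele {allele.allele_id!r} shorter than one codon")
    if frame_policy == "first_atg":
        start = seq.find("ATG")
        if start < 0:
            return ProteinReport(allele.allele_id, "", False, False, "none")
    elif frame_policy == "fixed_frame":
        start = 0
    else:
        raise ValueError(f"unknown frame policy {frame_policy!r}")
    frame = seq[start:]
    frame = frame[: len(frame) - len(frame) % 3]
    n_codons = len(frame) // 3
    aa_full = str(Seq(frame).translate())
    stop_at = aa_full.find("*")
    if stop_at < 0:
        aa = aa_full
        early = False
    else:
        aa = aa_full[:stop_at]
        early = stop_at < n_codons - 1
    motif = next((m for m in TM_MOTIFS if m in aa), "none")
    return ProteinReport(allele.allele_id, aa, bool(aa), early, motif)


def protein_report_table(reports) -> "pandas.DataFrame":  # noqa: F821
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "allele_id": r.allele_id,
                "has_orf": r.has_orf,
                "early_stop": r.early_stop,
                "tm_motif": r.tm_motif,
            }
            for r in reports
        ]
    )


def group_discriminating_positions(
    aligned_aa_group_a,
    aligned_aa_group_b,
    include_gap_columns: bool = False,
    gap_char: str = "-",
) -> list[tuple[int, set, set]]:
    """Aligned columns where the residue sets of two groups are disjoint.

    Input sequences must come from one multiple alignment (equal lengths).
    Columns containing a gap in any sequence are skipped unless
    ``include_gap_columns`` (gaps are then ignored within the column).
    Returns 0-based positions with the two residue sets.
    """
    group_a = list(aligned_aa_group_a)
    group_b = list(aligned_aa_group_b)
    if not group_a or not group_b:
        return []
    lengths = {len(s) for s in group_a + group_b}
    if len(lengths) != 1:
        raise CatalogueError(f"aligned sequences differ in length: {sorted(lengths)}")
    width = lengths.pop()
    out = []
    for pos in range(width):
        col_a = {s[pos] for s in group_a}
        col_b = {s[pos] for s in group_b}
        if gap_char in col_a or gap_char in col_b:
            if not include_gap_columns:
                continue
            col_a.discard(gap_char)
            col_b.discard(gap_char)
            if not col_a or not col_b:
                continue
        if col_a.isdisjoint(col_b):
            out.append((pos, col_a, col_b))
    return out


def as_novel(allele: Allele, **changes) -> Allele:
    """Copy an allele with field changes (dataclass convenience)."""
    return replace(allele, **changes)
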